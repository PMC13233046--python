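"""File formats: FASTA, VCF v4.2 call sets, and the pipeline's TSV tables.

Call sets travel as one uncompressed VCF per sample (INFO keys ``SPECIES``,
``SAMPLE``, ``CONDITION``, flag ``GERMLINE`` for generator ground truth) or as
the equivalent 6-column TSV dialect (species, sample, chrom, pos, ref, alt).
A cohort directory is tied together by ``samples.tsv`` (species, sample,
condition, callable_bases, path) and ``metadata.tsv`` (species, mls_years,
body_mass_g, lq).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .categories import CATEGORIES, PYRIMIDINE_TRINUCS
from .spectrum import ContextSpectrum, SNVRecord, TrinucFreq


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Fasta:
    """Indexed FASTA access (mapping chrom -> sliceable sequence)."""
    return Fasta(str(path), sequence_always_upper=True)


# ---------------------------------------------------------------- VCF

def _vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("SPECIES", 1, "String", "Species of origin")
    header.info.add("SAMPLE", 1, "String", "Sample identifier")
    header.info.add("CONDITION", 1, "String", "control or treated")
    header.info.add("GERMLINE", 0, "Flag", "Simulated germline variant (ground truth)")
    return header


def write_vcf(
    records: Iterable[SNVRecord], path, contigs: Mapping[str, int]
) -> None:
    """Write calls as an uncompressed VCF v4.2, sorted by (chrom, pos)."""
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            row = vcf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos,
                alleles=(rec.ref, rec.alt),
            )
            row.info["SPECIES"] = rec.species
            row.info["SAMPLE"] = rec.sample
            row.info["CONDITION"] = rec.condition
            if rec.is_germline:
                row.info["GERMLINE"] = True
            vcf.write(row)


def read_vcf_calls(
    path,
    species: str | None = None,
    sample: str | None = None,
    condition: str | None = None,
) -> list[SNVRecord]:
    """Read SNV calls from a VCF; INFO keys supply provenance unless
    overridden by the keyword arguments. Non-SNV rows raise."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            ref, alt = row.ref, row.alts[0] if row.alts else None
            if alt is None or len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"{path}: non-SNV record at {row.chrom}:{row.pos}")
            out.append(
                SNVRecord(
                    species=species or str(row.info.get("SPECIES", "")),
                    sample=sample or str(row.info.get("SAMPLE", "")),
                    condition=condition or str(row.info.get("CONDITION", "control")),
                    chrom=row.chrom,
                    pos=row.pos,
                    ref=ref,
                    alt=alt,
                    is_germline=bool(row.info.get("GERMLINE", False)),
                )
            )
    return out


# ---------------------------------------------------------------- TSV dialect

CALL_TSV_COLUMNS = ["species", "sample", "chrom", "pos", "ref", "alt"]


def write_calls_tsv(records: Iterable[SNVRecord], path, condition_column: bool = True) -> None:
    rows = []
    for r in sorted(records, key=lambda r: (r.species, r.sample, r.chrom, r.pos)):
        row = {c: getattr(r, c) for c in CALL_TSV_COLUMNS}
        if condition_column:
            row["condition"] = r.condition
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path, condition: str | None = None) -> list[SNVRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CALL_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing call columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        cond = condition or getattr(row, "condition", "control")
        out.append(
            SNVRecord(
                species=row.species,
                sample=row.sample,
                condition=cond,
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                is_germline=bool(getattr(row, "is_germline", False)),
            )
        )
    return out


def read_calls(path, **kwargs) -> list[SNVRecord]:
    """Dispatch on extension: .vcf -> VCF reader, anything else -> TSV dialect."""
    if str(path).endswith(".vcf"):
        return read_vcf_calls(path, **kwargs)
    return read_calls_tsv(path, condition=kwargs.get("condition"))


# ---------------------------------------------------------------- tables

def write_spectrum_tsv(spectrum: ContextSpectrum, path) -> None:
    pd.DataFrame(
        {"category": list(CATEGORIES), "count": spectrum.counts}
    ).to_csv(path, sep="\t", index=False)


def read_spectrum_tsv(path, label: str = "") -> ContextSpectrum:
    df = pd.read_csv(path, sep="\t").set_index("category").loc[list(CATEGORIES)]
    return ContextSpectrum(counts=df["count"].to_numpy(), label=label)


def write_spectra_matrix_tsv(matrix: np.ndarray, group_labels: Sequence[str], path) -> None:
    pd.DataFrame(matrix, index=list(CATEGORIES), columns=list(group_labels)).rename_axis(
        "category"
    ).to_csv(path, sep="\t")


def read_spectra_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t").set_index("category").loc[list(CATEGORIES)]
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_trinuc_freq_tsv(freq: TrinucFreq, path) -> None:
    pd.DataFrame(
        {"trinucleotide": list(PYRIMIDINE_TRINUCS), "frequency": freq.freqs}
    ).to_csv(path, sep="\t", index=False)


def read_trinuc_freq_tsv(path) -> TrinucFreq:
    df = pd.read_csv(path, sep="\t").set_index("trinucleotide").loc[list(PYRIMIDINE_TRINUCS)]
    return TrinucFreq(freqs=df["frequency"].to_numpy())


def read_metadata_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"species", "mls_years", "body_mass_g", "lq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return df


def read_catalog_tsv(path):
    from .signatures import ReferenceCatalog

    return ReferenceCatalog.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------- cohort directory

def write_cohort(dataset, out_dir) -> Path:
    """Materialize a simulated cohort: per-species FASTA, per-sample VCF,
    samples.tsv manifest, metadata.tsv, and a germline ground-truth TSV."""
    out = Path(out_dir)
    (out / "fasta").mkdir(parents=True, exist_ok=True)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for species, seq in dataset.genomes.items():
        write_fasta({"chr1": seq}, out / "fasta" / f"{species}.fa")
    for sc in dataset.samples:
        path = out / "calls" / f"{sc.sample}.vcf"
        write_vcf(sc.records, path, {"chr1": len(dataset.genomes[sc.species])})
        manifest_rows.append(
            {
                "species": sc.species,
                "sample": sc.sample,
                "condition": sc.condition,
                "callable_bases": sc.callable_bases,
                "path": os.path.join("calls", f"{sc.sample}.vcf"),
            }
        )
    pd.DataFrame(manifest_rows).to_csv(out / "samples.tsv", sep="\t", index=False)
    dataset.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    germ_rows = [
        {"species": sp, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        for sp, sites in dataset.germline_truth.items()
        for chrom, pos, ref, alt in sites
    ]
    pd.DataFrame(
        germ_rows, columns=["species", "chrom", "pos", "ref", "alt"]
    ).to_csv(out / "germline_truth.tsv", sep="\t", index=False)
    return out


def read_cohort(cohort_dir):
    """Load a cohort directory written by :func:`write_cohort` back into
    memory (genome sequences as plain strings)."""
    from .simulate import CohortDataset, SampleCalls
    from .spectrum import trinucleotide_frequencies

    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "samples.tsv", sep="\t")
    metadata = read_metadata_tsv(root / "metadata.tsv")
    genomes, freqs = {}, {}
    for species in metadata["species"]:
        fa = read_fasta(root / "fasta" / f"{species}.fa")
        genomes[species] = str(fa["chr1"])
        freqs[species] = trinucleotide_frequencies(genomes[species])
    samples = []
    for row in manifest.itertuples(index=False):
        records = read_calls(
            root / row.path,
            species=row.species,
            sample=row.sample,
            condition=row.condition,
        )
        samples.append(
            SampleCalls(
                species=row.species,
                sample=row.sample,
                condition=row.condition,
                records=records,
                callable_bases=int(row.callable_bases),
            )
        )
    germ_df = pd.read_csv(root / "germline_truth.tsv", sep="\t")
    germline_truth: dict[str, list] = {sp: [] for sp in metadata["species"]}
    for row in germ_df.itertuples(index=False):
        germline_truth[row.species].append((str(row.chrom), int(row.pos), row.ref, row.alt))
    return CohortDataset(
        genomes=genomes,
        trinuc_freqs=freqs,
        metadata=metadata,
        samples=samples,
        germline_truth=germline_truth,
    )
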