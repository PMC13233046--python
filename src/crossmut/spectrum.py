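"""SNV context classification, 96-channel spectra, and cross-species humanization.

Mutation spectra from different species are not directly comparable because
genome trinucleotide composition differs between species. ``humanize_counts``
rescales each category count by the ratio of target-genome (human) to
species-genome frequency of the category's trinucleotide, putting all species
on a common compositional footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .categories import (
    CATEGORIES,
    CATEGORY_TRINUC,
    PYRIMIDINE_TRINUCS,
    PYRIMIDINES,
    category_index,
    trinuc32_codes,
    encode_sequence,
)

logger = logging.getLogger(__name__)

N_CATEGORIES = 96
N_TRINUCS = 32

VALID_BASES = frozenset("ACGT")


class ReferenceMismatchError(ValueError):
    """The call's REF base disagrees with the reference genome."""


class AmbiguousContextError(ValueError):
    """Flank off the contig end or containing an ambiguity code; record is skippable."""


@dataclass(frozen=True)
class SNVRecord:
    """One somatic single-nucleotide variant call with provenance.

    ``pos`` is 1-based. ``condition`` is ``"control"`` or ``"treated"``.
    ``is_germline`` marks generator ground truth only; the germline filter
    never reads it.
    """

    species: str
    sample: str
    condition: str
    chrom: str
    pos: int
    ref: str
    alt: str
    is_germline: bool = False

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"invalid alleles {self.ref}>{self.alt}")
        if self.condition not in ("control", "treated"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class ContextSpectrum:
    """Counts over the 96 trinucleotide-context substitution categories.

    ``counts`` follows the canonical category order in
    :data:`crossmut.categories.CATEGORIES`. Entries may be non-integer after
    humanization. ``n_skipped`` tallies records dropped for ambiguous context.
    """

    counts: np.ndarray
    label: str = ""
    n_skipped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CATEGORIES,):
            raise ValueError(f"expected 96 categories, got shape {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("negative category count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class TrinucFreq:
    """Genome-wide frequencies of the 32 strand-collapsed trinucleotides.

    Ordered as :data:`crossmut.categories.PYRIMIDINE_TRINUCS`; sums to 1.
    """

    freqs: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (N_TRINUCS,):
            raise ValueError(f"expected 32 trinucleotides, got shape {self.freqs.shape}")
        if np.any(self.freqs < 0):
            raise ValueError("negative trinucleotide frequency")
        if not np.isclose(self.freqs.sum(), 1.0, atol=1e-9):
            raise ValueError(f"frequencies sum to {self.freqs.sum()}, not 1")

    def __getitem__(self, trinuc: str) -> float:
        return float(self.freqs[PYRIMIDINE_TRINUCS.index(trinuc)])


def _fetch_context(genome, chrom: str, pos: int) -> str:
    """Uppercase 3-mer centered on 1-based ``pos``; raises AmbiguousContextError
    at contig edges. ``genome`` is any mapping from chrom to a sliceable
    sequence (str, pyfaidx.FastaRecord, Bio.Seq)."""
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc
    if pos < 2 or pos + 1 > len(seq):
        raise AmbiguousContextError(f"{chrom}:{pos} flank off contig end")
    return str(seq[pos - 2 : pos + 1]).upper()


def classify_context(snv: SNVRecord, genome) -> int:
    """Classify an SNV into its pyrimidine-strand 96-category index.

    The reference base at ``snv.pos`` must equal ``snv.ref``
    (:class:`ReferenceMismatchError` otherwise). Purine-reference calls are
    reverse-complemented onto the pyrimidine strand before lookup. Flanks off
    the contig end or containing non-ACGT codes raise
    :class:`AmbiguousContextError`, which callers may treat as a skip.
    """
    tri = _fetch_context(genome, snv.chrom, snv.pos)
    if tri[1] != snv.ref:
        raise ReferenceMismatchError(
            f"{snv.chrom}:{snv.pos} REF {snv.ref} != genome {tri[1]}"
        )
    if tri[0] not in VALID_BASES or tri[2] not in VALID_BASES:
        raise AmbiguousContextError(f"{snv.chrom}:{snv.pos} ambiguous flank {tri}")
    return category_index(snv.ref, snv.alt, tri[0], tri[2])


def build_spectrum(
    snvs: Iterable[SNVRecord], genome, label: str = ""
) -> ContextSpectrum:
    """Tally SNVs into a 96-channel spectrum.

    Records with ambiguous context (flank off the contig or containing N) are
    skipped with a logged warning and counted in ``n_skipped``; a REF mismatch
    with the genome is a data-integrity error and propagates.
    """
    counts = np.zeros(N_CATEGORIES)
    skipped = 0
    for snv in snvs:
        try:
            counts[classify_context(snv, genome)] += 1
        except AmbiguousContextError as exc:
            logger.warning("skipping record: %s", exc)
            skipped += 1
    return ContextSpectrum(counts=counts, label=label, n_skipped=skipped)


def trinucleotide_frequencies(sequence, mask=None) -> TrinucFreq:
    """Strand-collapsed trinucleotide frequencies of a sequence.

    A width-3 window slides with step 1; windows containing non-ACGT codes are
    skipped; purine-centered windows are counted as their reverse complement.
    ``mask`` optionally restricts counting to 0-based half-open ``(start, end)``
    intervals (windows whose center lies in an interval).

    Raises ``ValueError`` if no valid window exists.
    """
    seq = str(sequence)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one trinucleotide window")
    codes = encode_sequence(seq)
    tri = trinuc32_codes(codes)
    if mask is not None:
        keep = np.zeros(tri.size, dtype=bool)
        centers = np.arange(1, len(seq) - 1)  # 0-based window centers
        for start, end in mask:
            keep |= (centers >= start) & (centers < end)
        tri = tri[keep]
    tri = tri[tri >= 0]
    if tri.size == 0:
        raise ValueError("no valid trinucleotide window in sequence")
    counts = np.bincount(tri, minlength=N_TRINUCS).astype(float)
    return TrinucFreq(freqs=counts / counts.sum())


def genome_trinucleotide_frequencies(genome, mask: Mapping | None = None) -> TrinucFreq:
    """Pooled trinucleotide frequencies over all contigs of a genome mapping.

    ``mask`` maps chrom name to intervals as accepted by
    :func:`trinucleotide_frequencies`.
    """
    counts = np.zeros(N_TRINUCS)
    for chrom in genome.keys():
        seq = str(genome[chrom])
        if len(seq) < 3:
            continue
        tri = trinuc32_codes(encode_sequence(seq))
        if mask is not None:
            keep = np.zeros(tri.size, dtype=bool)
            centers = np.arange(1, len(seq) - 1)
            for start, end in mask.get(chrom, ()):
                keep |= (centers >= start) & (centers < end)
            tri = tri[keep]
        tri = tri[tri >= 0]
        counts += np.bincount(tri, minlength=N_TRINUCS)
    if counts.sum() == 0:
        raise ValueError("no valid trinucleotide window in genome")
    return TrinucFreq(freqs=counts / counts.sum())


def humanize_counts(
    spectrum: ContextSpectrum,
    f_species: TrinucFreq,
    f_target: TrinucFreq,
    preserve_total: bool = False,
) -> ContextSpectrum:
    """Rescale category counts by target/species trinucleotide-frequency ratios.

    ``counts'[c] = counts[c] * f_target(t(c)) / f_species(t(c))`` where ``t(c)``
    is the pyrimidine-strand trinucleotide of category ``c``; the three
    substitution classes sharing a trinucleotide share one ratio. Output counts
    may be non-integer and are not renormalized unless ``preserve_total``
    rescales them back to the input total (sensitivity mode).

    A zero species frequency at a trinucleotide with non-zero counts is an
    error naming the trinucleotide — never a silent pseudocount.
    """
    fs = f_species.freqs[CATEGORY_TRINUC]
    ft = f_target.freqs[CATEGORY_TRINUC]
    bad = (fs == 0) & (spectrum.counts > 0)
    if np.any(bad):
        tri = PYRIMIDINE_TRINUCS[CATEGORY_TRINUC[np.flatnonzero(bad)[0]]]
        raise ValueError(
            f"species trinucleotide frequency is zero for {tri} "
            "but the spectrum has counts there"
        )
    ratio = np.divide(ft, fs, out=np.zeros(N_CATEGORIES), where=fs > 0)
    counts = spectrum.counts * ratio
    if preserve_total and counts.sum() > 0:
        counts = counts * (spectrum.total / counts.sum())
    return ContextSpectrum(
        counts=counts, label=spectrum.label, n_skipped=spectrum.n_skipped
    )
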