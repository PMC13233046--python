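"""End-to-end orchestration: filter -> burden/ΔSNV -> spectra/humanize ->
regressions -> signatures, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import DeltaResult, SampleBurden, delta_snv, germline_filter
from .categories import CATEGORIES
from .comparative import (
    RegressionResult,
    fit_regression,
    leave_one_out,
    paired_t_test,
)
from .config import PipelineConfig, stage_seed
from .io import (
    read_catalog_tsv,
    read_cohort,
    write_spectra_matrix_tsv,
    write_trinuc_freq_tsv,
)
from .signatures import (
    SignatureSet,
    SpectraMatrix,
    contribution_fractions,
    match_signatures,
    nmf_extract,
    signature_lifespan_association,
    synthetic_reference_catalog,
)
from .spectrum import build_spectrum, humanize_counts

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class PipelineResult:
    """In-memory results of a run; the same numbers are written as TSV/JSON
    into the output directory."""

    config: PipelineConfig
    metadata: pd.DataFrame
    burdens: pd.DataFrame
    deltas: list[DeltaResult]
    regressions: list[RegressionResult]
    spectra_raw: np.ndarray
    spectra_humanized: np.ndarray
    group_labels: list[str]
    signature_set: SignatureSet
    matches: pd.DataFrame
    fractions: pd.DataFrame
    s1_treated_vs_control: tuple[float, float]
    association: tuple[float, float]
    filter_tallies: dict[str, dict]
    skip_tallies: dict[str, int]
    out_dir: Path


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Parse-and-cross-reference check of a file-backed cohort.

    Errors: unparseable files, species present in call sets but absent from
    metadata, non-positive callable bases, and VCF REF bases disagreeing with
    the FASTA (one error per offending record). Warnings never raise.
    """
    report = ValidationReport()
    if config.simulate:
        return report
    if not config.cohort_dir:
        report.errors.append("cohort_dir not set and simulate=False")
        return report
    try:
        dataset = read_cohort(config.cohort_dir)
    except Exception as exc:
        report.errors.append(f"cohort unreadable: {exc}")
        return report
    meta_species = set(dataset.metadata["species"])
    for sc in dataset.samples:
        if sc.species not in meta_species:
            report.errors.append(
                f"species {sc.species!r} in call sets but absent from metadata"
            )
        if sc.callable_bases <= 0:
            report.errors.append(
                f"sample {sc.sample}: callable_bases must be positive"
            )
        genome = dataset.genomes.get(sc.species, "")
        for rec in sc.records:
            if rec.pos > len(genome):
                report.errors.append(
                    f"{sc.sample} {rec.chrom}:{rec.pos} beyond contig end"
                )
            elif genome[rec.pos - 1].upper() != rec.ref:
                report.errors.append(
                    f"{sc.sample} {rec.chrom}:{rec.pos} REF {rec.ref} "
                    f"!= FASTA {genome[rec.pos - 1].upper()}"
                )
    for sp in meta_species - {sc.species for sc in dataset.samples}:
        report.warnings.append(f"species {sp!r} has metadata but no call sets")
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle.

    Stage order: load/simulate -> germline filter -> per-sample burdens and
    per-species ΔSNV -> per-group spectra, trinucleotide frequencies and
    humanization -> covariate regressions with leave-one-out -> NMF signature
    extraction, catalog matching, contribution fractions, paired S1 test, and
    the signature-vs-lifespan association. A stage failure aborts with the
    stage named; partial outputs stay on disk next to a FAILED marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    try:
        return _run(config, out)
    except Exception as exc:
        stage = exc.stage if isinstance(exc, PipelineError) else "unknown"
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


def _run(config: PipelineConfig, out: Path) -> PipelineResult:
    dataset = _load(config)
    meta = dataset.metadata

    # ---- germline filtering, per species over pooled samples
    filtered, tallies = {}, {}
    for species in meta["species"]:
        pooled = [r for sc in dataset.calls_for(species) for r in sc.records]
        kept, tally = _stage("germline_filter")(germline_filter)(
            pooled, recurrence_threshold=config.recurrence_threshold
        )
        filtered[species] = kept
        tallies[species] = asdict(tally) | {"n_kept": tally.n_kept}

    # ---- burdens and ΔSNV
    boot_seed = stage_seed(config.seed, "bootstrap")
    burdens_rows, deltas = [], []
    for species in meta["species"]:
        by_sample = {sc.sample: sc for sc in dataset.calls_for(species)}
        counts = {name: 0 for name in by_sample}
        for rec in filtered[species]:
            counts[rec.sample] += 1
        sample_burdens = [
            SampleBurden(
                species=species,
                sample=name,
                condition=sc.condition,
                n_snv=counts[name],
                callable_bases=sc.callable_bases,
            )
            for name, sc in by_sample.items()
        ]
        deltas.append(
            _stage("delta_snv")(delta_snv)(
                sample_burdens,
                n_boot=config.n_boot,
                seed=boot_seed,
                paired=config.paired_delta,
            )
        )
        burdens_rows += [
            asdict(b) | {"freq_per_mb": b.freq_per_mb} for b in sample_burdens
        ]
    burdens = pd.DataFrame(burdens_rows).sort_values(["species", "sample"]).reset_index(drop=True)

    # ---- spectra and humanization
    target = config.target_species
    if target not in dataset.trinuc_freqs:
        raise PipelineError(
            "humanize", ValueError(f"target species {target!r} not in cohort")
        )
    f_target = dataset.trinuc_freqs[target]
    group_labels, raw_cols, hum_cols, skip_tallies = [], [], [], {}
    for species in meta["species"]:
        genome = {"chr1": dataset.genomes[species]}
        for condition in ("control", "treated"):
            records = [r for r in filtered[species] if r.condition == condition]
            label = f"{species}:{condition}"
            spec = _stage("spectrum")(build_spectrum)(records, genome, label=label)
            hum = _stage("humanize")(humanize_counts)(
                spec,
                dataset.trinuc_freqs[species],
                f_target,
                preserve_total=config.preserve_total,
            )
            group_labels.append(label)
            raw_cols.append(spec.counts)
            hum_cols.append(hum.counts)
            skip_tallies[label] = spec.n_skipped
    spectra_raw = np.column_stack(raw_cols)
    spectra_hum = np.column_stack(hum_cols)

    # ---- regressions vs MLS / body mass / LQ, with leave-one-out on MLS
    points = _regression_points(burdens, meta, config)
    regressions = []
    for covariate, col in (("mls", "mls_years"), ("mass", "body_mass_g"), ("lq", "lq")):
        x = points[col].to_numpy(dtype=float)
        if covariate == "mass" and config.log10_mass:
            x = np.log10(x)
        regressions.append(
            _stage("regression")(fit_regression)(x, points["y"], covariate=covariate)
        )
    loo_points = points.rename(columns={"mls_years": "x"})
    exclusions = [[sp] for sp in config.loo_species if sp in set(points["species"])]
    regressions += _stage("regression")(leave_one_out)(
        loo_points, exclusions, covariate="mls"
    )

    # ---- signature extraction and downstream analyses
    matrix = SpectraMatrix(matrix=spectra_hum, group_labels=group_labels)
    sig_set = _stage("nmf")(nmf_extract)(
        matrix,
        k=config.k,
        max_iter=config.nmf_max_iter,
        tol=config.nmf_tol,
        n_restarts=config.n_restarts,
        seed=stage_seed(config.seed, "nmf"),
    )
    catalog = (
        read_catalog_tsv(config.catalog_path)
        if config.catalog_path
        else synthetic_reference_catalog()
    )
    matches = _stage("match")(match_signatures)(sig_set, catalog)
    fractions = _stage("fractions")(contribution_fractions)(sig_set)
    s1_control = [fractions.loc["S1", f"{sp}:control"] for sp in meta["species"]]
    s1_treated = [fractions.loc["S1", f"{sp}:treated"] for sp in meta["species"]]
    s1_test = _stage("paired_test")(paired_t_test)(s1_control, s1_treated)
    association = _stage("association")(signature_lifespan_association)(
        fractions,
        meta,
        signature=config.association_signature,
        condition=config.association_condition,
        exclude=config.association_exclude,
    )

    result = PipelineResult(
        config=config,
        metadata=meta,
        burdens=burdens,
        deltas=deltas,
        regressions=regressions,
        spectra_raw=spectra_raw,
        spectra_humanized=spectra_hum,
        group_labels=group_labels,
        signature_set=sig_set,
        matches=matches,
        fractions=fractions,
        s1_treated_vs_control=s1_test,
        association=association,
        filter_tallies=tallies,
        skip_tallies=skip_tallies,
        out_dir=out,
    )
    _write_outputs(result, dataset)
    return result


def _load(config: PipelineConfig):
    from .simulate import default_cohort_configs, simulate_cohort

    if config.simulate:
        configs = default_cohort_configs(
            genome_length=config.genome_length,
            callable_bases=config.callable_bases,
            n_control=config.n_control,
            n_treated=config.n_treated,
        )
        return _stage("simulate")(simulate_cohort)(
            configs, seed=stage_seed(config.seed, "simulate")
        )
    report = validate_inputs(config)
    if not report.ok:
        raise PipelineError("validate", ValueError("; ".join(report.errors)))
    return _stage("load")(read_cohort)(config.cohort_dir)


def _regression_points(burdens: pd.DataFrame, meta: pd.DataFrame, config) -> pd.DataFrame:
    """Regression response per config: per-treated-sample excess frequency
    (sample freq minus the species' control mean) or per-species ΔSNV means."""
    rows = []
    for species, grp in burdens.groupby("species"):
        ctrl_mean = grp.loc[grp["condition"] == "control", "freq_per_mb"].mean()
        treated = grp.loc[grp["condition"] == "treated", "freq_per_mb"]
        if config.regression_points == "per_sample":
            rows += [{"species": species, "y": f - ctrl_mean} for f in treated]
        else:
            rows.append({"species": species, "y": treated.mean() - ctrl_mean})
    return pd.DataFrame(rows).merge(meta, on="species")


def _write_outputs(result: PipelineResult, dataset) -> None:
    out = result.out_dir
    config = result.config
    result.burdens.to_csv(out / "burdens.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(d) for d in result.deltas]).to_csv(
        out / "delta_snv.tsv", sep="\t", index=False
    )
    reg = pd.DataFrame(
        [
            {
                "covariate": r.covariate,
                "excluded": ",".join(r.excluded),
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
                "n": r.n,
            }
            for r in result.regressions
        ]
    )
    reg.to_csv(out / "regressions.tsv", sep="\t", index=False)
    write_spectra_matrix_tsv(result.spectra_raw, result.group_labels, out / "spectra_raw.tsv")
    write_spectra_matrix_tsv(
        result.spectra_humanized, result.group_labels, out / "spectra_humanized.tsv"
    )
    for species, freq in dataset.trinuc_freqs.items():
        write_trinuc_freq_tsv(freq, out / f"trinuc_freq_{species}.tsv")
    write_spectra_matrix_tsv(
        result.signature_set.W, result.signature_set.signature_names, out / "signatures_W.tsv"
    )
    pd.DataFrame(
        result.signature_set.H,
        index=result.signature_set.signature_names,
        columns=result.group_labels,
    ).rename_axis("signature").to_csv(out / "signatures_H.tsv", sep="\t")
    result.matches.to_csv(out / "signature_matches.tsv", sep="\t", index=False)
    result.fractions.rename_axis("signature").to_csv(out / "signature_fractions.tsv", sep="\t")

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in ("simulate", "bootstrap", "nmf")
        },
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "input_checksums": _input_checksums(config),
        "filter_tallies": result.filter_tallies,
        "context_skips": result.skip_tallies,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _write_summary(result, out)
    if config.make_figures:
        _write_figures(result, out)


def _input_checksums(config: PipelineConfig) -> dict:
    sums = {}
    if config.cohort_dir:
        root = Path(config.cohort_dir)
        for path in sorted(root.rglob("*")):
            if path.is_file() and path.suffix in (".vcf", ".tsv", ".fa", ".fasta"):
                sums[str(path.relative_to(root))] = _sha256(path)
    if config.catalog_path:
        sums[Path(config.catalog_path).name] = _sha256(Path(config.catalog_path))
    return sums


def _write_summary(result: PipelineResult, out: Path) -> None:
    lines = [f"crossmut {__version__} run summary", ""]
    lines.append("Per-species excess mutation frequency (per Mb):")
    for d in result.deltas:
        lines.append(
            f"  {d.species:<16} dSNV={d.delta_snv:.3f} "
            f"[{d.ci_low:.3f}, {d.ci_high:.3f}] "
            f"(control {d.mean_control:.3f}, treated {d.mean_treated:.3f})"
        )
    lines.append("")
    lines.append("Regressions (excess frequency vs covariate):")
    for r in result.regressions:
        excl = f" excluding {','.join(r.excluded)}" if r.excluded else ""
        lines.append(
            f"  {r.covariate:<5}{excl}: slope={r.slope:.4g} R2={r.r_squared:.4f} "
            f"p={r.p_value:.3g} n={r.n}"
        )
    lines.append("")
    lines.append("Signature matches (top reference per extracted signature):")
    top = result.matches[result.matches["rank"] == 1]
    for row in top.itertuples(index=False):
        lines.append(f"  {row.signature} -> {row.reference} (cosine {row.cosine:.3f})")
    t, p = result.s1_treated_vs_control
    mean_tr = result.fractions.loc[
        "S1", [c for c in result.fractions.columns if c.endswith(":treated")]
    ].mean()
    lines.append("")
    lines.append(
        f"S1 contribution: mean {100 * mean_tr:.1f}% in treated groups; "
        f"paired t vs control: t={t:.3f} p={p:.3g}"
    )
    rho, ap = result.association
    cfg = result.config
    lines.append(
        f"{cfg.association_signature} fraction ({cfg.association_condition} groups, "
        f"excluding {','.join(cfg.association_exclude) or 'none'}) vs MLS: "
        f"Spearman rho={rho:.3f} p={ap:.3g}"
    )
    lines.append("")
    lines.append("Germline-filter removals by species:")
    for sp, tally in result.filter_tallies.items():
        lines.append(
            f"  {sp:<16} input={tally['n_input']} "
            f"germline_set={tally['removed_germline_set']} "
            f"recurrent={tally['removed_recurrent']} kept={tally['n_kept']}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def _write_figures(result: PipelineResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta_mls = result.metadata.set_index("species")["mls_years"].to_dict()

    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [meta_mls[d.species] for d in result.deltas]
    ys = [d.delta_snv for d in result.deltas]
    ax.scatter(xs, ys)
    for d, x, y in zip(result.deltas, xs, ys):
        ax.annotate(d.species, (x, y), fontsize=6)
    full = next(r for r in result.regressions if r.covariate == "mls" and not r.excluded)
    grid = np.linspace(min(xs), max(xs), 50)
    ax.plot(grid, full.intercept + full.slope * grid, "k--", lw=1)
    ax.set_xlabel("maximum lifespan (years)")
    ax.set_ylabel("excess SNV frequency (per Mb)")
    ax.set_title(f"R$^2$={full.r_squared:.3f}, p={full.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(out / "delta_vs_mls.png", dpi=150)
    plt.close(fig)

    k = result.signature_set.k
    fig, axes = plt.subplots(k, 1, figsize=(10, 1.8 * k), sharex=True)
    axes = np.atleast_1d(axes)
    for i, ax in enumerate(axes):
        ax.bar(range(96), result.signature_set.W[:, i], width=0.8)
        ax.set_ylabel(result.signature_set.signature_names[i])
    axes[-1].set_xticks(range(0, 96, 16))
    axes[-1].set_xticklabels([CATEGORIES[i][2:5] for i in range(0, 96, 16)])
    fig.tight_layout()
    fig.savefig(out / "signatures.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(10, 3.5))
    bottom = np.zeros(len(result.group_labels))
    for name in result.signature_set.signature_names:
        vals = result.fractions.loc[name].to_numpy()
        ax.bar(result.group_labels, vals, bottom=bottom, label=name)
        bottom += vals
    ax.legend(fontsize=7)
    ax.set_ylabel("contribution fraction")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(out / "contributions.png", dpi=150)
    plt.close(fig)
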