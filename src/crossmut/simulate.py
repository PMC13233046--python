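"""Synthetic cohorts of paired control / mutagen-treated somatic SNV call sets.

The generator emulates the call-level output of an error-corrected
single-molecule mutation sequencing assay applied to primary fibroblast
cultures of mammalian species spanning maximum lifespans from 3 to over 200
years. Each sample's somatic SNV count is Poisson with mean
``rate_per_mb * callable_bases / 1e6``; each SNV's 96-channel category is
drawn from a condition-specific mixture of generator signatures (an ENU-like
A>T/T>A-rich signature for treated samples plus clock-like backgrounds) and
placed at a genome position whose trinucleotide context matches the drawn
category exactly. Germline variants are generated once per species, shared by
all its samples, and flagged in the ground truth so the germline filter has
something real to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import (
    CATEGORIES,
    CATEGORY_TRINUC,
    PYRIMIDINES,
    COMPLEMENT,
    TA_CATEGORY_MASK,
    encode_sequence,
    trinuc32_codes,
)
from .spectrum import N_CATEGORIES, SNVRecord, TrinucFreq, trinucleotide_frequencies


class GenerationError(RuntimeError):
    """A drawn mutation category has no placeable genome position."""


@dataclass(frozen=True)
class GeneratorSignature:
    """A named probability vector over the 96 substitution categories."""

    name: str
    probs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if self.probs.shape != (N_CATEGORIES,):
            raise ValueError("signature must have 96 entries")
        if np.any(self.probs < 0):
            raise ValueError("negative signature probability")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValueError(f"signature sums to {self.probs.sum()}, not 1")


def enu_like_signature(ta_mass: float = 0.75) -> GeneratorSignature:
    """Synthetic mutagen signature: mass concentrated uniformly on the 16 T>A
    categories (ENU's dominant transversion class), remainder uniform.

    This is a stand-in built from the qualitative enrichment, not a copy of
    any published experimental signature.
    """
    probs = np.full(N_CATEGORIES, (1.0 - ta_mass) / 80.0)
    probs[TA_CATEGORY_MASK] = ta_mass / 16.0
    return GeneratorSignature(name="ENU_like_synthetic", probs=probs)


def flat_signature() -> GeneratorSignature:
    """Featureless clock-like background: uniform over all 96 categories."""
    return GeneratorSignature(name="flat_clock_synthetic", probs=np.full(N_CATEGORIES, 1 / 96))


def cpg_deamination_signature(cpg_mass: float = 0.6) -> GeneratorSignature:
    """Synthetic deamination-style background: mass on the four N[C>T]G
    categories (CpG>TpG), remainder uniform — the shape of clock-like
    5-methylcytosine deamination."""
    cpg = np.array(
        [lab[2:5] == "C>T" and lab[6] == "G" for lab in CATEGORIES], dtype=bool
    )
    probs = np.full(N_CATEGORIES, (1.0 - cpg_mass) / (96 - int(cpg.sum())))
    probs[cpg] = cpg_mass / cpg.sum()
    return GeneratorSignature(name="cpg_deamination_synthetic", probs=probs)


def oxidative_like_signature(ca_mass: float = 0.6) -> GeneratorSignature:
    """Synthetic oxidative-damage-style background: mass spread uniformly over
    the 16 C>A categories (the 8-oxo-guanine transversion class), remainder
    uniform."""
    ca = np.array([lab[2:5] == "C>A" for lab in CATEGORIES], dtype=bool)
    probs = np.full(N_CATEGORIES, (1.0 - ca_mass) / 80.0)
    probs[ca] = ca_mass / 16.0
    return GeneratorSignature(name="oxidative_CA_synthetic", probs=probs)


DEFAULT_SIGNATURES: tuple[GeneratorSignature, ...] = (
    enu_like_signature(),
    flat_signature(),
    cpg_deamination_signature(),
)


@dataclass
class SimSpeciesConfig:
    """Per-species simulation parameters.

    ``signature_weights_*`` are mixture weights over ``signatures`` (default
    ENU-like, flat clock-like, CpG-deamination) and must each sum to 1.
    ``mls_years``, ``body_mass_g`` and ``lq`` feed the comparative regressions
    downstream. Rates are per megabase of callable sequence.
    """

    species_name: str
    genome_length: int = 100_000
    gc_bias: float = 0.42
    mls_years: float = 10.0
    body_mass_g: float = 1000.0
    lq: float = 1.0
    n_control: int = 3
    n_treated: int = 3
    callable_bases: int = 50_000_000
    control_rate_per_mb: float = 0.3
    treated_rate_per_mb: float = 1.0
    signature_weights_control: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.6, 0.4])
    )
    signature_weights_treated: np.ndarray = field(
        default_factory=lambda: np.array([0.8, 0.12, 0.08])
    )
    germline_density_per_mb: float = 1.0
    seed: int = 0
    signatures: tuple[GeneratorSignature, ...] = DEFAULT_SIGNATURES

    def __post_init__(self):
        self.signature_weights_control = np.asarray(
            self.signature_weights_control, dtype=float
        )
        self.signature_weights_treated = np.asarray(
            self.signature_weights_treated, dtype=float
        )
        for name, w in (
            ("control", self.signature_weights_control),
            ("treated", self.signature_weights_treated),
        ):
            if w.shape != (len(self.signatures),):
                raise ValueError(f"{name} weights length != number of signatures")
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} signature weights must be >=0 and sum to 1")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        for attr in ("mls_years", "body_mass_g", "lq", "callable_bases"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        for attr in ("control_rate_per_mb", "treated_rate_per_mb", "germline_density_per_mb"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")

    def rate(self, condition: str) -> float:
        return self.treated_rate_per_mb if condition == "treated" else self.control_rate_per_mb

    def weights(self, condition: str) -> np.ndarray:
        return (
            self.signature_weights_treated
            if condition == "treated"
            else self.signature_weights_control
        )


def simulate_genome(length: int, gc_bias: float, seed) -> tuple[str, TrinucFreq]:
    """I.i.d. base sequence of the requested length and GC fraction.

    Returns the sequence and its trinucleotide frequencies (exactly
    :func:`crossmut.spectrum.trinucleotide_frequencies` of the sequence).
    """
    if length < 3 or length <= 0:
        raise ValueError(f"genome length must be positive and >= 3, got {length}")
    if not 0.0 <= gc_bias <= 1.0:
        raise ValueError("gc_bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    return seq, trinucleotide_frequencies(seq)


class GenomeIndex:
    """Positions of each collapsed trinucleotide in a genome, for category-
    faithful placement of simulated mutations.

    ``positions(t)`` returns the 1-based center positions (interior only)
    whose strand-collapsed trinucleotide index is ``t``.
    """

    def __init__(self, sequence: str, chrom: str = "chr1"):
        self.sequence = sequence
        self.chrom = chrom
        codes = encode_sequence(sequence)
        tri = trinuc32_codes(codes)
        self._by_trinuc = [np.flatnonzero(tri == t) + 2 for t in range(32)]

    def positions(self, trinuc_index: int) -> np.ndarray:
        return self._by_trinuc[trinuc_index]


def _place_snv(
    index: GenomeIndex, cat: int, rng: np.random.Generator, used: set[int]
) -> tuple[int, str, str]:
    """Choose an unused 1-based position matching category ``cat``; return
    (pos, ref, alt) on the reference strand."""
    positions = index.positions(CATEGORY_TRINUC[cat])
    if positions.size == 0:
        raise GenerationError(
            f"no genome position matches category {CATEGORIES[cat]}"
        )
    label = CATEGORIES[cat]
    pyr_ref, pyr_alt = label[2], label[4]
    for _ in range(1000):
        pos = int(positions[rng.integers(positions.size)])
        if pos not in used:
            used.add(pos)
            ref = index.sequence[pos - 1].upper()
            if ref in PYRIMIDINES:
                return pos, ref, pyr_alt
            return pos, ref, COMPLEMENT[pyr_alt]
    raise GenerationError(
        f"could not place category {CATEGORIES[cat]}: all matching positions used"
    )


def simulate_germline(
    index: GenomeIndex, config: SimSpeciesConfig, rng: np.random.Generator
) -> list[tuple[str, int, str, str]]:
    """Species-level germline variants: Poisson at ``germline_density_per_mb``
    over the genome, uniform category, shared by every sample of the species."""
    n = rng.poisson(config.germline_density_per_mb * config.genome_length / 1e6)
    used: set[int] = set()
    out = []
    for cat in rng.integers(N_CATEGORIES, size=n):
        pos, ref, alt = _place_snv(index, int(cat), rng, used)
        out.append((index.chrom, pos, ref, alt))
    return out


def simulate_sample(
    genome: GenomeIndex | str,
    config: SimSpeciesConfig,
    condition: str,
    sample_index: int,
    rng: np.random.Generator | int | None = None,
    germline: Sequence[tuple[str, int, str, str]] = (),
) -> tuple[list[SNVRecord], int]:
    """One sample's call set: Poisson-count somatic SNVs drawn from the
    condition's signature mixture, plus the species' shared germline variants
    (flagged ``is_germline`` in the ground truth).

    Returns ``(records, callable_bases)``. Every emitted somatic record's
    genome context reproduces its drawn category exactly (placement is by
    rejection sampling among matching positions; within-sample position
    collisions are redrawn).
    """
    if condition not in ("control", "treated"):
        raise ValueError(f"unknown condition {condition!r}")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    rng = np.random.default_rng(rng)
    sample = f"{config.species_name}_{condition}_{sample_index}"
    mixture = np.zeros(N_CATEGORIES)
    for w, sig in zip(config.weights(condition), config.signatures):
        mixture += w * sig.probs
    n_snv = rng.poisson(config.rate(condition) * config.callable_bases / 1e6)
    used = {pos for _, pos, _, _ in germline}
    records = []
    for cat in rng.choice(N_CATEGORIES, size=n_snv, p=mixture):
        pos, ref, alt = _place_snv(index, int(cat), rng, used)
        records.append(
            SNVRecord(
                species=config.species_name,
                sample=sample,
                condition=condition,
                chrom=index.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
            )
        )
    for chrom, pos, ref, alt in germline:
        records.append(
            SNVRecord(
                species=config.species_name,
                sample=sample,
                condition=condition,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                is_germline=True,
            )
        )
    return records, config.callable_bases


@dataclass
class SampleCalls:
    species: str
    sample: str
    condition: str
    records: list[SNVRecord]
    callable_bases: int


@dataclass
class CohortDataset:
    """In-memory multi-species dataset: genomes, metadata, per-sample calls,
    and germline ground truth."""

    genomes: dict[str, str]
    trinuc_freqs: dict[str, TrinucFreq]
    metadata: pd.DataFrame
    samples: list[SampleCalls]
    germline_truth: dict[str, list[tuple[str, int, str, str]]]
    seed: int | None = None

    def calls_for(self, species: str) -> list[SampleCalls]:
        return [s for s in self.samples if s.species == species]


def default_effect_model(
    mls_years: float,
    control_rate: float = 0.3,
    excess_at_short: float = 0.8,
    excess_at_long: float = 0.35,
    mls_short: float = 3.0,
    mls_long: float = 211.0,
) -> float:
    """Treated rate per Mb: control baseline plus an excess declining
    log-linearly in maximum lifespan, from 0.8/Mb at MLS 3 y to 0.35/Mb at
    MLS 211 y (the generator's mutagen-sensitivity model)."""
    frac = (np.log(mls_years) - np.log(mls_short)) / (np.log(mls_long) - np.log(mls_short))
    excess = excess_at_short + (excess_at_long - excess_at_short) * frac
    return control_rate + excess


# (species, MLS years, adult body mass g) for the ten-species study cohort;
# the three short-lived rodents are entered at 3 y, human at 120 y, bowhead
# whale at 211 y; mid-cohort values are typical literature maxima.
DEFAULT_COHORT_SPECIES: tuple[tuple[str, float, float], ...] = (
    ("mouse", 3.0, 20.5),
    ("hamster", 3.0, 105.0),
    ("rat", 3.0, 300.0),
    ("guinea_pig", 12.0, 728.0),
    ("chinchilla", 17.0, 500.0),
    ("beaver", 23.0, 20_000.0),
    ("cow", 20.0, 750_000.0),
    ("naked_mole_rat", 32.0, 35.0),
    ("human", 120.0, 62_000.0),
    ("whale", 211.0, 100_000_000.0),
)


def allometric_lq(mls_years: float, body_mass_g: float, a: float = 4.88, b: float = 0.153) -> float:
    """Longevity quotient: observed MLS over the allometric expectation
    ``a * mass_g**b`` (defaults are the common mammalian fit constants)."""
    return mls_years / (a * body_mass_g**b)


def default_cohort_configs(
    genome_length: int = 100_000,
    callable_bases: int = 50_000_000,
    n_control: int = 3,
    n_treated: int = 3,
    control_rate_per_mb: float = 0.3,
) -> list[SimSpeciesConfig]:
    """Ten-species study-shaped cohort with the default negative effect model."""
    configs = []
    for species, mls, mass in DEFAULT_COHORT_SPECIES:
        configs.append(
            SimSpeciesConfig(
                species_name=species,
                genome_length=genome_length,
                mls_years=mls,
                body_mass_g=mass,
                lq=allometric_lq(mls, mass),
                n_control=n_control,
                n_treated=n_treated,
                callable_bases=callable_bases,
                control_rate_per_mb=control_rate_per_mb,
                treated_rate_per_mb=default_effect_model(mls, control_rate_per_mb),
            )
        )
    return configs


def simulate_cohort(
    configs: Sequence[SimSpeciesConfig],
    effect_model: Callable[[float], float] | None = None,
    seed: int | None = 0,
    genomes: Mapping[str, str] | None = None,
) -> CohortDataset:
    """Simulate a full multi-species paired control/treated dataset.

    ``effect_model`` (MLS years -> treated rate per Mb), if given, overrides
    each config's ``treated_rate_per_mb``. Pre-built ``genomes`` (species ->
    sequence) may be passed to reuse context indexes across replicate cohorts.
    Fully reproducible from ``seed``.
    """
    if len(configs) < 2:
        raise ValueError("a cohort needs at least 2 species")
    names = [c.species_name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in cohort")
    root = np.random.SeedSequence(seed)
    species_seeds = root.spawn(len(configs))
    out_genomes: dict[str, str] = {}
    freqs: dict[str, TrinucFreq] = {}
    samples: list[SampleCalls] = []
    germline_truth: dict[str, list] = {}
    meta_rows = []
    for config, sseq in zip(configs, species_seeds):
        if effect_model is not None:
            config = replace(config, treated_rate_per_mb=effect_model(config.mls_years))
        genome_rng, germ_rng, calls_rng = [np.random.default_rng(s) for s in sseq.spawn(3)]
        if genomes is not None and config.species_name in genomes:
            seq = genomes[config.species_name]
            freq = trinucleotide_frequencies(seq)
        else:
            seq, freq = simulate_genome(config.genome_length, config.gc_bias, genome_rng)
        index = GenomeIndex(seq)
        germline = simulate_germline(index, config, germ_rng)
        out_genomes[config.species_name] = seq
        freqs[config.species_name] = freq
        germline_truth[config.species_name] = germline
        for condition, n in (("control", config.n_control), ("treated", config.n_treated)):
            for i in range(1, n + 1):
                records, callable_bases = simulate_sample(
                    index, config, condition, i, calls_rng, germline
                )
                samples.append(
                    SampleCalls(
                        species=config.species_name,
                        sample=records[0].sample if records else f"{config.species_name}_{condition}_{i}",
                        condition=condition,
                        records=records,
                        callable_bases=callable_bases,
                    )
                )
        meta_rows.append(
            {
                "species": config.species_name,
                "mls_years": config.mls_years,
                "body_mass_g": config.body_mass_g,
                "lq": config.lq,
            }
        )
    return CohortDataset(
        genomes=out_genomes,
        trinuc_freqs=freqs,
        metadata=pd.DataFrame(meta_rows),
        samples=samples,
        germline_truth=germline_truth,
        seed=seed,
    )
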