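"""Germline filtering, per-sample SNV frequency, and excess-mutation (ΔSNV) estimation.

ΔSNV — the species' mean treated-sample SNV frequency minus its mean
control-sample frequency, per megabase of callable sequence — measures the
mutation burden the mutagen adds on top of the culture background, i.e. the
error rate of the species' DNA repair under challenge.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .spectrum import SNVRecord

logger = logging.getLogger(__name__)


@dataclass
class FilterTally:
    """Structured count of germline-filter removals by rule."""

    n_input: int
    removed_germline_set: int
    removed_recurrent: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.removed_germline_set - self.removed_recurrent


@dataclass
class SampleBurden:
    species: str
    sample: str
    condition: str
    n_snv: int
    callable_bases: int

    @property
    def freq_per_mb(self) -> float:
        return snv_frequency(self.n_snv, self.callable_bases)


@dataclass
class DeltaResult:
    """Per-species excess mutation frequency with a bootstrap interval."""

    species: str
    mean_control: float
    mean_treated: float
    delta_snv: float
    ci_low: float
    ci_high: float
    n_control: int
    n_treated: int


def germline_filter(
    calls: Iterable[SNVRecord],
    germline_set: set[tuple[str, int, str, str]] | None = None,
    recurrence_threshold: int = 2,
    use_recurrence: bool = True,
) -> tuple[list[SNVRecord], FilterTally]:
    """Remove inherited variants from a species' pooled somatic call sets.

    Two rules: (a) drop any call matching ``germline_set`` on
    ``(chrom, pos, ref, alt)``; (b) drop any call whose ``(chrom, pos, alt)``
    recurs in at least ``recurrence_threshold`` distinct samples of the
    species — true somatic mutations are private to a culture, inherited
    variants are shared. Rule (b) needs cross-sample context; with a single
    sample and no germline set it is disabled with a logged warning.

    Returns the surviving calls (input order preserved) and a removal tally.
    """
    calls = list(calls)
    species = {c.species for c in calls}
    if len(species) > 1:
        raise ValueError(f"germline_filter expects one species, got {sorted(species)}")
    recurrent: set[tuple[str, int, str]] = set()
    if use_recurrence:
        samples_by_site: dict[tuple[str, int, str], set[str]] = {}
        for c in calls:
            samples_by_site.setdefault((c.chrom, c.pos, c.alt), set()).add(c.sample)
        n_samples = len({c.sample for c in calls})
        if n_samples < 2 and germline_set is None:
            logger.warning(
                "recurrence rule disabled: single sample and no germline set"
            )
        else:
            recurrent = {
                site for site, ss in samples_by_site.items()
                if len(ss) >= recurrence_threshold
            }
    kept: list[SNVRecord] = []
    tally = FilterTally(n_input=len(calls), removed_germline_set=0, removed_recurrent=0)
    for c in calls:
        if germline_set is not None and (c.chrom, c.pos, c.ref, c.alt) in germline_set:
            tally.removed_germline_set += 1
        elif (c.chrom, c.pos, c.alt) in recurrent:
            tally.removed_recurrent += 1
        else:
            kept.append(c)
    return kept, tally


def snv_frequency(n_snv: int, callable_bases: int) -> float:
    """SNV frequency per megabase: ``n_snv / callable_bases * 1e6``."""
    if callable_bases <= 0:
        raise ValueError(f"callable_bases must be positive, got {callable_bases}")
    if n_snv < 0:
        raise ValueError("n_snv must be non-negative")
    return n_snv / callable_bases * 1e6


def delta_snv(
    samples: Sequence[SampleBurden],
    n_boot: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
    paired: bool = False,
) -> DeltaResult:
    """Excess mutation frequency of one species with a percentile-bootstrap CI.

    ``delta_snv = mean(treated freq) - mean(control freq)``; the bootstrap
    resamples per-sample frequencies within condition. ``paired`` instead
    averages per-pair differences (requires equal group sizes), a sensitivity
    mode for matched designs.
    """
    species = {s.species for s in samples}
    if len(species) != 1:
        raise ValueError(f"delta_snv expects one species, got {sorted(species)}")
    (species_name,) = species
    control = np.array([s.freq_per_mb for s in samples if s.condition == "control"])
    treated = np.array([s.freq_per_mb for s in samples if s.condition == "treated"])
    if control.size == 0 or treated.size == 0:
        raise ValueError(f"species {species_name}: need >=1 control and >=1 treated sample")
    if paired:
        if control.size != treated.size:
            raise ValueError(f"species {species_name}: paired mode needs equal group sizes")
        delta = float(np.mean(treated - control))
    else:
        delta = float(treated.mean() - control.mean())
    rng = np.random.default_rng(seed)
    if n_boot > 0:
        boot_c = rng.choice(control, size=(n_boot, control.size)).mean(axis=1)
        boot_t = rng.choice(treated, size=(n_boot, treated.size)).mean(axis=1)
        alpha = (1.0 - level) / 2
        lo, hi = np.quantile(boot_t - boot_c, [alpha, 1 - alpha])
        # percentile interval may exclude the point estimate in tiny samples
        ci_low, ci_high = min(float(lo), delta), max(float(hi), delta)
    else:
        ci_low = ci_high = delta
    return DeltaResult(
        species=species_name,
        mean_control=float(control.mean()),
        mean_treated=float(treated.mean()),
        delta_snv=delta,
        ci_low=ci_low,
        ci_high=ci_high,
        n_control=int(control.size),
        n_treated=int(treated.size),
    )


def sample_burdens(sample_calls, count_germline: bool = False) -> SampleBurden:
    """Burden of one sample's (already filtered) call list."""
    n = sum(1 for r in sample_calls.records if count_germline or not r.is_germline)
    return SampleBurden(
        species=sample_calls.species,
        sample=sample_calls.sample,
        condition=sample_calls.condition,
        n_snv=n,
        callable_bases=sample_calls.callable_bases,
    )
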