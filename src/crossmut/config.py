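"""Pipeline configuration and deterministic seed fan-out.

A single global seed drives every stochastic stage. Each stage draws its own
seed as ``SeedSequence(global_seed, spawn_key=(stage_index,))`` with a fixed
stage order, so any stage can be re-run in isolation and reproduce the full
run's numbers exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: fixed stage order for seed derivation — do not reorder
STAGES = ("simulate", "bootstrap", "nmf")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from the global seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML and echoed verbatim
    into the output directory.

    With ``simulate=True`` the run generates the default ten-species synthetic
    cohort; otherwise ``cohort_dir`` must point at a cohort directory
    (samples.tsv + metadata.tsv + fasta/ + call files).
    """

    out_dir: str = "crossmut_run"
    seed: int = 0
    simulate: bool = True
    cohort_dir: str | None = None
    catalog_path: str | None = None  # COSMIC-style TSV; synthetic catalog if None

    # synthetic cohort geometry
    genome_length: int = 100_000
    callable_bases: int = 50_000_000
    n_control: int = 3
    n_treated: int = 3

    # burden stage
    recurrence_threshold: int = 2
    n_boot: int = 2000
    paired_delta: bool = False
    humanize_burdens: bool = False

    # spectra / humanization
    target_species: str = "human"
    preserve_total: bool = False

    # comparative stage
    regression_points: str = "per_sample"  # or "species_mean"
    loo_species: tuple[str, ...] = ("human", "whale", "rat")
    log10_mass: bool = False

    # signatures stage
    k: int = 3
    n_restarts: int = 30
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-9
    association_signature: str = "S3"
    association_condition: str = "control"
    association_exclude: tuple[str, ...] = ("human",)

    make_figures: bool = True

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["loo_species"] = list(self.loo_species)
        d["association_exclude"] = list(self.association_exclude)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("loo_species", "association_exclude"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
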