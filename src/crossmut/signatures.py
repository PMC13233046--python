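"""De novo mutational-signature extraction by non-negative matrix factorization.

A 96 x G matrix of (humanized) mutation spectra — one column per
species-condition group — is factorized as ``M ≈ W H`` with ``W`` (96 x k)
holding k signature probability vectors and ``H`` (k x G) their per-group
contributions. The factorization minimizes the generalized Kullback-Leibler
divergence ``D(M ‖ WH)`` by multiplicative updates, the classic choice for
count data; the best of several random restarts is kept. Extracted signatures
are then matched to a reference catalog by cosine similarity, and contribution
fractions are related to species covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CATEGORIES
from .comparative import spearman_correlation
from .spectrum import N_CATEGORIES

_EPS = np.finfo(float).eps


@dataclass
class SpectraMatrix:
    """96 x G matrix of mutation spectra with group labels (species:condition)."""

    matrix: np.ndarray
    group_labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != N_CATEGORIES:
            raise ValueError(f"expected 96 x G matrix, got {self.matrix.shape}")
        if self.matrix.shape[1] != len(self.group_labels):
            raise ValueError("group label count != number of columns")
        if np.any(self.matrix < 0):
            raise ValueError("negative spectra entry")
        if np.any(self.matrix.sum(axis=0) == 0):
            empty = [l for l, s in zip(self.group_labels, self.matrix.sum(axis=0)) if s == 0]
            raise ValueError(f"all-zero spectrum column(s): {empty}")

    @property
    def n_groups(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SignatureSet:
    """NMF result: column-normalized signatures W (named S1..Sk in descending
    total-contribution order), contributions H, and the winning restart's
    objective trace."""

    W: np.ndarray
    H: np.ndarray
    group_labels: list[str]
    objective_trace: np.ndarray
    seed_used: int | None
    n_restarts: int
    converged: bool = True

    @property
    def k(self) -> int:
        return self.W.shape[1]

    @property
    def signature_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.k)]


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V ‖ WH) = Σ V log(V/WH) - V + WH."""
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)))
    return float(div - V.sum() + WH.sum())


def _nmf_single(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    method: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    n, g = V.shape
    # W depends on the seed only; each H column depends on the seed pattern
    # and that column's own mass. This makes the whole update trajectory
    # exactly equivariant under permutation of the data columns.
    W = rng.random((n, k)) + 0.1
    h_pattern = rng.random(k) + 0.1
    col_mass = V.sum(axis=0)
    H = np.outer(h_pattern, col_mass / (W @ h_pattern).sum())
    trace = []
    converged = False
    prev = None
    for _ in range(max_iter):
        if method == "kl":
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
            obj = kl_divergence(V, np.maximum(W @ H, _EPS))
        elif method == "frobenius":
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ V) / np.maximum(W.T @ WH, _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= (V @ H.T) / np.maximum(WH @ H.T, _EPS)
            obj = 0.5 * float(np.sum((V - W @ H) ** 2))
        else:
            raise ValueError(f"unknown NMF method {method!r}")
        trace.append(obj)
        if prev is not None and abs(prev - obj) <= tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = obj
    return W, H, np.array(trace), converged


def nmf_extract(
    M: SpectraMatrix,
    k: int,
    max_iter: int = 2000,
    tol: float = 1e-9,
    n_restarts: int = 30,
    seed: int | None = None,
    method: str = "kl",
) -> SignatureSet:
    """Extract k de novo signatures from a spectra matrix.

    Runs ``n_restarts`` random non-negative initializations (seeds derived
    deterministically from ``seed``, one fixed child seed per restart) and
    keeps the factorization with the lowest final divergence. ``W`` columns
    are normalized to sum to 1 with compensating row scaling of ``H``;
    signatures are ordered by total contribution, descending. A restart
    hitting ``max_iter`` without meeting ``tol`` flags ``converged=False``
    on the result rather than raising.
    """
    if k < 1 or k > min(N_CATEGORIES, M.n_groups):
        raise ValueError(f"k={k} out of bounds for a 96 x {M.n_groups} matrix")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_restarts)
    best = None
    for child in children:
        W, H, trace, conv = _nmf_single(
            M.matrix, k, np.random.default_rng(child), max_iter, tol, method
        )
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace, conv)
    W, H, trace, conv = best
    colsum = np.maximum(W.sum(axis=0), _EPS)
    W = W / colsum
    H = H * colsum[:, None]
    order = np.argsort(-H.sum(axis=1), kind="stable")
    return SignatureSet(
        W=W[:, order],
        H=H[order, :],
        group_labels=list(M.group_labels),
        objective_trace=trace,
        seed_used=seed,
        n_restarts=n_restarts,
        converged=conv,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two non-negative 96-vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("signature vectors must be non-negative")
    return float(a @ b / (na * nb))


@dataclass
class ReferenceCatalog:
    """Named reference signatures, each a normalized 96-vector."""

    entries: dict[str, np.ndarray]

    def __post_init__(self):
        norm = {}
        for name, v in self.entries.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (N_CATEGORIES,):
                raise ValueError(f"catalog entry {name} is not a 96-vector")
            if np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-9):
                raise ValueError(f"catalog entry {name} is not normalized")
            norm[name] = v
        self.entries = norm

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceCatalog":
        """Build from a COSMIC-style table: category rows x signature columns.

        Accepts a first column of category labels (any of the common header
        names) or a category index; rows are reordered to canonical order and
        columns normalized to sum to 1.
        """
        df = df.copy()
        label_cols = [c for c in df.columns if str(c).lower() in
                      ("type", "mutationtype", "mutation_type", "category")]
        if label_cols:
            df = df.set_index(label_cols[0])
        df = df.loc[list(CATEGORIES)]
        entries = {
            str(name): (col / col.sum()).to_numpy(dtype=float)
            for name, col in df.items()
        }
        return cls(entries=entries)


def synthetic_reference_catalog() -> ReferenceCatalog:
    """Bundled synthetic catalog (no external download): the generator's
    ENU-like, flat clock-like, and CpG-deamination signatures. A real COSMIC
    TSV plus an experimental ENU entry can be loaded with
    :meth:`ReferenceCatalog.from_frame` instead."""
    from .simulate import DEFAULT_SIGNATURES

    return ReferenceCatalog(entries={s.name: s.probs for s in DEFAULT_SIGNATURES})


def match_signatures(
    S: SignatureSet, catalog: ReferenceCatalog, top_n: int = 3
) -> pd.DataFrame:
    """Rank catalog entries by cosine similarity to each extracted signature.

    Ties break lexicographically by catalog name. Returns a tidy frame with
    columns signature, rank, reference, cosine.
    """
    if not catalog.entries:
        raise ValueError("empty reference catalog")
    rows = []
    for i, sig_name in enumerate(S.signature_names):
        sims = sorted(
            ((name, cosine_similarity(S.W[:, i], v)) for name, v in catalog.entries.items()),
            key=lambda t: (-t[1], t[0]),
        )
        for rank, (name, cos) in enumerate(sims[:top_n], start=1):
            rows.append(
                {"signature": sig_name, "rank": rank, "reference": name, "cosine": cos}
            )
    return pd.DataFrame(rows)


def contribution_fractions(S: SignatureSet) -> pd.DataFrame:
    """Per-group signature contribution fractions (columns sum to 1).

    Returns a k x G frame indexed by signature name, columns = group labels.
    """
    colsum = S.H.sum(axis=0)
    if np.any(colsum == 0):
        bad = [l for l, s in zip(S.group_labels, colsum) if s == 0]
        raise ValueError(f"all-zero contribution column(s): {bad}")
    frac = S.H / colsum
    return pd.DataFrame(frac, index=S.signature_names, columns=S.group_labels)


def signature_lifespan_association(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    signature: str,
    condition: str = "control",
    exclude: Sequence[str] = (),
) -> tuple[float, float]:
    """Spearman association between a signature's per-species contribution
    fraction (in the named condition's groups) and maximum lifespan.

    Group labels must be ``species:condition``. ``exclude`` drops named
    species (e.g. an outlier) before the correlation.
    """
    mls = meta.set_index("species")["mls_years"]
    xs, ys = [], []
    for label in fractions.columns:
        species, _, cond = label.rpartition(":")
        if cond != condition or species in set(exclude):
            continue
        xs.append(float(mls.loc[species]))
        ys.append(float(fractions.loc[signature, label]))
    return spearman_correlation(xs, ys)
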