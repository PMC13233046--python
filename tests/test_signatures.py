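"""NMF extraction, cosine matching, contributions, lifespan association."""

import numpy as np
import pandas as pd
import pytest

from crossmut.signatures import (
    ReferenceCatalog,
    SpectraMatrix,
    contribution_fractions,
    cosine_similarity,
    kl_divergence,
    match_signatures,
    nmf_extract,
    signature_lifespan_association,
    synthetic_reference_catalog,
)
from crossmut.simulate import (
    DEFAULT_SIGNATURES,
    cpg_deamination_signature,
    enu_like_signature,
    oxidative_like_signature,
)


def _planted_matrix(rng, n_groups=12, total=2e5, alpha=0.4):
    sigs = np.column_stack(
        [s.probs for s in (enu_like_signature(), cpg_deamination_signature(),
                           oxidative_like_signature())]
    )
    cols, labels = [], []
    for g in range(n_groups):
        w = rng.dirichlet([alpha] * 3)
        cols.append(rng.poisson(total * (sigs @ w)).astype(float))
        labels.append(f"g{g}")
    return SpectraMatrix(np.column_stack(cols), labels), sigs


class TestNmfExtract:
    def test_rank_one_exact_recovery(self):
        rng = np.random.default_rng(0)
        w = rng.random(96)
        h = rng.random(8) * 100
        M = SpectraMatrix(np.outer(w, h), [f"g{i}" for i in range(8)])
        S = nmf_extract(M, k=1, n_restarts=3, seed=1)
        assert cosine_similarity(S.W[:, 0], w / w.sum()) >= 0.999

    def test_objective_trace_non_increasing(self):
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            M = SpectraMatrix(
                rng.uniform(0, 50, size=(96, 6)), [f"g{i}" for i in range(6)]
            )
            S = nmf_extract(M, k=2, n_restarts=1, seed=seed, max_iter=300)
            diffs = np.diff(S.objective_trace)
            assert np.all(diffs <= 1e-8 * max(abs(S.objective_trace[0]), 1.0))

    def test_w_columns_normalized_and_ordered(self):
        rng = np.random.default_rng(3)
        M, _ = _planted_matrix(rng)
        S = nmf_extract(M, k=3, n_restarts=5, seed=4)
        np.testing.assert_allclose(S.W.sum(axis=0), 1.0, atol=1e-9)
        totals = S.H.sum(axis=1)
        assert np.all(np.diff(totals) <= 1e-9)  # descending contribution

    def test_reconstruction_quality_on_planted_data(self):
        """Relative KL divergence below 1% of total counts at convergence."""
        rng = np.random.default_rng(9)
        M, _ = _planted_matrix(rng, total=1e5)
        S = nmf_extract(M, k=3, n_restarts=10, seed=5)
        rel = kl_divergence(M.matrix, S.W @ S.H) / M.matrix.sum()
        assert rel < 0.01

    def test_permutation_equivariance(self):
        """Permuting data columns permutes H identically and leaves W
        invariant up to signature matching."""
        rng = np.random.default_rng(5)
        M, _ = _planted_matrix(rng)
        perm = rng.permutation(M.n_groups)
        Mp = SpectraMatrix(
            M.matrix[:, perm], [M.group_labels[i] for i in perm]
        )
        S1 = nmf_extract(M, k=3, n_restarts=4, seed=3)
        S2 = nmf_extract(Mp, k=3, n_restarts=4, seed=3)
        cos = np.array(
            [[cosine_similarity(S1.W[:, i], S2.W[:, j]) for j in range(3)]
             for i in range(3)]
        )
        assert cos.max(axis=1).min() >= 0.999
        j = cos.argmax(axis=1)
        np.testing.assert_allclose(
            S2.H[j, :], S1.H[:, perm], rtol=1e-6, atol=1e-8
        )

    def test_agrees_with_sklearn_cross_check(self):
        """Final KL divergence within 1% of scikit-learn's KL NMF on the
        same matrix (independent implementation, same objective)."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(11)
        M, _ = _planted_matrix(rng)
        S = nmf_extract(M, k=3, n_restarts=8, seed=2)
        skl = NMF(
            n_components=3, solver="mu", beta_loss="kullback-leibler",
            init="random", max_iter=2000, tol=1e-9, random_state=0,
        )
        Wr = skl.fit_transform(M.matrix)
        ours = kl_divergence(M.matrix, S.W @ S.H)
        theirs = kl_divergence(M.matrix, Wr @ skl.components_)
        assert ours <= theirs * 1.01

    def test_k_bounds(self):
        rng = np.random.default_rng(1)
        M, _ = _planted_matrix(rng, n_groups=4)
        with pytest.raises(ValueError):
            nmf_extract(M, k=0)
        with pytest.raises(ValueError):
            nmf_extract(M, k=5)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            SpectraMatrix(np.zeros((96, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            SpectraMatrix(-np.ones((96, 2)), ["a", "b"])


class TestCosine:
    def test_self_similarity(self):
        v = np.random.default_rng(0).random(96)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        a, b = np.zeros(96), np.zeros(96)
        a[:48], b[48:] = 1, 1
        assert cosine_similarity(a, b) == 0.0

    def test_closed_form(self):
        a, b = np.zeros(96), np.zeros(96)
        a[0] = a[1] = 1
        b[0] = 1
        assert cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(96), np.ones(96))


class TestMatchSignatures:
    def test_self_match_is_rank_one(self):
        rng = np.random.default_rng(7)
        M, sigs = _planted_matrix(rng)
        S = nmf_extract(M, k=3, n_restarts=8, seed=0)
        catalog = ReferenceCatalog(
            entries={f"ref{j}": sigs[:, j] / sigs[:, j].sum() for j in range(3)}
        )
        # add the extracted signatures themselves: they must win at cosine 1
        for i, name in enumerate(S.signature_names):
            catalog.entries[f"self_{name}"] = S.W[:, i] / S.W[:, i].sum()
        matches = match_signatures(S, ReferenceCatalog(entries=catalog.entries))
        for name in S.signature_names:
            top = matches[(matches["signature"] == name) & (matches["rank"] == 1)]
            assert top.iloc[0]["reference"] == f"self_{name}"
            assert top.iloc[0]["cosine"] == pytest.approx(1.0)

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(13)
        M, _ = _planted_matrix(rng)
        S = nmf_extract(M, k=3, n_restarts=4, seed=6)
        catalog = synthetic_reference_catalog()
        matches = match_signatures(S, catalog, top_n=len(catalog.entries))
        for i, name in enumerate(S.signature_names):
            brute = sorted(
                ((n, cosine_similarity(S.W[:, i], v)) for n, v in catalog.entries.items()),
                key=lambda t: (-t[1], t[0]),
            )
            got = matches[matches["signature"] == name].sort_values("rank")
            assert list(got["reference"]) == [n for n, _ in brute]

    def test_empty_catalog_rejected(self):
        rng = np.random.default_rng(1)
        M, _ = _planted_matrix(rng)
        S = nmf_extract(M, k=2, n_restarts=2, seed=0)
        with pytest.raises(ValueError):
            match_signatures(S, ReferenceCatalog(entries={}))


class TestContributions:
    def test_k_equals_one_gives_unit_fractions(self):
        rng = np.random.default_rng(2)
        M, _ = _planted_matrix(rng, n_groups=5)
        S = nmf_extract(M, k=1, n_restarts=2, seed=0)
        fr = contribution_fractions(S)
        np.testing.assert_allclose(fr.to_numpy(), 1.0)

    def test_known_column(self):
        rng = np.random.default_rng(2)
        M, _ = _planted_matrix(rng, n_groups=4)
        S = nmf_extract(M, k=3, n_restarts=2, seed=0)
        S.H = np.array([[2.0], [1.0], [1.0]]) @ np.ones((1, 4))
        fr = contribution_fractions(S)
        np.testing.assert_allclose(fr.iloc[:, 0], [0.5, 0.25, 0.25])

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(6)
        M, _ = _planted_matrix(rng)
        S = nmf_extract(M, k=3, n_restarts=3, seed=1)
        fr = contribution_fractions(S)
        np.testing.assert_allclose(fr.sum(axis=0), 1.0, atol=1e-9)


class TestLifespanAssociation:
    def _fractions(self, values, species, condition="control"):
        cols = [f"{sp}:{condition}" for sp in species]
        return pd.DataFrame([values], index=["S1"], columns=cols)

    def _meta(self, species, mls):
        return pd.DataFrame(
            {"species": species, "mls_years": mls,
             "body_mass_g": 1.0, "lq": 1.0}
        )

    def test_monotone_fraction_gives_rho_one(self):
        sp = [f"s{i}" for i in range(6)]
        mls = [3.0, 10, 20, 40, 80, 200]
        fr = self._fractions([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], sp)
        rho, _ = signature_lifespan_association(fr, self._meta(sp, mls), "S1")
        assert rho == pytest.approx(1.0)

    def test_exclusion_reduces_n_and_matches_direct(self):
        from crossmut.comparative import spearman_correlation

        sp = [f"s{i}" for i in range(7)]
        mls = [3.0, 5, 10, 20, 40, 80, 200]
        vals = [0.3, 0.1, 0.4, 0.2, 0.5, 0.45, 0.35]
        fr = self._fractions(vals, sp)
        meta = self._meta(sp, mls)
        rho, p = signature_lifespan_association(fr, meta, "S1", exclude=["s3"])
        keep = [i for i in range(7) if sp[i] != "s3"]
        rho_d, p_d = spearman_correlation(
            [mls[i] for i in keep], [vals[i] for i in keep]
        )
        assert (rho, p) == (rho_d, p_d)

    def test_condition_selects_groups(self):
        sp = ["a", "b", "c", "d", "e"]
        mls = [3.0, 10, 30, 90, 200]
        fr_c = self._fractions([0.1, 0.2, 0.3, 0.4, 0.5], sp, "control")
        fr_t = self._fractions([0.5, 0.4, 0.3, 0.2, 0.1], sp, "treated")
        fr = pd.concat([fr_c, fr_t], axis=1)
        rho_c, _ = signature_lifespan_association(fr, self._meta(sp, mls), "S1", "control")
        rho_t, _ = signature_lifespan_association(fr, self._meta(sp, mls), "S1", "treated")
        assert rho_c == pytest.approx(1.0) and rho_t == pytest.approx(-1.0)


class TestReferenceCatalog:
    def test_from_frame_cosmic_layout(self):
        from crossmut.categories import CATEGORIES

        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"Type": list(CATEGORIES),
             "SBSX": rng.random(96), "SBSY": rng.random(96)}
        )
        cat = ReferenceCatalog.from_frame(df)
        assert set(cat.entries) == {"SBSX", "SBSY"}
        for v in cat.entries.values():
            assert v.sum() == pytest.approx(1.0)

    def test_unnormalized_entry_rejected(self):
        with pytest.raises(ValueError):
            ReferenceCatalog(entries={"bad": np.full(96, 0.5)})
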