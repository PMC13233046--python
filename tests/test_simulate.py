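"""Synthetic-data generator: determinism, sampling distributions, fidelity."""

import numpy as np
import pytest

from crossmut.categories import TA_CATEGORY_MASK
from crossmut.simulate import (
    DEFAULT_SIGNATURES,
    GeneratorSignature,
    GenomeIndex,
    SimSpeciesConfig,
    cpg_deamination_signature,
    default_cohort_configs,
    default_effect_model,
    enu_like_signature,
    flat_signature,
    oxidative_like_signature,
    simulate_cohort,
    simulate_genome,
    simulate_sample,
)
from crossmut.spectrum import build_spectrum, classify_context, trinucleotide_frequencies


class TestSimulateGenome:
    def test_seed_determinism(self):
        s1, _ = simulate_genome(10_000, 0.5, seed=1)
        s2, _ = simulate_genome(10_000, 0.5, seed=1)
        assert s1 == s2

    def test_degenerate_gc(self):
        seq, _ = simulate_genome(2_000, 1.0, seed=2)
        assert set(seq) <= {"G", "C"}
        seq, _ = simulate_genome(2_000, 0.0, seed=2)
        assert set(seq) <= {"A", "T"}

    def test_gc_fraction_within_three_se(self):
        n, gc = 100_000, 0.4
        seq, _ = simulate_genome(n, gc, seed=7)
        observed = (seq.count("G") + seq.count("C")) / n
        se = np.sqrt(gc * (1 - gc) / n)
        assert abs(observed - gc) < 3 * se

    def test_returned_freq_matches_recomputation(self):
        seq, freq = simulate_genome(5_000, 0.42, seed=9)
        np.testing.assert_array_equal(
            freq.freqs, trinucleotide_frequencies(seq).freqs
        )

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            simulate_genome(0, 0.5, seed=0)


class TestGeneratorSignatures:
    @pytest.mark.parametrize(
        "sig",
        [enu_like_signature(), flat_signature(), cpg_deamination_signature(),
         oxidative_like_signature()],
        ids=lambda s: s.name,
    )
    def test_normalized(self, sig):
        assert sig.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(sig.probs >= 0)

    def test_enu_mass_on_ta(self):
        sig = enu_like_signature()
        assert sig.probs[TA_CATEGORY_MASK].sum() == pytest.approx(0.75)

    def test_invalid_signature_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSignature(name="bad", probs=np.full(96, 0.5))


class TestSimulateSample:
    def test_poisson_mean(self, genome_index):
        """Mean SNV count over 200 replicate samples within 3 SE of
        rate * callable / 1e6 = 50."""
        config = SimSpeciesConfig(
            species_name="m", genome_length=20_000,
            control_rate_per_mb=1.0, callable_bases=50_000_000,
            germline_density_per_mb=0.0,
        )
        rng = np.random.default_rng(21)
        counts = [
            len(simulate_sample(genome_index, config, "control", i, rng)[0])
            for i in range(200)
        ]
        se = np.sqrt(50 / 200)
        assert abs(np.mean(counts) - 50) < 3 * se

    def test_treated_ta_fraction_matches_mixture_expectation(self, genome_index):
        """The observed T>A fraction of treated SNVs matches the signature
        mixture's expected mass within 3 binomial standard errors, and the
        ENU-weighted mixture strongly enriches T>A over the uniform 1/6."""
        config = SimSpeciesConfig(
            species_name="m", genome_length=20_000,
            treated_rate_per_mb=2.0, callable_bases=50_000_000,
            germline_density_per_mb=0.0,
        )
        expected = sum(
            w * sig.probs[TA_CATEGORY_MASK].sum()
            for w, sig in zip(config.signature_weights_treated, config.signatures)
        )
        rng = np.random.default_rng(5)
        genome = {"chr1": genome_index.sequence}
        ta = total = 0
        for i in range(30):
            records, _ = simulate_sample(genome_index, config, "treated", i, rng)
            for r in records:
                ta += bool(TA_CATEGORY_MASK[classify_context(r, genome)])
                total += 1
        observed = ta / total
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(observed - expected) < 3 * se
        assert observed > 0.5  # far above the 16/96 background share

    def test_category_fidelity_every_record(self, genome_index, base_config):
        """Classifying each emitted somatic SNV at its genome position
        reproduces the generator's drawn category distribution: every record
        classifies cleanly and REF always matches the genome."""
        genome = {"chr1": genome_index.sequence}
        records, _ = simulate_sample(
            genome_index, base_config, "treated", 1, np.random.default_rng(3)
        )
        for r in records:
            classify_context(r, genome)  # raises on mismatch or bad flank

    def test_germline_appended_and_flagged(self, genome_index):
        config = SimSpeciesConfig(
            species_name="m", genome_length=20_000, control_rate_per_mb=0.5,
            callable_bases=10_000_000,
        )
        germline = [("chr1", 100, genome_index.sequence[99], "T")]
        if germline[0][2] == "T":
            germline = [("chr1", 100, "T", "C")]
        records, _ = simulate_sample(
            genome_index, config, "control", 1, np.random.default_rng(1), germline
        )
        flagged = [r for r in records if r.is_germline]
        assert len(flagged) == 1 and flagged[0].pos == 100

    def test_bad_condition(self, genome_index, base_config):
        with pytest.raises(ValueError):
            simulate_sample(genome_index, base_config, "mock", 1, 0)


class TestSimulateCohort:
    def _tiny_configs(self, **kw):
        return [
            SimSpeciesConfig(
                species_name=f"sp{i}", genome_length=10_000, mls_years=mls,
                callable_bases=10_000_000, control_rate_per_mb=0.5,
                treated_rate_per_mb=0.5, germline_density_per_mb=0.0, **kw
            )
            for i, mls in enumerate([3.0, 30.0])
        ]

    def test_same_seed_bit_identical(self, tmp_path):
        from crossmut.io import write_cohort
        import hashlib

        def tree_hash(root):
            h = hashlib.sha256()
            for p in sorted(root.rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        configs = self._tiny_configs()
        d1 = simulate_cohort(configs, seed=11)
        d2 = simulate_cohort(configs, seed=11)
        write_cohort(d1, tmp_path / "a")
        write_cohort(d2, tmp_path / "b")
        assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")

    def test_equal_rates_give_null_delta(self):
        """With treated == control rates, cohort ΔSNV is centered on zero."""
        from crossmut.burden import delta_snv, sample_burdens

        configs = self._tiny_configs(n_control=4, n_treated=4)
        deltas = []
        for rep in range(40):
            ds = simulate_cohort(configs, seed=100 + rep)
            for c in configs:
                sb = [sample_burdens(s) for s in ds.calls_for(c.species_name)]
                deltas.append(delta_snv(sb, n_boot=0).delta_snv)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se

    def test_duplicate_species_rejected(self):
        configs = self._tiny_configs()
        configs[1] = type(configs[1])(
            **{**configs[1].__dict__, "species_name": "sp0"}
        )
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort(configs, seed=0)

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(self._tiny_configs()[:1], seed=0)

    def test_effect_model_overrides_rates(self):
        configs = default_cohort_configs(genome_length=10_000, callable_bases=1_000_000)
        ds = simulate_cohort(configs[:3], effect_model=lambda mls: 5.0, seed=1)
        # metadata shape and per-sample structure
        assert len(ds.metadata) == 3
        assert len(ds.samples) == 3 * 6

    def test_default_effect_model_endpoints(self):
        assert default_effect_model(3.0) == pytest.approx(0.3 + 0.8)
        assert default_effect_model(211.0) == pytest.approx(0.3 + 0.35)
        assert default_effect_model(20.0) < default_effect_model(3.0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"genome_length": 500},
            {"mls_years": -1},
            {"control_rate_per_mb": -0.1},
            {"signature_weights_control": [0.5, 0.5, 0.5]},
        ],
    )
    def test_invalid_config(self, kw):
        with pytest.raises(ValueError):
            SimSpeciesConfig(species_name="x", **kw)
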