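import numpy as np
import pytest

from prsport import (
    PopulationModel,
    PopulationSpec,
    ScoreSet,
    TruthSet,
    build_weight_table,
    expected_prs_moments,
    simulate_frequencies,
    simulate_genotypes,
    simulate_phenotypes,
    write_fixture,
)


def _model(**kw):
    defaults = dict(
        n_snps=100,
        populations=[PopulationSpec("A", 50, 0.01), PopulationSpec("B", 50, 0.1, 0.05)],
        seed=1,
    )
    defaults.update(kw)
    return PopulationModel(**defaults)


class TestModelValidation:
    def test_bad_fst_rejected(self):
        with pytest.raises(ValueError, match="F must"):
            _model(populations=[PopulationSpec("A", 10, 1.5)])

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            _model(populations=[PopulationSpec("A", 1, 0.1)])

    def test_bad_freq_range_rejected(self):
        with pytest.raises(ValueError):
            _model(ancestral_freq_range=(0.0, 0.9))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            _model(populations=[PopulationSpec("A", 10, 0.1)] * 2)


class TestSimulateFrequencies:
    def test_small_fst_limit_tracks_ancestral(self):
        model = _model(
            n_snps=2000,
            populations=[PopulationSpec("A", 10, 1e-4)],
            ancestral_freq_range=(0.2, 0.8),
        )
        truth = simulate_frequencies(model)
        assert np.abs(truth.pop_freqs["A"] - truth.ancestral_freqs).max() < 0.05

    def test_balding_nichols_mean_and_variance(self):
        # Beta(p(1-F)/F, (1-p)(1-F)/F): mean p, variance F p (1-p)
        model = _model(
            n_snps=10000,
            populations=[PopulationSpec("A", 10, 0.1)],
            ancestral_freq_range=(0.499, 0.501),
            seed=23,
        )
        truth = simulate_frequencies(model)
        dev = truth.pop_freqs["A"] - truth.ancestral_freqs
        assert abs(dev.mean()) < 3 * dev.std() / np.sqrt(len(dev))
        emp_var = np.mean(dev**2)
        se_var = np.std(dev**2) / np.sqrt(len(dev))
        assert abs(emp_var - 0.1 * 0.5 * 0.5) < 3 * se_var

    def test_shift_moves_risk_allele_frequency(self):
        model = _model(n_snps=500, seed=2)
        truth = simulate_frequencies(model)
        sign = np.sign(truth.weights)
        no_shift_model = _model(
            n_snps=500, seed=2,
            populations=[PopulationSpec("A", 50, 0.01), PopulationSpec("B", 50, 0.1, 0.0)],
        )
        base = simulate_frequencies(no_shift_model)
        moved = (truth.pop_freqs["B"] - base.pop_freqs["B"]) * sign
        base_freq = base.pop_freqs["B"]
        # only SNPs untouched by clipping before AND after the shift move by
        # exactly delta
        unclipped = (
            (base_freq > 0.01) & (base_freq < 0.99)
            & (base_freq + 0.05 * sign > 0.01) & (base_freq + 0.05 * sign < 0.99)
        )
        np.testing.assert_allclose(moved[unclipped], 0.05, atol=1e-12)

    def test_frequencies_clipped_to_open_interval(self):
        model = _model(n_snps=2000, populations=[PopulationSpec("A", 10, 0.5, 0.3)])
        truth = simulate_frequencies(model)
        assert truth.pop_freqs["A"].min() >= 0.01
        assert truth.pop_freqs["A"].max() <= 0.99

    def test_double_weighting_applied(self):
        model = _model(pi_range=(0.2, 0.8))
        truth = simulate_frequencies(model)
        np.testing.assert_allclose(truth.weights, truth.betas * truth.pis)
        assert truth.pis.min() >= 0.2 and truth.pis.max() <= 0.8


class TestSimulateGenotypes:
    def test_fixed_frequency_one_gives_all_homozygous(self):
        model = _model(n_snps=5, populations=[PopulationSpec("A", 20, 0.01)])
        truth = simulate_frequencies(model)
        truth.pop_freqs["A"] = np.ones(5)
        matrix = simulate_genotypes(truth, model)
        np.testing.assert_array_equal(matrix.dosages, 2.0)

    def test_mean_dosage_matches_binomial_expectation(self):
        model = _model(n_snps=1, populations=[PopulationSpec("A", 10000, 0.01)])
        truth = simulate_frequencies(model)
        truth.pop_freqs["A"] = np.array([0.5])
        matrix = simulate_genotypes(truth, model)
        se = np.sqrt(2 * 0.5 * 0.5 / 10000)
        assert abs(matrix.dosages.mean() - 1.0) < 3 * se

    def test_deterministic_under_seed(self):
        model = _model(seed=77)
        t1, t2 = simulate_frequencies(model), simulate_frequencies(model)
        m1 = simulate_genotypes(t1, model)
        m2 = simulate_genotypes(t2, model)
        np.testing.assert_array_equal(m1.dosages, m2.dosages)
        np.testing.assert_array_equal(m1.sample_ids, m2.sample_ids)

    def test_matrix_is_effect_oriented(self):
        model = _model()
        truth = simulate_frequencies(model)
        matrix = simulate_genotypes(truth, model)
        np.testing.assert_array_equal(matrix.alt, truth.effect_alleles)
        np.testing.assert_array_equal(matrix.ref, truth.other_alleles)


class TestExpectedPrsMoments:
    def test_single_snp_closed_form(self):
        truth = TruthSet(
            snp_ids=np.array(["rs1"], dtype=object),
            effect_alleles=np.array(["G"], dtype=object),
            other_alleles=np.array(["A"], dtype=object),
            ancestral_freqs=np.array([0.5]),
            pop_freqs={"A": np.array([0.5])},
            betas=np.array([1.0]), pis=None, weights=np.array([1.0]),
        )
        table = build_weight_table(["rs1"], ["G"], ["A"], [1.0])
        mean, var = expected_prs_moments(truth, table, "A")
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(0.5)

    def test_zero_weights_give_zero_moments(self):
        model = _model()
        truth = simulate_frequencies(model)
        truth.weights[:] = 0.0
        truth.betas[:] = 0.0
        mean, var = expected_prs_moments(truth, truth.weight_table(), "A")
        assert mean == 0.0 and var == 0.0

    def test_empirical_mean_within_clt_band(self):
        model = _model(
            n_snps=500, populations=[PopulationSpec("A", 2000, 0.05)], seed=3
        )
        truth = simulate_frequencies(model)
        matrix = simulate_genotypes(truth, model)
        table = truth.weight_table()
        mean, var = expected_prs_moments(truth, table, "A")
        raw = matrix.dosages @ table.weights
        assert abs(raw.mean() - mean) < 4 * np.sqrt(var / 2000)


class TestSimulatePhenotypes:
    def _scores(self, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        return ScoreSet([f"s{i}" for i in range(n)], x, scaled=x)

    def test_prevalence_hits_target(self):
        s = self._scores()
        y = simulate_phenotypes(s, true_or=1.76, prevalence_target=0.2, seed=5)
        se = np.sqrt(0.2 * 0.8 / 5000)
        assert abs(y.mean() - 0.2) < 3 * se

    def test_or_one_means_independence(self):
        s = self._scores(seed=1)
        y = simulate_phenotypes(s, true_or=1.0, prevalence_target=0.3, seed=6)
        r = np.corrcoef(s.scaled, y)[0, 1]
        assert abs(r) < 3 / np.sqrt(5000)

    def test_bad_prevalence_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotypes(self._scores(n=10), 1.5, 0.0, seed=1)


class TestWriteFixture:
    def test_exact_category_counts(self, tmp_path):
        model = _model(n_snps=1000, seed=4)
        fixture = write_fixture(
            model, tmp_path, palindromic_fraction=0.1, absent_fraction=0.05,
            ref_effect_fraction=0.2,
        )
        counts = fixture.categories["category"].value_counts()
        assert counts["palindromic"] == 100
        assert counts["absent"] == 50
        assert counts["ref_effect"] == 200

    def test_zero_fractions_mean_no_exclusions(self, tmp_path):
        from prsport import harmonize, load_weights, read_genotypes

        model = _model(n_snps=100, seed=5)
        fixture = write_fixture(
            model, tmp_path, ref_effect_fraction=0.0, palindromic_fraction=0.0,
            absent_fraction=0.0,
        )
        table = load_weights(fixture.weights)
        matrix, log = read_genotypes(fixture.vcf, table)
        hset = harmonize(matrix, table, log=log)
        assert len(hset.log) == 0
        assert hset.matrix.n_snps == 100

    def test_invalid_fractions_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_fixture(_model(), tmp_path, palindromic_fraction=0.8,
                          absent_fraction=0.4)


def test_full_pipeline_bit_identical_under_seed(tmp_path):
    from prsport import RunConfig, run_pipeline

    model = _model(n_snps=150, seed=99)
    outputs = []
    for rep in ("r1", "r2"):
        fixture = write_fixture(model, tmp_path / rep, alias_fraction=0.05,
                                missing_rate=0.02)
        config = RunConfig(
            vcf=str(fixture.vcf), weights=str(fixture.weights),
            pop_map=str(fixture.pop_map), alias_map=str(fixture.alias_map),
            out_dir=str(tmp_path / rep / "report"), seed=99,
        )
        run_pipeline(config)
        outputs.append((tmp_path / rep / "report" / "scores.tsv").read_bytes())
    assert outputs[0] == outputs[1]
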