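import numpy as np
import pytest

from prsport import (
    PopulationModel,
    PopulationSpec,
    ScoreSet,
    build_weight_table,
    compare_effect_allele_freqs,
    genotype_pca,
    orient_to_risk_increasing,
    prs_pc1_correlation,
    simulate_frequencies,
    simulate_genotypes,
    top_effect_snps,
)
from prsport.genotypes import GenotypeMatrix


def _two_pop_matrix(seed=0, fst=0.2, n_snps=2000, n=100):
    model = PopulationModel(
        n_snps=n_snps,
        populations=[PopulationSpec("A", n, fst), PopulationSpec("B", n, fst)],
        seed=seed,
    )
    truth = simulate_frequencies(model)
    return simulate_genotypes(truth, model), truth, model


class TestGenotypePCA:
    def test_pc1_separates_differentiated_populations(self):
        matrix, _, _ = _two_pop_matrix(seed=7)
        pca = genotype_pca(matrix, n_components=2)
        pc1 = pca.scores[:, 0]
        a = pc1[matrix.populations == "A"]
        b = pc1[matrix.populations == "B"]
        pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert abs(a.mean() - b.mean()) > 5 * pooled_sd

    def test_identical_rows_rejected(self):
        dosages = np.ones((10, 5))
        matrix = GenotypeMatrix(
            dosages, [f"s{i}" for i in range(10)], [f"rs{j}" for j in range(5)],
            ["A"] * 5, ["G"] * 5,
        )
        with pytest.raises(ValueError, match="monomorphic"):
            genotype_pca(matrix, n_components=1)

    def test_decomposition_properties(self):
        matrix, _, _ = _two_pop_matrix(seed=3, n_snps=300, n=40)
        pca = genotype_pca(matrix, n_components=4)
        evf = pca.explained_variance_fraction
        assert evf.sum() <= 1.0 + 1e-12
        assert (np.diff(evf) <= 1e-12).all()
        gram = pca.loadings @ pca.loadings.T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)
        assert (pca.loadings.sum(axis=1) >= 0).all()

    def test_too_many_components_rejected(self):
        matrix, _, _ = _two_pop_matrix(seed=3, n_snps=50, n=10)
        with pytest.raises(ValueError, match="n_components"):
            genotype_pca(matrix, n_components=20)

    def test_sample_permutation_invariance_up_to_sign(self):
        matrix, _, _ = _two_pop_matrix(seed=5, n_snps=200, n=30)
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_samples)
        permuted = GenotypeMatrix(
            matrix.dosages[perm], matrix.sample_ids[perm], matrix.snp_ids,
            matrix.ref, matrix.alt, matrix.populations[perm],
        )
        base = genotype_pca(matrix, n_components=2).scores
        other = genotype_pca(permuted, n_components=2).scores
        for k in range(2):
            diff = np.minimum(
                np.abs(other[:, k] - base[perm, k]).max(),
                np.abs(other[:, k] + base[perm, k]).max(),
            )
            assert diff < 1e-8

    def test_missing_dosages_mean_substituted(self):
        matrix, _, _ = _two_pop_matrix(seed=9, n_snps=100, n=20)
        holey = matrix.dosages.copy()
        holey[0, 0] = np.nan
        withnan = GenotypeMatrix(
            holey, matrix.sample_ids, matrix.snp_ids,
            matrix.ref, matrix.alt, matrix.populations,
        )
        result = genotype_pca(withnan, n_components=1)
        assert np.isfinite(result.scores).all()


class TestPrsPc1Correlation:
    def test_perfect_correlation_when_prs_is_pc1(self):
        matrix, _, _ = _two_pop_matrix(seed=2, n_snps=200, n=40)
        pc1 = genotype_pca(matrix, n_components=1, population="A").scores[:, 0]
        scaled = np.zeros(matrix.n_samples)
        scaled[matrix.populations == "A"] = pc1
        scores = ScoreSet(
            matrix.sample_ids, scaled, populations=matrix.populations, scaled=scaled
        )
        r, p = prs_pc1_correlation(scores, matrix, "A")
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert p < 1e-20

    def test_admixture_gradient_detected(self):
        # samples interpolating between two diverged frequency sets produce
        # a PC1 gradient that the frequency-driven PRS tracks
        rng = np.random.default_rng(4)
        m, n = 400, 120
        w = rng.normal(0, 0.1, size=m)
        pa = rng.uniform(0.1, 0.9, size=m)
        # risk-allele frequencies rise along the admixture gradient so the
        # PRS tracks it by construction
        pb = np.clip(pa + 0.3 * np.sign(w), 0.05, 0.95)
        admix = np.linspace(0, 1, n)[:, None]
        p_ind = (1 - admix) * pa + admix * pb
        dosages = rng.binomial(2, p_ind).astype(float)
        matrix = GenotypeMatrix(
            dosages, [f"s{i}" for i in range(n)], [f"rs{j}" for j in range(m)],
            ["A"] * m, ["G"] * m, ["MIX"] * n,
        )
        raw = dosages @ w
        scaled = (raw - raw.mean()) / raw.std(ddof=1)
        scores = ScoreSet(
            matrix.sample_ids, raw, populations=matrix.populations, scaled=scaled
        )
        r, p = prs_pc1_correlation(scores, matrix, "MIX")
        assert abs(r) > 0.5 and p < 1e-6

    def test_constant_prs_rejected(self):
        matrix, _, _ = _two_pop_matrix(seed=2, n_snps=50, n=20)
        scaled = np.zeros(matrix.n_samples)
        scores = ScoreSet(
            matrix.sample_ids, scaled, populations=matrix.populations, scaled=scaled
        )
        with pytest.raises(ValueError, match="constant"):
            prs_pc1_correlation(scores, matrix, "A")


class TestTopEffectSnps:
    def test_orders_by_absolute_weight(self):
        table = build_weight_table(
            ["rs1", "rs2", "rs3"], ["A"] * 3, ["G"] * 3, [0.1, -0.5, 0.3]
        )
        top = top_effect_snps(table, 2)
        assert list(top.snp_ids) == ["rs2", "rs3"]

    def test_k_equals_n_returns_whole_table(self):
        table = build_weight_table(["rs1", "rs2"], ["A"] * 2, ["G"] * 2, [0.1, 0.2])
        assert top_effect_snps(table, 2).n_snps == 2

    def test_tie_broken_by_lexicographic_id(self):
        table = build_weight_table(
            ["rs_b", "rs_a", "rs_c"], ["A"] * 3, ["G"] * 3, [0.2, -0.2, 0.2]
        )
        top = top_effect_snps(table, 2)
        assert list(top.snp_ids) == ["rs_a", "rs_b"]

    def test_k_too_large_rejected(self):
        table = build_weight_table(["rs1"], ["A"], ["G"], [0.1])
        with pytest.raises(ValueError):
            top_effect_snps(table, 2)


class TestCompareEffectAlleleFreqs:
    def _matrix(self, dosages, pops):
        dosages = np.asarray(dosages, dtype=float)
        m = dosages.shape[1]
        return GenotypeMatrix(
            dosages, [f"s{i}" for i in range(dosages.shape[0])],
            [f"rs{j}" for j in range(m)], ["A"] * m, ["G"] * m, pops,
        )

    def test_hand_frequencies(self):
        matrix = self._matrix(
            [[2, 0], [2, 1], [2, 2], [1, 1]], ["X", "X", "X", "Y"]
        )
        table = build_weight_table(["rs0", "rs1"], ["G", "G"], ["A", "A"], [0.1, 0.2])
        out = compare_effect_allele_freqs(matrix, table, "X", "Y")
        assert out["freq_X"].tolist() == [1.0, 0.5]  # 6/6 and 3/6
        assert out["freq_Y"].tolist() == [0.5, 0.5]

    def test_orientation_invariance(self):
        # expressing the same SNP with swapped stored alleles and
        # complemented dosages must give identical risk-allele frequencies
        dosages = np.array([[0.0], [1.0], [2.0], [2.0], [1.0]])
        pops = ["X"] * 4 + ["Y"]
        as_alt = self._matrix(dosages, pops)  # effect G stored as ALT
        swapped = GenotypeMatrix(
            2.0 - dosages, as_alt.sample_ids, as_alt.snp_ids,
            ["G"], ["A"], pops,
        )  # dosages count A, effect G is now REF
        table = orient_to_risk_increasing(
            build_weight_table(["rs0"], ["G"], ["A"], [0.4])
        )
        f1 = compare_effect_allele_freqs(as_alt, table, "X", "Y")["freq_X"][0]
        f2 = compare_effect_allele_freqs(swapped, table, "X", "Y")["freq_X"][0]
        assert f1 == f2 == pytest.approx(5 / 8)

    def test_absent_snp_skipped_with_warning(self):
        matrix = self._matrix([[1], [1]], ["X", "Y"])
        table = build_weight_table(["rs0", "rs_gone"], ["G"] * 2, ["A"] * 2, [0.1, 0.2])
        with pytest.warns(UserWarning, match="rs_gone"):
            out = compare_effect_allele_freqs(matrix, table, "X", "Y")
        assert list(out["snp_id"]) == ["rs0"]

    def test_directional_shift_recovered_in_top_snps(self):
        # delta = +0.05 on risk alleles in B: mean(freq_B - freq_A) over the
        # top SNPs should sit within 3 combined binomial SEs of 0.05
        model = PopulationModel(
            n_snps=500,
            populations=[
                PopulationSpec("A", 400, 0.001, 0.0),
                PopulationSpec("B", 400, 0.001, 0.05),
            ],
            seed=13,
        )
        truth = simulate_frequencies(model)
        matrix = simulate_genotypes(truth, model)
        table = orient_to_risk_increasing(truth.weight_table())
        top = top_effect_snps(table, 50)
        out = compare_effect_allele_freqs(matrix, top, "A", "B")
        diffs = out["freq_B"] - out["freq_A"]
        se = np.sqrt(np.mean(2 * 0.5 * 0.5 / (2 * 400)) / len(out))
        assert abs(diffs.mean() - 0.05) < 3 * se + 0.01


def test_no_differentiation_means_no_prs_shift():
    # F -> 0 and delta = 0: cross-population mean PRS difference stays
    # within 4 standard errors of zero
    model = PopulationModel(
        n_snps=1000,
        populations=[
            PopulationSpec("A", 500, 0.0005, 0.0),
            PopulationSpec("B", 500, 0.0005, 0.0),
        ],
        seed=19,
    )
    truth = simulate_frequencies(model)
    matrix = simulate_genotypes(truth, model)
    w = truth.weights
    raw = matrix.dosages @ w
    a = raw[matrix.populations == "A"]
    b = raw[matrix.populations == "B"]
    p = truth.ancestral_freqs
    bn_var = float(np.sum(4 * w**2 * (2 * 0.0005) * p * (1 - p)))
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b) + bn_var)
    assert abs(a.mean() - b.mean()) < 4 * se
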