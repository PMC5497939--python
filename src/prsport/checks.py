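"""Self-contained end-to-end checks of the pipeline's statistical contracts.

Each function runs one study-condition scenario from scratch — simulate,
score, stratify or decompose — and returns the measured quantities together
with the analytic reference values, so callers (the test suite, the
reproduction script) can apply their own pass thresholds.  All randomness is
derived from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from .ancestry import genotype_pca, prs_pc1_correlation
from .genotypes import GenotypeMatrix
from .harmonize import harmonize
from .scoring import ScoreSet, compute_prs, scale_scores
from .simulate import (
    PopulationModel,
    PopulationSpec,
    expected_prs_moments,
    simulate_frequencies,
    simulate_genotypes,
    simulate_phenotypes,
    write_fixture,
)
from .stratify import (
    assign_quintiles,
    cross_population_shift,
    fit_prs_logistic,
    summarize_population,
)
from .weights import build_weight_table, load_weights


def _sub_seed(seed: int, k: int) -> int:
    return (int(seed) * 1000 + k) % (2**31)


def scoring_loop_discrepancy(seed: int, n_instances: int = 100) -> dict:
    """Vectorized PRS vs the explicit per-sample/per-SNP double loop.

    Random instances up to 50 samples x 200 SNPs with 10% missing dosages,
    scored under every missing policy; returns the largest absolute
    difference seen.
    """
    rng = np.random.default_rng(_sub_seed(seed, 1))
    worst = 0.0
    total = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, 51))
        m = int(rng.integers(1, 201))
        dosages = rng.integers(0, 3, size=(n, m)).astype(float)
        dosages[rng.random((n, m)) < 0.1] = np.nan
        w = rng.normal(0, 0.1, size=m)
        ids = np.array([f"rs{j}" for j in range(m)], dtype=object)
        matrix = GenotypeMatrix(
            dosages, np.array([f"s{i}" for i in range(n)], dtype=object),
            ids, np.array(["A"] * m, dtype=object), np.array(["G"] * m, dtype=object),
        )
        table = build_weight_table(ids, ["G"] * m, ["A"] * m, w)
        for policy in ("mean_dosage", "zero"):
            got = compute_prs(matrix, table, missing_policy=policy).raw
            want = _loop_prs(dosages, w, policy)
            worst = max(worst, float(np.abs(got - want).max()))
        total += n * m
    return {"max_abs_diff": worst, "n": total}


def _loop_prs(dosages: np.ndarray, weights: np.ndarray, policy: str) -> np.ndarray:
    n, m = dosages.shape
    col_mean = np.zeros(m)
    for j in range(m):
        vals = [dosages[i, j] for i in range(n) if not np.isnan(dosages[i, j])]
        col_mean[j] = sum(vals) / len(vals) if vals else 0.0
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(m):
            x = dosages[i, j]
            if np.isnan(x):
                if policy == "mean_dosage":
                    x = col_mean[j]
                else:
                    continue
            acc += weights[j] * x
        out[i] = acc
    return out


def _scored_study(model: PopulationModel) -> tuple[ScoreSet, object]:
    truth = simulate_frequencies(model)
    matrix = simulate_genotypes(truth, model)
    table = truth.weight_table()
    hset = harmonize(matrix, table, drop_palindromic=False)
    return scale_scores(compute_prs(hset, table)), truth


def scaling_contract(seed: int) -> dict:
    """Pooled mean/SD of scaled scores over a synthetic two-population run."""
    model = PopulationModel(
        n_snps=300,
        populations=[PopulationSpec("A", 150, 0.01), PopulationSpec("B", 150, 0.05, 0.03)],
        seed=_sub_seed(seed, 2),
    )
    scores, _ = _scored_study(model)
    return {
        "mean": float(scores.scaled.mean()),
        "sd": float(scores.scaled.std(ddof=1)),
        "n": scores.n_samples,
    }


def quintile_occupancy(seed: int, n: int = 1000) -> dict:
    """Own-threshold quintile counts within one simulated population."""
    model = PopulationModel(
        n_snps=400, populations=[PopulationSpec("P", n, 0.01)],
        seed=_sub_seed(seed, 3),
    )
    scores, _ = _scored_study(model)
    table = summarize_population(scores)
    assigned = assign_quintiles(scores, table, "P")
    counts = np.bincount(assigned["quintile"].to_numpy(), minlength=6)[1:6]
    return {"counts": counts, "max_dev": int(np.abs(counts - n // 5).max()), "n": n}


def moment_recovery(seed: int, n_snps: int = 5000, n_per_pop: int = 2000) -> dict:
    """Empirical vs analytic raw-PRS mean and variance, five populations.

    Analytic moments use the realized per-population frequencies, so the
    only discrepancy is binomial sampling noise; deviations are reported as
    multiples of the standard error (mean: sqrt(var/n); variance:
    var*sqrt(2/(n-1)) by the normal approximation the CLT justifies here).
    """
    pops = [
        PopulationSpec("EST", n_per_pop, 0.004),
        PopulationSpec("EUR", n_per_pop, 0.005),
        PopulationSpec("SAS", n_per_pop, 0.03),
        PopulationSpec("EAS", n_per_pop, 0.05),
        PopulationSpec("AFR", n_per_pop, 0.08),
    ]
    model = PopulationModel(n_snps=n_snps, populations=pops, seed=_sub_seed(seed, 4))
    truth = simulate_frequencies(model)
    table = truth.weight_table()
    rng_free = simulate_genotypes(truth, model)
    raw = rng_free.dosages @ table.weights
    mean_z, var_z = [], []
    for spec in pops:
        mask = rng_free.populations == spec.label
        mean, var = expected_prs_moments(truth, table, spec.label)
        x = raw[mask]
        mean_z.append(abs(x.mean() - mean) / np.sqrt(var / spec.n_samples))
        var_z.append(abs(x.var(ddof=1) - var) / (var * np.sqrt(2.0 / (spec.n_samples - 1))))
    return {
        "max_mean_z": float(max(mean_z)),
        "max_var_z": float(max(var_z)),
        "n": n_per_pop * len(pops),
    }


def shift_mechanism(seed: int, delta: float = 0.05, n: int = 1000) -> dict:
    """Directional risk-allele shift: observed vs analytic 2*delta*sum|w|.

    Two nearly undifferentiated populations (F = 5e-4) so the
    Balding-Nichols realization noise stays subdominant; the discrepancy SE
    combines the two samples' mean SEs with the analytic realization term
    sum(4 w^2 (F_a+F_b) p (1-p)).  Also counts the shifted population's
    samples landing in the reference population's top own-quintile.
    """
    fst = 5e-4
    model = PopulationModel(
        n_snps=1000,
        populations=[
            PopulationSpec("REF", n, fst, 0.0),
            PopulationSpec("SHIFT", n, fst, delta),
        ],
        seed=_sub_seed(seed, 5),
    )
    scores, truth = _scored_study(model)
    w = truth.weights
    raw = scores.raw
    pops = scores.populations
    obs_diff = raw[pops == "SHIFT"].mean() - raw[pops == "REF"].mean()
    analytic = 2.0 * delta * np.abs(w).sum()
    p = truth.ancestral_freqs
    bn_var = float(np.sum(4.0 * w**2 * (2 * fst) * p * (1 - p)))
    _, var_ref = expected_prs_moments(truth, truth.weight_table(), "REF")
    se = np.sqrt(2.0 * var_ref / n + bn_var)

    qtable = summarize_population(scores)
    frac = cross_population_shift(scores, qtable, "REF", "SHIFT")
    # shift size on the within-population SD axis vs the transfer threshold
    within_sd = np.sqrt(var_ref)
    q80_gap = (qtable.row("REF")["q80"] - qtable.row("REF")["mean"]) * raw.std(ddof=1)
    return {
        "observed_diff": float(obs_diff),
        "analytic_diff": float(analytic),
        "z": float(abs(obs_diff - analytic) / se),
        "top_quintile_fraction": float(frac[4]),
        "shift_exceeds_threshold": bool(analytic > q80_gap + within_sd),
        "n": 2 * n,
    }


def null_integrity(seed: int, n: int = 1000, n_reps: int = 200) -> dict:
    """No differentiation, no shift: transfer uniformity and PC1 null rate.

    Part 1: three populations with equal tiny F and delta = 0; every
    cross-population quintile-transfer cell should sit near 0.2 within the
    combined sampling error: binomial sqrt(0.2*0.8/n) plus the
    Balding-Nichols realization term (the independent frequency draws give
    each population pair a random mean offset of SD
    sqrt(sum 4 w^2 * 2F * p(1-p)) raw, which perturbs a quintile cell by at
    most the normal density at the quintile boundary times that offset on
    the scaled axis).
    Part 2: within one homogeneous population, a PRS drawn independently of
    the genotypes should reject the PRS-PC1 correlation test at ~5%.
    """
    fst = 5e-4
    model = PopulationModel(
        n_snps=1000,
        populations=[PopulationSpec(lbl, n, fst) for lbl in ("A", "B", "C")],
        seed=_sub_seed(seed, 6),
    )
    scores, truth = _scored_study(model)
    qtable = summarize_population(scores)
    max_dev = 0.0
    for ref in ("A", "B", "C"):
        for target in ("A", "B", "C"):
            frac = cross_population_shift(scores, qtable, ref, target)
            max_dev = max(max_dev, float(np.abs(frac - 0.2).max()))
    w = truth.weights
    p = truth.ancestral_freqs
    bn_shift_raw = np.sqrt(np.sum(4.0 * w**2 * (2 * fst) * p * (1 - p)))
    bn_shift_scaled = bn_shift_raw / scores.raw.std(ddof=1)
    # steepest quintile-boundary density of a standard normal is phi(0.84)
    cell_se = np.sqrt(0.2 * 0.8 / n + (0.2803 * bn_shift_scaled) ** 2)

    rng = np.random.default_rng(_sub_seed(seed, 7))
    rejections = 0
    for rep in range(n_reps):
        sub = PopulationModel(
            n_snps=200, populations=[PopulationSpec("P", 500, 0.01)],
            seed=int(rng.integers(2**31)),
        )
        truth = simulate_frequencies(sub)
        matrix = simulate_genotypes(truth, sub)
        x = rng.normal(size=500)
        null_scores = ScoreSet(
            matrix.sample_ids, x, populations=matrix.populations, scaled=x
        )
        _, p = prs_pc1_correlation(null_scores, matrix, "P")
        rejections += p < 0.05
    return {
        "max_transfer_dev": max_dev,
        "transfer_cell_se": float(cell_se),
        "rejection_rate": rejections / n_reps,
        "n_reps": n_reps,
        "n": 3 * n,
    }


def pca_separation(seed: int) -> dict:
    """PC1 class-mean separation, two populations at F = 0.2."""
    model = PopulationModel(
        n_snps=2000,
        populations=[PopulationSpec("A", 100, 0.2), PopulationSpec("B", 100, 0.2)],
        seed=_sub_seed(seed, 8),
    )
    truth = simulate_frequencies(model)
    matrix = simulate_genotypes(truth, model)
    pca = genotype_pca(matrix, n_components=2)
    pc1 = pca.scores[:, 0]
    a, b = pc1[matrix.populations == "A"], pc1[matrix.populations == "B"]
    pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return {
        "separation_sds": float(abs(a.mean() - b.mean()) / pooled_sd),
        "n": matrix.n_samples,
    }


def or_recovery(seed: int, true_or: float = 1.76, n: int = 5000, n_reps: int = 100) -> dict:
    """Logistic OR recovery: point estimate and 95% CI coverage over reps."""
    rng = np.random.default_rng(_sub_seed(seed, 9))
    x = rng.normal(size=n)
    scores = ScoreSet([f"s{i}" for i in range(n)], x, scaled=x)
    covered = 0
    first_or = None
    for rep in range(n_reps):
        y = simulate_phenotypes(
            scores, true_or=true_or, prevalence_target=0.15,
            seed=int(rng.integers(2**31)),
        )
        fit = fit_prs_logistic(scores, y)
        if first_or is None:
            first_or = fit.odds_ratio
        covered += fit.covers(true_or)
    return {
        "odds_ratio": float(first_or),
        "coverage": covered / n_reps,
        "true_or": true_or,
        "n": n,
        "n_reps": n_reps,
    }


def harmonization_exactness(seed: int, out_dir, n_snps: int = 1000) -> dict:
    """Constructed-fixture bookkeeping: exact exclusion counts, exact flips."""
    from .genotypes import attach_populations, read_genotypes

    model = PopulationModel(
        n_snps=n_snps,
        populations=[PopulationSpec("A", 40, 0.01), PopulationSpec("B", 40, 0.05)],
        seed=_sub_seed(seed, 10),
    )
    fixture = write_fixture(
        model, out_dir, ref_effect_fraction=0.3, palindromic_fraction=0.1,
        absent_fraction=0.05, alias_fraction=0.05, missing_rate=0.02,
    )
    table = load_weights(fixture.weights)
    matrix, log = read_genotypes(fixture.vcf, table, alias_map=fixture.alias_map)
    matrix = attach_populations(matrix, fixture.pop_map)
    hset = harmonize(matrix, table, drop_palindromic=True, log=log)
    counts = hset.log.counts()

    col_of = {s: j for j, s in enumerate(fixture.matrix.snp_ids)}
    max_err = 0.0
    for j, sid in enumerate(hset.matrix.snp_ids):
        got = hset.matrix.dosages[:, j]
        want = fixture.matrix.dosages[:, col_of[sid]]
        both = ~(np.isnan(got) | np.isnan(want))
        if not (np.isnan(got) == np.isnan(want)).all():
            max_err = np.inf
        elif both.any():
            max_err = max(max_err, float(np.abs(got[both] - want[both]).max()))
    cat_counts = fixture.categories["category"].value_counts()
    return {
        "palindromic_logged": counts["palindromic"],
        "palindromic_constructed": int(cat_counts.get("palindromic", 0)),
        "not_in_vcf_logged": counts["not_in_vcf"],
        "absent_constructed": int(cat_counts.get("absent", 0)),
        "flip_max_abs_err": max_err,
        "retained_plus_dropped": hset.matrix.n_snps + len(hset.log),
        "model_snps": table.n_snps,
        "n": n_snps,
    }
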