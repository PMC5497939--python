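"""Quantile-based risk stratification and cross-population threshold transfer.

Risk stratification by PRS is quantile-based: within a reference cohort,
individuals are split into quintiles of the score distribution and the top
quintile is read as highest genetic risk.  The portability question is what
happens when one population's absolute thresholds are applied to samples
from another population whose score distribution is shifted — this module
quantifies exactly that, and validates the score's effect scale with a
single-covariate logistic fit (odds ratio per pooled-SD unit of PRS).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import ScoreSet

_QUANTILE_COLUMNS = [
    "population", "n", "mean", "ci_low", "ci_high",
    "min", "q20", "q40", "q60", "q80", "max",
]


@dataclass
class QuantileTable:
    """Per-population summary of the scaled-PRS distribution.

    One row per population: mean with normal-approximation 95% CI, min/max,
    and the 20/40/60/80% quintile thresholds computed with the
    linear-interpolation empirical quantile estimator.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _QUANTILE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"quantile table missing column(s) {missing}")
        self.frame = self.frame.reset_index(drop=True)
        for _, row in self.frame.iterrows():
            seq = [row["min"], row["q20"], row["q40"], row["q60"], row["q80"], row["max"]]
            if not all(a <= b for a, b in zip(seq, seq[1:])):
                raise ValueError(
                    f"non-monotone quantiles for population {row['population']!r}"
                )
            if not (row["ci_low"] <= row["mean"] <= row["ci_high"]):
                raise ValueError(
                    f"CI does not bracket mean for population {row['population']!r}"
                )

    @property
    def populations(self) -> list:
        return list(self.frame["population"])

    def row(self, population: str) -> pd.Series:
        hit = self.frame.loc[self.frame["population"] == population]
        if hit.empty:
            raise KeyError(f"population {population!r} not in quantile table")
        return hit.iloc[0]

    def thresholds(self, population: str) -> np.ndarray:
        """The four quintile cut-points (q20, q40, q60, q80)."""
        row = self.row(population)
        return row[["q20", "q40", "q60", "q80"]].to_numpy(dtype=float)

    def write_tsv(self, path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return path


def summarize_population(scores: ScoreSet, min_samples: int = 5) -> QuantileTable:
    """Per-population mean, 95% CI, extremes and quintile thresholds.

    Works on the pooled-scaled axis so rows are directly comparable across
    populations.  A population with fewer than ``min_samples`` samples is a
    hard error naming it.  The 95% CI is mean +/- 1.96*sd/sqrt(n).
    """
    scaled = scores.require_scaled()
    pops = scores.require_populations()
    rows = []
    for pop in _ordered_unique(pops):
        x = scaled[pops == pop]
        n = len(x)
        if n < min_samples:
            raise ValueError(
                f"population {pop!r} has {n} samples; need >= {min_samples}"
            )
        half = 1.96 * x.std(ddof=1) / np.sqrt(n)
        q20, q40, q60, q80 = np.quantile(x, [0.2, 0.4, 0.6, 0.8], method="linear")
        rows.append(
            {
                "population": pop, "n": n,
                "mean": x.mean(), "ci_low": x.mean() - half, "ci_high": x.mean() + half,
                "min": x.min(), "q20": q20, "q40": q40, "q60": q60, "q80": q80,
                "max": x.max(),
            }
        )
    return QuantileTable(pd.DataFrame(rows, columns=_QUANTILE_COLUMNS))


def _ordered_unique(values) -> list:
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def assign_quintiles(
    scores: ScoreSet, table: QuantileTable, reference_pop: str
) -> pd.DataFrame:
    """Assign every sample a quintile 1-5 against one population's thresholds.

    A score exactly at a threshold falls in the lower quintile (so a score
    equal to q80 is quintile 4); scores beyond the reference extremes still
    map to quintile 1 or 5 — that unbounded tail behaviour is what makes
    threshold transfer to a shifted population degenerate.
    """
    scaled = scores.require_scaled()
    cuts = table.thresholds(reference_pop)
    quintile = 1 + (scaled[:, np.newaxis] > cuts[np.newaxis, :]).sum(axis=1)
    return pd.DataFrame(
        {
            "sample_id": scores.sample_ids,
            "population": (
                scores.populations if scores.populations is not None else "NA"
            ),
            "reference_population": reference_pop,
            "quintile": quintile,
        }
    )


def cross_population_shift(
    scores: ScoreSet, table: QuantileTable, reference_pop: str, target_pop: str
) -> np.ndarray:
    """Fraction of the target population falling in each reference quintile.

    Returns five fractions summing to 1.  With ``target == reference`` this
    is uniform fifths up to 1/n; under a distribution shift the mass piles
    into the extreme quintiles.
    """
    pops = scores.require_populations()
    mask = pops == target_pop
    if not mask.any():
        raise KeyError(f"population {target_pop!r} has no samples")
    assigned = assign_quintiles(scores, table, reference_pop)
    q = assigned.loc[np.asarray(mask), "quintile"].to_numpy()
    counts = np.bincount(q, minlength=6)[1:6]
    return counts / counts.sum()


@dataclass
class LogisticPRSFit:
    """Single-covariate logistic fit of a binary phenotype on scaled PRS."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    slope: float
    slope_se: float
    p_value: float
    n: int

    def covers(self, odds_ratio: float) -> bool:
        return self.ci_low <= odds_ratio <= self.ci_high


def fit_prs_logistic(scores: ScoreSet, phenotype) -> LogisticPRSFit:
    """Maximum-likelihood logistic regression of phenotype on scaled PRS.

    The reported odds ratio is per scaled-PRS unit, i.e. per pooled standard
    deviation of the score, with a Wald 95% CI.  Requires both phenotype
    classes; complete separation is a hard error.
    """
    scaled = scores.require_scaled()
    y = np.asarray(phenotype, dtype=float)
    if y.shape != scaled.shape:
        raise ValueError("phenotype length does not match score set")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("phenotype must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("phenotype has a single class; cannot fit logistic model")
    if scaled[y == 1].min() > scaled[y == 0].max() or (
        scaled[y == 1].max() < scaled[y == 0].min()
    ):
        raise ValueError("complete separation: PRS perfectly splits the classes")

    X = sm.add_constant(scaled)
    fit = sm.Logit(y, X).fit(disp=0)
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    return LogisticPRSFit(
        odds_ratio=float(np.exp(slope)),
        ci_low=float(np.exp(slope - 1.96 * se)),
        ci_high=float(np.exp(slope + 1.96 * se)),
        slope=slope,
        slope_se=se,
        p_value=float(fit.pvalues[1]),
        n=len(y),
    )
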