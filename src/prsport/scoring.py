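"""Polygenic risk score computation and pooled scaling.

The score of sample j is the weighted effect-allele count

    PRS_j = sum_i w_i * X_ij,    X_ij in {0, 1, 2}

with missing dosages substituted per an explicit policy.  For
comparability across populations, scores are z-scored over ALL samples
pooled — never per population: the between-population shift is the signal
of interest and per-population scaling would erase it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .harmonize import HarmonizedSet
from .weights import WeightTable

MISSING_POLICIES = ("mean_dosage", "zero", "drop_snp_for_sample")


@dataclass
class ScoreSet:
    """Per-sample raw and (optionally) pooled-scaled scores."""

    sample_ids: np.ndarray
    raw: np.ndarray
    populations: np.ndarray | None = None
    n_snps_used: np.ndarray | None = None
    scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
        if self.n_snps_used is not None:
            self.n_snps_used = np.asarray(self.n_snps_used, dtype=int)
        if self.scaled is not None:
            self.scaled = np.asarray(self.scaled, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.raw)

    def require_scaled(self) -> np.ndarray:
        if self.scaled is None:
            raise ValueError("scores have not been scaled; call scale_scores first")
        return self.scaled

    def require_populations(self) -> np.ndarray:
        if self.populations is None:
            raise ValueError("score set has no population labels")
        return self.populations

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"sample_id": self.sample_ids})
        frame["population"] = (
            self.populations if self.populations is not None else "NA"
        )
        frame["raw"] = self.raw
        frame["scaled"] = self.scaled if self.scaled is not None else np.nan
        frame["n_snps_used"] = (
            self.n_snps_used if self.n_snps_used is not None else -1
        )
        return frame

    def write_tsv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
        return path


def read_scores(path) -> ScoreSet:
    """Read a score TSV written by :meth:`ScoreSet.write_tsv`."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "population": str},
        float_precision="round_trip",
    )
    scaled = frame["scaled"].to_numpy(dtype=float)
    return ScoreSet(
        sample_ids=frame["sample_id"].to_numpy(dtype=object),
        raw=frame["raw"].to_numpy(dtype=float),
        populations=frame["population"].to_numpy(dtype=object),
        n_snps_used=frame["n_snps_used"].to_numpy(dtype=int),
        scaled=None if np.isnan(scaled).all() else scaled,
    )


def compute_prs(
    harmonized, table: WeightTable, missing_policy: str = "mean_dosage"
) -> ScoreSet:
    """Raw PRS per sample from a harmonized dosage matrix.

    ``missing_policy`` fills missing dosages before the weighted sum:
    ``mean_dosage`` uses the pooled mean dosage of that SNP (the common
    scoring-tool default), ``zero`` substitutes 0, and
    ``drop_snp_for_sample`` omits the term — numerically identical to
    ``zero`` for a sum, but kept as its own name because the intent
    differs.  ``n_snps_used`` records the non-missing SNP count per sample.
    """
    matrix = harmonized.matrix if isinstance(harmonized, HarmonizedSet) else harmonized
    if not isinstance(matrix, GenotypeMatrix):
        raise TypeError("expected a HarmonizedSet or GenotypeMatrix")
    if matrix.n_snps == 0:
        raise ValueError("cannot score an empty SNP set")
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(
            f"unknown missing_policy {missing_policy!r}; choose from {MISSING_POLICIES}"
        )

    lookup = table.frame.set_index("snp_id")["weight"]
    try:
        w = lookup.loc[list(matrix.snp_ids)].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"weight missing for matrix SNP: {exc}") from exc

    X = matrix.dosages
    nan_mask = np.isnan(X)
    n_used = (~nan_mask).sum(axis=1)
    if missing_policy == "mean_dosage":
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(nan_mask.all(axis=0), 0.0, X), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        filled = np.where(nan_mask, col_mean[np.newaxis, :], X)
    else:  # zero / drop_snp_for_sample
        filled = np.where(nan_mask, 0.0, X)
    raw = filled @ w
    return ScoreSet(
        sample_ids=matrix.sample_ids,
        raw=raw,
        populations=matrix.populations,
        n_snps_used=n_used,
    )


def scale_scores(scores: ScoreSet) -> ScoreSet:
    """Z-score raw PRS over the pooled sample set (SD with denominator n-1)."""
    raw = scores.raw
    if len(raw) < 2:
        raise ValueError("scaling requires at least 2 samples")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("raw scores have zero variance; cannot scale")
    scaled = (raw - raw.mean()) / sd
    return ScoreSet(
        sample_ids=scores.sample_ids,
        raw=raw,
        populations=scores.populations,
        n_snps_used=scores.n_snps_used,
        scaled=scaled,
    )
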