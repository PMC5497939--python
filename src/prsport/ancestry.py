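"""Population structure seen through the model's own SNPs.

Even before any weighting, the SNP panel of a large PRS carries ancestry
information: a PCA of the dosage matrix separates continental populations,
and within a population the score can correlate with the leading principal
component — so misclassifying an individual's population systematically
biases their risk estimate.  This module provides the genotype PCA
(with the standard 2p(1-p) dosage normalization), per-population PRS-PC1
correlation, and effect-allele frequency comparison of the top-weight SNPs
between two populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .genotypes import GenotypeMatrix
from .harmonize import HarmonizedSet
from .scoring import ScoreSet
from .weights import WeightTable


@dataclass
class PCAResult:
    """Principal components of a standardized dosage matrix."""

    scores: np.ndarray  # samples x components
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray  # components x SNPs
    snp_ids: np.ndarray
    sample_ids: np.ndarray
    populations: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"sample_id": self.sample_ids})
        frame["population"] = (
            self.populations if self.populations is not None else "NA"
        )
        for k in range(self.scores.shape[1]):
            frame[f"PC{k + 1}"] = self.scores[:, k]
        return frame

    def write_tsv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path


def _standardize_dosages(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-substitute missing values, then center by 2p and scale by
    sqrt(2p(1-p)).  Monomorphic columns are dropped (zero scale); returns
    the standardized matrix and the kept-column mask."""
    X = dosages.copy()
    nan_mask = np.isnan(X)
    if nan_mask.any():
        col_mean = np.nanmean(np.where(nan_mask.all(axis=0), 0.0, X), axis=0)
        X[nan_mask] = np.take(np.nan_to_num(col_mean), np.nonzero(nan_mask)[1])
    p_hat = X.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    # a constant column (monomorphic or all-het) carries no variation and
    # would either divide by zero or inject an exactly-zero direction
    keep = (scale > 0) & (X.var(axis=0) > 0)
    Xs = (X[:, keep] - 2.0 * p_hat[keep]) / scale[keep]
    return Xs, keep


def genotype_pca(
    matrix: GenotypeMatrix, n_components: int = 2, population: str | None = None
) -> PCAResult:
    """PCA of the (standardized) model-SNP dosage matrix.

    ``population`` restricts the decomposition to one population's samples
    (the within-population analysis); by default all samples enter.  Each
    dosage column is centered by twice its allele-frequency estimate and
    scaled by its binomial SD; missing dosages are mean-substituted first
    (scoring keeps its own missing policy — this substitution is local to
    the PCA).  PC signs are fixed so each component's loading sum is
    non-negative.
    """
    if population is not None:
        matrix = matrix.subset_samples(matrix.samples_in(population))
    Xs, keep = _standardize_dosages(matrix.dosages)
    if Xs.shape[1] == 0:
        raise ValueError("all SNP columns are monomorphic or constant; PCA is undefined")
    max_comp = min(Xs.shape[0] - 1, Xs.shape[1])
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, SNPs)={max_comp}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_
    flip = loadings.sum(axis=1) < 0
    loadings[flip] *= -1.0
    scores[:, flip] *= -1.0
    return PCAResult(
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_,
        loadings=loadings,
        snp_ids=matrix.snp_ids[keep],
        sample_ids=matrix.sample_ids,
        populations=matrix.populations,
    )


def prs_pc1_correlation(
    scores: ScoreSet, matrix: GenotypeMatrix, population: str
) -> tuple[float, float]:
    """Pearson correlation between scaled PRS and PC1 within one population.

    The PCA is recomputed on that population's samples only.  Because the
    eigenvector sign is arbitrary, |r| is the meaningful magnitude; the
    signed r is returned as computed under the non-negative-loading-sum
    convention.  Returns ``(r, p_value)`` from the two-sided t-test.
    """
    mask = matrix.samples_in(population)
    if mask.sum() < 3:
        raise ValueError(f"population {population!r} needs >= 3 samples")
    scaled = scores.require_scaled()
    if not np.array_equal(scores.sample_ids, matrix.sample_ids):
        raise ValueError("score set and matrix sample ordering differ")
    pca = genotype_pca(matrix.subset_samples(mask), n_components=1)
    pc1 = pca.scores[:, 0]
    prs = scaled[np.asarray(mask)]
    if np.ptp(prs) == 0 or np.ptp(pc1) == 0:
        raise ValueError("constant PRS or PC1; correlation undefined")
    r, p = stats.pearsonr(prs, pc1)
    return float(r), float(p)


def top_effect_snps(table: WeightTable, k: int) -> WeightTable:
    """The k records with largest |weight| (a proxy for the strongest GWAS
    signals), ties broken by lexicographically smaller SNP ID."""
    if k > table.n_snps:
        raise ValueError(f"k={k} exceeds table size {table.n_snps}")
    frame = table.frame.copy()
    frame["_absw"] = frame["weight"].abs()
    frame = frame.sort_values(
        ["_absw", "snp_id"], ascending=[False, True], kind="mergesort"
    )
    out = frame.head(k).drop(columns="_absw")
    return WeightTable(out, model_name=table.model_name)


def compare_effect_allele_freqs(
    harmonized, subset: WeightTable, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Effect-allele frequencies of a SNP subset in two populations.

    ``subset`` should be risk-increasing oriented (see
    :func:`prsport.weights.orient_to_risk_increasing`) so that "effect
    allele" reads as "risk-raising allele" in both columns.  Frequencies
    are (sum of dosages) / (2 * non-missing samples); the harmonized
    dosages are re-oriented per SNP when the subset's effect allele is the
    harmonized other allele, so the result does not depend on the stored
    orientation.  SNPs absent from the harmonized matrix are skipped with a
    warning.
    """
    if pop_a == pop_b:
        raise ValueError("pop_a and pop_b must differ")
    matrix = harmonized.matrix if isinstance(harmonized, HarmonizedSet) else harmonized
    mask_a = matrix.samples_in(pop_a)
    mask_b = matrix.samples_in(pop_b)
    col_of = {sid: j for j, sid in enumerate(matrix.snp_ids)}
    rows = []
    for _, rec in subset.frame.iterrows():
        sid = rec["snp_id"]
        if sid not in col_of:
            warnings.warn(f"SNP {sid!r} absent from harmonized set; skipped")
            continue
        j = col_of[sid]
        dose = matrix.dosages[:, j]
        if rec["effect_allele"] == matrix.alt[j]:
            pass
        elif rec["effect_allele"] == matrix.ref[j]:
            dose = 2.0 - dose
        else:
            warnings.warn(f"SNP {sid!r}: alleles do not match harmonized set; skipped")
            continue
        rows.append(
            {
                "snp_id": sid,
                "weight": rec["weight"],
                f"freq_{pop_a}": _allele_freq(dose[np.asarray(mask_a)]),
                f"freq_{pop_b}": _allele_freq(dose[np.asarray(mask_b)]),
            }
        )
    return pd.DataFrame(rows, columns=["snp_id", "weight", f"freq_{pop_a}", f"freq_{pop_b}"])


def _allele_freq(dose: np.ndarray) -> float:
    ok = ~np.isnan(dose)
    if not ok.any():
        return float("nan")
    return float(dose[ok].sum() / (2.0 * ok.sum()))
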