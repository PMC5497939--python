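"""PRS weight tables.

A weight table is the polygenic model itself: one row per SNP with its
effect allele, the other allele, the GWAS effect size ``beta`` and, for
double-weighted models, a shrinkage multiplier ``pi`` in [0, 1] applied to
counter the winner's curse.  The final per-SNP weight is

    w_i = beta_i            (single-weighted)
    w_i = beta_i * pi_i     (double-weighted)

Tables are stored as tab-separated text with a header; columns are matched
by name, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

_REQUIRED_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta")


@dataclass
class WeightTable:
    """Ordered per-SNP weights of a polygenic score model.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``snp_id, effect_allele, other_allele, beta, pi, weight``.
        ``pi`` is NaN for single-weighted models.  Row order is the model's
        SNP order and is preserved by all operations.
    model_name : str
        Free-text label, e.g. ``"CHD"`` or ``"T2D"``.
    """

    frame: pd.DataFrame
    model_name: str = "model"

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        _validate_frame(self.frame)

    # -- accessors ---------------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.frame["snp_id"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.frame["weight"].to_numpy(dtype=float)

    def subset(self, snp_ids) -> "WeightTable":
        """Rows for ``snp_ids``, kept in this table's order."""
        wanted = set(snp_ids)
        sub = self.frame[self.frame["snp_id"].isin(wanted)]
        return WeightTable(sub.copy(), model_name=self.model_name)

    def alleles_for(self, snp_id: str) -> tuple[str, str]:
        row = self.frame.loc[self.frame["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(f"SNP {snp_id!r} not in weight table")
        return str(row["effect_allele"].iloc[0]), str(row["other_allele"].iloc[0])


def _validate_frame(frame: pd.DataFrame) -> None:
    for col in (*_REQUIRED_COLUMNS, "weight"):
        if col not in frame.columns:
            raise ValueError(f"weight table missing required column {col!r}")
    dup = frame["snp_id"][frame["snp_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate snp_id in weight table: {dup.iloc[0]!r}")
    for col in ("effect_allele", "other_allele"):
        bad = frame.loc[~frame[col].isin(VALID_BASES), "snp_id"]
        if not bad.empty:
            raise ValueError(
                f"non-ACGT {col} for SNP {bad.iloc[0]!r}"
            )
    same = frame.loc[frame["effect_allele"] == frame["other_allele"], "snp_id"]
    if not same.empty:
        raise ValueError(f"effect_allele == other_allele for SNP {same.iloc[0]!r}")
    if "pi" in frame.columns:
        pi = frame["pi"].dropna()
        if ((pi < 0) | (pi > 1)).any():
            raise ValueError("pi values must lie in [0, 1]")


def build_weight_table(
    snp_ids,
    effect_alleles,
    other_alleles,
    betas,
    pis=None,
    model_name: str = "model",
) -> WeightTable:
    """Construct a :class:`WeightTable` from aligned arrays.

    ``pis=None`` gives a single-weighted model (weight = beta); otherwise
    weight = beta * pi per SNP.
    """
    frame = pd.DataFrame(
        {
            "snp_id": np.asarray(snp_ids, dtype=object),
            "effect_allele": np.asarray(effect_alleles, dtype=object),
            "other_allele": np.asarray(other_alleles, dtype=object),
            "beta": np.asarray(betas, dtype=float),
        }
    )
    if pis is None:
        frame["pi"] = np.nan
        frame["weight"] = frame["beta"]
    else:
        frame["pi"] = np.asarray(pis, dtype=float)
        frame["weight"] = frame["beta"] * frame["pi"]
    return WeightTable(frame, model_name=model_name)


def load_weights(
    path, double_weighted: bool = False, model_name: str | None = None
) -> WeightTable:
    """Read a weight table from tab-separated text.

    The file must have a header naming at least ``snp_id``, ``effect_allele``,
    ``other_allele`` and ``beta``; a ``pi`` column is required iff
    ``double_weighted``.  Weights are computed on load (beta, or beta*pi) and
    parsed as binary64 without rounding.  Row order is preserved.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str}, float_precision="round_trip"
    )
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"weight file {path} missing column(s) {missing}")
    if double_weighted:
        if "pi" not in frame.columns:
            raise ValueError(
                f"weight file {path}: double_weighted requires a 'pi' column"
            )
        if frame["pi"].isna().any():
            bad = frame.loc[frame["pi"].isna(), "snp_id"].iloc[0]
            raise ValueError(f"missing pi for SNP {bad!r} in double-weighted model")
        frame["weight"] = frame["beta"].astype(float) * frame["pi"].astype(float)
    else:
        frame["pi"] = np.nan
        frame["weight"] = frame["beta"].astype(float)
    name = model_name if model_name is not None else path.stem
    return WeightTable(frame[[*_REQUIRED_COLUMNS, "pi", "weight"]], model_name=name)


def write_weights(table: WeightTable, path) -> Path:
    """Write a table as TSV; ``load_weights`` round-trips weights bit-exactly.

    Floats are serialized with repr-level precision (17 significant digits).
    """
    path = Path(path)
    out = table.frame.copy()
    single = out["pi"].isna().all()
    cols = list(_REQUIRED_COLUMNS) if single else [*_REQUIRED_COLUMNS, "pi"]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def orient_to_risk_increasing(table: WeightTable) -> WeightTable:
    """Re-express every SNP so its effect allele is the risk-increasing one.

    Records with negative weight have their alleles swapped and beta/weight
    negated; zero-weight records are untouched.  Idempotent.  Scores change
    only by a per-SNP additive constant (2*|w| for each flipped SNP), so
    score *differences* between samples are invariant.
    """
    frame = table.frame.copy()
    neg = frame["weight"] < 0
    ea = frame.loc[neg, "effect_allele"].copy()
    frame.loc[neg, "effect_allele"] = frame.loc[neg, "other_allele"]
    frame.loc[neg, "other_allele"] = ea
    frame.loc[neg, "beta"] = -frame.loc[neg, "beta"]
    frame.loc[neg, "weight"] = -frame.loc[neg, "weight"]
    return WeightTable(frame, model_name=table.model_name)
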