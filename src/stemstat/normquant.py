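"""Normalization and small quantification utilities.

* median-of-ratios size factors for count matrices (the convention of the
  standard differential-expression framework: per-gene geometric-mean
  reference computed on genes with all-positive counts, per-sample factor
  = median ratio to that reference);
* gene-wise (row) z-scores of normalized expression, as used for heat-map
  matrices;
* ΔΔCt relative quantification for qPCR, with optional per-primer
  amplification efficiencies (Pfaffl form; perfect doubling E = 2 by
  default), centred by subtracting the control group's mean ΔCt;
* the X1 stem-cell fraction of FACS-gated planarian cell populations,
  100 · X1 / (X1 + X2 + Xins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "CtTable",
    "FacsFractions",
    "size_factors",
    "normalize_counts",
    "row_zscore",
    "relative_quantification",
    "x1_fraction",
]


@dataclass
class CountMatrix:
    """Nonnegative integer counts, genes × samples."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


@dataclass
class NormalizedMatrix:
    """Counts divided columnwise by their sample size factors."""

    values: pd.DataFrame
    size_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean across samples, computed
    only on genes with strictly positive counts in every sample; each
    sample's factor is the median over those genes of count / reference.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "size factors need at least one gene with positive counts in all samples"
        )
    logs = np.log(counts[all_pos])
    ref = logs.mean(axis=1, keepdims=True)  # log geometric mean per gene
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def normalize_counts(m: CountMatrix) -> NormalizedMatrix:
    sf = size_factors(m)
    return NormalizedMatrix(values=m.counts / sf, size_factors=sf)


def row_zscore(values) -> pd.DataFrame:
    """Gene-wise z-scores: per row, (x − mean) / sd with sample sd (n−1).

    Constant rows cannot be standardized and are mapped to all-zero rows
    with a warning.  A single-column matrix is an error.
    """
    df = pd.DataFrame(values)
    if df.shape[1] < 2:
        raise ValueError("row z-scores need at least two columns")
    x = df.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) mapped to zeros", stacklevel=2
        )
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns)


@dataclass
class CtTable:
    """qPCR Ct values: one row per sample with target and reference Ct."""

    rows: pd.DataFrame  # columns: sample, group, ct_target, ct_reference
    control_group: str

    def __post_init__(self) -> None:
        required = {"sample", "group", "ct_target", "ct_reference"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        for col in ("ct_target", "ct_reference"):
            if not np.isfinite(self.rows[col].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite Ct values in {col}")
        if not (self.rows["group"] == self.control_group).any():
            raise ValueError(f"control group {self.control_group!r} not present")

    @classmethod
    def from_tsv(cls, path, control_group: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), control_group)


def relative_quantification(
    t: CtTable,
    efficiency_target: float = 2.0,
    efficiency_reference: float = 2.0,
) -> pd.Series:
    """Per-sample fold change by ΔΔCt relative quantification.

    ΔCt = ct_target − ct_reference per sample; ΔΔCt subtracts the mean ΔCt
    of the control group.  With equal amplification efficiencies the fold
    change is E^(−ΔΔCt); with per-primer efficiencies it is the Pfaffl
    ratio E_t^(−ΔCt_t,scaled) · E_r^(ΔCt_r,scaled), each Ct centred on the
    control-group mean.  Control-group folds have geometric mean 1 by
    construction.
    """
    if efficiency_target <= 1 or efficiency_reference <= 1:
        raise ValueError("amplification efficiencies must exceed 1")
    df = t.rows
    ctrl = df["group"] == t.control_group
    if efficiency_target == efficiency_reference:
        dct = df["ct_target"] - df["ct_reference"]
        ddct = dct - dct[ctrl].mean()
        fold = np.power(efficiency_target, -ddct)
    else:
        dct_t = df["ct_target"] - df.loc[ctrl, "ct_target"].mean()
        dct_r = df["ct_reference"] - df.loc[ctrl, "ct_reference"].mean()
        fold = np.power(efficiency_target, -dct_t) * np.power(
            efficiency_reference, dct_r
        )
    return pd.Series(fold.to_numpy(), index=df["sample"].to_numpy(), name="fold")


@dataclass(frozen=True)
class FacsFractions:
    """FACS percentages of the X1 / X2 / Xins gates among live cells."""

    x1: float
    x2: float
    xins: float

    def __post_init__(self) -> None:
        if min(self.x1, self.x2, self.xins) < 0:
            raise ValueError("percentages must be nonnegative")
        if self.x1 + self.x2 + self.xins <= 0:
            raise ValueError("X1 + X2 + Xins must be positive")


def x1_fraction(f: FacsFractions) -> float:
    """Share of the proliferative X1 gate: 100 · X1 / (X1 + X2 + Xins)."""
    return 100.0 * f.x1 / (f.x1 + f.x2 + f.xins)
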