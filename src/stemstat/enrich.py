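"""Gene-set overlap enrichment against an explicit background.

Differentially expressed genes (DEGs) are genes with a Benjamini–Hochberg
adjusted p-value below a threshold (0.05 by default), optionally restricted
to strong signals (|log2 fold change| above a cutoff).  Overlap of the DEG
set with a named gene set is tested with the hypergeometric upper tail
against a caller-supplied background universe; directional skew within the
overlap is tested with a one-sided exact binomial whose null success
probability — the *ground probability* — is the empirical fraction of all
DEGs regulated in the tested direction.

Backgrounds are always explicit arguments: different analyses legitimately
use different universes (all measured genes, or only the genes assignable
to a particular transcriptome assembly), so the universe is never inferred
from the inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEGTable",
    "GeneSet",
    "GeneSetCollection",
    "OverlapTestResult",
    "DirectionalTestResult",
    "filter_degs",
    "hypergeometric_overlap",
    "ground_probability",
    "directional_binomial",
    "bh_adjust",
    "enrich_report",
]

DEG_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj"]


@dataclass
class DEGTable:
    """Per-gene differential-expression results plus the background size.

    ``records`` must carry columns gene_id, log2fc, pvalue, padj with unique
    gene ids; ``universe_size`` is the number of measured genes (the
    enrichment background), at least as large as the table itself.
    """

    records: pd.DataFrame
    universe_size: int

    def __post_init__(self) -> None:
        missing = [c for c in DEG_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"DEG table missing columns: {missing}")
        if self.records["gene_id"].duplicated().any():
            dup = self.records.loc[self.records["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids: {sorted(set(dup))[:5]}")
        if self.universe_size < len(self.records) or self.universe_size <= 0:
            raise ValueError(
                f"universe_size {self.universe_size} inconsistent with "
                f"{len(self.records)} records"
            )
        for col in ("pvalue", "padj"):
            vals = self.records[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_tsv(cls, path, universe_size: int | None = None) -> "DEGTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df, universe_size if universe_size is not None else len(df))

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class GeneSet:
    """A named, flat list of gene identifiers (no ontology structure)."""

    name: str
    source: str
    members: list[str]

    def __post_init__(self) -> None:
        # duplicated ids within a set are collapsed before any counting
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m, None)
        self.members = list(seen)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, i):
        return self.sets[i]

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass(frozen=True)
class OverlapTestResult:
    """Hypergeometric overlap of a DEG set with a gene set.

    ``x`` overlap count, ``K`` DEG count, ``n`` set size within the
    background, ``N`` background size, ``p_hyper`` the inclusive upper tail
    P(X >= x).
    """

    x: int
    K: int
    n: int
    N: int
    p_hyper: float


@dataclass(frozen=True)
class DirectionalTestResult:
    """One-sided binomial test of directional skew within an overlap."""

    m: int
    d: int
    p0: float
    p_binom: float
    direction: str


def filter_degs(
    table: DEGTable,
    alpha: float = 0.05,
    min_abs_lfc: float | None = None,
) -> set[str]:
    """Gene ids passing the DEG definition: padj strictly below ``alpha``
    and, when ``min_abs_lfc`` is given, |log2fc| strictly above it."""
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    df = table.records
    if df["padj"].isna().any():
        bad = df.loc[df["padj"].isna(), "gene_id"].iloc[0]
        raise ValueError(f"missing padj for gene {bad!r}")
    keep = df["padj"] < alpha
    if min_abs_lfc is not None:
        keep &= df["log2fc"].abs() > min_abs_lfc
    return set(df.loc[keep, "gene_id"])


def hypergeometric_overlap(
    deg_ids: set[str], gene_set: GeneSet, background: set[str]
) -> OverlapTestResult:
    """Inclusive upper-tail hypergeometric test of DEG / gene-set overlap.

    Both sets are restricted to the background first.  With ``N`` background
    genes, ``K`` DEGs, ``n`` set members in the background and overlap
    ``x``, the p-value is P(X >= x) for X ~ Hypergeometric(N, K, n); an
    empty overlap gives p = 1 exactly.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    deg = set(deg_ids) & bg
    members = set(gene_set.members) & bg
    x = len(deg & members)
    K, n, N = len(deg), len(members), len(bg)
    if n == 0:
        warnings.warn(
            f"gene set {gene_set.name!r} lies entirely outside the background",
            stacklevel=2,
        )
        return OverlapTestResult(x=0, K=K, n=0, N=N, p_hyper=1.0)
    if x == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(x - 1, N, n, K))
    return OverlapTestResult(x=x, K=K, n=n, N=N, p_hyper=p)


def ground_probability(
    table: DEGTable, direction: str, alpha: float = 0.05
) -> float:
    """Empirical fraction of DEGs regulated in ``direction``.

    This is the null success probability of the directional binomial test.
    Genes with log2fc exactly 0 carry no direction and are excluded from
    numerator and denominator alike.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    df = table.records
    if df["padj"].isna().any():
        bad = df.loc[df["padj"].isna(), "gene_id"].iloc[0]
        raise ValueError(f"missing padj for gene {bad!r}")
    degs = df[(df["padj"] < alpha) & (df["log2fc"] != 0)]
    if len(degs) == 0:
        raise ValueError(f"no DEGs with direction at alpha={alpha}")
    if direction == "down":
        d = int((degs["log2fc"] < 0).sum())
    else:
        d = int((degs["log2fc"] > 0).sum())
    return d / len(degs)


def directional_binomial(d: int, m: int, p0: float) -> float:
    """One-sided exact binomial tail P(X >= d) for X ~ Binomial(m, p0)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not (0 <= d <= m):
        raise ValueError(f"need 0 <= d <= m, got d={d}, m={m}")
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if d == 0:
        return 1.0
    return float(stats.binom.sf(d - 1, m, p0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, preserving input order.

    Sort ascending, multiply p_(i) by m/i, take the cumulative minimum from
    the largest rank down, cap at 1 and restore the original order.  The
    adjusted values dominate the raw ones elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def enrich_report(
    deg_table: DEGTable,
    sets: GeneSetCollection,
    background: set[str],
    alpha: float = 0.05,
    min_abs_lfc: float | None = None,
    directions: tuple[str, ...] = ("up", "down"),
) -> pd.DataFrame:
    """Batch enrichment report: one row per gene set, in input order.

    Each row carries the hypergeometric overlap statistics plus, per tested
    direction, the directional count within the overlap, the ground
    probability from the whole DEG universe and the one-sided binomial
    p-value (NaN when the overlap has no directed genes).  A BH-adjusted
    hypergeometric column is appended across the collection.
    """
    deg_ids = filter_degs(deg_table, alpha=alpha, min_abs_lfc=min_abs_lfc)
    lfc = dict(zip(deg_table.records["gene_id"], deg_table.records["log2fc"]))
    p0 = {dd: ground_probability(deg_table, dd, alpha=alpha) for dd in directions}
    bg = set(background)
    rows = []
    for gs in sets:
        ov = hypergeometric_overlap(deg_ids, gs, bg)
        overlap_genes = (deg_ids & set(gs.members)) & bg
        directed = [g for g in overlap_genes if lfc.get(g, 0.0) != 0.0]
        m = len(directed)
        row: dict = {
            "set": gs.name, "source": gs.source,
            "x": ov.x, "K": ov.K, "n": ov.n, "N": ov.N,
            "p_hyper": ov.p_hyper, "m": m,
        }
        for dd in directions:
            if dd == "down":
                d = sum(lfc[g] < 0 for g in directed)
            else:
                d = sum(lfc[g] > 0 for g in directed)
            row[f"d_{dd}"] = d
            row[f"p0_{dd}"] = p0[dd]
            row[f"p_binom_{dd}"] = (
                directional_binomial(d, m, p0[dd]) if m > 0 else np.nan
            )
        rows.append(row)
    report = pd.DataFrame(rows)
    if len(report):
        report["p_hyper_adj"] = bh_adjust(report["p_hyper"].to_numpy())
    return report
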