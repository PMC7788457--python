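"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses consume,
not the raw assays behind it:

* grouped two-group time courses with per-timepoint effect sizes in
  noise-sd units (group sizes 3 + 3 over 5 timepoints by default, the
  design of the expression series the separation-run test was built for);
* differential-expression result tables with a controlled number of true
  DEGs, a controlled proportion of down-regulated genes and BH-adjusted
  p-values (defaults: 6,339 true DEGs with down-proportion 0.5534 in a
  20,000-gene universe — the scale of the planarian X1 comparison);
* gene-set collections with tunable overlap enrichment and directional
  bias;
* toy genome annotations plus transcript alignments with coverage and
  identity values, with planted unique / ambiguous / sub-threshold
  transcripts for the ID-mapping stage.

Every generator is a pure function of its config and seed; emitted files
are byte-identical across runs and round-trip through the package's
readers.  The accompanying truth objects suffice to compute every
downstream expected value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ssio
from .enrich import DEGTable, GeneSet, GeneSetCollection, bh_adjust
from .idmap import AlignmentRecord, GeneModel, GenomeInterval
from .septest import GroupedTimeCourse

__all__ = [
    "TimecourseConfig",
    "DEGConfig",
    "SetsConfig",
    "GenomeConfig",
    "SimConfig",
    "gen_timecourse",
    "gen_timecourse_batch",
    "gen_deg_table",
    "gen_gene_sets",
    "gen_genome_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class TimecourseConfig:
    """Two-group time-course design: T timepoints, group sizes n1/n2,
    per-timepoint group-B effects in units of the noise sd."""

    T: int = 5
    n1: int = 3
    n2: int = 3
    effects: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.T < 1 or self.n1 < 1 or self.n2 < 1:
            raise ValueError("T, n1, n2 must be positive")
        if len(self.effects) != self.T:
            raise ValueError("effects must list one value per timepoint")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class DEGConfig:
    """DEG-universe model: ``n_true`` genes get small p-values from
    Beta(beta_a, 1) and signed log2 fold changes (log-normal magnitude,
    negative with probability ``prop_down``); nulls get Uniform(0,1)
    p-values and small symmetric fold changes."""

    n_genes: int = 20_000
    n_true: int = 6_339
    prop_down: float = 0.5534
    beta_a: float = 0.1
    lfc_log_mean: float = 0.0
    lfc_log_sd: float = 0.5
    null_lfc_sd: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.n_true <= self.n_genes):
            raise ValueError("need 0 <= n_true <= n_genes")
        if not (0.0 <= self.prop_down <= 1.0):
            raise ValueError("prop_down must be in [0, 1]")
        if not (0 < self.beta_a <= 1):
            raise ValueError("beta_a must be in (0, 1]")


@dataclass(frozen=True)
class SetsConfig:
    """Gene-set collection: ``n_enriched`` sets sample DEG members with
    probability inflated by ``rho``; the rest are uniform draws from the
    universe.  ``delta`` fixes the down-fraction among a set's DEG
    members (None keeps the table's own directions)."""

    n_sets: int = 20
    set_size: int = 800
    rho: float = 1.0
    delta: float | None = None
    n_enriched: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1 or self.set_size < 1:
            raise ValueError("n_sets and set_size must be positive")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        if self.delta is not None and not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must be in [0, 1]")
        if not (0 <= self.n_enriched <= self.n_sets):
            raise ValueError("need 0 <= n_enriched <= n_sets")


@dataclass(frozen=True)
class GenomeConfig:
    """Toy single-chromosome genome for the ID-mapping stage."""

    n_genes: int = 100
    gene_length: tuple[int, int] = (600, 2000)
    gap: tuple[int, int] = (200, 800)
    n_transcripts: int = 100
    frac_ambiguous: float = 0.1
    frac_filtered: float = 0.1
    jitter_frac: float = 0.1
    n_published: int = 30

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_transcripts < 1:
            raise ValueError("n_genes and n_transcripts must be positive")
        if self.frac_ambiguous + self.frac_filtered > 1:
            raise ValueError("planted fractions exceed 1")
        if not (0.0 <= self.jitter_frac < 0.5):
            raise ValueError("jitter_frac must be in [0, 0.5)")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    timecourse: TimecourseConfig = field(default_factory=TimecourseConfig)
    deg: DEGConfig = field(default_factory=DEGConfig)
    sets: SetsConfig = field(default_factory=SetsConfig)
    genome: GenomeConfig = field(default_factory=GenomeConfig)


def gen_timecourse(
    cfg: TimecourseConfig = TimecourseConfig(), seed: int = 0
) -> tuple[GroupedTimeCourse, dict]:
    """One grouped time course: group A ~ N(0, sd²); group B gets the
    per-timepoint effect (in sd units) added.  Truth records the effects
    and which timepoints carry a true group difference."""
    rng = np.random.default_rng(seed)
    n = cfg.n1 + cfg.n2
    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.T, n))
    shifts = np.array(cfg.effects) * cfg.noise_sd
    values[:, cfg.n1:] += shifts[:, None]
    tc = GroupedTimeCourse(
        timepoints=list(range(cfg.T)),
        values=values,
        group=["A"] * cfg.n1 + ["B"] * cfg.n2,
    )
    truth = {
        "effects": list(cfg.effects),
        "null_timepoints": [t for t, e in enumerate(cfg.effects) if e == 0],
    }
    return tc, truth


def gen_timecourse_batch(
    cfg: TimecourseConfig, n_series: int, seed: int = 0
) -> np.ndarray:
    """Many series at once, shape (n_series, T, n1+n2); the first n1
    sample columns are group A.  Used for calibration studies."""
    rng = np.random.default_rng(seed)
    n = cfg.n1 + cfg.n2
    values = rng.normal(0.0, cfg.noise_sd, size=(n_series, cfg.T, n))
    shifts = np.array(cfg.effects) * cfg.noise_sd
    values[:, :, cfg.n1:] += shifts[None, :, None]
    return values


def gen_deg_table(
    cfg: DEGConfig = DEGConfig(), seed: int = 0
) -> tuple[DEGTable, dict]:
    """DEG result table with known true DEGs and directions.

    True DEGs draw p ~ Beta(beta_a, 1) and a signed log-normal log2 fold
    change; nulls draw p ~ Uniform(0, 1) and small symmetric fold changes.
    The adjusted p-values come from the package's own BH step-up.
    """
    rng = np.random.default_rng(seed)
    N, K = cfg.n_genes, cfg.n_true
    gene_ids = np.array([f"g{i:06d}" for i in range(N)])
    true_idx = rng.choice(N, size=K, replace=False)
    is_true = np.zeros(N, dtype=bool)
    is_true[true_idx] = True

    pvals = rng.uniform(0.0, 1.0, size=N)
    if K:
        pvals[true_idx] = rng.beta(cfg.beta_a, 1.0, size=K)
    lfc = rng.normal(0.0, cfg.null_lfc_sd, size=N)
    if K:
        mag = rng.lognormal(cfg.lfc_log_mean, cfg.lfc_log_sd, size=K)
        down = rng.random(K) < cfg.prop_down
        lfc[true_idx] = np.where(down, -mag, mag)
    padj = bh_adjust(pvals)

    df = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": lfc, "pvalue": pvals, "padj": padj}
    )
    table = DEGTable(df, universe_size=N)
    truth = {
        "true_deg_ids": gene_ids[is_true].tolist(),
        "directions": {
            g: ("down" if l < 0 else "up")
            for g, l in zip(gene_ids[is_true], lfc[is_true])
        },
        "prop_down": cfg.prop_down,
        "universe": gene_ids.tolist(),
    }
    return table, truth


def gen_gene_sets(
    universe: list[str],
    truth: dict,
    cfg: SetsConfig = SetsConfig(),
    seed: int = 0,
) -> tuple[GeneSetCollection, dict]:
    """Gene-set collection over ``universe`` with planted enrichment.

    Null sets are uniform draws without replacement.  Enriched sets draw
    their DEG-member count from Binomial(set_size, rho·K/N) — inflating
    the per-member DEG probability by ``rho`` — then fill members from the
    DEG and non-DEG pools; an infeasible rho (rho·K/N > 1) is rejected
    with the maximal feasible value in the message.  ``delta`` overrides
    the down-fraction among each enriched set's DEG members.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    N = len(universe)
    if cfg.set_size > N:
        raise ValueError("set_size exceeds the universe")
    universe_set = set(universe)
    deg_ids = [g for g in truth["true_deg_ids"] if g in universe_set]
    directions = truth.get("directions", {})
    down_pool = [g for g in deg_ids if directions.get(g) == "down"]
    up_pool = [g for g in deg_ids if directions.get(g) == "up"]
    deg_set = set(deg_ids)
    non_deg = sorted(universe_set - deg_set)
    universe_arr = np.asarray(universe, dtype=object)
    non_deg_arr = np.asarray(non_deg, dtype=object)
    deg_arr = np.asarray(deg_ids, dtype=object)
    K = len(deg_ids)
    q = cfg.rho * K / N if N else 0.0
    if cfg.n_enriched and q > 1.0:
        raise ValueError(
            f"rho={cfg.rho} infeasible: rho*K/N must be <= 1 "
            f"(maximal feasible rho = {N / K:.4g})"
        )
    sets = []
    set_truth = {}
    for i in range(cfg.n_sets):
        name = f"set{i:03d}"
        enriched = i < cfg.n_enriched
        if not enriched:
            members = list(rng.choice(universe_arr, size=cfg.set_size, replace=False))
        else:
            d = int(rng.binomial(cfg.set_size, q))
            d = min(d, K, cfg.set_size)
            if cfg.delta is not None:
                n_down = min(int(round(cfg.delta * d)), len(down_pool))
                n_up = min(d - n_down, len(up_pool))
                chosen = list(
                    rng.choice(down_pool, size=n_down, replace=False)
                ) + list(rng.choice(up_pool, size=n_up, replace=False))
            else:
                chosen = list(rng.choice(deg_arr, size=d, replace=False))
            n_rest = cfg.set_size - len(chosen)
            chosen += list(rng.choice(non_deg_arr, size=n_rest, replace=False))
            members = chosen
        gs = GeneSet(name=name, source="simgen", members=[str(m) for m in members])
        sets.append(gs)
        member_degs = [g for g in gs.members if g in deg_set]
        set_truth[name] = {
            "enriched": enriched,
            "rho": cfg.rho if enriched else 1.0,
            "n_deg_members": len(member_degs),
            "n_down_members": sum(
                directions.get(g) == "down" for g in member_degs
            ),
        }
    return GeneSetCollection(sets), set_truth


def gen_genome_fixture(
    cfg: GenomeConfig = GenomeConfig(), seed: int = 0
) -> tuple[list[GeneModel], list[AlignmentRecord], GeneSetCollection, dict]:
    """Toy genome, alignments and a published set with planted mapping truth.

    Unique transcripts get jittered intervals over distinct genes and pass
    the coverage/identity filter; filtered transcripts target a gene but
    draw sub-threshold coverage or identity; ambiguous transcripts span a
    contiguous pair of equal-length genes so that they reciprocally
    overlap both at exactly the 0.5 boundary.
    """
    rng = np.random.default_rng(seed)
    n_amb = int(round(cfg.frac_ambiguous * cfg.n_transcripts))
    n_filt = int(round(cfg.frac_filtered * cfg.n_transcripts))
    n_uniq = cfg.n_transcripts - n_amb - n_filt
    if n_uniq < 0:
        raise ValueError("planted fractions exceed the transcript count")
    if n_uniq + n_filt > cfg.n_genes:
        raise ValueError("not enough genes for the planted unique/filtered targets")

    chrom = "chrT"
    genes: list[GeneModel] = []
    pos = 1000
    lo, hi = cfg.gene_length
    # regular genes, separated by gaps
    for i in range(cfg.n_genes):
        length = int(rng.integers(lo, hi + 1))
        genes.append(
            GeneModel(f"G{i:04d}", GenomeInterval(chrom, pos, pos + length, "+"))
        )
        pos += length + int(rng.integers(cfg.gap[0], cfg.gap[1] + 1))
    # contiguous equal-length pairs for ambiguous transcripts
    pair_starts = []
    for j in range(n_amb):
        length = 2 * (int(rng.integers(lo, hi + 1)) // 2)
        genes.append(
            GeneModel(
                f"GA{j:04d}a", GenomeInterval(chrom, pos, pos + length, "+")
            )
        )
        genes.append(
            GeneModel(
                f"GA{j:04d}b",
                GenomeInterval(chrom, pos + length, pos + 2 * length, "+"),
            )
        )
        pair_starts.append((pos, length))
        pos += 2 * length + int(rng.integers(cfg.gap[0], cfg.gap[1] + 1))

    def _good_quality() -> tuple[float, float]:
        return (
            float(rng.uniform(0.9, 1.0)),
            float(rng.uniform(0.9, 1.0)),
        )

    def _jitter_interval(iv: GenomeInterval) -> GenomeInterval:
        max_j = int(cfg.jitter_frac * len(iv))
        if max_j == 0:
            return iv
        j1 = int(rng.integers(-max_j, max_j + 1))
        j2 = int(rng.integers(-max_j, max_j + 1))
        return GenomeInterval(iv.chrom, iv.start + j1, iv.end + j2, iv.strand)

    targets = rng.choice(cfg.n_genes, size=n_uniq + n_filt, replace=False)
    records: list[AlignmentRecord] = []
    truth_class: dict[str, dict] = {}
    t = 0
    for gi in targets[:n_uniq]:
        gene = genes[gi]
        cov, ident = _good_quality()
        records.append(
            AlignmentRecord(f"t{t:04d}", _jitter_interval(gene.interval), cov, ident)
        )
        truth_class[f"t{t:04d}"] = {"class": "unique", "gene": gene.gene_id}
        t += 1
    for gi in targets[n_uniq:]:
        gene = genes[gi]
        # fail at least one filter
        if rng.random() < 0.5:
            cov = float(rng.uniform(0.5, 0.89))
            ident = float(rng.uniform(0.9, 1.0))
        else:
            cov = float(rng.uniform(0.9, 1.0))
            ident = float(rng.uniform(0.5, 0.89))
        records.append(
            AlignmentRecord(f"t{t:04d}", _jitter_interval(gene.interval), cov, ident)
        )
        truth_class[f"t{t:04d}"] = {"class": "filtered", "gene": gene.gene_id}
        t += 1
    for j, (start, length) in enumerate(pair_starts):
        cov, ident = _good_quality()
        # spans exactly half of each gene in the pair: reciprocal overlap
        # is 0.5 for both genes and for the transcript (inclusive boundary)
        iv = GenomeInterval(chrom, start + length // 2, start + 3 * length // 2, "+")
        records.append(AlignmentRecord(f"t{t:04d}", iv, cov, ident))
        truth_class[f"t{t:04d}"] = {
            "class": "ambiguous",
            "genes": [f"GA{j:04d}a", f"GA{j:04d}b"],
        }
        t += 1

    # published set: transcript ids with an isoform appendix added
    order = rng.permutation(cfg.n_transcripts)[: min(cfg.n_published, t)]
    published_ids = [f"t{i:04d}_{int(rng.integers(1, 4))}" for i in sorted(order)]
    published = GeneSetCollection(
        [GeneSet(name="published_set", source="simgen", members=published_ids)]
    )
    expected_mapped = sorted(
        {
            truth_class[f"t{i:04d}"]["gene"]
            for i in sorted(order)
            if truth_class[f"t{i:04d}"]["class"] == "unique"
        }
    )
    truth = {
        "classes": truth_class,
        "n_unique": n_uniq,
        "n_ambiguous": n_amb,
        "n_filtered": n_filt,
        "published_ids": published_ids,
        "expected_mapped_genes": expected_mapped,
    }
    return genes, records, published, truth


def write_fixture(cfg: SimConfig, outdir) -> dict:
    """Write the full synthetic fixture set to ``outdir`` and return truth.

    Files: timecourse.tsv, degs.tsv, background.txt, sets.gmt,
    annotation.gff3, alignments.bed, published.gmt, truth.json.  Byte
    deterministic for a given config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed

    tc, tc_truth = gen_timecourse(cfg.timecourse, seed=seed)
    tc.to_long().to_csv(outdir / "timecourse.tsv", sep="\t", index=False)

    table, deg_truth = gen_deg_table(cfg.deg, seed=seed + 1)
    table.to_tsv(outdir / "degs.tsv")
    ssio.write_background(table.records["gene_id"], outdir / "background.txt")

    sets, set_truth = gen_gene_sets(
        deg_truth["universe"], deg_truth, cfg.sets, seed=seed + 2
    )
    ssio.write_gmt(sets, outdir / "sets.gmt")

    genes, records, published, genome_truth = gen_genome_fixture(
        cfg.genome, seed=seed + 3
    )
    ssio.write_annotation_gff3(genes, outdir / "annotation.gff3")
    ssio.write_alignments_bed(records, outdir / "alignments.bed")
    ssio.write_gmt(published, outdir / "published.gmt")

    truth = {
        "config": asdict(cfg),
        "timecourse": tc_truth,
        "deg": {k: v for k, v in deg_truth.items() if k != "universe"},
        "sets": set_truth,
        "genome": genome_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
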