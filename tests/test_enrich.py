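"""Enrichment: DEG filtering, hypergeometric/binomial tails, BH, reports."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemstat import simgen
from stemstat.enrich import (
    DEGTable,
    GeneSet,
    GeneSetCollection,
    bh_adjust,
    directional_binomial,
    enrich_report,
    filter_degs,
    ground_probability,
    hypergeometric_overlap,
)


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, x: int) -> float:
    """Oracle: enumerate every K-subset of an N-universe and count those
    overlapping a fixed n-subset in at least x elements."""
    members = set(range(n))
    hits = total = 0
    for draw in itertools.combinations(range(N), K):
        total += 1
        if len(members.intersection(draw)) >= x:
            hits += 1
    return hits / total


def binom_tail_by_enumeration(d: int, m: int, p0: float) -> float:
    """Oracle: sum the probabilities of all 2^m outcome vectors with at
    least d successes."""
    total = 0.0
    for bits in itertools.product((0, 1), repeat=m):
        s = sum(bits)
        if s >= d:
            total += p0**s * (1 - p0) ** (m - s)
    return total


class TestFilterDegs:
    def test_strict_alpha_boundary(self, toy_deg_table):
        assert filter_degs(toy_deg_table, alpha=0.05) == {"g0", "g1", "g5"}

    def test_strong_signal_filter_is_strict(self, toy_deg_table):
        # of the alpha-passing genes, only |lfc| strictly above 0.5 remain
        assert filter_degs(toy_deg_table, alpha=0.05, min_abs_lfc=0.5) == {
            "g0",
            "g5",
        }

    def test_alpha_one_keeps_everything_below_one(self, toy_deg_table):
        assert filter_degs(toy_deg_table, alpha=1.0) == {
            "g0", "g1", "g2", "g3", "g4", "g5",
        }

    def test_missing_padj_names_the_gene(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "log2fc": [1.0, 2.0],
                "pvalue": [0.1, 0.2],
                "padj": [0.1, np.nan],
            }
        )
        with pytest.raises(ValueError, match="'b'"):
            filter_degs(DEGTable(df, universe_size=2))


class TestHypergeometricOverlap:
    def test_zero_overlap_gives_one(self):
        res = hypergeometric_overlap(
            {"a"}, GeneSet("s", "src", ["b", "c"]), {"a", "b", "c", "d"}
        )
        assert res.x == 0 and res.p_hyper == 1.0

    def test_small_case_matches_combinatorics(self):
        # N=10, K=5, n=4, x=4: C(5,4)/C(10,4)... enumerated over DEG draws
        bg = {f"g{i}" for i in range(10)}
        gene_set = GeneSet("s", "src", [f"g{i}" for i in range(4)])
        degs = {"g0", "g1", "g2", "g3", "g9"}
        res = hypergeometric_overlap(degs, gene_set, bg)
        assert res.x == 4 and res.K == 5 and res.n == 4 and res.N == 10
        assert res.p_hyper == pytest.approx(
            hypergeom_tail_by_enumeration(10, 5, 4, 4), abs=1e-12
        )

    def test_every_background_gene_deg_forces_overlap(self):
        bg = {f"g{i}" for i in range(8)}
        gene_set = GeneSet("s", "src", ["g0", "g1", "g2"])
        res = hypergeometric_overlap(bg, gene_set, bg)
        assert res.x == res.n and res.p_hyper == 1.0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap({"a"}, GeneSet("s", "src", ["a"]), set())

    def test_set_outside_background_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="outside the background"):
            res = hypergeometric_overlap(
                {"a"}, GeneSet("s", "src", ["zz"]), {"a", "b"}
            )
        assert res.n == 0 and res.p_hyper == 1.0

    def test_upper_tail_matches_enumeration_on_small_universes(self, rng):
        for _ in range(25):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            bg = {f"g{i}" for i in range(N)}
            degs = {f"g{i}" for i in rng.choice(N, size=K, replace=False)}
            gene_set = GeneSet("s", "src", [f"g{i}" for i in range(n)])
            res = hypergeometric_overlap(degs, gene_set, bg)
            expected = hypergeom_tail_by_enumeration(N, K, n, res.x)
            assert res.p_hyper == pytest.approx(expected, abs=1e-10)

    def test_pmf_sums_to_one_and_tail_decreases(self, rng):
        from scipy import stats

        for _ in range(10):
            N = int(rng.integers(3, 30))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            support = np.arange(lo, hi + 1)
            pmf = stats.hypergeom.pmf(support, N, n, K)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
            tails = stats.hypergeom.sf(support - 1, N, n, K)
            assert np.all(np.diff(tails) < 0)


class TestGroundProbability:
    def test_balanced_directions(self):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(6)],
                "log2fc": [1, -1, 2, -2, 3, -3],
                "pvalue": [0.001] * 6,
                "padj": [0.01] * 6,
            }
        )
        t = DEGTable(df, universe_size=6)
        assert ground_probability(t, "down") == 0.5
        assert ground_probability(t, "up") == 0.5

    def test_zero_lfc_excluded_from_both_sides(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [0.0, -1.0, 2.0],
                "pvalue": [0.001] * 3,
                "padj": [0.01] * 3,
            }
        )
        t = DEGTable(df, universe_size=3)
        assert ground_probability(t, "down") == 0.5

    def test_no_degs_is_an_error(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a"],
                "log2fc": [1.0],
                "pvalue": [0.5],
                "padj": [0.9],
            }
        )
        with pytest.raises(ValueError, match="no DEGs"):
            ground_probability(DEGTable(df, universe_size=1), "down")

    def test_recovers_generator_proportion(self):
        table, truth = simgen.gen_deg_table(
            simgen.DEGConfig(prop_down=0.7, n_true=10_000, n_genes=20_000),
            seed=5,
        )
        p = ground_probability(table, "down")
        assert abs(p - 0.7) <= 3 * math.sqrt(0.7 * 0.3 / 10_000) + 0.01


class TestDirectionalBinomial:
    def test_zero_successes_gives_one(self):
        assert directional_binomial(0, 10, 0.5) == 1.0

    def test_all_successes_is_power(self):
        assert directional_binomial(3, 3, 0.5) == pytest.approx(0.125, abs=1e-15)

    def test_matches_full_enumeration(self):
        assert directional_binomial(8, 10, 0.5534) == pytest.approx(
            binom_tail_by_enumeration(8, 10, 0.5534), abs=1e-12
        )

    def test_enumeration_agreement_across_small_m(self, rng):
        for m in range(1, 13):
            d = int(rng.integers(0, m + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            assert directional_binomial(d, m, p0) == pytest.approx(
                binom_tail_by_enumeration(d, m, p0), abs=1e-12
            )

    @pytest.mark.parametrize(
        "d, m, p0", [(-1, 5, 0.5), (6, 5, 0.5), (1, 0, 0.5), (1, 5, 0.0), (1, 5, 1.0)]
    )
    def test_invalid_arguments_rejected(self, d, m, p0):
        with pytest.raises(ValueError):
            directional_binomial(d, m, p0)


def bh_by_definition(p):
    """Step-up oracle straight from the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_uniform_spacing_collapses(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_ties_preserved(self):
        np.testing.assert_allclose(bh_adjust([0.05, 0.05, 0.05]), [0.05] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_step_up_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_by_definition(p), atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariant_and_dominates_raw(self, p, rand):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        perm = list(range(len(p)))
        rand.shuffle(perm)
        adj_perm = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)

    def test_readjustment_inflates_and_fixes_plateaus(self, rng):
        # step-up is not idempotent in general (p=(0.1, 0.3) -> (0.2, 0.3)
        # -> (0.3, 0.3)); re-adjustment can only inflate, and a fully
        # collapsed (constant) vector is a fixed point
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        again = bh_adjust(adj)
        assert (again >= adj - 1e-15).all()
        const = np.full(7, 0.2)
        np.testing.assert_allclose(bh_adjust(const), const, atol=1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(5):
            p = rng.uniform(size=50)
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestEnrichReport:
    def _small_world(self, seed=0):
        cfg = simgen.DEGConfig(n_genes=2000, n_true=200, prop_down=0.6)
        table, truth = simgen.gen_deg_table(cfg, seed=seed)
        return table, truth

    def test_enriched_set_has_smallest_hypergeometric_p(self):
        wins = 0
        reps = 200
        for rep in range(reps):
            table, truth = self._small_world(seed=100 + rep)
            sets, _ = simgen.gen_gene_sets(
                truth["universe"],
                truth,
                simgen.SetsConfig(n_sets=10, set_size=100, rho=4.0, n_enriched=1),
                seed=500 + rep,
            )
            bg = set(truth["universe"])
            report = enrich_report(table, sets, bg)
            if report.loc[report["p_hyper"].idxmin(), "set"] == "set000":
                wins += 1
        assert wins / reps >= 0.95

    def test_rows_follow_input_set_order(self):
        table, truth = self._small_world()
        sets, _ = simgen.gen_gene_sets(
            truth["universe"], truth, simgen.SetsConfig(n_sets=5, set_size=50),
            seed=3,
        )
        report = enrich_report(table, sets, set(truth["universe"]))
        assert report["set"].tolist() == sets.names()

    def test_disjoint_set_row_has_unit_p_and_no_binomial(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d"],
                "log2fc": [1.0, -1.0, 2.0, 0.5],
                "pvalue": [0.001] * 4,
                "padj": [0.01, 0.01, 0.01, 0.9],
            }
        )
        table = DEGTable(df, universe_size=4)
        sets = GeneSetCollection([GeneSet("lonely", "src", ["d"])])
        report = enrich_report(table, sets, {"a", "b", "c", "d"})
        row = report.iloc[0]
        assert row["p_hyper"] == 1.0 and row["m"] == 0
        assert np.isnan(row["p_binom_down"])

    def test_deterministic(self):
        table, truth = self._small_world()
        sets, _ = simgen.gen_gene_sets(
            truth["universe"], truth, simgen.SetsConfig(n_sets=5, set_size=50),
            seed=3,
        )
        bg = set(truth["universe"])
        r1 = enrich_report(table, sets, bg)
        r2 = enrich_report(table, sets, bg)
        pd.testing.assert_frame_equal(r1, r2)
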