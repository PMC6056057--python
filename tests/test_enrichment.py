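"""Exact tests, BH adjustment, random-gene control and multi-study overlap."""

import math

import numpy as np
import pytest
from scipy import stats

from line1meth.enrichment import (
    ContingencyTable,
    bh_adjust,
    build_contingency,
    enrich_study,
    fisher_exact,
    hypergeom_upper_tail,
    multi_study_overlap,
    random_gene_control,
)
from line1meth.insertions import InsertionRecord, build_gene_sets
from line1meth.simulate import ExpressionSimConfig, simulate_expression_study


# --- independent oracles ----------------------------------------------------


def hypergeom_pmf(k, N, K, n):
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def fisher_two_sided_oracle(a, b, c, d):
    """Sum of hypergeometric point probabilities <= observed (enumeration)."""
    N, K, n = a + b + c + d, a + c, a + b
    p_obs = hypergeom_pmf(a, N, K, n)
    total = 0.0
    for k in range(max(0, n + K - N), min(K, n) + 1):
        pk = hypergeom_pmf(k, N, K, n)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def upper_tail_oracle(a, K, n, N):
    return min(
        sum(hypergeom_pmf(k, N, K, n) for k in range(a, min(K, n) + 1)), 1.0
    )


def bh_oracle(p):
    """By-definition step-up adjustment on a sorted copy."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


# --- tests -------------------------------------------------------------------


class TestBuildContingency:
    def test_hand_count(self):
        t = build_contingency(
            deg_genes={"g1", "g2", "g3", "g4"},
            inserted_genes={"g1", "g2", "g3", "g4", "g5"},
            universe={f"g{i}" for i in range(1, 11)},
        )
        assert (t.a, t.b, t.c, t.d) == (4, 0, 1, 5)

    def test_empty_deg_set(self):
        t = build_contingency(set(), {"g1"}, {"g1", "g2"})
        assert (t.a, t.b) == (0, 0)

    def test_inserted_equals_universe(self):
        u = {"g1", "g2", "g3"}
        t = build_contingency({"g1"}, u, u)
        assert (t.b, t.d) == (0, 0)

    def test_out_of_universe_degs_intersected(self):
        t = build_contingency({"g1", "zz"}, {"g1"}, {"g1", "g2"})
        assert t.a + t.b == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            build_contingency({"g"}, {"g"}, set())


class TestFisherExact:
    def test_hand_enumeration_case(self):
        p, oddsr = fisher_exact(ContingencyTable(4, 0, 1, 5), "greater")
        assert p == pytest.approx(5 / 210, abs=1e-12)
        assert oddsr == math.inf

    def test_balanced_tiny_table_two_sided_p1(self):
        p, _ = fisher_exact(ContingencyTable(1, 1, 1, 1), "two_sided")
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            cells = rng.multinomial(rng.integers(4, 30), [0.25] * 4)
            t = ContingencyTable(*[int(x) for x in cells])
            if t.degenerate():
                continue
            p2, _ = fisher_exact(t, "two_sided")
            pg, _ = fisher_exact(t, "greater")
            assert p2 == pytest.approx(
                fisher_two_sided_oracle(t.a, t.b, t.c, t.d), abs=1e-12)
            assert pg == pytest.approx(
                upper_tail_oracle(t.a, t.a + t.c, t.a + t.b, t.n), abs=1e-12)

    def test_cross_checked_against_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            cells = [int(x) for x in rng.integers(0, 12, 4)]
            t = ContingencyTable(*cells)
            if t.degenerate():
                continue
            p2, _ = fisher_exact(t, "two_sided")
            assert p2 == pytest.approx(
                stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1], abs=1e-9)

    def test_degenerate_margin_gives_p1(self):
        p, oddsr = fisher_exact(ContingencyTable(0, 0, 3, 4), "two_sided")
        assert p == 1.0
        assert math.isnan(oddsr)


class TestHypergeomUpperTail:
    def test_a_zero_gives_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_hand_case_4dp(self):
        assert hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(0.0238, abs=5e-5)

    def test_monotone_nonincreasing_in_a(self):
        ps = [hypergeom_upper_tail(a, 8, 6, 20) for a in range(7)]
        assert all(x >= y - 1e-15 for x, y in zip(ps, ps[1:]))

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            N = int(rng.integers(2, 40))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n + K - N), min(K, n)
            a = int(rng.integers(lo, hi + 1))
            assert hypergeom_upper_tail(a, K, n, N) == pytest.approx(
                upper_tail_oracle(a, K, n, N), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent|support"):
            hypergeom_upper_tail(5, 3, 3, 10)


class TestBhAdjust:
    def test_hand_case(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_by_definition_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 50)))
            assert np.max(np.abs(bh_adjust(p) - bh_oracle(p))) <= 1e-15


class TestRandomGeneControl:
    def test_reproducible_from_seed(self):
        universe = {f"g{i}" for i in range(100)}
        ins = {f"g{i}" for i in range(30)}
        deg = {f"g{i}" for i in range(0, 100, 7)}
        r1 = random_gene_control(deg, ins, universe, n_draws=50, seed=4)
        r2 = random_gene_control(deg, ins, universe, n_draws=50, seed=4)
        assert np.array_equal(r1.draw_ps, r2.draw_ps)
        assert r1.observed_p_hypergeom == r2.observed_p_hypergeom

    def test_empty_deg_set_gives_p1(self):
        r = random_gene_control(set(), {"g1"}, {f"g{i}" for i in range(10)},
                                n_draws=5, seed=1)
        assert r.observed_overlap == 0
        assert r.observed_p_hypergeom == 1.0

    def test_enriched_list_beats_random_draws(self):
        rng = np.random.default_rng(23)
        universe = {f"g{i}" for i in range(500)}
        ins = {f"g{i}" for i in range(150)}
        # a deliberately enriched DEG list: 30 of 40 genes inserted
        deg = {f"g{i}" for i in range(30)} | {f"g{i}" for i in range(400, 410)}
        r = random_gene_control(deg, ins, universe, n_draws=500, seed=int(rng.integers(100)))
        assert r.observed_p_hypergeom < np.quantile(r.draw_ps, 0.05)
        assert r.empirical_rank < 0.05

    def test_invalid_draw_count_rejected(self):
        with pytest.raises(ValueError, match="n_draws"):
            random_gene_control({"g1"}, {"g1"}, {"g1", "g2"}, n_draws=0)


class TestMultiStudyOverlap:
    def test_hand_case(self):
        v = multi_study_overlap({"s1": {"g1", "g2"}, "s2": {"g2", "g3"}, "s3": {"g3"}})
        assert v.at_least(2) == {"g2", "g3"}

    def test_disjoint_lists(self):
        v = multi_study_overlap({"s1": {"a"}, "s2": {"b"}})
        assert v.at_least(2) == frozenset()

    def test_identical_lists(self):
        v = multi_study_overlap({"s1": {"a", "b"}, "s2": {"a", "b"}})
        assert v.at_least(2) == {"a", "b"}

    def test_regions_partition_the_union(self):
        rng = np.random.default_rng(31)
        lists = {
            f"s{j}": {f"g{i}" for i in rng.integers(0, 40, size=15)}
            for j in range(4)
        }
        v = multi_study_overlap(lists)
        union = set().union(*lists.values())
        assert v.union_size == len(union)
        seen = set()
        for genes in v.regions.values():
            assert not (seen & genes)
            seen |= genes
        assert seen == union


class TestEnrichStudy:
    def test_planted_intronic_enrichment_detected_in_right_rows(self):
        cfg = ExpressionSimConfig(n_genes=4000, n_case=15, n_control=15,
                                  frac_deg=0.03, frac_inserted=0.25,
                                  enrichment_odds=6.0, effect_size=4.0, seed=77)
        matrix, truth = simulate_expression_study(cfg)
        from line1meth.expression import call_degs

        degs = call_degs(matrix, "ASD", "CTRL")
        records = [InsertionRecord(g, "intronic")
                   for g in truth.index[truth["is_inserted"]]]
        sets = build_gene_sets(records)
        report = enrich_study(degs, sets, set(truth.index), study="sim")
        sig = report[report["p_adj"] < 0.05]
        assert set(sig["insertion_type"]) <= {"intronic", "all_insertion"}
        assert {"intronic", "all_insertion"} <= set(
            sig[sig["direction"] == "all"]["insertion_type"])
        # overlap gene lists agree with the a-cell counts
        assert (
            report["overlap_genes"].str.split(";").map(
                lambda g: 0 if g == [""] else len(g))
            == report["n_overlap"]
        ).all()
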