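"""Clustering agreement, reference accuracy and annotation conservation."""

import math

import numpy as np
import pytest

from orthomerge.evaluate import (
    best_match_average,
    count_identical_groups,
    ec_ic_table,
    function_benchmark,
    fusion_fission,
    ic_table,
    jaccard,
    ortholog_pairs,
    pair_functional_similarity,
    parameter_sweep,
    sim_rel,
)
from orthomerge.model import (
    AnnotationStore,
    GroupSet,
    ProteinRef,
    ReferenceGroups,
    ValidationError,
)

from oracles import bruteforce_pairs, random_partition, sim_rel_oracle


def fs(*names):
    return frozenset(ProteinRef("S", n) for n in names)


class TestPairsAndJaccard:
    def test_pair_counts(self):
        assert len(ortholog_pairs(GroupSet("x", [fs("a", "b", "c")]))) == 3
        assert len(ortholog_pairs(GroupSet("x", [fs("a", "b"), fs("c", "d")]))) == 2

    def test_identical_and_disjoint(self):
        a = ortholog_pairs(GroupSet("x", [fs("a", "b", "c")]))
        b = ortholog_pairs(GroupSet("y", [fs("d", "e"), fs("f", "g")]))
        assert jaccard(a, a) == 1.0
        assert jaccard(a, b) == 0.0
        assert jaccard(set(), set()) == 1.0  # documented convention

    def test_split_versus_merged(self):
        a = ortholog_pairs(GroupSet("x", [fs("a", "b"), fs("c", "d")]))
        b = ortholog_pairs(GroupSet("y", [fs("a", "b", "c", "d")]))
        assert jaccard(a, b) == pytest.approx(2 / 6)

    def test_symmetric_and_matches_bruteforce(self):
        rng = np.random.default_rng(13)
        proteins = [ProteinRef("S", f"p{k}") for k in range(30)]
        for _case in range(50):
            ga = random_partition(rng, proteins, 6)
            gb = random_partition(rng, proteins, 6)
            if not ga or not gb:
                continue
            pa = ortholog_pairs(GroupSet("a", ga))
            pb = ortholog_pairs(GroupSet("b", gb))
            assert pa == bruteforce_pairs(ga)
            assert jaccard(pa, pb) == jaccard(pb, pa)
            inter = len(pa & pb)
            union = len(pa | pb)
            assert jaccard(pa, pb) == pytest.approx(inter / union)

    def test_count_identical_groups(self):
        a = GroupSet("a", [fs("a", "b", "c"), fs("d", "e")])
        b = GroupSet("b", [fs("a", "b"), fs("d", "e")])
        assert count_identical_groups(a, a) == 2
        assert count_identical_groups(a, b) == 1
        assert count_identical_groups(GroupSet("c", [fs("a", "b", "c")]),
                                      GroupSet("d", [fs("a", "b")])) == 0


class TestFusionFission:
    def _refs(self, *groups):
        refogs = {f"R{k}": frozenset(g) for k, g in enumerate(groups)}
        universe = frozenset(p for g in groups for p in g)
        return ReferenceGroups(refogs, universe)

    def test_perfect_prediction(self):
        refs = self._refs(fs("a", "b", "c"), fs("d", "e", "f"))
        pred = GroupSet("p", [fs("a", "b", "c"), fs("d", "e", "f")])
        report = fusion_fission(pred, refs)
        assert report.pct_accurate == 100.0
        assert report.total_fusions == 0
        assert report.total_fissions == 0

    def test_split_into_three_gives_two_fissions(self):
        members = fs(*"abcdefgh")
        refs = self._refs(members)
        pred = GroupSet("p", [fs("a", "b", "c"), fs("d", "e", "f"), fs("g", "h")])
        report = fusion_fission(pred, refs)
        assert report.per_refog["R0"].fissions == 2
        assert report.total_fissions == 2
        assert not report.per_refog["R0"].fusion

    def test_fusion_boundary_at_more_than_three_foreign(self):
        core = fs("a", "b", "c", "d")
        refs3 = ReferenceGroups(
            {"R": core},
            core | fs("x1", "x2", "x3", "x4"),
        )
        pred3 = GroupSet("p", [core | fs("x1", "x2", "x3")])
        pred4 = GroupSet("p", [core | fs("x1", "x2", "x3", "x4")])
        assert not fusion_fission(pred3, refs3).per_refog["R"].fusion
        assert fusion_fission(pred4, refs3).per_refog["R"].fusion

    def test_foreign_outside_universe_ignored(self):
        core = fs("a", "b", "c", "d")
        refs = ReferenceGroups({"R": core}, core)  # universe excludes x*
        pred = GroupSet("p", [core | fs("x1", "x2", "x3", "x4", "x5")])
        assert not fusion_fission(pred, refs).per_refog["R"].fusion

    def test_uncovered_refog_not_accurate(self):
        refs = self._refs(fs("a", "b", "c"), fs("d", "e", "f"))
        pred = GroupSet("p", [fs("a", "b", "c")])
        report = fusion_fission(pred, refs)
        assert report.per_refog["R1"].fissions == 0
        assert not report.per_refog["R1"].fusion
        assert not report.per_refog["R1"].accurate
        assert report.pct_accurate == 50.0

    def test_merging_all_refogs(self):
        refs = self._refs(fs("a", "b", "c", "d", "e"), fs("f", "g", "h", "i", "j"))
        pred = GroupSet("p", [fs(*"abcdefghij")])
        report = fusion_fission(pred, refs)
        for rec in report.per_refog.values():
            assert rec.fissions == 0
            assert rec.fusion  # 5 foreign proteins > 3
        assert report.total_fissions == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            fusion_fission(
                GroupSet("p", [fs("a", "b")]),
                ReferenceGroups({}, frozenset()),
            )


class TestInformationContent:
    def test_root_probability_one(self, tiny_store):
        table = ic_table(tiny_store, "bp")
        assert table.p["root"] == pytest.approx(1.0)
        assert table.ic["root"] == pytest.approx(0.0)

    def test_hand_counted_frequency(self, tiny_store):
        table = ic_table(tiny_store, "bp")
        assert table.p["c"] == pytest.approx(0.2)
        assert table.ic["c"] == pytest.approx(-math.log(0.2))

    def test_parent_child_monotonicity(self, tiny_store):
        table = ic_table(tiny_store, "bp")
        for term, parents in table.parents.items():
            for parent in parents:
                assert table.p[parent] >= table.p[term]

    def test_empty_namespace_rejected(self, tiny_store):
        with pytest.raises(ValidationError):
            ic_table(tiny_store, "mf")


class TestSimRel:
    def test_self_similarity_closed_form(self, tiny_store):
        table = ic_table(tiny_store, "bp")
        assert sim_rel("c", "c", table) == pytest.approx(0.8)

    def test_root_only_common_ancestor_scores_zero(self, tiny_store):
        table = ic_table(tiny_store, "bp")
        assert sim_rel("c", "e", table) == pytest.approx(0.0)

    def test_both_roots_defined_zero(self, tiny_store):
        table = ic_table(tiny_store, "bp")
        assert sim_rel("root", "root", table) == 0.0

    def test_in_unit_interval_and_matches_oracle(self):
        rng = np.random.default_rng(55)
        for _case in range(10):
            table, terms = _random_ic_table(rng)
            for _pair in range(20):
                c1, c2 = rng.choice(terms, size=2)
                got = sim_rel(str(c1), str(c2), table)
                want = sim_rel_oracle(str(c1), str(c2), table.p, table.parents)
                assert got == pytest.approx(want, abs=1e-12)
                assert 0.0 <= got <= 1.0


class TestPairSimilarity:
    def test_identical_single_term_sets(self, tiny_store):
        p0, p1 = ProteinRef("S", "p0"), ProteinRef("S", "p1")  # both term c
        got = pair_functional_similarity(p0, p1, tiny_store, "GO")
        assert got == pytest.approx(0.8)

    def test_unannotated_pair_skipped_not_zeroed(self, tiny_store):
        p0 = ProteinRef("S", "p0")
        stranger = ProteinRef("S", "nothing")
        assert pair_functional_similarity(p0, stranger, tiny_store, "GO") is None

    def test_ec_identical_unique_among_corpus(self):
        # 1.1.1.1 twice among 4 annotations -> p(leaf) = 0.5
        store = AnnotationStore(
            {}, {}, {},
            {
                ProteinRef("S", "p1"): frozenset({"1.1.1.1"}),
                ProteinRef("S", "p2"): frozenset({"1.1.1.1"}),
                ProteinRef("S", "p3"): frozenset({"2.1.1.1"}),
                ProteinRef("S", "p4"): frozenset({"3.1.1.1"}),
            },
        )
        got = pair_functional_similarity(
            ProteinRef("S", "p1"), ProteinRef("S", "p2"), store, "EC"
        )
        assert got == pytest.approx(1 - 0.5)

    def test_ec_wildcard_annotates_internal_node(self, tiny_store):
        store = AnnotationStore(
            {}, {}, {},
            {
                ProteinRef("S", "w1"): frozenset({"1.2.-.-"}),
                ProteinRef("S", "w2"): frozenset({"1.2.3.4"}),
                ProteinRef("S", "w3"): frozenset({"4.4.4.4"}),
            },
        )
        table = ec_ic_table(store)
        assert "1.2" in table.p
        got = pair_functional_similarity(
            ProteinRef("S", "w1"), ProteinRef("S", "w2"), store, "EC"
        )
        assert got is not None and got > 0

    def test_best_match_average_is_symmetric(self, tiny_store):
        table = ic_table(tiny_store, "bp")
        a = best_match_average(["c", "d"], ["c"], table)
        b = best_match_average(["c"], ["c", "d"], table)
        assert a == pytest.approx(b)


class TestFunctionBenchmark:
    def test_no_annotations_reported_missing(self, tiny_store):
        gs = GroupSet("x", [fs("q1", "q2")])  # unannotated proteins
        fb = function_benchmark(gs, tiny_store, "GO")
        assert fb.n_annotated_pairs == 0
        assert fb.mean_similarity is None

    def test_identical_term_sets_closed_form(self, tiny_store):
        gs = GroupSet("x", [frozenset({ProteinRef("S", "p0"),
                                       ProteinRef("S", "p1")})])
        fb = function_benchmark(gs, tiny_store, "GO")
        assert fb.n_annotated_pairs == 1
        assert fb.mean_similarity == pytest.approx(0.8)

    def test_splitting_reduces_pairs_not_scores(self, tiny_store):
        # p5..p8 all carry term e (p = 0.4)
        quad = [ProteinRef("S", f"p{k}") for k in (5, 6, 7, 8)]
        merged = GroupSet("x", [frozenset(quad)])
        split = GroupSet("y", [frozenset(quad[:2]), frozenset(quad[2:])])
        fb_m = function_benchmark(merged, tiny_store, "GO")
        fb_s = function_benchmark(split, tiny_store, "GO")
        assert fb_m.n_annotated_pairs == 6
        assert fb_s.n_annotated_pairs == 2
        assert fb_m.mean_similarity == pytest.approx(fb_s.mean_similarity)


class TestParameterSweep:
    def test_grid_shape_and_determinism(self):
        groups = [fs("a", "b", "c", "d"), fs("e", "f", "g", "h")]
        m1, m2 = GroupSet("m1", groups), GroupSet("m2", groups)
        refs = ReferenceGroups(
            {"R0": groups[0], "R1": groups[1]},
            frozenset(p for g in groups for p in g),
        )
        table = parameter_sweep(
            [m1, m2], None, refs,
            evalues=[1e-10, 1e-5], coverages=[0.4, 0.8], min_sizes=[4],
            seed=3,
        )
        assert len(table) == 4
        assert set(table["min_size"]) == {4}
        again = parameter_sweep(
            [m1, m2], None, refs,
            evalues=[1e-10, 1e-5], coverages=[0.4, 0.8], min_sizes=[4],
            seed=3,
        )
        assert table.equals(again)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            parameter_sweep([], None,
                            ReferenceGroups({"R": fs("a", "b")}, fs("a", "b")),
                            [], [0.4], [4])


def _random_ic_table(rng):
    """Random DAG + IC table over ~12 terms with random annotation counts."""
    from orthomerge.evaluate import IcTable

    n = int(rng.integers(6, 13))
    parents = {"t0": frozenset()}
    for k in range(1, n):
        n_par = int(rng.integers(1, min(3, k) + 1))
        chosen = rng.choice(k, size=n_par, replace=False)
        parents[f"t{k}"] = frozenset(f"t{int(j)}" for j in chosen)
    counts = {f"t{k}": 0 for k in range(n)}
    total = 0
    for _a in range(40):
        term = f"t{int(rng.integers(n))}"
        seen = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(parents[t])
        for t in seen:
            counts[t] += 1
        total += 1
    p = {t: c / total for t, c in counts.items() if c > 0}
    table = IcTable(
        p=p,
        ic={t: -math.log(v) for t, v in p.items()},
        parents={t: frozenset(q for q in parents[t] if q in p) for t in p},
    )
    return table, sorted(p)
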