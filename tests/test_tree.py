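"""Pruned inexact search: branch points, pair rules, D bounds, drivers."""

import numpy as np
import pytest

import fmmap as fm
from fmmap.index import _CODE
from fmmap.search import SAInterval
from fmmap.tree import EditOp, compute_D, is_pair_allowed

from conftest import random_instance


def codes_of(read):
    return [_CODE.get(c, 5) for c in read]


class TestBranchPoints:
    def test_worked_example(self, toy_index):
        assert fm.detect_branch_points(toy_index, "AGGATC") == [2, 4]

    def test_stable_prefixes_yield_no_points(self, toy_index):
        # "A" and "AG" both occur twice: res never shrinks after the baseline
        assert fm.detect_branch_points(toy_index, "AG") == []

    def test_matches_naive_res_recomputation(self):
        rng = np.random.default_rng(13)
        text = fm.generate_reference(500, seed=13)
        idx = fm.build_index(text, r=4)
        for _ in range(30):
            L = int(rng.integers(3, 15))
            read = fm.generate_reference(L, int(rng.integers(1 << 30)))
            expected = []
            prev = None
            for i in range(1, L + 1):
                res = len(naive := {
                    j for j in range(len(text) - i + 1) if text[j : j + i] == read[:i]
                })
                if prev is not None and res < prev:
                    expected.append(i - 1)
                if res == 0:
                    break
                prev = res
            assert fm.detect_branch_points(idx, read) == expected, read


class TestPairRules:
    W = codes_of("AGCATG")

    def p(self, kind, pos, base=""):
        return EditOp(kind, pos, _CODE[base] if base else 0)

    @pytest.mark.parametrize(
        "prev,nxt,allowed",
        [
            # insertion next to deletion, any bases: always equivalent to a mismatch
            (("I", 1, "A"), ("D", 1), False),
            (("D", 1), ("I", 2, "C"), False),
            # mismatch after insertion of the read's own base re-labels the insertion
            (("I", 2, "G"), ("M", 1, "T"), False),  # read[1] is G
            (("I", 2, "C"), ("M", 1, "T"), True),
            # deletion adjacent to a mismatch carrying the deleted base
            (("M", 0, "G"), ("D", 1), False),  # read[1] is G
            (("M", 0, "C"), ("D", 1), True),
            # mismatches never pair-conflict
            (("M", 0, "C"), ("M", 1, "T"), True),
        ],
    )
    def test_rule_table(self, prev, nxt, allowed):
        prev_op = self.p(*prev)
        nxt_op = self.p(*nxt)
        assert is_pair_allowed(prev_op, nxt_op, self.W) is allowed

    def test_examples_from_rule_statements(self):
        W = codes_of("AGCATG")
        # (M(A), D) deleting base A: read position 3 holds A
        assert not is_pair_allowed(self.p("M", 2, "A"), self.p("D", 3), W)
        # (M(A), M(C)) always allowed
        assert is_pair_allowed(self.p("M", 2, "A"), self.p("M", 3, "C"), W)
        # first edit of a run has nothing to pair with
        assert is_pair_allowed(None, self.p("D", 0), W)

    def test_leading_insertion_fold_exception(self):
        W = codes_of("GTCA")
        prev = self.p("I", 1, "G")  # inserted base equals read[0]
        nxt = self.p("M", 0, "T")
        # interior: fold to a single insertion applies, pair forbidden
        assert not is_pair_allowed(prev, nxt, W)
        # at the left edge the fold target would be an insertion before the
        # read, i.e. a different mapping position: pair must be kept
        assert is_pair_allowed(prev, nxt, W, fold_budget=0)

    def test_rules_halve_branching(self):
        text = fm.generate_reference(800, seed=41)
        idx = fm.build_index(text, r=4)
        rng = np.random.default_rng(41)
        reads = [
            fm.generate_reads(
                text, fm.SimParams(n_reads=1, read_length=40, mutation_rate=0.05,
                                   indel_fraction=0.5, seed=int(rng.integers(1 << 30)))
            )[0].sequence
            for _ in range(10)
        ]
        def total_branches(pair_rules):
            counters = {}
            cfg = fm.SearchConfig(max_errors=3, segsize=8, pair_rules=pair_rules)
            for read in reads:
                fm.search_complete(idx, read, cfg, counters=counters)
            return counters.get("branches", 0)
        assert total_branches(True) < total_branches(False)


class TestRedundancyPruning:
    REF = "CCTGGGGATT"  # contains TGGGGA, and nothing else alignable

    def test_unpruned_enumeration_yields_five_deletions(self):
        scripts = fm.enumerate_edit_scripts(self.REF, "TGGGGGA", 1)
        assert len(scripts) == 5
        assert {s for s, _ in scripts} == {2}
        assert all(ops[0][1] == "D" for _, ops in scripts)

    def test_pruned_search_yields_single_result(self):
        idx = fm.build_index(self.REF)
        maps = fm.search_prototype(idx, "TGGGGGA", 1)
        assert len(maps) == 1
        (m,) = maps
        assert m.position == 2 and m.n_errors == 1 and m.edits[0][1] == "D"


class TestDVector:
    def test_exact_read_is_all_zero(self, toy_index):
        D = compute_D(toy_index, "GGAG", 0, 3, "forward")
        assert D.tolist() == [0, 0, 0, 0]

    def test_worked_read_lower_bound(self, toy_index):
        D = compute_D(toy_index, "AGGATC", 0, 2, "forward")
        assert D[4] >= 1
        # the bound covers W[i..L-1], so it can only grow away from the read end
        assert all(D[i] >= D[i + 1] for i in range(3, 5))

    def test_is_admissible_lower_bound(self):
        # D never exceeds the true minimum edits of the remaining region
        rng = np.random.default_rng(59)
        text = fm.generate_reference(800, seed=59)
        idx = fm.build_index(text, r=4)
        for _ in range(20):
            read = fm.generate_reads(
                text, fm.SimParams(n_reads=1, read_length=30, mutation_rate=0.05,
                                   indel_fraction=0.4, seed=int(rng.integers(1 << 30)))
            )[0].sequence
            D = compute_D(idx, read, len(read) - 5, len(read) - 1, "backward")
            for i in range(len(read) - 5):
                prefix = read[: i + 1]
                h = fm.edit_distance_scan(text, prefix)
                assert D[i] <= h.min(), (read, i)

    def test_pruning_is_lossless(self):
        rng = np.random.default_rng(61)
        for _ in range(15):
            ref, read, e = random_instance(rng, ref_lo=300, ref_hi=1200,
                                           read_lo=24, read_hi=48)
            idx = fm.build_index(ref, r=4)
            with_d = fm.search_complete(
                idx, read, fm.SearchConfig(max_errors=e, segsize=6, use_d_vector=True)
            )
            without = fm.search_complete(
                idx, read, fm.SearchConfig(max_errors=e, segsize=6, use_d_vector=False)
            )
            key = lambda ms: {(m.position, m.edits) for m in ms}
            assert key(with_d) == key(without)


class TestChangeDirection:
    def test_toy_interval_round_trip(self, toy_index):
        res = fm.bws(toy_index, "AG")  # backward, forward-text index
        rev_iv = fm.change_direction(toy_index, res.interval, 2, backward=False)
        # located positions are unchanged in the other index
        assert fm.locate(toy_index, rev_iv, 2, "forward") == {0, 3}
        # and changing back is an involution on the located set
        back = fm.change_direction(toy_index, rev_iv, 2, backward=True)
        assert fm.locate(toy_index, back, 2, "backward") == {0, 3}

    def test_singleton_stays_singleton(self, toy_index):
        res = fm.bws(toy_index, "GC")
        out = fm.change_direction(toy_index, res.interval, 2, backward=False)
        assert out.k == out.l


class TestPrototype:
    def test_toy_single_mismatch(self, toy_index):
        maps = fm.search_prototype(toy_index, "AGGATC", 1)
        assert [(m.position, m.edit_string) for m in maps] == [(0, "4:M(G)")]

    def test_zero_budget_equals_exact_search(self, toy_index):
        maps = fm.search_prototype(toy_index, "AG", 0)
        assert {m.position for m in maps} == {0, 3}
        assert all(m.n_errors == 0 for m in maps)

    def test_no_duplicate_results_up_to_two_errors(self):
        rng = np.random.default_rng(67)
        counters = {}
        for _ in range(25):
            ref, read, _ = random_instance(rng, ref_lo=300, ref_hi=1000,
                                           read_lo=20, read_hi=40, e_max=2)
            idx = fm.build_index(ref, r=4)
            for e in (1, 2):
                fm.search_prototype(idx, read, e, counters=counters)
        assert counters.get("duplicates", 0) == 0


class TestComplete:
    def test_zero_budget_equals_exact_search(self, toy_index):
        cfg = fm.SearchConfig(max_errors=0, segsize=3)
        maps = fm.search_complete(toy_index, "AGGAGC", cfg)
        assert [(m.position, m.n_errors) for m in maps] == [(0, 0)]

    def test_segment_arithmetic(self):
        assert fm.max_errors_for(250, 31) == 7
        assert fm.max_errors_for(100, 10) == 9
        assert fm.max_errors_for(30, 31) == 0

    def test_budget_lowered_with_warning(self, toy_index):
        text = fm.generate_reference(300, seed=71)
        idx = fm.build_index(text, r=4)
        read = text[40:70]
        cfg = fm.SearchConfig(max_errors=5, segsize=10)  # 6*10 > 30
        with pytest.warns(UserWarning, match="lowering e"):
            maps = fm.search_complete(idx, read, cfg)
        assert {m.position for m in maps} >= {40}

    def test_short_read_falls_back_to_prototype(self, toy_index):
        cfg = fm.SearchConfig(max_errors=1, segsize=10)
        with pytest.warns(UserWarning, match="shorter than segsize"):
            maps = fm.search_complete(toy_index, "AGGATC", cfg)
        assert [(m.position, m.edit_string) for m in maps] == [(0, "4:M(G)")]

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(73)
        for _ in range(20):
            ref, read, e = random_instance(rng, ref_lo=500, ref_hi=2000,
                                           read_lo=30, read_hi=80)
            idx = fm.build_index(ref, r=8)
            cfg = fm.SearchConfig(max_errors=e, segsize=7)
            got = {m.position for m in fm.search_complete(idx, read, cfg)}
            expected = {p for p, _ in fm.brute_force_map(ref, read, e)}
            assert got == expected, (read, e)

    def test_traversal_order_is_immaterial(self):
        rng = np.random.default_rng(79)
        for _ in range(8):
            ref, read, e = random_instance(rng, ref_lo=300, ref_hi=900,
                                           read_lo=24, read_hi=48)
            idx = fm.build_index(ref, r=4)
            key = lambda ms: {(m.position, m.edits) for m in ms}
            runs = [
                key(fm.search_complete(
                    idx, read, fm.SearchConfig(max_errors=e, segsize=6, traversal=t)
                ))
                for t in ("bfs", "hybrid")
            ]
            assert runs[0] == runs[1]

    def test_self_consistency_of_reported_alignments(self):
        # every mapping, applied to the read, aligns within its error count
        rng = np.random.default_rng(83)
        for _ in range(10):
            ref, read, e = random_instance(rng, ref_lo=300, ref_hi=900,
                                           read_lo=24, read_hi=48)
            idx = fm.build_index(ref, r=4)
            cfg = fm.SearchConfig(max_errors=e, segsize=6)
            h = fm.edit_distance_scan(ref, read)
            for m in fm.search_complete(idx, read, cfg):
                assert h[m.position] <= m.n_errors


class TestStackLimit:
    @staticmethod
    def repeat_instance(motif_len):
        motif = fm.generate_reference(motif_len, motif_len)
        ref = list((motif * 600)[:1200])
        rng = np.random.default_rng(5)
        for p in rng.integers(0, len(ref), 30):
            ref[p] = "ACGT"[rng.integers(4)]
        ref = "".join(ref)
        return ref, ref[500:536]

    @pytest.mark.parametrize("motif_len", [2, 3])
    def test_limited_run_is_error_bounded_subset(self, motif_len):
        ref, read = self.repeat_instance(motif_len)
        idx = fm.build_index(ref, r=4)
        key = lambda ms: {(m.position, m.edits): m for m in ms}
        unlimited = key(fm.search_complete(
            idx, read, fm.SearchConfig(max_errors=3, segsize=6)))
        limited = key(fm.search_complete(
            idx, read, fm.SearchConfig(max_errors=3, segsize=6, stack_limit=500)))
        assert set(limited) < set(unlimited)  # strict: the cap did bite
        retained_max = max(m.n_errors for m in limited.values())
        dropped = [unlimited[k].n_errors for k in set(unlimited) - set(limited)]
        assert all(d >= retained_max for d in dropped)

    def test_overflow_policy_prefers_low_error_results(self):
        from fmmap.tree import PartialResult, ResultList

        rl = ResultList(capacity=3)
        for n_err, analysed in [(2, 5), (0, 1), (1, 8), (3, 9)]:
            r = PartialResult(SAInterval(0, 0), 0)
            r.errors = tuple(EditOp("D", i, 0) for i in range(n_err))
            r.analysed = analysed
            rl.add(r)
        assert rl.overflowed
        assert sorted(len(r.errors) for r in rl.items) == [0, 1, 2]


class TestMapRead:
    def test_n_policy_skips_overloaded_reads(self, toy_index):
        cfg = fm.SearchConfig(max_errors=1, segsize=3, max_read_ns=2)
        assert fm.map_read(toy_index, "r", "ANNNAG", cfg) == []

    def test_read_with_n_consumes_an_error(self, toy_index):
        cfg = fm.SearchConfig(max_errors=1, segsize=3)
        maps = fm.map_read(toy_index, "r", "AGGNGC", cfg)
        assert maps and maps[0].position == 0 and maps[0].n_errors == 1

    def test_reverse_complement_mapping(self, toy_index):
        cfg = fm.SearchConfig(max_errors=0, segsize=3)
        rc = fm.revcomp("AGGAGC")
        maps = fm.map_read(toy_index, "r", rc, cfg, rc=True)
        assert [(m.position, m.strand) for m in maps] == [(0, "-")]

    def test_boundary_crossing_hits_are_dropped(self):
        idx = fm.build_index([("chrA", "ACGTAC"), ("chrB", "GTACGG")])
        cfg = fm.SearchConfig(max_errors=0, segsize=2)
        maps = fm.map_read(idx, "r", "CGTA", cfg)
        # "CGTA" occurs inside chrA (kept) and across the boundary (dropped)
        assert [m.position for m in maps] == [1]


class TestBranchingFactor:
    @staticmethod
    def reads_for(idx_text, n, rng):
        return [
            fm.generate_reads(
                idx_text, fm.SimParams(n_reads=1, read_length=40, mutation_rate=0.02,
                                       indel_fraction=0.3, seed=int(rng.integers(1 << 30)))
            )[0].sequence
            for _ in range(n)
        ]

    def test_exact_search_is_a_chain(self, toy_index):
        cfg = fm.SearchConfig(max_errors=0, segsize=3)
        assert fm.measure_branching_factor(toy_index, ["AGGAGC"], cfg) == 1.0

    def test_below_unoptimised_bound_and_deterministic(self):
        text = fm.generate_reference(1500, seed=97)
        idx = fm.build_index(text, r=8)
        reads = self.reads_for(text, 12, np.random.default_rng(97))
        cfg = fm.SearchConfig(max_errors=3, segsize=8)
        bf1 = fm.measure_branching_factor(idx, reads, cfg)
        bf2 = fm.measure_branching_factor(idx, reads, cfg)
        assert bf1 == bf2
        assert 1.0 <= bf1 < 9.0


class TestSegsizeHeuristic:
    def test_returns_sane_deterministic_length(self):
        text = fm.generate_reference(2000, seed=101)
        idx = fm.build_index(text, r=8)
        a = fm.estimate_segsize(idx, probes=50, max_len=30, seed=7)
        b = fm.estimate_segsize(idx, probes=50, max_len=30, seed=7)
        assert a == b
        assert 1 <= a <= 30
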