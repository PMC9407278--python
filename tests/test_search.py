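"""Exact and heuristic shortest-ladderpath search."""

import random

import pytest

from ladderpath import (
    BasicSet,
    SearchConfig,
    SizeGuardError,
    TargetSystem,
    conservation_check,
    exact_shortest,
    heuristic_shortest,
    ladderpath_length,
    serialize_pom,
    shortest,
    size_index,
    validate_ladderpath,
)


class TestExactWorkedExamples:
    def test_structured_string(self, fixtures):
        fx = fixtures["X"]
        res = exact_shortest(fx.target, fx.basic)
        assert res.summary == fx.expected
        assert res.optimal
        assert serialize_pom(res.ladderpath) == "{A, B, C, D, E, F // CD, EF // BCD(2)}"

    def test_repeat_free_string_has_zero_order(self, fixtures):
        fx = fixtures["W"]
        res = exact_shortest(fx.target, fx.basic)
        assert res.summary == fx.expected
        assert res.optimal
        assert res.ladderpath.is_trivial

    def test_five_member_system(self, fixtures):
        fx = fixtures["Q"]
        res = exact_shortest(fx.target, fx.basic)
        assert res.summary == fx.expected
        assert res.optimal

    @pytest.mark.parametrize(
        "s,lam",
        [("AA", 2), ("AAAA", 3), ("AB", 2), ("ABAB", 3), ("A", 1)],
    )
    def test_tiny_strings(self, s, lam):
        target = TargetSystem(s, BasicSet("AB"))
        assert exact_shortest(target).summary.ladderpath_index == lam

    def test_token_granularity_multi_block_basic_set(self, fixtures):
        # the 18-token signal over {T,R,H,K,EF,MU,BCD}: the textbook
        # decomposition (TEF + BCDEF) costs 16 lifts, but the token run
        # EF-H-K repeats as well, and reusing it is one lift cheaper
        fx = fixtures["Yprime"]
        res = exact_shortest(fx.target, fx.basic)
        assert res.summary.size_index == 18
        assert res.summary.ladderpath_index == 15
        assert res.optimal
        blocks = {e.block for e in res.ladderpath.non_basic()}
        assert blocks == {"BCDEF", "EFHK"}


class TestHeuristic:
    def test_alien_signal(self, fixtures):
        # 34-letter signal: heuristic reproduces the reference length 25;
        # the level-3 ladderons EFH and TEF overlap and tie, the tie-break
        # picks the lexicographically smaller EFH
        fx = fixtures["Y"]
        res = heuristic_shortest(fx.target, fx.basic)
        assert res.summary == fx.expected
        assert not res.optimal
        blocks = {e.block: e.multiplicity for e in res.ladderpath.non_basic()}
        assert blocks == {"EF": 2, "MU": 1, "EFH": 1, "BCDEF": 1}

    def test_matches_exact_on_structured_string(self, fixtures):
        fx = fixtures["X"]
        he = heuristic_shortest(fx.target, fx.basic)
        ex = exact_shortest(fx.target, fx.basic)
        assert he.summary == ex.summary

    def test_matches_exact_on_system(self, fixtures):
        fx = fixtures["Q"]
        assert heuristic_shortest(fx.target).summary.ladderpath_index == 17


class TestSearchProperties:
    def test_exact_at_most_heuristic_at_most_size(self):
        rnd = random.Random(5)
        for _ in range(40):
            n = rnd.randint(1, 14)
            alpha = "ABC"[: rnd.randint(1, 3)]
            s = "".join(rnd.choice(alpha) for _ in range(n))
            target = TargetSystem(s, BasicSet(alpha))
            ex = exact_shortest(target).summary.ladderpath_index
            he = heuristic_shortest(target).summary.ladderpath_index
            assert ex <= he <= size_index(target)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_repeated_doubling(self, k):
        target = TargetSystem("A" * 2**k, BasicSet("A"))
        assert exact_shortest(target).summary.ladderpath_index == k + 1

    def test_duplicating_a_member_adds_one_lift(self, fixtures):
        fx = fixtures["Q"]
        cfg = SearchConfig(force_exact=True)
        base = exact_shortest(fx.target, fx.basic).summary
        for member in ["ABDED", "ED", "ABDEDBED"]:
            bigger = fx.target.with_extra_copy(member)
            res = exact_shortest(bigger, fx.basic, cfg).summary
            assert res.ladderpath_index == base.ladderpath_index + 1
            assert res.order_index == base.order_index + size_index(member, fx.basic) - 1

    def test_unique_digram_strings_are_incompressible(self):
        # every length-2 window distinct -> no reusable block -> lambda = S
        for s in ["ABCDEFCFEDCBFDBA", "ABCD", "ABACBC"]:
            target = TargetSystem(s, BasicSet("ABCDEF"))
            windows = [s[i : i + 2] for i in range(len(s) - 1)]
            assert len(set(windows)) == len(windows)
            res = exact_shortest(target)
            assert res.summary.ladderpath_index == size_index(target)
            assert res.summary.order_index == 0

    def test_results_are_deterministic(self, fixtures):
        fx = fixtures["Q"]
        first = exact_shortest(fx.target, fx.basic)
        second = exact_shortest(fx.target, fx.basic)
        assert serialize_pom(first.ladderpath) == serialize_pom(second.ladderpath)
        h1 = heuristic_shortest(fx.target)
        h2 = heuristic_shortest(fx.target)
        assert serialize_pom(h1.ladderpath) == serialize_pom(h2.ladderpath)

    def test_emitted_ladderpaths_are_valid_and_consistent(self, fixtures):
        for fx in fixtures.values():
            res = (
                exact_shortest(fx.target, fx.basic)
                if fx.exact_feasible
                else heuristic_shortest(fx.target, fx.basic)
            )
            lp = res.ladderpath
            assert conservation_check(lp).passed
            assert ladderpath_length(lp) == res.summary.ladderpath_index
            assert validate_ladderpath(lp).valid
            s = res.summary
            assert s.ladderpath_index + s.order_index == s.size_index


class TestGuardsAndConfig:
    def test_size_guard_refuses_large_exact_runs(self):
        target = TargetSystem("AB" * 30, BasicSet("AB"))
        with pytest.raises(SizeGuardError, match="heuristic"):
            exact_shortest(target, cfg=SearchConfig(max_exact_size=40))

    def test_force_exact_overrides_the_guard(self):
        # lambda(A^16) = 5: four doublings plus the take-out
        target = TargetSystem("A" * 16, BasicSet("A"))
        cfg = SearchConfig(max_exact_size=10, force_exact=True)
        assert exact_shortest(target, cfg=cfg).summary.ladderpath_index == 5

    def test_node_budget_falls_back_to_heuristic(self, fixtures):
        fx = fixtures["Q"]
        res = exact_shortest(fx.target, fx.basic, SearchConfig(node_budget=3))
        assert not res.optimal
        assert res.summary.ladderpath_index >= 17

    def test_mode_dispatch(self, fixtures):
        fx = fixtures["X"]
        assert shortest(fx.target, cfg=SearchConfig(mode="heuristic")).optimal is False
        assert shortest(fx.target, cfg=SearchConfig(mode="exact")).optimal is True
        with pytest.raises(ValueError):
            shortest(fx.target, cfg=SearchConfig(mode="magic"))

    def test_empty_target_system(self):
        basic = BasicSet("A")
        res = exact_shortest(TargetSystem.empty(basic), basic)
        assert res.summary.size_index == 0
        assert res.summary.ladderpath_index == 0
        assert serialize_pom(res.ladderpath) == "{}"
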