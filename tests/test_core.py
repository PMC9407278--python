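"""Index algebra, path simulation and ladderpath validation."""

import pytest

from ladderpath import (
    BasicSet,
    GenerationOp,
    GenerationPath,
    IndexSummary,
    Ladderpath,
    SimulationError,
    TargetSystem,
    TokenizationError,
    conservation_check,
    ladderpath_length,
    order_index_of,
    parse_pom,
    path_to_ladderpath,
    serialize_pom,
    simulate_path,
    size_index,
    validate_ladderpath,
)


class TestTokenization:
    def test_single_character_size_index_is_letter_count(self, fixtures):
        assert size_index(fixtures["X"].target) == 16

    def test_multi_block_basic_set_uses_shortest_segmentation(self):
        basic = BasicSet(set("ABCDEF") | {"BCD"})
        assert size_index("ABCDBCDBCDCDEFEF", basic) == 10

    def test_target_system_size_index_sums_instances(self, fixtures):
        assert size_index(fixtures["Q"].target) == 39

    def test_single_basic_block(self):
        assert size_index("A", BasicSet("ABCDEFGHIJKLMNOPQRSTUVWXYZ")) == 1

    def test_untokenizable_member_names_position(self):
        basic = BasicSet("AB")
        with pytest.raises(TokenizationError) as err:
            TargetSystem("ABXA", basic)
        assert err.value.member == "ABXA"
        assert err.value.position == 2

    def test_canonical_tokenization_prefers_longest_blocks(self):
        basic = BasicSet({"T", "R", "H", "K", "EF", "MU", "BCD"})
        toks = basic.tokenize("TBCDEFRBCDEFTEFHKREFHKMUTEFMU")
        assert len(toks) == 18
        assert toks[:4] == ("T", "BCD", "EF", "R")


class TestLengthFormula:
    def test_reference_multiset_lengths(self, jx1, jx2, jx0, jq):
        assert ladderpath_length(jx1) == 10
        assert ladderpath_length(jx2) == 13
        assert ladderpath_length(jx0) == 16  # trivial: no reuse, length = S
        assert ladderpath_length(jq) == 17

    def test_order_index_values(self, jx1, jx0, jq):
        assert order_index_of(jq) == 22
        assert order_index_of(jx1) == 6
        assert order_index_of(jx0) == 0

    def test_length_plus_order_is_size(self, jx1, jx2, jx0, jq, fixtures):
        for lp, fx in [(jx1, "X"), (jx2, "X"), (jx0, "X"), (jq, "Q")]:
            s = size_index(fixtures[fx].target)
            assert ladderpath_length(lp) + order_index_of(lp) == s


class TestConservation:
    def test_letter_balance_on_jx1(self, jx1):
        report = conservation_check(jx1)
        assert report.passed
        b = report.entries["B"]
        # three Bs in the target; BCD contributes 2x1, basic B contributes 1
        assert (b.target_count, b.ladderpath_count) == (3, 3)

    def test_trivial_ladderpath_balances_raw_letter_counts(self, jx0):
        report = conservation_check(jx0)
        assert report.passed
        assert report.entries["C"].ladderpath_count == 4

    def test_system_balance_on_jq(self, jq):
        report = conservation_check(jq)
        assert report.passed
        assert report.entries["A"].target_count == 7
        assert report.entries["A"].ladderpath_count == 7

    def test_corrupted_multiplicity_fails(self, fixtures):
        fx = fixtures["X"]
        bad = parse_pom(
            "{A, B, C, D, E, F // CD, EF // BCD(3)}", fx.basic, fx.target
        )
        report = conservation_check(bad)
        assert not report.passed
        assert {e.token for e in report.failures()} == {"B", "C", "D"}


class TestSimulation:
    def test_worked_paths_lengths_and_costs(self, paths):
        expected = {
            "Ex1": (10, [1, 1, 1, 6, 1]),
            "Ex2": (13, [2, 1, 2, 1, 1, 5, 1]),
            "Ex3": (13, [2, 1, 9, 1]),
            "Ex4": (17, [1, 1, 1, 1, 1, 1, 2, 9]),
        }
        for name, (length, costs) in expected.items():
            sim = simulate_path(paths[name])
            assert sim.length == length, name
            assert sim.op_costs == costs, name

    def test_negative_transients_are_allowed(self, paths):
        sim = simulate_path(paths["Ex1"])
        assert sim.multiset["BCD"] == -2
        assert sim.multiset["ABCDBCDBCDCDEFEF"] == 0

    def test_regenerating_an_existing_block_is_rejected(self, fixtures):
        fx = fixtures["X"]
        ops = (GenerationOp.merge("C", "D"), GenerationOp.merge("C", "D"))
        with pytest.raises(SimulationError, match="must not be present"):
            simulate_path(GenerationPath(ops, fx.basic, fx.target))

    def test_using_an_unknown_block_is_rejected(self, fixtures):
        fx = fixtures["X"]
        ops = (GenerationOp.merge("B", "CD"),)
        with pytest.raises(SimulationError, match="neither basic nor previously"):
            simulate_path(GenerationPath(ops, fx.basic, fx.target))

    def test_taking_out_a_non_member_is_rejected(self, fixtures):
        fx = fixtures["X"]
        ops = (GenerationOp.merge("C", "D"), GenerationOp.takeout("CD"))
        with pytest.raises(SimulationError, match="not a member"):
            simulate_path(GenerationPath(ops, fx.basic, fx.target))

    def test_merge_concatenation_is_checked(self):
        with pytest.raises(ValueError, match="concatenate"):
            GenerationOp("merge", ("A", "B"), "BA")


class TestPathToLadderpath:
    def test_ex1_distills_to_jx1(self, paths, jx1):
        assert path_to_ladderpath(paths["Ex1"]) == jx1

    def test_two_paths_one_ladderpath(self, paths, jx2):
        assert path_to_ladderpath(paths["Ex2"]) == jx2
        assert path_to_ladderpath(paths["Ex3"]) == jx2

    def test_ex4_distills_to_jq(self, paths, jq):
        assert path_to_ladderpath(paths["Ex4"]) == jq

    def test_path_length_equals_ladderpath_length(self, paths):
        for path in paths.values():
            sim = simulate_path(path)
            assert sim.length == ladderpath_length(path_to_ladderpath(path))

    def test_incomplete_takeout_is_rejected(self, fixtures):
        fx = fixtures["Q"]
        ops = (GenerationOp.merge("E", "D"), GenerationOp.takeout("ED"))
        with pytest.raises(SimulationError, match="exactly"):
            path_to_ladderpath(GenerationPath(ops, fx.basic, fx.target))


class TestValidation:
    def test_jx1_is_valid_with_replayable_witness(self, jx1):
        verdict = validate_ladderpath(jx1)
        assert verdict.valid
        assert path_to_ladderpath(verdict.witness) == jx1
        assert verdict.witness.length == 10

    def test_jq_is_valid(self, jq):
        verdict = validate_ladderpath(jq)
        assert verdict.valid
        assert path_to_ladderpath(verdict.witness) == jq

    def test_duplicate_block_across_levels_is_invalid(self):
        basic = BasicSet("A")
        target = TargetSystem("AAAA", basic)
        lp = Ladderpath([{"A": 1}, {"AA": 1}, {"AA": 1}], basic, target)
        verdict = validate_ladderpath(lp)
        assert not verdict.valid
        assert "duplicate" in verdict.problems[0]

    def test_conservation_violation_is_invalid(self, fixtures):
        fx = fixtures["X"]
        bad = parse_pom(
            "{A, B, C, D, E, F // CD, EF // BCD(3)}", fx.basic, fx.target
        )
        verdict = validate_ladderpath(bad)
        assert not verdict.valid
        assert any("conservation" in p for p in verdict.problems)

    def test_wrong_level_is_invalid(self, fixtures):
        fx = fixtures["X"]
        # BCD placed at level 2 cannot reach a level-1-only segmentation
        # one step below itself while CD sits beside it
        lp = Ladderpath(
            [{"A": 1, "B": 1, "C": 1, "D": 1, "E": 1, "F": 1},
             {"CD": 1, "EF": 1, "BCD": 2}],
            fx.basic,
            fx.target,
        )
        verdict = validate_ladderpath(lp)
        assert not verdict.valid

    def test_basic_block_must_sit_at_level_one(self, fixtures):
        fx = fixtures["X"]
        lp = Ladderpath([{"CD": 1}, {"A": 1}], fx.basic, fx.target)
        assert not validate_ladderpath(lp).valid


class TestInvariants:
    def test_relabeling_leaves_indices_unchanged(self, fixtures):
        from ladderpath import exact_shortest

        fx = fixtures["X"]
        table = str.maketrans("ABCDEF", "UVWXYZ")
        relabeled = TargetSystem(
            {m.translate(table): c for m, c in fx.target.members.items()},
            BasicSet("UVWXYZ"),
        )
        assert exact_shortest(relabeled).summary == exact_shortest(fx.target).summary

    def test_index_summary_enforces_identity(self):
        with pytest.raises(ValueError):
            IndexSummary(16, 10, 5)

    def test_empty_target_has_zero_indices(self):
        basic = BasicSet("A")
        assert size_index(TargetSystem.empty(basic), basic) == 0


class TestReaders:
    def test_lines_roundtrip(self, tmp_path, fixtures):
        from ladderpath import read_targets_lines
        from ladderpath.notation import write_targets_lines

        fx = fixtures["Q"]
        p = tmp_path / "q.txt"
        write_targets_lines(fx.target, p)
        back = read_targets_lines(p, fx.basic)
        assert back.members == fx.target.members

    def test_fasta_duplicates_accumulate(self, tmp_path):
        from ladderpath import read_targets_fasta

        p = tmp_path / "t.fasta"
        p.write_text(">a\nABAB\n>b\nABAB\n>c\nCD\n")
        ts = read_targets_fasta(p)
        assert ts.members == {"ABAB": 2, "CD": 1}

    def test_empty_lines_file_gives_empty_system(self, tmp_path):
        from ladderpath import read_targets_lines

        p = tmp_path / "empty.txt"
        p.write_text("")
        assert read_targets_lines(p).is_empty
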