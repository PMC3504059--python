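"""Statement enumeration: worked examples, closed forms, invariants."""

import random
from itertools import combinations
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from threeitem.matrix_io import CharacterMatrix, DataType, EmptyMatrixError
from threeitem.statement_engine import (
    RepresentationConfig,
    StatementBlock,
    ThreeItemStatement,
    build_three_item_matrix,
    decompose_additive,
    enumerate_binary,
    enumerate_block,
    enumerate_omc,
    enumerate_umc_g,
    enumerate_umc_w,
    render_column,
)

from conftest import make_matrix


def pairs(block):
    return [(s.out_taxon, s.in_pair) for s in block.statements]


class TestBinaryRepresentation:
    def test_two_zeros_two_ones_gives_both_statements(self):
        block = enumerate_binary("0110")
        assert pairs(block) == [(0, (1, 2)), (3, (1, 2))]

    def test_all_apomorphic_column_is_empty(self):
        assert len(enumerate_binary("1111")) == 0

    def test_missing_taxon_excluded(self):
        # A:0 B:1 C:? D:1 E:1 -> A(BD), A(BE), A(DE)
        block = enumerate_binary(["0", "1", None, "1", "1"])
        assert pairs(block) == [(0, (1, 3)), (0, (1, 4)), (0, (3, 4))]

    @given(st.lists(st.sampled_from(["0", "1", None]), min_size=3, max_size=10))
    @settings(deadline=None)
    def test_count_matches_closed_form(self, column):
        m, n = column.count("0"), column.count("1")
        assert len(enumerate_binary(column)) == m * comb(n, 2)


class TestGRepresentation:
    def test_three_state_worked_column(self, umc_5taxa):
        block = enumerate_umc_g(umc_5taxa.column(0))
        assert pairs(block) == [
            (0, (1, 2)), (0, (3, 4)), (1, (3, 4)),
            (2, (3, 4)), (3, (1, 2)), (4, (1, 2)),
        ]

    def test_binary_column_yields_both_directions(self):
        block = enumerate_umc_g("0110")
        assert len(block) == 4
        assert set(pairs(block)) == {
            (0, (1, 2)), (3, (1, 2)), (1, (0, 3)), (2, (0, 3))
        }

    def test_constant_column_is_empty(self):
        assert len(enumerate_umc_g("2222")) == 0

    def test_binary_enumeration_is_a_subset_of_g(self):
        rng = random.Random(0)
        for _ in range(20):
            col = [rng.choice(["0", "1", None]) for _ in range(8)]
            sub = {(s.out_taxon, s.in_pair, s.p_state, s.a_state)
                   for s in enumerate_binary(col).statements}
            sup = {(s.out_taxon, s.in_pair, s.p_state, s.a_state)
                   for s in enumerate_umc_g(col).statements}
            assert sub <= sup

    @given(st.lists(st.sampled_from(["0", "1", "2", None]), min_size=3, max_size=10))
    @settings(deadline=None)
    def test_count_matches_pair_sum_form(self, column):
        tallies = {s: column.count(s) for s in set(column) if s is not None}
        expected = sum(
            n_p * comb(n_a, 2)
            for p, n_p in tallies.items()
            for a, n_a in tallies.items()
            if a != p
        )
        assert len(enumerate_umc_g(column)) == expected


class TestWRepresentation:
    def test_fixed_state_zero(self, umc_5taxa):
        block = enumerate_umc_w(umc_5taxa.column(0), "0")
        assert pairs(block) == [(0, (1, 2)), (0, (3, 4))]

    def test_fixed_state_one(self, umc_5taxa):
        block = enumerate_umc_w(umc_5taxa.column(0), "1")
        assert pairs(block) == [(1, (3, 4)), (2, (3, 4))]

    def test_no_shared_ingroup_state_gives_empty_block(self):
        assert len(enumerate_umc_w("0123", "0")) == 0

    def test_w_is_a_subset_of_g_for_every_state(self, umc_5taxa):
        col = umc_5taxa.column(0)
        g = set(pairs(enumerate_umc_g(col)))
        for state in "012":
            assert set(pairs(enumerate_umc_w(col, state))) <= g


class TestAdditiveDecomposition:
    def test_textbook_farris_coding(self):
        assert decompose_additive("0122") == [
            ["0", "1", "1", "1"],
            ["0", "0", "1", "1"],
        ]

    def test_constant_column_yields_nothing(self):
        assert decompose_additive("111") == []

    def test_observed_levels_skip_gaps(self):
        assert decompose_additive("02") == [["0", "1"]]

    def test_missing_propagates(self):
        assert decompose_additive(["0", None, "1"]) == [["0", None, "1"]]

    def test_non_integer_symbol_is_an_error(self):
        from threeitem.matrix_io import MatrixError

        with pytest.raises(MatrixError, match="not an integer"):
            decompose_additive("0a1")


class TestOmcRepresentation:
    def test_duplicates_across_levels_without_mus(self):
        block = enumerate_omc("0122")
        assert len(block) == 5
        assert pairs(block).count((0, (2, 3))) == 2

    def test_mus_collapses_duplicates(self):
        block = enumerate_omc("0122", mus=True)
        assert len(block) == 4
        assert sorted(set(pairs(block))) == pairs(block)

    def test_binary_valued_column_unaffected_by_mus(self):
        assert pairs(enumerate_omc("0110", mus=True)) == pairs(
            enumerate_omc("0110")
        ) == pairs(enumerate_binary("0110"))

    def test_constant_column_empty(self):
        assert len(enumerate_omc("22")) == 0

    def test_mus_dedup_is_order_independent(self):
        block = enumerate_omc("011222", mus=False)
        rng = random.Random(7)
        shuffled = block.statements[:]
        rng.shuffle(shuffled)
        a = StatementBlock(0, "omc", shuffled).dedup()
        b = block.dedup()
        assert a.statements == b.statements
        assert b.dedup().statements == b.statements  # idempotent


class TestRenderColumn:
    def test_binary_notation(self):
        s = ThreeItemStatement(0, 0, (1, 2), "0", "1")
        assert render_column(s, "binary", 4) == ("0", "1", "1", "?")

    def test_multistate_notation_keeps_state_symbols(self):
        s = ThreeItemStatement(0, 0, (1, 2), "A", "G")
        assert render_column(s, "multistate", 4) == ("A", "G", "G", "?")

    def test_non_missing_positions_recover_the_statement(self):
        s = ThreeItemStatement(3, 2, (0, 4), "0", "1")
        col = render_column(s, "binary", 6)
        present = {i for i, sym in enumerate(col) if sym != "?"}
        assert present == {s.out_taxon, *s.in_pair}


class TestBuildThreeItemMatrix:
    def test_column_count_is_sum_of_per_character_counts(self, binary_4x2):
        tim = build_three_item_matrix(binary_4x2, RepresentationConfig())
        per_char = [
            len(enumerate_binary(binary_4x2.column(j))) for j in range(2)
        ]
        assert tim.n_columns == sum(per_char) == 4

    def test_taxon_permutation_equivariance(self, binary_4x2):
        perm = [3, 1, 0, 2]
        permuted = CharacterMatrix(
            tuple(binary_4x2.taxon_names[i] for i in perm),
            tuple(binary_4x2.cells[i] for i in perm),
            binary_4x2.data_type,
        )
        cfg = RepresentationConfig()
        a = build_three_item_matrix(binary_4x2, cfg)
        b = build_three_item_matrix(permuted, cfg)

        def named(tim):
            return sorted(
                (p.source_char, tim.taxon_names[p.out_taxon],
                 tuple(sorted(tim.taxon_names[k] for k in p.in_pair)))
                for p in tim.provenance
            )

        assert named(a) == named(b)

    def test_deterministic_output(self, umc_5taxa):
        cfg = RepresentationConfig(notation="multistate")
        a = build_three_item_matrix(umc_5taxa, cfg)
        b = build_three_item_matrix(umc_5taxa, cfg)
        assert a.columns == b.columns and a.weights == b.weights

    def test_uninformative_matrix_raises(self):
        m = make_matrix({"A": "1", "B": "1", "C": "1"}, "binary")
        with pytest.raises(EmptyMatrixError, match="no informative"):
            build_three_item_matrix(m, RepresentationConfig())

    def test_w_character_skipped_when_outgroup_unscored(self):
        m = make_matrix({"A": "?0", "B": "11", "C": "11", "D": "00"}, "umc")
        cfg = RepresentationConfig(outgroup="A")
        assert enumerate_block(m, 0, cfg) is None
        tim = build_three_item_matrix(m, cfg)
        assert {p.source_char for p in tim.provenance} == {1}

    def test_g_enumeration_of_a_dna_column_matches_brute_force(self):
        # 12 taxa sharing a single site, as in a mitochondrial alignment
        states = "TTCCCCCCTTCA"
        m = make_matrix(
            {f"t{i:02d}": s for i, s in enumerate(states)}, "dna"
        )
        tim = build_three_item_matrix(
            m, RepresentationConfig(notation="multistate")
        )
        brute = 0
        for x in range(12):
            for y, z in combinations(range(12), 2):
                if x not in (y, z) and states[y] == states[z] != states[x]:
                    brute += 1
        assert tim.n_columns == brute
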