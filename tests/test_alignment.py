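import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bfoamsa.alignment import (
    Bacterium,
    clean_gap_columns,
    column_pairs,
    count_pairs,
    cuadra,
    evaluation_time_seconds,
    gap_column_indices,
    swim,
    tumble,
)
from conftest import random_bacterium


def gapstrip(rows):
    return [r.replace("-", "") for r in rows]


class TestCuadra:
    def test_pads_to_max_length(self):
        assert cuadra(Bacterium(["ACGT", "AC"])).rows == ["ACGT", "AC--"]

    def test_idempotent_on_rectangular(self):
        b = Bacterium(["ACGT", "AC--"])
        assert cuadra(b).rows == b.rows

    def test_residue_counts_conserved(self, rng):
        rows = ["ACG", "ACGTA", "ACGTACG"]
        out = cuadra(Bacterium(rows))
        assert {len(r) for r in out.rows} == {7}
        assert gapstrip(out.rows) == rows


class TestGapColumns:
    def test_detects_trailing_gap_column(self):
        assert gap_column_indices(Bacterium(["A-", "C-"])) == [1]

    def test_no_gap_columns(self):
        assert gap_column_indices(Bacterium(["AC", "GT"])) == []

    def test_matches_brute_force_scan(self, rng):
        b = random_bacterium(rng, 10, 20, gap_frac=0.6)
        brute = [
            j for j in range(b.width) if all(row[j] == "-" for row in b.rows)
        ]
        assert gap_column_indices(b) == brute

    def test_clean_removes_and_preserves_order(self):
        assert clean_gap_columns(Bacterium(["A-C", "G-T"])).rows == ["AC", "GT"]

    def test_clean_idempotent(self, rng):
        b = random_bacterium(rng, 5, 15, gap_frac=0.7)
        once = clean_gap_columns(b)
        assert clean_gap_columns(once).rows == once.rows

    def test_clean_conserves_rows(self, rng):
        for _ in range(20):
            b = random_bacterium(rng, 4, 12, gap_frac=0.7)
            assert gapstrip(clean_gap_columns(b).rows) == gapstrip(b.rows)

    def test_all_gap_matrix_becomes_zero_width(self):
        out = clean_gap_columns(Bacterium(["---", "---"]))
        assert out.rows == ["", ""] and out.width == 0


class TestTumble:
    def test_zero_gaps_is_just_cuadra(self, rng):
        b = Bacterium(["ACGT", "AC"])
        assert tumble(b, 0, rng).rows == cuadra(b).rows

    def test_gap_count_audit(self, rng):
        b = random_bacterium(rng, 4, 10, gap_frac=0.2)
        before = sum(len(r) - r.count("-") for r in b.rows)
        out = tumble(b, 5, rng)
        after = sum(len(r) - r.count("-") for r in out.rows)
        assert after == before  # non-gap characters unchanged
        assert out.gap_count() >= b.gap_count() + 5  # 5 inserted + padding
        assert out.is_rectangular()

    def test_deterministic_under_fixed_seed(self):
        b = Bacterium(["ACGTACGT", "ACGTAC", "ACGTA"])
        r1 = tumble(b, 7, np.random.default_rng(42)).rows
        r2 = tumble(b, 7, np.random.default_rng(42)).rows
        assert r1 == r2

    def test_does_not_mutate_input(self, rng):
        b = Bacterium(["ACGT", "ACGT"])
        tumble(b, 3, rng)
        assert b.rows == ["ACGT", "ACGT"]

    def test_negative_count_rejected(self, rng):
        with pytest.raises(ValueError):
            tumble(Bacterium(["AC", "GT"]), -1, rng)


class TestSwim:
    def test_gap_free_matrix_unchanged(self, rng):
        b = Bacterium(["ACGT", "GTAC"])
        assert swim(b, 50, rng).rows == b.rows

    def test_removes_all_gaps_when_fewer_than_requested(self, rng):
        b = Bacterium(["A-CG-T", "ACGT-A"])  # exactly 3 gaps
        out = swim(b, 50, rng)
        # only re-rectangularization padding can remain
        assert out.gap_count() == sum(out.width - len(s) for s in gapstrip(out.rows))
        assert gapstrip(out.rows) == gapstrip(b.rows)

    def test_deterministic_under_fixed_seed(self):
        b = Bacterium(["A--CG--T", "AC-GT--A"])
        r1 = swim(b, 3, np.random.default_rng(9)).rows
        r2 = swim(b, 3, np.random.default_rng(9)).rows
        assert r1 == r2

    def test_never_increases_gap_count(self, rng):
        for _ in range(20):
            b = random_bacterium(rng, 4, 15, gap_frac=0.4)
            assert swim(b, 5, rng).gap_count() <= b.gap_count()


class TestColumnPairs:
    def test_small_exact_count(self):
        pairs = column_pairs(Bacterium(["ACG", "TGC"]))
        assert len(pairs) == 3
        assert pairs[0].column == 0 and {pairs[0].a, pairs[0].b} == {"A", "T"}

    def test_pair_list_length_matches_closed_form(self, rng):
        b = random_bacterium(rng, 5, 8)
        assert len(column_pairs(b)) == count_pairs(5, 8, 1)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            column_pairs(Bacterium(["ACGT"]))


class TestCountPairs:
    def test_hundred_cubed_scenario(self):
        assert count_pairs(100, 1, 1) == 4950
        assert count_pairs(100, 100, 1) == 495_000
        assert count_pairs(100, 100, 100) == 49_500_000

    def test_minimal_case(self):
        assert count_pairs(2, 1, 1) == 1

    def test_matches_enumeration_on_random_matrices(self, rng):
        total = sum(
            len(column_pairs(random_bacterium(rng, 7, 13))) for _ in range(3)
        )
        assert total == count_pairs(7, 13, 3)

    @pytest.mark.parametrize("bad", [(1, 5, 1), (3, 0, 1), (3, 5, 0)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            count_pairs(*bad)


def test_evaluation_time_linear_scaling():
    secs = evaluation_time_seconds(49_500_000, ms_per_pair=1.0)
    assert secs == pytest.approx(49_500_000 / 1000)
    assert evaluation_time_seconds(1000, 1.0, workers=4) == pytest.approx(0.25)


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 2 ** 31 - 1), op_seed=st.integers(0, 2 ** 31 - 1))
def test_operators_conserve_residues(seed, op_seed):
    """cuadra/clean/tumble/swim never change any row's gap-stripped sequence."""
    rng = np.random.default_rng(seed)
    b = random_bacterium(rng, int(rng.integers(2, 6)), int(rng.integers(3, 20)))
    before = gapstrip(b.rows)
    op_rng = np.random.default_rng(op_seed)
    for op in (
        cuadra,
        clean_gap_columns,
        lambda x: tumble(x, 4, op_rng),
        lambda x: swim(x, 4, op_rng),
    ):
        b = op(b)
        assert gapstrip(b.rows) == before
        assert b.is_rectangular()
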