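"""Named-position resolution, frequency matrices, bins, ordering and pair tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recprofiler.align import align_to_reference, assign_landmarks
from recprofiler.io import MISSING
from recprofiler.profiles import (
    DEFAULT_KEY_POSITIONS,
    compute_frequency_matrix,
    d2_t2_pair_table,
    display_matrix,
    extract_positions,
    order_types,
    parse_position,
    quintile_bin,
    reference_index,
    resolve_position,
)


@pytest.fixture(scope="module")
def identity_assignment(model):
    aln = align_to_reference(model.sequence, model)
    return assign_landmarks(aln, model)


class TestResolvePosition:
    def test_k_minus_3_is_tyr106(self, model, identity_assignment):
        idx, res = resolve_position(
            identity_assignment, parse_position("K-3"), model.sequence
        )
        assert (idx, res) == (106, "Y")

    def test_dd17_lies_in_a1b2_loop(self, model, identity_assignment):
        idx, _ = resolve_position(
            identity_assignment, parse_position("DD+17"), model.sequence
        )
        assert idx == 30
        assert idx in model.loop("a1b2")

    def test_dd_pair_is_two_letter_string(self, model, identity_assignment):
        idx, res = resolve_position(
            identity_assignment, parse_position("DD"), model.sequence
        )
        assert (idx, res) == (12, "DD")

    def test_missing_anchor_is_undefined(self, model):
        seq = model.sequence[:84] + model.sequence[89:]  # T column deleted
        a = assign_landmarks(align_to_reference(seq, model), model)
        assert a.indices["t"] is None
        assert resolve_position(a, parse_position("T+1"), seq) is None

    def test_offset_off_sequence_end_is_undefined(self, model, identity_assignment):
        assert (
            resolve_position(identity_assignment, parse_position("K+25"), model.sequence)
            is None
        )

    def test_identity_matches_reference_arithmetic(self, model, identity_assignment):
        """On the identity query every named position is plain index addition."""
        for pos in DEFAULT_KEY_POSITIONS:
            hit = resolve_position(identity_assignment, pos, model.sequence)
            ref_idx = reference_index(pos, model)
            if pos.is_pair:
                assert hit[0] == model.dd1
            else:
                assert hit == (ref_idx, model.sequence[ref_idx - 1])


class TestExtractPositions:
    def test_identity_extraction(self, model, identity_assignment):
        out = extract_positions(model.sequence, identity_assignment)
        assert out["K-3"] == "Y"
        assert out["D+4"] == "P"   # γ-turn Pro
        assert out["D+8"] == "G"   # Gly initiating α3
        assert out["K+1"] == "P"
        assert out["K+2"] == "F"

    def test_all_missing_landmarks_give_all_na(self, model):
        class Empty:
            indices = {k: None for k in ("dd1", "dd2", "d", "t", "k")}

        out = extract_positions(model.sequence, Empty())
        assert set(out.values()) == {MISSING}


def _toy_table():
    return pd.DataFrame(
        {
            "rd_type": ["Skn7", "Skn7", "Ssk1", "Ssk1"],
            "pos_DD+17": ["C", "S", "A", MISSING],
            "pos_DD": ["DD", "ED", "ED", "ED"],
            "pos_D+2": ["M", "M", "M", "Q"],
            "pos_T+2": ["R", "R", "K", MISSING],
        }
    )


class TestFrequencyMatrix:
    def test_simple_fractions(self):
        freq = compute_frequency_matrix(
            _toy_table(), positions=(parse_position("DD+17"),)
        )
        skn7 = freq[freq["rd_type"] == "Skn7"].set_index("residue")["fraction"]
        assert skn7["C"] == 0.5 and skn7["S"] == 0.5

    def test_missing_category_keeps_denominator(self):
        freq = compute_frequency_matrix(
            _toy_table(), positions=(parse_position("DD+17"),)
        )
        ssk1 = freq[freq["rd_type"] == "Ssk1"]
        assert ssk1["fraction"].sum() == pytest.approx(1.0)
        assert MISSING in set(ssk1["residue"])
        assert ssk1["count"].sum() == 2

    def test_drop_missing_switch(self):
        freq = compute_frequency_matrix(
            _toy_table(), positions=(parse_position("DD+17"),), drop_missing=True
        )
        ssk1 = freq[freq["rd_type"] == "Ssk1"].set_index("residue")["fraction"]
        assert ssk1["A"] == 1.0

    def test_fractions_sum_to_one_per_cell(self):
        freq = compute_frequency_matrix(
            _toy_table(),
            positions=(parse_position("DD+17"), parse_position("DD")),
        )
        sums = freq.groupby(["rd_type", "position"])["fraction"].sum()
        assert np.allclose(sums, 1.0)


class TestQuintileBin:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.0, "ZERO"),
            (1.0, "FULL"),
            (0.1, "Q1"),
            (0.2, "Q1"),
            (0.2000001, "Q2"),
            (0.37, "Q2"),
            (0.6, "Q3"),
            (0.61, "Q4"),
            (0.99, "Q5"),
        ],
    )
    def test_examples(self, fraction, expected):
        assert quintile_bin(fraction) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quintile_bin(1.5)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_nondecreasing(self, a, b):
        order = ["ZERO", "Q1", "Q2", "Q3", "Q4", "Q5", "FULL"]
        lo, hi = min(a, b), max(a, b)
        assert order.index(quintile_bin(lo)) <= order.index(quintile_bin(hi))


class TestOrderTypes:
    def _freq(self, rows):
        return pd.DataFrame(rows, columns=["rd_type", "position", "residue", "count", "fraction"])

    def test_descending_ed_within_category(self):
        freq = self._freq(
            [
                ["Skn7", "DD", "ED", 4, 0.4],
                ["Ssk1", "DD", "ED", 9, 0.9],
            ]
        )
        assert order_types(freq) == ["Ssk1", "Skn7"]

    def test_rr_precedes_hhk_regardless_of_ed(self):
        freq = self._freq(
            [
                ["Skn7", "DD", "ED", 1, 0.1],
                ["group I", "DD", "ED", 9, 0.99],
            ]
        )
        assert order_types(freq) == ["Skn7", "group I"]

    def test_tie_breaks_alphabetically(self):
        freq = self._freq(
            [
                ["Ssk1", "DD", "ED", 5, 0.5],
                ["Skn7", "DD", "ED", 5, 0.5],
            ]
        )
        assert order_types(freq) == ["Skn7", "Ssk1"]


class TestDisplayMatrix:
    def test_residue_kept_iff_some_type_reaches_threshold(self):
        table = pd.DataFrame(
            {
                "rd_type": ["Skn7"] * 10 + ["Ssk1"] * 10,
                "pos_T+1": ["S"] * 9 + ["A"] + ["G"] * 1 + ["A"] * 9,
            }
        )
        freq = compute_frequency_matrix(table, positions=(parse_position("T+1"),))
        disp = display_matrix(freq, min_fraction=0.20)
        kept = set(disp["residue"])
        assert "S" in kept and "A" in kept
        assert "G" not in kept  # max fraction 0.10 < 0.20

    def test_bins_are_valid_and_missing_never_displayed(self):
        freq = compute_frequency_matrix(
            _toy_table(), positions=(parse_position("DD+17"),)
        )
        disp = display_matrix(freq, min_fraction=0.20)
        assert set(disp["bin"]) <= {"ZERO", "Q1", "Q2", "Q3", "Q4", "Q5", "FULL"}
        assert MISSING not in set(disp["residue"])


class TestD2T2PairTable:
    def test_ranked_counts(self):
        table = pd.DataFrame(
            {
                "rd_type": ["t"] * 3,
                "pos_D+2": ["M", "M", "M"],
                "pos_T+2": ["R", "R", "K"],
            }
        )
        pairs = d2_t2_pair_table(table)
        assert list(pairs[["d2", "t2", "count"]].itertuples(index=False, name=None)) == [
            ("M", "R", 2),
            ("M", "K", 1),
        ]

    def test_missing_member_excluded_from_denominator(self):
        pairs = d2_t2_pair_table(_toy_table())
        ssk1 = pairs[pairs["rd_type"] == "Ssk1"]
        assert ssk1["count"].sum() == 1  # the (Q, NA) row dropped
        assert ssk1.iloc[0]["fraction"] == 1.0
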