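"""Global alignment to CheY, landmark assignment and placement confidence."""

import numpy as np
import pytest
from helpers_oracle import oracle_global_score

from recprofiler.align import (
    AlignmentParams,
    _matrix_with_neutral_x,
    align_to_reference,
    assign_landmarks,
    landmark_confidence,
    make_aligner,
)
from conftest import random_protein


def _score_fn():
    mat = _matrix_with_neutral_x("BLOSUM62")
    return lambda a, b: float(mat[a, b])


class TestAlignToReference:
    def test_identity_alignment_has_no_gaps(self, model):
        aln = align_to_reference(model.sequence, model)
        assert all(r is not None and q is not None for r, q in aln.columns)
        assert [q for _, q in aln.columns] == list(range(1, 130))

    def test_short_query_rejected(self, model):
        with pytest.raises(ValueError, match="60"):
            align_to_reference("M" * 59, model)

    def test_insertion_in_a3b4_is_one_block(self, model):
        loop = model.loop("a3b4")
        mid = (loop.start + loop.end) // 2
        insert = "PSPSPSPSPSPS"
        query = model.sequence[:mid] + insert + model.sequence[mid:]
        aln = align_to_reference(query, model)
        gap_runs = []
        run = 0
        for r, q in aln.columns:
            if r is None:
                run += 1
            elif run:
                gap_runs.append(run)
                run = 0
        assert gap_runs == [12]
        # every landmark still aligned to its own residue
        assignment = assign_landmarks(aln, model)
        for lm, ref_idx in model.landmarks.items():
            shift = 12 if ref_idx > mid else 0
            assert assignment.indices[lm] == ref_idx + shift

    def test_deletion_in_a4_is_one_block(self, model):
        query = model.sequence[:90] + model.sequence[94:]  # drop residues 91-94
        aln = align_to_reference(query, model)
        del_cols = [r for r, q in aln.columns if q is None]
        assert len(del_cols) == 4
        a4 = model.element("a4")
        assert all(r in a4 for r in del_cols)

    def test_x_scores_zero_against_everything(self):
        mat = _matrix_with_neutral_x("BLOSUM62")
        assert all(mat["X", a] == 0 for a in "ACDEFGHIKLMNPQRSTVWYX")

    @pytest.mark.parametrize("trial", range(8))
    def test_score_matches_brute_force_oracle(self, model, trial):
        rng = np.random.default_rng(500 + trial)
        n, m = rng.integers(70, 181, size=2)
        ref = random_protein(rng, int(n))
        query = random_protein(rng, int(m))
        aligner = make_aligner()
        assert aligner.score(ref, query) == pytest.approx(
            oracle_global_score(ref, query, _score_fn()), abs=1e-9
        )

    def test_monotonic_landmark_shift_under_loop_insertions(self, model):
        """Inserting L residues strictly inside a loop shifts every landmark
        C-terminal of the loop by exactly +L and leaves the others alone."""
        for loop_name, length in (("a2b3", 7), ("a3b4", 25), ("b1a1", 12)):
            loop = model.loop(loop_name)
            mid = (loop.start + loop.end) // 2
            query = model.sequence[:mid] + "P" * length + model.sequence[mid:]
            assignment = assign_landmarks(align_to_reference(query, model), model)
            for lm, ref_idx in model.landmarks.items():
                expected = ref_idx + (length if ref_idx > mid else 0)
                assert assignment.indices[lm] == expected, (loop_name, lm)


class TestAssignLandmarks:
    def test_identity_query_is_typical(self, model):
        aln = align_to_reference(model.sequence, model)
        a = assign_landmarks(aln, model)
        assert a.typical and a.missing == frozenset()
        assert a.residues == {"dd1": "D", "dd2": "D", "d": "D", "t": "T", "k": "K"}

    def test_t87a_substitution_flags_t(self, model):
        seq = list(model.sequence)
        seq[86] = "A"
        a = assign_landmarks(align_to_reference("".join(seq), model), model)
        assert a.missing == frozenset({"T"})
        assert not a.typical

    def test_glu_at_d_does_not_satisfy_d(self, model):
        """The Ascomycota Rim15 signature (Glu replacing the phosphorylatable
        Asp) is atypical by the strict-Asp rule."""
        seq = list(model.sequence)
        seq[56] = "E"
        a = assign_landmarks(align_to_reference("".join(seq), model), model)
        assert "D" in a.missing

    def test_glu_asp_pair_satisfies_dd(self, model):
        seq = list(model.sequence)
        seq[11] = "E"  # ED pair
        a = assign_landmarks(align_to_reference("".join(seq), model), model)
        assert "DD" not in a.missing

    def test_x_never_satisfies_a_landmark(self, model):
        seq = list(model.sequence)
        seq[108] = "X"
        a = assign_landmarks(align_to_reference("".join(seq), model), model)
        assert "K" in a.missing


class TestLandmarkConfidence:
    def test_identity_all_anchored(self, model):
        aln = align_to_reference(model.sequence, model)
        conf = landmark_confidence(aln, assign_landmarks(aln, model), model)
        assert set(conf.values()) == {"anchored"}

    def test_insertion_far_from_landmarks_keeps_them_anchored(self, model):
        loop = model.loop("a3b4")
        mid = (loop.start + loop.end) // 2
        query = model.sequence[:mid] + "PSPSPSPSPSPS" + model.sequence[mid:]
        aln = align_to_reference(query, model)
        conf = landmark_confidence(aln, assign_landmarks(aln, model), model)
        assert conf["d"] == "anchored"
        assert conf["t"] == "anchored"
        assert conf["k"] == "anchored"

    def test_deletion_spanning_t_reports_absent(self, model):
        query = model.sequence[:84] + model.sequence[89:]  # removes T87
        aln = align_to_reference(query, model)
        conf = landmark_confidence(aln, assign_landmarks(aln, model), model)
        assert conf["t"] == "absent"
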