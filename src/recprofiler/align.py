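"""Landmark mapping: global alignment to CheY and assignment of the five landmarks.

Each query receiver domain is globally aligned to the CheY reference
(BLOSUM62, affine gaps, terminal gaps at half weight since the inputs are
pre-excised domains with possibly ragged boundaries).  The reference landmark
columns then name the query's own DD1/DD2/D/T/K residues; a domain missing the
expected residue class at any landmark is atypical (a pseudo-receiver domain).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .reference import LANDMARK_CLASSES, ReferenceModel

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "LandmarkAssignment",
    "make_aligner",
    "align_to_reference",
    "assign_landmarks",
    "landmark_confidence",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for the global alignment.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``; terminal gaps are
    charged at ``terminal_factor`` of that (0.5 tolerates ragged ends of
    pre-excised domains without letting the alignment float freely).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    terminal_factor: float = 0.5


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment as 1-based (ref, query) column pairs."""

    columns: tuple[tuple[int | None, int | None], ...]
    score: float
    query: str

    def query_at_ref(self, ref_index: int) -> int | None:
        """Query index aligned to a reference index, or None if gapped there."""
        for r, q in self.columns:
            if r == ref_index:
                return q
        raise IndexError(f"reference index {ref_index} not covered by alignment")


@dataclass(frozen=True)
class LandmarkAssignment:
    """Query indices/residues for the five landmarks plus the typicality call.

    ``missing`` holds the landmark groups (DD, D, T, K) whose expected residue
    class is absent; a domain is typical iff ``missing`` is empty.
    """

    indices: dict[str, int | None]       # dd1, dd2, d, t, k -> query index or None
    residues: dict[str, str | None]
    missing: frozenset[str]

    @property
    def typical(self) -> bool:
        return not self.missing


@lru_cache(maxsize=4)
def _matrix_with_neutral_x(name: str):
    """Substitution matrix over the 20 standard residues plus X scoring 0."""
    base = substitution_matrices.load(name)
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    mat = substitution_matrices.Array(alphabet, dims=2, dtype=float)
    for a in alphabet[:-1]:
        for b in alphabet[:-1]:
            mat[a, b] = base[a, b]
    # X never informs the alignment: zero against everything, including itself.
    for a in alphabet:
        mat["X", a] = 0.0
        mat[a, "X"] = 0.0
    return mat


def make_aligner(params: AlignmentParams = AlignmentParams()) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix_with_neutral_x(params.matrix)
    aligner.open_internal_gap_score = -params.gap_open
    aligner.extend_internal_gap_score = -params.gap_extend
    aligner.open_end_gap_score = -params.gap_open * params.terminal_factor
    aligner.extend_end_gap_score = -params.gap_extend * params.terminal_factor
    return aligner


def align_to_reference(
    query: str,
    model: ReferenceModel,
    params: AlignmentParams = AlignmentParams(),
    aligner: PairwiseAligner | None = None,
) -> AlignmentResult:
    """Optimal global alignment of ``query`` against the reference sequence.

    Deterministic: among co-optimal alignments the aligner's first traceback
    is taken, which is stable for fixed inputs and parameters.
    """
    if len(query) < 60:
        raise ValueError(f"query length {len(query)} < 60")
    if aligner is None:
        aligner = make_aligner(params)
    query = query.upper()
    alignment = next(iter(aligner.align(model.sequence, query)))
    indices = alignment.indices  # 2 x L, -1 at gaps, 0-based
    columns = tuple(
        (int(r) + 1 if r >= 0 else None, int(q) + 1 if q >= 0 else None)
        for r, q in zip(indices[0], indices[1])
    )
    return AlignmentResult(columns=columns, score=float(alignment.score), query=query)


def assign_landmarks(alignment: AlignmentResult, model: ReferenceModel) -> LandmarkAssignment:
    """Read the query residues at the five reference landmark columns.

    Missing-landmark logic: DD requires both dd residues to be acidic (D/E) —
    Asp-Asp and Glu-Asp pairs both bind the catalytic metal; D requires Asp
    exactly; T requires Ser or Thr; K requires Lys exactly.  A gapped landmark
    column or an 'X' never satisfies its class.  Unalignable landmarks surface
    as missing rather than raising.
    """
    ref_to_query = {r: q for r, q in alignment.columns if r is not None}
    query = alignment.query
    indices: dict[str, int | None] = {}
    residues: dict[str, str | None] = {}
    for name, ref_idx in model.landmarks.items():
        qidx = ref_to_query.get(ref_idx)
        indices[name] = qidx
        residues[name] = query[qidx - 1] if qidx is not None else None

    missing: set[str] = set()
    if not (
        residues["dd1"] in LANDMARK_CLASSES["dd1"]
        and residues["dd2"] in LANDMARK_CLASSES["dd2"]
    ):
        missing.add("DD")
    for group, key in (("D", "d"), ("T", "t"), ("K", "k")):
        res = residues[key]
        if res is None or res not in LANDMARK_CLASSES[key]:
            missing.add(group)
    return LandmarkAssignment(indices=indices, residues=residues, missing=frozenset(missing))


def landmark_confidence(
    alignment: AlignmentResult, assignment: LandmarkAssignment, model: ReferenceModel
) -> dict[str, str]:
    """Per-landmark placement confidence: anchored, shifted, or absent.

    A landmark is ``absent`` when its reference column is aligned to a gap,
    ``anchored`` when no gap occurs within two alignment columns of it, and
    ``shifted`` otherwise (a nearby gap opening may have displaced it).
    """
    cols = alignment.columns
    ref_col = {r: i for i, (r, _) in enumerate(cols) if r is not None}
    out: dict[str, str] = {}
    for name, ref_idx in model.landmarks.items():
        c = ref_col[ref_idx]
        if cols[c][1] is None:
            out[name] = "absent"
            continue
        lo, hi = max(0, c - 2), min(len(cols) - 1, c + 2)
        window = cols[lo : hi + 1]
        if all(r is not None and q is not None for r, q in window):
            out[name] = "anchored"
        else:
            out[name] = "shifted"
    return out
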