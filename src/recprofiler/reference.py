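"""Reference model: E. coli CheY sequence, secondary structure and catalytic landmarks.

Receiver domains share a (βα)5 fold — a central five-stranded parallel β sheet
flanked by five α helices — with five conserved catalytic residues at the
C-terminal ends of β1 (the acidic DD pair), β3 (the phosphorylatable Asp, D),
β4 (Thr/Ser, T) and within β5 (Lys, K).  Every query receiver domain is
numbered relative to these landmarks, so the reference model is the coordinate
system for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "SecondaryStructureElement",
    "LoopInterval",
    "ReferenceModel",
    "load_reference",
    "validate_reference",
    "detect_hydrophobic_strands",
    "ELEMENT_ORDER",
    "LOOP_ORDER",
    "HYDROPHOBIC_SET",
]

#: Canonical (βα)5 element order, ASCII labels (b=β strand, a=α helix).
ELEMENT_ORDER = ("b1", "a1", "b2", "a2", "b3", "a3", "b4", "a4", "b5", "a5")

#: Loops between consecutive elements, named by their flanking elements.
LOOP_ORDER = ("b1a1", "a1b2", "b2a2", "a2b3", "b3a3", "a3b4", "b4a4", "a4b5", "b5a5")

#: Default hydrophobic residue set used by the β-strand heuristic.
HYDROPHOBIC_SET = frozenset("AVILMFWC")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residue classes each landmark must satisfy for a domain to be "typical".
LANDMARK_CLASSES = {
    "dd1": frozenset("DE"),
    "dd2": frozenset("DE"),
    "d": frozenset("D"),
    "t": frozenset("ST"),
    "k": frozenset("K"),
}


@dataclass(frozen=True)
class SecondaryStructureElement:
    """One α helix or β strand of the reference, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LoopInterval:
    """Residues strictly between two consecutive elements (may be empty)."""

    name: str
    start: int
    end: int  # end < start denotes an empty loop

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)


@dataclass(frozen=True)
class ReferenceModel:
    """CheY reference: sequence, elements, and the five landmark indices."""

    sequence: str
    elements: tuple[SecondaryStructureElement, ...]
    dd1: int
    dd2: int
    d: int
    t: int
    k: int

    @property
    def landmarks(self) -> dict[str, int]:
        return {"dd1": self.dd1, "dd2": self.dd2, "d": self.d, "t": self.t, "k": self.k}

    @property
    def loops(self) -> tuple[LoopInterval, ...]:
        """Loops derived from consecutive element pairs."""
        out = []
        for left, right in zip(self.elements, self.elements[1:]):
            out.append(LoopInterval(left.name + right.name, left.end + 1, right.start - 1))
        return tuple(out)

    def element(self, name: str) -> SecondaryStructureElement:
        for el in self.elements:
            if el.name == name:
                return el
        raise KeyError(f"no element named {name!r}")

    def loop(self, name: str) -> LoopInterval:
        for lp in self.loops:
            if lp.name == name:
                return lp
        raise KeyError(f"no loop named {name!r}")

    def intervals(self) -> dict[str, tuple[int, int]]:
        """All named intervals (elements, loops, terminal tails) covering the sequence."""
        out: dict[str, tuple[int, int]] = {}
        first, last = self.elements[0], self.elements[-1]
        if first.start > 1:
            out["n_tail"] = (1, first.start - 1)
        merged = []
        for el, lp in zip(self.elements, list(self.loops) + [None]):
            merged.append((el.name, (el.start, el.end)))
            if lp is not None:
                merged.append((lp.name, (lp.start, lp.end)))
        out.update(dict(merged))
        if last.end < len(self.sequence):
            out["c_tail"] = (last.end + 1, len(self.sequence))
        return out

    def residue(self, index: int) -> str:
        return self.sequence[index - 1]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("recprofiler").joinpath("data", name)))


def load_reference(directory: str | Path | None = None) -> ReferenceModel:
    """Load the packaged CheY reference model (or one from ``directory``).

    The model directory holds ``chey.fasta`` (sequence), ``chey_elements.tsv``
    (element, start, end) and ``chey_landmarks.tsv`` (landmark, index).
    Deterministic and idempotent; the returned model is validated.
    """
    if directory is None:
        fasta, elem_tsv, lm_tsv = (
            _data_path("chey.fasta"),
            _data_path("chey_elements.tsv"),
            _data_path("chey_landmarks.tsv"),
        )
    else:
        directory = Path(directory)
        fasta = directory / "chey.fasta"
        elem_tsv = directory / "chey_elements.tsv"
        lm_tsv = directory / "chey_landmarks.tsv"

    for path in (fasta, elem_tsv, lm_tsv):
        if not path.exists():
            raise FileNotFoundError(f"reference data file missing: {path}")

    try:
        record = next(SeqIO.parse(str(fasta), "fasta"))
    except StopIteration:
        raise ValueError(f"reference FASTA {fasta} contains no record") from None
    sequence = str(record.seq).upper()

    elements = []
    for line in _read_tsv_lines(elem_tsv, "element"):
        name, start, end = line
        elements.append(SecondaryStructureElement(name, int(start), int(end)))

    landmarks = {}
    for name, index in _read_tsv_lines(lm_tsv, "landmark"):
        landmarks[name] = int(index)

    model = ReferenceModel(sequence=sequence, elements=tuple(elements), **landmarks)
    violations = validate_reference(model)
    if violations:
        raise ValueError(
            f"reference model in {fasta.parent} is invalid: " + "; ".join(violations)
        )
    return model


def _read_tsv_lines(path: Path, expected_first_col: str):
    rows = []
    with open(path) as fh:
        header = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                if header[0] != expected_first_col:
                    raise ValueError(
                        f"corrupt reference file {path}: expected first column "
                        f"{expected_first_col!r}, found {header[0]!r}"
                    )
                continue
            rows.append(cells)
    if header is None:
        raise ValueError(f"corrupt reference file {path}: no header row")
    return rows


def validate_reference(model: ReferenceModel) -> list[str]:
    """Return a list of invariant violations (empty when the model is valid)."""
    v: list[str] = []
    n = len(model.sequence)

    names = tuple(el.name for el in model.elements)
    if names != ELEMENT_ORDER:
        v.append(f"elements out of order: expected {ELEMENT_ORDER}, found {names}")
    prev_end = 0
    for el in model.elements:
        if el.start > el.end:
            v.append(f"element {el.name} has start > end")
        if el.start <= prev_end:
            v.append(f"element {el.name} overlaps or precedes its predecessor")
        prev_end = max(prev_end, el.end)
        if el.end > n:
            v.append(f"element {el.name} extends past the sequence end")

    lm = model.landmarks
    for name, idx in lm.items():
        if not 1 <= idx <= n:
            v.append(f"landmark {name} index {idx} outside sequence")
    if all(1 <= lm[x] <= n for x in lm):
        if model.residue(model.d) != "D":
            v.append("landmark D is not Asp")
        if model.residue(model.dd1) not in "DE" or model.residue(model.dd2) not in "DE":
            v.append("DD landmark residues are not acidic")
        if model.residue(model.t) not in "ST":
            v.append("landmark T is not Thr/Ser")
        if model.residue(model.k) != "K":
            v.append("landmark K is not Lys")
    if model.dd1 + 1 != model.dd2:
        v.append("dd1 and dd2 are not adjacent")
    if not (model.dd2 < model.d < model.t < model.k):
        v.append("landmarks are not in dd2 < d < t < k order")

    if not v:
        b3, b4, b5 = model.element("b3"), model.element("b4"), model.element("b5")
        if model.d != b3.end:
            v.append("landmark D is not at the C-terminal end of b3")
        if model.t != b4.end:
            v.append("landmark T is not at the C-terminal end of b4")
        if model.k not in b5:
            v.append("landmark K is not within b5")
        if model.dd2 != model.element("b1").end:
            v.append("DD pair is not at the C-terminal end of b1")
    return v


def detect_hydrophobic_strands(
    sequence: str,
    min_run: int = 4,
    hydrophobic: frozenset[str] | set[str] = HYDROPHOBIC_SET,
) -> list[tuple[int, int]]:
    """Maximal runs of ≥ ``min_run`` consecutive hydrophobic residues.

    Interior β strands of receiver domains tend to show up in the primary
    sequence as runs of consecutive hydrophobic residues; this is a heuristic
    locator, not a secondary-structure predictor.  Returns 1-based inclusive
    intervals left to right.
    """
    if not sequence:
        raise ValueError("sequence is empty")
    seq = sequence.upper()
    allowed = set(STANDARD_AA) | {"X"}
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(f"nonstandard residue {ch!r} at position {pos}")

    runs: list[tuple[int, int]] = []
    start = None
    for pos, ch in enumerate(seq + "$", start=1):  # sentinel flushes final run
        if ch in hydrophobic:
            if start is None:
                start = pos
        else:
            if start is not None and pos - start >= min_run:
                runs.append((start, pos - 1))
            start = None
    return runs
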