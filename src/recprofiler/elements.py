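"""Per-element and per-loop length deltas versus CheY, and loop-insertion scoring.

Receiver domains keep the (βα)5 core but vary markedly in loop length; fungal
domains in particular carry long, Pro/Ser-rich (intrinsically disordered)
insertions in the α2β3 and α3β4 loops that are thought to mediate protein
binding.  This module measures, per reference interval (element or loop), how
many query residues map there, flags insertions of 10 or more residues, and
scores the Pro/Ser composition of the inserted segments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignmentResult
from .reference import ReferenceModel

__all__ = [
    "ElementDelta",
    "InsertionReport",
    "LoopInsertion",
    "element_length_deltas",
    "flag_loop_insertions",
    "insert_composition",
    "DEFAULT_INSERTION_LOOPS",
    "DEFAULT_INSERTION_THRESHOLD",
]

DEFAULT_INSERTION_LOOPS = ("a2b3", "a3b4")
DEFAULT_INSERTION_THRESHOLD = 10


@dataclass(frozen=True)
class ElementDelta:
    """Query residue count mapped to one reference interval, versus reference."""

    name: str
    query_count: int
    ref_count: int
    inserted_segments: tuple[str, ...]

    @property
    def delta(self) -> int:
        return self.query_count - self.ref_count


@dataclass(frozen=True)
class LoopInsertion:
    """Insertion call for one loop: net delta, flag, and inserted residues."""

    loop: str
    delta: int
    flagged: bool
    segments: tuple[str, ...]
    pro_fraction: float
    ser_fraction: float


@dataclass(frozen=True)
class InsertionReport:
    loops: dict[str, LoopInsertion]

    def __getitem__(self, loop: str) -> LoopInsertion:
        return self.loops[loop]

    @property
    def any_flagged(self) -> bool:
        return any(li.flagged for li in self.loops.values())


def element_length_deltas(
    alignment: AlignmentResult, model: ReferenceModel
) -> list[ElementDelta]:
    """Count query residues per reference interval and take deltas.

    Ref-consuming columns are attributed to the interval containing their
    reference index.  A run of query-insertion columns is attributed to the
    interval containing the reference position immediately preceding the run;
    a run before the first reference column belongs to the N-terminal tail.
    Because the (βα)5 elements are fixed-length structural cores, a run whose
    preceding position falls inside an element is an alignment-jitter artifact
    (the gap opened a column or two past a loop boundary) and is reattached to
    the nearer flanking interval — the loop or tail adjacent to the element.
    Deltas are net per-interval length differences, so a 12-residue insertion
    plus a 2-residue deletion in one loop yields +10.
    """
    intervals = model.intervals()
    order = list(intervals)
    if "n_tail" not in intervals:
        order.insert(0, "n_tail")
    element_names = {el.name for el in model.elements}

    def interval_of(ref_idx: int) -> str:
        for name, (lo, hi) in intervals.items():
            if lo <= ref_idx <= hi:
                return name
        raise ValueError(f"reference index {ref_idx} outside all intervals")

    def run_home(prev_ref: int | None) -> str:
        """Interval an insertion run belongs to, given the ref position before it."""
        if prev_ref is None:
            return "n_tail"
        name = interval_of(prev_ref)
        if name not in element_names:
            return name
        lo, hi = intervals[name]
        pos = order.index(name)
        before = order[pos - 1] if pos > 0 else "n_tail"
        after = order[pos + 1] if pos + 1 < len(order) else order[-1]
        return before if (prev_ref - lo) <= (hi - prev_ref) else after

    counts = {name: 0 for name in order}
    segments: dict[str, list[str]] = {name: [] for name in order}

    prev_ref: int | None = None
    run: list[str] = []  # residues of the open insertion run
    for ref_idx, q_idx in alignment.columns:
        if ref_idx is not None:
            if run:
                segments[run_home(prev_ref)].append("".join(run))
                run = []
            prev_ref = ref_idx
            if q_idx is not None:
                counts[interval_of(ref_idx)] += 1
        else:
            run.append(alignment.query[q_idx - 1])
    if run:
        segments[run_home(prev_ref)].append("".join(run))
    for name, segs in segments.items():
        counts[name] += sum(len(s) for s in segs)

    out = []
    for name in order:
        lo_hi = intervals.get(name)
        ref_count = (lo_hi[1] - lo_hi[0] + 1) if lo_hi else 0
        out.append(
            ElementDelta(
                name=name,
                query_count=counts[name],
                ref_count=ref_count,
                inserted_segments=tuple(segments[name]),
            )
        )
    return out


def insert_composition(segment: str) -> tuple[float, float]:
    """(Pro fraction, Ser fraction) of an inserted segment; empty -> (0, 0)."""
    if not segment:
        return (0.0, 0.0)
    n = len(segment)
    return (segment.count("P") / n, segment.count("S") / n)


def flag_loop_insertions(
    deltas: list[ElementDelta],
    loops: tuple[str, ...] = DEFAULT_INSERTION_LOOPS,
    threshold: int = DEFAULT_INSERTION_THRESHOLD,
) -> InsertionReport:
    """Flag loops whose net length gain reaches ``threshold`` (inclusive).

    The inserted-segment composition pools all insertion runs attributed to
    the loop; a loop with no insertion columns reports (0, 0).
    """
    by_name = {d.name: d for d in deltas}
    report: dict[str, LoopInsertion] = {}
    for loop in loops:
        if loop not in by_name:
            raise KeyError(f"unknown loop {loop!r}")
        d = by_name[loop]
        pooled = "".join(d.inserted_segments)
        pro, ser = insert_composition(pooled)
        report[loop] = LoopInsertion(
            loop=loop,
            delta=d.delta,
            flagged=d.delta >= threshold,
            segments=d.inserted_segments,
            pro_fraction=pro,
            ser_fraction=ser,
        )
    return InsertionReport(loops=report)
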