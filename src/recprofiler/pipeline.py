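"""End-to-end annotation: records in, per-domain characteristics table out.

One row per receiver domain: taxonomy and type, the five landmark indices and
residues with the typical/atypical call, the residue at every named key
position, per-loop length deltas versus CheY, insertion flags for the α2β3
and α3β4 loops, the α4 delta, and the Pro/Ser composition of inserted
segments.  This flat table is the substrate for the frequency matrices and
the summary statistics.
"""

from __future__ import annotations

import pandas as pd

from .align import (
    AlignmentParams,
    align_to_reference,
    assign_landmarks,
    landmark_confidence,
    make_aligner,
)
from .elements import (
    DEFAULT_INSERTION_LOOPS,
    DEFAULT_INSERTION_THRESHOLD,
    element_length_deltas,
    flag_loop_insertions,
    insert_composition,
)
from .io import MISSING, ReceiverDomainRecord
from .profiles import DEFAULT_KEY_POSITIONS, NamedPosition, extract_positions
from .reference import LOOP_ORDER, ReferenceModel, load_reference

__all__ = ["annotate_record", "annotate_records", "CHARACTERISTICS_COLUMNS"]

_LANDMARKS = ("dd1", "dd2", "d", "t", "k")

CHARACTERISTICS_COLUMNS = (
    ["id", "species", "phylum", "rd_type", "category", "domain_index",
     "domains_in_protein", "has_tm"]
    + [f"{lm}_idx" for lm in _LANDMARKS]
    + [f"{lm}_res" for lm in _LANDMARKS]
    + ["missing", "typical", "score"]
    + [f"pos_{p.name}" for p in DEFAULT_KEY_POSITIONS]
    + [f"delta_{loop}" for loop in LOOP_ORDER]
    + ["delta_a4", "ins_a2b3_flag", "ins_a3b4_flag", "ins_pro_frac", "ins_ser_frac"]
)


def annotate_record(
    record: ReceiverDomainRecord,
    model: ReferenceModel,
    params: AlignmentParams = AlignmentParams(),
    positions: tuple[NamedPosition, ...] = DEFAULT_KEY_POSITIONS,
    insertion_threshold: int = DEFAULT_INSERTION_THRESHOLD,
    aligner=None,
) -> dict:
    """Build one characteristics row for a record."""
    aln = align_to_reference(record.sequence, model, params, aligner=aligner)
    assignment = assign_landmarks(aln, model)
    deltas = element_length_deltas(aln, model)
    report = flag_loop_insertions(
        deltas, loops=DEFAULT_INSERTION_LOOPS, threshold=insertion_threshold
    )
    pos_map = extract_positions(record.sequence, assignment, positions)

    delta_by_name = {d.name: d for d in deltas}
    pooled = "".join(
        seg for loop in DEFAULT_INSERTION_LOOPS
        for seg in delta_by_name[loop].inserted_segments
    )
    pro, ser = insert_composition(pooled)

    row: dict = {
        "id": record.id,
        "species": record.species,
        "phylum": record.phylum,
        "rd_type": record.rd_type,
        "category": record.category,
        "domain_index": record.domain_index,
        "domains_in_protein": record.domains_in_protein,
        "has_tm": record.has_tm,
    }
    for lm in _LANDMARKS:
        idx = assignment.indices[lm]
        row[f"{lm}_idx"] = idx if idx is not None else None
    for lm in _LANDMARKS:
        res = assignment.residues[lm]
        row[f"{lm}_res"] = res if res is not None else None
    row["missing"] = ",".join(sorted(assignment.missing)) if assignment.missing else ""
    row["typical"] = assignment.typical
    row["score"] = aln.score
    for pos in positions:
        row[f"pos_{pos.name}"] = pos_map[pos.name]
    for loop in LOOP_ORDER:
        row[f"delta_{loop}"] = delta_by_name[loop].delta
    row["delta_a4"] = delta_by_name["a4"].delta
    row["ins_a2b3_flag"] = report["a2b3"].flagged
    row["ins_a3b4_flag"] = report["a3b4"].flagged
    row["ins_pro_frac"] = pro
    row["ins_ser_frac"] = ser
    return row


def annotate_records(
    records: list[ReceiverDomainRecord],
    model: ReferenceModel | None = None,
    params: AlignmentParams = AlignmentParams(),
    positions: tuple[NamedPosition, ...] = DEFAULT_KEY_POSITIONS,
    insertion_threshold: int = DEFAULT_INSERTION_THRESHOLD,
) -> pd.DataFrame:
    """Characteristics table for a dataset (one row per record, input order)."""
    if model is None:
        model = load_reference()
    aligner = make_aligner(params)
    rows = [
        annotate_record(
            rec, model, params, positions, insertion_threshold, aligner=aligner
        )
        for rec in records
    ]
    df = pd.DataFrame(rows)
    return df[[c for c in CHARACTERISTICS_COLUMNS if c in df.columns]]
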