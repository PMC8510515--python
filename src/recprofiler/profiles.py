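"""Landmark-relative named positions and per-type amino-acid frequency matrices.

Variable residues in receiver domains are named by their signed offset from
the conserved catalytic landmarks: K-3 is three residues N-terminal of the
conserved Lys, DD+17 seventeen residues C-terminal of the second residue of
the acidic DD pair, and so on.  Offsets count residues in the query's own
sequence (not alignment columns), which keeps names well-defined across loop
insertions N-terminal of the anchor.

The frequency matrix tallies, per receiver-domain type and named position,
the fraction of domains showing each residue (plus an explicit missing
category so denominators stay equal to the type's record count).  The display
matrix applies the 20% residue filter and quintile color bins used for
heatmap rendering.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import pandas as pd

from .align import LandmarkAssignment
from .io import MISSING, type_category
from .reference import ReferenceModel

logger = logging.getLogger(__name__)

__all__ = [
    "NamedPosition",
    "DEFAULT_KEY_POSITIONS",
    "parse_position",
    "resolve_position",
    "reference_index",
    "extract_positions",
    "compute_frequency_matrix",
    "quintile_bin",
    "order_types",
    "display_matrix",
    "d2_t2_pair_table",
]

_ANCHOR_KEY = {"DD": "dd2", "D": "d", "T": "t", "K": "k"}


@dataclass(frozen=True)
class NamedPosition:
    """A landmark-relative position, e.g. K-3 or DD+17.

    The DD anchor resolves to the second residue of the acidic pair (dd2); an
    offset of 0 means the landmark itself, and the bare name ``DD`` denotes
    the ordered two-residue pair.
    """

    anchor: str  # DD, D, T, K
    offset: int

    @property
    def name(self) -> str:
        if self.offset == 0:
            return self.anchor
        return f"{self.anchor}{self.offset:+d}"

    @property
    def is_pair(self) -> bool:
        return self.anchor == "DD" and self.offset == 0


_POS_RE = re.compile(r"^(DD|D|T|K)([+-]\d+)?$")


def parse_position(name: str) -> NamedPosition:
    """Parse a canonical position name such as 'K-3', 'DD+17' or 'T'."""
    m = _POS_RE.match(name.replace("−", "-").replace("–", "-"))
    if not m:
        raise ValueError(f"unparseable position name {name!r}")
    return NamedPosition(m.group(1), int(m.group(2) or 0))


#: Every position symbol used in the analysis, N→C in reference coordinates.
DEFAULT_KEY_POSITIONS: tuple[NamedPosition, ...] = tuple(
    parse_position(p)
    for p in (
        "DD", "DD+1", "DD+17",
        "D", "D+2", "D+4", "D+8", "D+10",
        "T", "T+1", "T+2", "T+8", "T+11",
        "K-6", "K-4", "K-3", "K-1", "K", "K+1", "K+2", "K+4",
    )
)


def reference_index(pos: NamedPosition, model: ReferenceModel) -> int:
    """The reference (CheY) index a named position resolves to on the identity query."""
    return model.landmarks[_ANCHOR_KEY[pos.anchor]] + pos.offset


def resolve_position(
    assignment: LandmarkAssignment, pos: NamedPosition, sequence: str
) -> tuple[int, str] | None:
    """Resolve a named position on a query: (1-based index, residue) or None.

    Undefined (None) when the anchor landmark is unaligned or the offset runs
    off either end of the sequence.  For the DD pair, the residue is the
    ordered two-letter string (e.g. 'ED' for Glu-Asp) and the index is dd1's.
    """
    if pos.is_pair:
        i1, i2 = assignment.indices["dd1"], assignment.indices["dd2"]
        if i1 is None or i2 is None:
            return None
        return i1, sequence[i1 - 1] + sequence[i2 - 1]
    anchor_idx = assignment.indices[_ANCHOR_KEY[pos.anchor]]
    if anchor_idx is None:
        return None
    idx = anchor_idx + pos.offset
    if not 1 <= idx <= len(sequence):
        return None
    return idx, sequence[idx - 1]


def extract_positions(
    sequence: str,
    assignment: LandmarkAssignment,
    positions: tuple[NamedPosition, ...] = DEFAULT_KEY_POSITIONS,
) -> dict[str, str]:
    """Per-domain position→residue map; undefined positions map to the NA token."""
    out: dict[str, str] = {}
    for pos in positions:
        hit = resolve_position(assignment, pos, sequence)
        out[pos.name] = hit[1] if hit is not None else MISSING
    return out


def compute_frequency_matrix(
    table: pd.DataFrame,
    positions: tuple[NamedPosition, ...] = DEFAULT_KEY_POSITIONS,
    type_column: str = "rd_type",
    drop_missing: bool = False,
) -> pd.DataFrame:
    """Per type × position residue frequencies, long format.

    ``table`` holds one row per domain with ``pos_<name>`` columns (as built
    by the pipeline).  Fractions at each type × position sum to 1 including
    the missing category; with ``drop_missing`` the denominator is instead
    the number of domains where the position is defined.

    Returns columns: rd_type, position, residue, count, fraction.
    """
    rows = []
    for rd_type, group in table.groupby(type_column, sort=True):
        n = len(group)
        if n == 0:
            logger.warning("type %s has no records; omitted", rd_type)
            continue
        for pos in positions:
            col = f"pos_{pos.name}"
            if col not in table.columns:
                raise KeyError(f"table lacks column {col!r}")
            values = group[col]
            if drop_missing:
                values = values[values != MISSING]
            denom = len(values) if drop_missing else n
            if denom == 0:
                continue
            for residue, count in values.value_counts().sort_index().items():
                rows.append(
                    {
                        "rd_type": rd_type,
                        "position": pos.name,
                        "residue": residue,
                        "count": int(count),
                        "fraction": count / denom,
                    }
                )
    return pd.DataFrame(rows, columns=["rd_type", "position", "residue", "count", "fraction"])


_BINS = ("ZERO", "Q1", "Q2", "Q3", "Q4", "Q5", "FULL")


def quintile_bin(fraction: float) -> str:
    """Heatmap color bin: 0 and 1 are their own (dark) bins, quintiles between.

    Bins are half-open: (0,0.2] -> Q1, (0.2,0.4] -> Q2, ... (0.8,1.0) -> Q5.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction == 0.0:
        return "ZERO"
    if fraction == 1.0:
        return "FULL"
    k = math.ceil(fraction * 5)
    return f"Q{min(k, 5)}"


def order_types(freq: pd.DataFrame) -> list[str]:
    """Row order for the heatmap: response regulators first, then HHKs, then
    unclassified; within each category by decreasing Glu-Asp ('ED') fraction
    at the DD pair, ties broken alphabetically."""
    types = freq["rd_type"].unique()
    ed = {
        t: float(
            freq.query("rd_type == @t and position == 'DD' and residue == 'ED'")[
                "fraction"
            ].sum()
        )
        for t in types
    }
    cat_rank = {"response_regulator": 0, "hhk": 1, "unclassified": 2}
    return sorted(types, key=lambda t: (cat_rank[type_category(t)], -ed[t], t))


def display_matrix(
    freq: pd.DataFrame,
    min_fraction: float = 0.20,
    model: ReferenceModel | None = None,
    positions: tuple[NamedPosition, ...] = DEFAULT_KEY_POSITIONS,
) -> pd.DataFrame:
    """Displayable heatmap cells: 20% residue filter, quintile bins, ordered types.

    A residue is retained at a position iff at least one type shows it at
    ``min_fraction`` or more there; the missing category is never displayed.
    Rows come back ordered by type (see ``order_types``) and by position N→C
    in reference coordinates, with a ``bin`` column in ZERO/Q1..Q5/FULL.
    """
    shown = freq[freq["residue"] != MISSING].copy()
    keep = (
        shown.groupby(["position", "residue"])["fraction"].max().reset_index()
    )
    keep = keep[keep["fraction"] >= min_fraction][["position", "residue"]]
    shown = shown.merge(keep, on=["position", "residue"], how="inner")
    shown["bin"] = shown["fraction"].map(quintile_bin)

    type_order = order_types(freq)
    shown["rd_type"] = pd.Categorical(shown["rd_type"], categories=type_order, ordered=True)
    if model is not None:
        pos_order = [
            p.name for p in sorted(positions, key=lambda p: reference_index(p, model))
        ]
    else:
        pos_order = [p.name for p in positions]
    shown["position"] = pd.Categorical(shown["position"], categories=pos_order, ordered=True)
    shown = shown.sort_values(["rd_type", "position", "residue"]).reset_index(drop=True)
    shown["rd_type"] = shown["rd_type"].astype(str)
    shown["position"] = shown["position"].astype(str)
    return shown


def d2_t2_pair_table(table: pd.DataFrame, type_column: str = "rd_type") -> pd.DataFrame:
    """Ranked (D+2, T+2) residue pairs per type.

    Domains missing either member are excluded from the denominator.  Ties in
    count are broken lexicographically by the pair.  Columns: rd_type, d2, t2,
    count, fraction.
    """
    rows = []
    for rd_type, group in table.groupby(type_column, sort=True):
        pairs = group[["pos_D+2", "pos_T+2"]]
        pairs = pairs[(pairs["pos_D+2"] != MISSING) & (pairs["pos_T+2"] != MISSING)]
        denom = len(pairs)
        if denom == 0:
            continue
        counts = (
            pairs.value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["count", "pos_D+2", "pos_T+2"], ascending=[False, True, True])
        )
        for _, row in counts.iterrows():
            rows.append(
                {
                    "rd_type": rd_type,
                    "d2": row["pos_D+2"],
                    "t2": row["pos_T+2"],
                    "count": int(row["count"]),
                    "fraction": row["count"] / denom,
                }
            )
    return pd.DataFrame(rows, columns=["rd_type", "d2", "t2", "count", "fraction"])
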