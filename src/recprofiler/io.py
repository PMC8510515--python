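"""Input/output: annotated receiver-domain sequences and flat result tables.

The canonical transport formats are FASTA (sequences) and TSV (annotations in;
characteristics, frequency and summary tables out).  Writers are deterministic:
fixed column order, floats at 4 decimals, missing values serialized as ``NA``,
so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ReceiverDomainRecord",
    "RESPONSE_REGULATOR_TYPES",
    "HHK_TYPES",
    "ALL_TYPES",
    "UNCLASSIFIED",
    "type_category",
    "read_fasta",
    "read_annotations",
    "load_dataset",
    "write_characteristics",
    "read_characteristics",
    "MISSING",
    "MIN_SEQUENCE_LENGTH",
]

MISSING = "NA"
MIN_SEQUENCE_LENGTH = 60
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: The five named fungal response-regulator receiver types.
RESPONSE_REGULATOR_TYPES = (
    "Rim15-Ascomycota",
    "Rim15-nonAscomycota",
    "Skn7",
    "Ssk1",
    "Srr1",
)

_ROMAN = (
    "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI XVII XVIII XIX".split()
)
#: The 20 hybrid-histidine-kinase receiver types (group XII has two receiver
#: domains, Rec1 and Rec2, counted as separate types).
HHK_TYPES = tuple(
    f"group {r}" for r in _ROMAN if r != "XII"
) + ("group XII-Rec1", "group XII-Rec2")

UNCLASSIFIED = "Unclassified"
ALL_TYPES = RESPONSE_REGULATOR_TYPES + HHK_TYPES + (UNCLASSIFIED,)


def type_category(rd_type: str) -> str:
    """Map a receiver-domain type label to its category."""
    if rd_type in RESPONSE_REGULATOR_TYPES:
        return "response_regulator"
    if rd_type in HHK_TYPES:
        return "hhk"
    return "unclassified"


@dataclass(frozen=True)
class ReceiverDomainRecord:
    """One annotated receiver-domain sequence."""

    id: str
    species: str
    phylum: str
    rd_type: str
    sequence: str
    domain_index: int = 1
    domains_in_protein: int = 1
    has_tm: bool | None = None

    @property
    def category(self) -> str:
        return type_category(self.rd_type)

    def __post_init__(self):
        if len(self.sequence) < MIN_SEQUENCE_LENGTH:
            raise ValueError(
                f"record {self.id}: sequence length {len(self.sequence)} < "
                f"{MIN_SEQUENCE_LENGTH} (too short to contain all five landmarks)"
            )
        bad = set(self.sequence) - set(STANDARD_AA) - {"X"}
        if bad:
            raise ValueError(f"record {self.id}: nonstandard residues {sorted(bad)}")
        if self.domain_index > self.domains_in_protein:
            raise ValueError(
                f"record {self.id}: domain_index {self.domain_index} exceeds "
                f"domains_in_protein {self.domains_in_protein}"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, upper-cased sequence) pairs in file order.

    The id is the first whitespace-delimited token of the header.  Duplicate
    ids and empty sequences are errors.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    return out


_REQUIRED_COLUMNS = ("id", "species", "phylum", "rd_type")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the TSV annotation table, keyed by ``id``.

    Required columns: id, species, phylum, rd_type.  Optional: domain_index,
    domains_in_protein, has_tm.  Unknown rd_type labels are demoted to
    ``Unclassified`` with a logged warning (the classification itself has an
    Unclassified bucket, so unknown labels are data, not errors).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"annotation table {path} is missing column {col!r}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate annotation ids: {dupes}")

    unknown = ~df["rd_type"].isin(ALL_TYPES)
    for rid, label in zip(df.loc[unknown, "id"], df.loc[unknown, "rd_type"]):
        logger.warning(
            "record %s: unknown rd_type %r mapped to Unclassified", rid, label
        )
    df.loc[unknown, "rd_type"] = UNCLASSIFIED

    if "domain_index" in df.columns:
        df["domain_index"] = df["domain_index"].replace("", "1").astype(int)
    else:
        df["domain_index"] = 1
    if "domains_in_protein" in df.columns:
        df["domains_in_protein"] = df["domains_in_protein"].replace("", "1").astype(int)
    else:
        df["domains_in_protein"] = 1
    if "has_tm" in df.columns:
        df["has_tm"] = df["has_tm"].map(
            {"True": True, "False": False, "true": True, "false": False,
             "1": True, "0": False, MISSING: None, "": None}
        )
    else:
        df["has_tm"] = None
    return df.set_index("id", drop=False)


def load_dataset(fasta_path: str | Path, annotation_path: str | Path) -> list[ReceiverDomainRecord]:
    """Join sequences and annotations into records; total over ids or fails loudly."""
    seqs = read_fasta(fasta_path)
    ann = read_annotations(annotation_path)
    missing_ann = [sid for sid, _ in seqs if sid not in ann.index]
    if missing_ann:
        raise ValueError(f"sequences without annotation rows: {missing_ann}")
    extra_ann = set(ann.index) - {sid for sid, _ in seqs}
    if extra_ann:
        raise ValueError(f"annotation rows without sequences: {sorted(extra_ann)}")

    records = []
    for sid, seq in seqs:
        row = ann.loc[sid]
        records.append(
            ReceiverDomainRecord(
                id=sid,
                species=row["species"],
                phylum=row["phylum"],
                rd_type=row["rd_type"],
                sequence=seq,
                domain_index=int(row["domain_index"]),
                domains_in_protein=int(row["domains_in_protein"]),
                has_tm=row["has_tm"],
            )
        )
    return records


def _format_cell(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return MISSING
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_characteristics(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the per-domain characteristics table as deterministic TSV."""
    if len(rows) == 0:
        raise ValueError("characteristics table is empty")
    with open(path, "w") as fh:
        fh.write("\t".join(rows.columns) + "\n")
        for _, row in rows.iterrows():
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


def read_characteristics(path: str | Path) -> pd.DataFrame:
    """Read a characteristics TSV back (all cells as strings; NA preserved)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
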