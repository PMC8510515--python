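"""Headline summary statistics over the per-domain characteristics table.

These are the database-level descriptive statistics of the analysis: the
type inventory, the atypical (pseudo-receiver) rate, the type-specific residue
signatures (Skn7 Cys at DD+17, Srr1 aromatic/His at K−4, Rim15 phylum
signatures), loop-insertion statistics (Ssk1 α3β4 insert mean ± SD, pooled
HHK insertion rate), the prevalence of Unclassified response regulators by
clade, the group XII single-domain rate, and transmembrane percentages.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field

import pandas as pd

from .io import MISSING, RESPONSE_REGULATOR_TYPES, UNCLASSIFIED

logger = logging.getLogger(__name__)

__all__ = ["SummaryReport", "compute_summary", "tm_percent_by_type"]

RIM15_TYPES = ("Rim15-Ascomycota", "Rim15-nonAscomycota")
GROUP_XII = ("group XII-Rec1", "group XII-Rec2")


@dataclass
class SummaryReport:
    """Computed summary statistics; fractions in [0, 1], percentages derived."""

    n_domains: int
    n_species: int
    inventory: dict[str, int]
    atypical_fraction: float
    skn7_cys_dd17_fraction: float | None
    skn7_lacking_st_d10_fraction: float | None
    hhk_insertion_fraction: float | None
    ssk1_insert_mean: float | None
    ssk1_insert_sd: float | None
    srr1_k4_aromatic_his_fraction: float | None
    unclassified_rr_fraction: float | None
    species_without_unclassified_fraction: float
    unclassified_presence_by_clade: dict[str, float]
    groupxii_single_domain_fraction: float | None
    rim15_signature_conformance: dict[str, float]

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def percentages(self) -> dict[str, float]:
        """The fraction-valued fields rounded to whole percentages."""
        out = {}
        for name, value in asdict(self).items():
            if name.endswith("_fraction") and value is not None:
                out[name.replace("_fraction", "_pct")] = round(100 * value)
        return out


def _frac(mask: pd.Series) -> float | None:
    return float(mask.mean()) if len(mask) else None


def compute_summary(table: pd.DataFrame, include_rim15_in_atypical: bool = False) -> SummaryReport:
    """Compute every summary field from the characteristics table.

    Rim15 domains are excluded from the atypical rate by default: the
    Ascomycota Rim15 signature replaces the phosphorylatable Asp with Glu by
    design, so counting them would conflate a lineage signature with landmark
    degradation.  ``include_rim15_in_atypical`` restores them.  Order-invariant:
    shuffling the input rows changes nothing.
    """
    if len(table) == 0:
        raise ValueError("characteristics table is empty")
    t = table

    inventory = t["rd_type"].value_counts().sort_index().astype(int).to_dict()

    atyp_pool = t if include_rim15_in_atypical else t[~t["rd_type"].isin(RIM15_TYPES)]
    atypical_fraction = float((~atyp_pool["typical"].astype(bool)).mean())

    skn7 = t[t["rd_type"] == "Skn7"]
    skn7_cys = _frac(skn7["pos_DD+17"] == "C")
    skn7_no_st = _frac(~skn7["pos_D+10"].isin(["S", "T"]))  # NA counts as lacking

    hhk = t[t["category"] == "hhk"]
    hhk_ins = _frac(hhk["ins_a2b3_flag"].astype(bool) | hhk["ins_a3b4_flag"].astype(bool)) if len(hhk) else None

    ssk1 = t[t["rd_type"] == "Ssk1"]
    if len(ssk1):
        deltas = ssk1["delta_a3b4"].astype(float)
        ssk1_mean = float(deltas.mean())
        ssk1_sd = float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0
    else:
        ssk1_mean = ssk1_sd = None

    srr1 = t[t["rd_type"] == "Srr1"]
    srr1_k4 = _frac(srr1["pos_K-4"].isin(["Y", "F", "H"]))

    rr_mask = t["rd_type"].isin(RESPONSE_REGULATOR_TYPES) | (t["rd_type"] == UNCLASSIFIED)
    rr = t[rr_mask]
    uncl_rr = _frac(rr["rd_type"] == UNCLASSIFIED)

    species_all = t.groupby("species")
    has_uncl = species_all.apply(
        lambda g: bool((g["rd_type"] == UNCLASSIFIED).any()), include_groups=False
    )
    species_without = float((~has_uncl).mean())
    phylum_of = t.drop_duplicates("species").set_index("species")["phylum"]
    ab = phylum_of.isin(["Ascomycota", "Basidiomycota"])
    clade = {
        "asco_basidio": float(has_uncl[ab.reindex(has_uncl.index)].mean())
        if ab.reindex(has_uncl.index).any()
        else 0.0,
        "other_phyla": float(has_uncl[~ab.reindex(has_uncl.index)].mean())
        if (~ab.reindex(has_uncl.index)).any()
        else 0.0,
    }

    xii = t[t["rd_type"].isin(GROUP_XII)]
    xii_single = _frac(xii["domains_in_protein"].astype(int) == 1)

    rim15_conf: dict[str, float] = {}
    asco = t[t["rd_type"] == "Rim15-Ascomycota"]
    if len(asco):
        rim15_conf["Ascomycota"] = float(
            (
                (asco["pos_D"] == "E")
                & (asco["pos_DD+1"] == "H")
                & (asco["pos_K-3"] == "L")
            ).mean()
        )
    non_asco = t[t["rd_type"] == "Rim15-nonAscomycota"]
    if len(non_asco):
        rim15_conf["nonAscomycota"] = float(
            ((non_asco["pos_D"] == "D") & (non_asco["pos_DD+1"] == "N")).mean()
        )

    return SummaryReport(
        n_domains=int(len(t)),
        n_species=int(t["species"].nunique()),
        inventory=inventory,
        atypical_fraction=atypical_fraction,
        skn7_cys_dd17_fraction=skn7_cys,
        skn7_lacking_st_d10_fraction=skn7_no_st,
        hhk_insertion_fraction=hhk_ins,
        ssk1_insert_mean=ssk1_mean,
        ssk1_insert_sd=ssk1_sd,
        srr1_k4_aromatic_his_fraction=srr1_k4,
        unclassified_rr_fraction=uncl_rr,
        species_without_unclassified_fraction=species_without,
        unclassified_presence_by_clade=clade,
        groupxii_single_domain_fraction=xii_single,
        rim15_signature_conformance=rim15_conf,
    )


def tm_percent_by_type(table: pd.DataFrame) -> dict[str, float]:
    """Per-type fraction of domains whose parent protein has ≥1 TM region.

    Records without a TM annotation are excluded from the denominator (with a
    warning); a type with no annotated record is omitted.
    """
    out: dict[str, float] = {}
    n_unannotated = int(table["has_tm"].isna().sum())
    if n_unannotated:
        logger.warning("%d records lack TM annotation; excluded", n_unannotated)
    annotated = table[table["has_tm"].notna()]
    if len(annotated) == 0:
        logger.warning("no records carry TM annotations; TM table is empty")
        return out
    for rd_type, group in annotated.groupby("rd_type", sort=True):
        out[str(rd_type)] = float(group["has_tm"].astype(bool).mean())
    return out
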