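"""Summary statistics over hand-built characteristics tables."""

import numpy as np
import pandas as pd
import pytest

from recprofiler.io import MISSING, type_category
from recprofiler.summary import compute_summary, tm_percent_by_type


def _table(rows):
    """Build a characteristics-like frame with sensible defaults."""
    defaults = {
        "species": "Asco_sp01",
        "phylum": "Ascomycota",
        "typical": True,
        "pos_DD+17": "A",
        "pos_D+10": "S",
        "pos_K-4": "A",
        "pos_K-3": "A",
        "pos_D": "D",
        "pos_DD+1": "D",
        "ins_a2b3_flag": False,
        "ins_a3b4_flag": False,
        "delta_a3b4": 0,
        "domains_in_protein": 1,
        "has_tm": None,
    }
    full = []
    for row in rows:
        r = dict(defaults)
        r.update(row)
        r["category"] = type_category(r["rd_type"])
        full.append(r)
    return pd.DataFrame(full)


class TestComputeSummary:
    def test_atypical_fraction_excludes_rim15(self):
        rows = (
            [{"rd_type": "Skn7", "typical": False}] * 2
            + [{"rd_type": "Skn7"}] * 6
            + [{"rd_type": "Rim15-Ascomycota", "typical": False}] * 2
        )
        rep = compute_summary(_table(rows))
        # 2 atypical among 8 non-Rim15
        assert rep.atypical_fraction == pytest.approx(0.25)
        rep_all = compute_summary(_table(rows), include_rim15_in_atypical=True)
        assert rep_all.atypical_fraction == pytest.approx(0.4)

    def test_inventory_sums_to_n(self):
        rows = [{"rd_type": "Skn7"}] * 3 + [{"rd_type": "group I"}] * 2
        rep = compute_summary(_table(rows))
        assert sum(rep.inventory.values()) == rep.n_domains == 5
        assert rep.inventory == {"Skn7": 3, "group I": 2}

    def test_skn7_statistics(self):
        rows = (
            [{"rd_type": "Skn7", "pos_DD+17": "C"}] * 3
            + [{"rd_type": "Skn7", "pos_DD+17": "S", "pos_D+10": "A"}]
            + [{"rd_type": "Skn7", "pos_DD+17": "C", "pos_D+10": MISSING}]
        )
        rep = compute_summary(_table(rows))
        assert rep.skn7_cys_dd17_fraction == pytest.approx(0.8)
        # NA at D+10 counts as lacking Ser/Thr
        assert rep.skn7_lacking_st_d10_fraction == pytest.approx(0.4)

    def test_hhk_insertion_pools_both_loops(self):
        rows = [
            {"rd_type": "group I", "ins_a2b3_flag": True},
            {"rd_type": "group I", "ins_a3b4_flag": True},
            {"rd_type": "group I", "ins_a2b3_flag": True, "ins_a3b4_flag": True},
            {"rd_type": "group I"},
            {"rd_type": "Skn7", "ins_a3b4_flag": True},  # RR: not counted
        ]
        rep = compute_summary(_table(rows))
        assert rep.hhk_insertion_fraction == pytest.approx(0.75)

    def test_ssk1_insert_mean_sd(self):
        rows = [{"rd_type": "Ssk1", "delta_a3b4": d} for d in (30, 40, 50)]
        rep = compute_summary(_table(rows))
        assert rep.ssk1_insert_mean == pytest.approx(40.0)
        assert rep.ssk1_insert_sd == pytest.approx(10.0)

    def test_srr1_k4_aromatic_his(self):
        rows = [{"rd_type": "Srr1", "pos_K-4": r} for r in "YFHLL"]
        rep = compute_summary(_table(rows))
        assert rep.srr1_k4_aromatic_his_fraction == pytest.approx(0.6)

    def test_unclassified_rr_fraction_uses_rr_denominator(self):
        rows = (
            [{"rd_type": "Skn7"}] * 3
            + [{"rd_type": "Unclassified"}] * 1
            + [{"rd_type": "group I"}] * 6  # HHKs excluded from this denominator
        )
        rep = compute_summary(_table(rows))
        assert rep.unclassified_rr_fraction == pytest.approx(0.25)

    def test_clade_presence_and_species_without(self):
        rows = [
            {"rd_type": "Unclassified", "species": "a1", "phylum": "Ascomycota"},
            {"rd_type": "Skn7", "species": "a2", "phylum": "Ascomycota"},
            {"rd_type": "Unclassified", "species": "c1", "phylum": "Chytridiomycota"},
            {"rd_type": "Skn7", "species": "c2", "phylum": "Chytridiomycota"},
        ]
        rep = compute_summary(_table(rows))
        assert rep.unclassified_presence_by_clade == {
            "asco_basidio": pytest.approx(0.5),
            "other_phyla": pytest.approx(0.5),
        }
        assert rep.species_without_unclassified_fraction == pytest.approx(0.5)

    def test_groupxii_single_domain(self):
        rows = [
            {"rd_type": "group XII-Rec1", "domains_in_protein": 1},
            {"rd_type": "group XII-Rec1", "domains_in_protein": 2},
            {"rd_type": "group XII-Rec2", "domains_in_protein": 2},
            {"rd_type": "group XII-Rec2", "domains_in_protein": 2},
        ]
        rep = compute_summary(_table(rows))
        assert rep.groupxii_single_domain_fraction == pytest.approx(0.25)

    def test_rim15_signature_conformance(self):
        rows = [
            {"rd_type": "Rim15-Ascomycota", "pos_D": "E", "pos_DD+1": "H", "pos_K-3": "L"},
            {"rd_type": "Rim15-Ascomycota", "pos_D": "E", "pos_DD+1": "H", "pos_K-3": "V"},
            {"rd_type": "Rim15-nonAscomycota", "pos_D": "D", "pos_DD+1": "N"},
        ]
        rep = compute_summary(_table(rows))
        assert rep.rim15_signature_conformance["Ascomycota"] == pytest.approx(0.5)
        assert rep.rim15_signature_conformance["nonAscomycota"] == pytest.approx(1.0)

    def test_order_invariance(self):
        rows = (
            [{"rd_type": "Skn7", "typical": False}]
            + [{"rd_type": "Ssk1", "delta_a3b4": 38}] * 3
            + [{"rd_type": "group I", "ins_a3b4_flag": True}] * 2
            + [{"rd_type": "Unclassified"}] * 2
        )
        t = _table(rows)
        shuffled = t.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert compute_summary(t).to_json() == compute_summary(shuffled).to_json()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_summary(pd.DataFrame())


class TestTmPercent:
    def test_fraction_per_type(self):
        t = _table(
            [{"rd_type": "group VI", "has_tm": f} for f in (True, False, False, False)]
        )
        assert tm_percent_by_type(t) == {"group VI": pytest.approx(0.25)}

    def test_unannotated_records_excluded(self, caplog):
        t = _table(
            [
                {"rd_type": "group VI", "has_tm": True},
                {"rd_type": "group VI", "has_tm": None},
            ]
        )
        with caplog.at_level("WARNING"):
            out = tm_percent_by_type(t)
        assert out == {"group VI": pytest.approx(1.0)}
        assert "excluded" in caplog.text

    def test_no_annotations_gives_empty_map(self, caplog):
        t = _table([{"rd_type": "group VI"}])
        with caplog.at_level("WARNING"):
            assert tm_percent_by_type(t) == {}
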