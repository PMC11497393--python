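"""MS1/MS2 matching, confidence-level assignment, compound DB, DDA lists."""

import numpy as np
import pandas as pd
import pytest

from credmet import (Config, LibraryEntry, SpectrumRecord, annotate_table,
                     assign_level, build_compound_db, db_coverage_percent,
                     generate_dda_lists, match_ms1, match_ms2, merge_polarity,
                     mini_library, monoisotopic_mass)
from credmet.annotate import Candidate, mw_rt_label, simulate_dda_rounds, \
    spectrum_snr
from credmet.formulas import adduct_mz
from credmet import SimConfig, generate_experiment, mock_filter
from credmet.credential import retained_ids

from conftest import tiny_table

GLU_MASS = monoisotopic_mass("C5H9NO4")
GLU_NEG = adduct_mz(GLU_MASS, "[M-H]-")


def glutamate_entry(rt=7.2):
    return LibraryEntry("glutamate", "C5H9NO4", GLU_MASS, ("[M-H]-", "[M+H]+"),
                        rt=rt, source="house_ms1")


class TestMatchMs1:
    def test_adduct_arithmetic_hit(self, cfg):
        """Observed 146.0459 in negative mode matches glutamate
        ([M-H]- of 147.0532) with ~0 ppm error."""
        cands = match_ms1(146.0459, 7.2 + 10 / 60, "negative",
                          [glutamate_entry()], cfg)
        assert len(cands) == 1
        assert cands[0].adduct == "[M-H]-"
        assert abs(cands[0].ppm_error) < 1.0
        assert abs(cands[0].rt_delta - 10.0) < 1e-9

    def test_rt_gate_blocks_isomer_confusion(self, cfg):
        """Same mass but ΔRT of 70 s exceeds the 40 s tolerance."""
        cands = match_ms1(GLU_NEG, 7.2 + 70 / 60, "negative",
                          [glutamate_entry()], cfg)
        assert cands == []

    def test_ppm_gate(self, cfg):
        off = GLU_NEG * (1 + 10e-6)
        assert match_ms1(off, 7.2, "negative", [glutamate_entry()], cfg) == []

    def test_entry_without_rt_matches_on_mass_alone(self, cfg):
        entry = LibraryEntry("glutamate", "C5H9NO4", GLU_MASS, ("[M-H]-",),
                             rt=None, source="external")
        cands = match_ms1(GLU_NEG, 99.0, "negative", [entry], cfg)
        assert len(cands) == 1 and cands[0].rt_delta is None

    def test_sorting_prefers_rt_match_then_ppm(self, cfg):
        no_rt = LibraryEntry("a", None, GLU_MASS, ("[M-H]-",), rt=None,
                             source="external")
        with_rt = LibraryEntry("b", None, GLU_MASS + 2e-4, ("[M-H]-",), rt=7.2,
                               source="house_ms1")
        cands = match_ms1(GLU_NEG, 7.2, "negative", [no_rt, with_rt], cfg)
        assert [c.entry.name for c in cands] == ["b", "a"]


class TestMatchMs2:
    def spec(self, peaks, name="q"):
        return SpectrumRecord(name, 150.0, "negative", "40", peaks)

    def test_self_similarity_is_one(self):
        s = self.spec([(50.0, 30.0), (80.0, 100.0), (120.0, 10.0)])
        assert match_ms2(s, s) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_is_zero(self):
        a = self.spec([(50.0, 100.0)])
        b = self.spec([(90.0, 100.0)])
        assert match_ms2(a, b) == 0.0

    def test_hand_enumerated_value(self):
        """{100:100, 120:50} vs {100:100, 150:50}: only the peak at 100
        matches; score = sqrt(100)*sqrt(100) / (sqrt(150)*sqrt(150)) = 2/3."""
        a = self.spec([(100.0, 100.0), (120.0, 50.0)])
        b = self.spec([(100.0, 100.0), (150.0, 50.0)])
        assert match_ms2(a, b) == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = self.spec(sorted((float(m), float(i)) for m, i in zip(
                rng.uniform(50, 500, 8), rng.uniform(1, 100, 8))))
            b = self.spec(sorted((float(m), float(i)) for m, i in zip(
                rng.uniform(50, 500, 8), rng.uniform(1, 100, 8))))
            s_ab, s_ba = match_ms2(a, b), match_ms2(b, a)
            assert s_ab == pytest.approx(s_ba, abs=1e-12)
            assert 0.0 <= s_ab <= 1.0 + 1e-12


class TestAssignLevel:
    def house_candidate(self, rt_delta=10.0):
        return Candidate(glutamate_entry(), "[M-H]-", 0.1, rt_delta)

    def external_candidate(self):
        entry = LibraryEntry("glutamate", "C5H9NO4", GLU_MASS, ("[M-H]-",),
                             rt=None, source="external")
        return Candidate(entry, "[M-H]-", 0.1, None)

    def test_house_rt_ms2_is_level1(self, cfg):
        rec = assign_level("f", GLU_NEG, 7.2, "negative", "C5H9NO4",
                           [self.house_candidate()], cfg, house_ms2_score=0.9)
        assert rec.level == 1
        assert "house_ms1_rt" in rec.evidence and "house_ms2" in rec.evidence
        assert rec.display_name == "glutamate"

    def test_house_rt_mass_only_is_level1(self, cfg):
        rec = assign_level("f", GLU_NEG, 7.2, "negative", "C5H9NO4",
                           [self.house_candidate()], cfg)
        assert rec.level == 1 and rec.evidence == ("house_ms1_rt",)

    def test_external_ms2_only_is_level2(self, cfg):
        rec = assign_level("f", GLU_NEG, 7.2, "negative", "C5H9NO4",
                           [self.external_candidate()], cfg,
                           external_ms2_score=0.85)
        assert rec.level == 2 and rec.evidence == ("external_ms2",)

    def test_external_name_without_ms2_is_level3(self, cfg):
        rec = assign_level("f", GLU_NEG, 7.2, "negative", "C5H9NO4",
                           [self.external_candidate()], cfg)
        assert rec.level == 3 and rec.display_name == "glutamate"

    def test_formula_only_is_level4_with_mw_rt_label(self, cfg):
        rec = assign_level("f", 241.0312, 6.1, "negative", "C9H11N2O4P",
                           [], cfg)
        assert rec.level == 4
        assert rec.display_name == "MW241.0312_RT6.10"

    def test_no_formula_excluded(self, cfg):
        assert assign_level("f", 241.0312, 6.1, "negative", None, [], cfg) is None

    def test_level_monotone_in_evidence(self, cfg):
        """Adding evidence never increases the level number."""
        base = assign_level("f", GLU_NEG, 7.2, "negative", "C5H9NO4", [], cfg)
        ext = assign_level("f", GLU_NEG, 7.2, "negative", "C5H9NO4",
                           [self.external_candidate()], cfg)
        ext_ms2 = assign_level("f", GLU_NEG, 7.2, "negative", "C5H9NO4",
                               [self.external_candidate()], cfg,
                               external_ms2_score=0.9)
        house = assign_level("f", GLU_NEG, 7.2, "negative", "C5H9NO4",
                             [self.house_candidate(), self.external_candidate()],
                             cfg, external_ms2_score=0.9)
        assert base.level >= ext.level >= ext_ms2.level >= house.level

    def test_sub_threshold_ms2_is_not_evidence(self, cfg):
        rec = assign_level("f", GLU_NEG, 7.2, "negative", "C5H9NO4",
                           [self.external_candidate()], cfg,
                           external_ms2_score=0.5)
        assert rec.level == 3


class TestCompoundDb:
    def annotated_table(self, cfg):
        table, truth = generate_experiment(SimConfig(n_true=50, n_contaminant=20,
                                                     rng_seed=31))
        kept = retained_ids(mock_filter(table, cfg))
        cred = table.subset_features(kept)
        anns = annotate_table(cred, mini_library(), cfg)
        return cred, anns

    def test_duplicate_name_demoted_to_mw_rt(self, cfg):
        table = tiny_table({"f1": [1e6], "f2": [1e6]}, ["biological"],
                           mz=[GLU_NEG, GLU_NEG], rt=[7.0, 9.5])
        table.features.loc["f1", "formula"] = "C5H9NO4"
        table.features.loc["f2", "formula"] = "C5H9NO4"
        lib = [glutamate_entry(rt=7.1)]
        cfg_wide = Config(rt_tol=40 * 60)  # admit both so the name collides
        anns = annotate_table(table, lib, cfg_wide)
        db = build_compound_db(table, anns, None, cfg_wide)
        names = {r.feature_id: r.display_name for _, r in
                 db.provenance.reset_index().iterrows()}
        assert names["f1"] == "glutamate"
        assert names["f2"] == mw_rt_label(GLU_NEG, 9.5)

    def test_single_peak_spectrum_retained(self, cfg):
        assert spectrum_snr(SpectrumRecord("x", 100.0, "negative", "40",
                                           [(50.0, 100.0)])) == np.inf

    def test_low_snr_spectrum_dropped(self, cfg):
        table = tiny_table({"f1": [1e6]}, ["biological"], mz=[GLU_NEG], rt=[7.2])
        table.features.loc["f1", "formula"] = "C5H9NO4"
        anns = annotate_table(table, [glutamate_entry()], cfg)
        flat = SpectrumRecord("glutamate", GLU_NEG, "negative", "40",
                              [(50.0, 10.0), (60.0, 10.0), (70.0, 10.0)])
        db = build_compound_db(table, anns, {"f1": flat}, cfg)
        assert db.ms2_entries == []
        sharp = SpectrumRecord("glutamate", GLU_NEG, "negative", "40",
                               [(50.0, 100.0), (60.0, 10.0), (70.0, 5.0)])
        db = build_compound_db(table, anns, {"f1": sharp}, cfg)
        assert len(db.ms2_entries) == 1

    def test_entry_count_bookkeeping(self, cfg):
        """DB MS1 entry count equals the retained-and-annotated count
        after de-duplication, by direct recount."""
        cred, anns = self.annotated_table(cfg)
        db = build_compound_db(cred, anns, None, cfg)
        unique_names = {(a.display_name, a.polarity) for a in anns}
        assert len(db.ms1_entries) == len(unique_names)
        assert len(db.provenance) == len(db.ms1_entries)

    def test_idempotent_rebuild(self, cfg):
        cred, anns = self.annotated_table(cfg)
        db1 = build_compound_db(cred, anns, None, cfg)
        db2 = build_compound_db(cred, anns, None, cfg)
        assert [e.name for e in db1.ms1_entries] == [e.name for e in db2.ms1_entries]
        assert db1.provenance.equals(db2.provenance)


class TestDbCoverage:
    @pytest.mark.parametrize("detected,total,expected", [
        (270, 421, 64), (198, 262, 76), (1, 2, 50)])
    def test_percent(self, detected, total, expected):
        assert db_coverage_percent(detected, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            db_coverage_percent(1, 0)


class TestDdaLists:
    def features_frame(self):
        return pd.DataFrame({
            "mz": [100.0, 200.0, 300.0],
            "rt": [2.0, 5.0, 8.0],
            "polarity": "negative",
        }, index=pd.Index(["f1", "f2", "f3"], name="feature_id"))

    def test_all_fragmented_empty_inclusion(self, cfg):
        feats = self.features_frame()
        inc, exc = generate_dda_lists(feats, feats.iloc[0:0],
                                      {"f1", "f2", "f3"}, cfg)
        assert inc.empty

    def test_window_is_rt_tolerance(self, cfg):
        feats = self.features_frame()
        inc, _ = generate_dda_lists(feats, feats.iloc[0:0], set(), cfg)
        assert inc.loc["f2", "rt_start"] == pytest.approx(5.0 - 40 / 60)
        assert inc.loc["f2", "rt_end"] == pytest.approx(5.0 + 40 / 60)

    def test_lists_disjoint(self, cfg):
        feats = self.features_frame()
        mock = self.features_frame().rename(index={"f1": "m1", "f2": "m2",
                                                   "f3": "m3"})
        inc, exc = generate_dda_lists(feats, mock, {"f1", "m1"}, cfg)
        assert set(inc.index).isdisjoint(set(exc.index))
        assert list(exc.index) == ["m1"]

    def test_iterative_rounds_shrink_to_empty(self, cfg):
        """Repeated acquisition rounds strictly shrink the inclusion
        list until it is empty."""
        rng = np.random.default_rng(2)
        n = 150
        feats = pd.DataFrame({
            "mz": rng.uniform(80, 800, n),
            "rt": rng.uniform(1, 12, n),
            "polarity": "negative",
        }, index=pd.Index([f"f{i}" for i in range(n)], name="feature_id"))
        intens = pd.Series(rng.lognormal(10, 1, n), index=feats.index)
        sizes = simulate_dda_rounds(feats, intens, cfg, scans_per_round=40,
                                    rounds=10)
        assert all(b < a for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 0 or len(sizes) == 10


class TestMergePolarity:
    def table_with_names(self, names, polarity, sample_ids=("s0",)):
        rows = {f"f{i}_{polarity[:3]}": [1000.0] * len(sample_ids)
                for i in range(len(names))}
        t = tiny_table(rows, ["biological"] * len(sample_ids),
                       polarity=polarity)
        t.features["display_name"] = list(names)
        return t

    def test_no_name_merging_and_suffix(self):
        neg = self.table_with_names(["kynurenine"], "negative")
        pos = self.table_with_names(["kynurenine"], "positive")
        merged = merge_polarity(neg, pos)
        names = set(merged.features["display_name"])
        assert names == {"kynurenine_[M-H]", "kynurenine"}
        assert merged.n_features == 2

    def test_empty_negative_equals_positive(self):
        pos = self.table_with_names(["a", "b"], "positive")
        neg = pos.subset_features([])
        neg.features["polarity"] = "negative"
        merged = merge_polarity(neg, pos)
        assert merged.n_features == pos.n_features
        assert list(merged.features["display_name"]) == ["a", "b"]

    def test_row_counts_add(self):
        neg = self.table_with_names(["a", "b", "c"], "negative")
        pos = self.table_with_names(["d", "e"], "positive")
        assert merge_polarity(neg, pos).n_features == 5

    def test_sample_mismatch_errors(self):
        neg = self.table_with_names(["a"], "negative", ("s0",))
        pos = self.table_with_names(["b"], "positive", ("s0", "s1"))
        with pytest.raises(ValueError, match="samples"):
            merge_polarity(neg, pos)


def test_annotation_levels_on_synthetic_truth(cfg):
    """Every true metabolite whose formula and RT sit in the house
    library annotates at Level 1; contaminants never reach Level 1-2."""
    table, truth = generate_experiment(SimConfig(n_true=60, n_contaminant=40,
                                                 rng_seed=33))
    anns = {a.feature_id: a for a in annotate_table(table, mini_library(), cfg)}
    for fid in truth.ids("true_metabolite"):
        assert anns[fid].level == 1, fid
    for fid in truth.ids("contaminant"):
        assert fid not in anns or anns[fid].level >= 3
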