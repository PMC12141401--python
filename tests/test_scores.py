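"""Deficit-accumulation indices and clinical risk scores."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from frailtyfalls.cohort import CohortTable, LabResult
from frailtyfalls.errors import DataError
from frailtyfalls.scores import (
    CCIMap,
    band_fi_lab,
    binarize_fi_lab,
    cci_score,
    compute_scores,
    fi_clinical_score,
    fi_lab_score,
    flag_abnormal,
    polypharmacy_score,
    stratify_plus_filab,
    stratify_score,
)
from frailtyfalls.simulate import SimConfig, generate_cohort
from .conftest import make_record


class TestFlagAbnormal:
    @pytest.mark.parametrize(
        "value,expected",
        [(140.0, 0), (130.0, 1), (150.0, 1), (135.0, 0), (145.0, 0)],
    )
    def test_sodium_interval_inclusive(self, panel, value, expected):
        # sodium reference interval [135, 145]; boundary values are normal
        assert flag_abnormal(LabResult("sodium", value), panel, "male") == expected

    def test_sex_specific_limits(self, panel):
        # hemoglobin: male [13.5, 17.5], female [12.0, 15.5]
        assert flag_abnormal(LabResult("hemoglobin", 13.0), panel, "male") == 1
        assert flag_abnormal(LabResult("hemoglobin", 13.0), panel, "female") == 0

    def test_upper_only_analyte(self, panel):
        assert flag_abnormal(LabResult("crp", 0.2), panel, "female") == 0
        assert flag_abnormal(LabResult("crp", 5.0), panel, "female") == 1

    def test_nonfinite_value_is_a_data_error(self, panel):
        with pytest.raises(DataError):
            flag_abnormal(LabResult("sodium", float("nan")), panel, "male")


class TestFiLab:
    def test_full_panel_seven_abnormal(self, panel, item_ids):
        rec = make_record(panel, item_ids, n_labs=35, n_abnormal=7)
        score, ratio = fi_lab_score(rec, panel)
        assert score == pytest.approx(0.2, abs=1e-12)
        assert ratio == 1.0

    def test_24_of_35_is_ineligible(self, panel, item_ids):
        rec = make_record(panel, item_ids, n_labs=24)
        score, ratio = fi_lab_score(rec, panel)
        assert np.isnan(score)
        assert ratio == pytest.approx(24 / 35)

    def test_25_of_35_is_eligible(self, panel, item_ids):
        rec = make_record(panel, item_ids, n_labs=25, n_abnormal=10)
        score, ratio = fi_lab_score(rec, panel)
        assert score == pytest.approx(0.4, abs=1e-12)
        assert ratio == pytest.approx(25 / 35)


class TestBandsAndBinary:
    @pytest.mark.parametrize(
        "score,band",
        [(0.24, "low"), (0.25, "mid"), (0.31, "mid"), (0.40, "mid"), (0.401, "high")],
    )
    def test_band_boundaries(self, score, band):
        assert band_fi_lab(score) == band

    def test_band_rejects_out_of_range(self):
        with pytest.raises(DataError):
            band_fi_lab(1.2)

    @pytest.mark.parametrize("score,expected", [(0.4, 0), (0.41, 1), (0.0, 0)])
    def test_binarize_default_cutoff(self, score, expected):
        assert binarize_fi_lab(score) == expected

    def test_binarize_sensitivity_cutoff(self):
        assert binarize_fi_lab(0.35, cutoff=0.345) == 1

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_band_high_iff_binary_one(self, score):
        assert (band_fi_lab(score) == "high") == (binarize_fi_lab(score, 0.4) == 1)


class TestFiClinical:
    def test_all_zero_items(self, panel, item_ids):
        rec = make_record(panel, item_ids)
        assert fi_clinical_score(rec) == 0.0

    def test_mixed_values(self, panel, item_ids):
        deficits = {i: 0.0 for i in item_ids}
        for i in item_ids[:4]:
            deficits[i] = 1.0
        for i in item_ids[4:8]:
            deficits[i] = 0.5
        rec = make_record(panel, item_ids, deficits=deficits)
        assert fi_clinical_score(rec) == pytest.approx(0.15, abs=1e-12)

    def test_31_of_40_items_ineligible(self, panel, item_ids):
        rec = make_record(panel, item_ids, deficits={i: 0.0 for i in item_ids[:31]})
        assert np.isnan(fi_clinical_score(rec))

    def test_32_of_40_items_eligible(self, panel, item_ids):
        deficits = {i: 1.0 for i in item_ids[:8]}
        deficits.update({i: 0.0 for i in item_ids[8:32]})
        rec = make_record(panel, item_ids, deficits=deficits)
        assert fi_clinical_score(rec) == pytest.approx(0.25, abs=1e-12)


class TestStratifyAndMeds:
    def test_stratify_extremes_and_single_item(self, panel, item_ids):
        assert stratify_score(make_record(panel, item_ids)) == 0
        all_items = (
            "history_of_falls", "mental_status", "vision", "toileting", "mobility",
        )
        assert stratify_score(make_record(panel, item_ids, stratify_true=all_items)) == 5
        assert (
            stratify_score(
                make_record(panel, item_ids, stratify_true=("history_of_falls",))
            )
            == 1
        )

    def test_stratify_missing_item_is_a_data_error(self, panel, item_ids):
        rec = make_record(panel, item_ids)
        rec.stratify_items = {"vision": True}
        with pytest.raises(DataError):
            stratify_score(rec)

    def test_stratify_plus_filab(self, panel, item_ids):
        all_items = (
            "history_of_falls", "mental_status", "vision", "toileting", "mobility",
        )
        # FI-lab 18/35 > 0.4 adds the sixth item
        rec = make_record(panel, item_ids, stratify_true=all_items, n_abnormal=18)
        assert stratify_plus_filab(rec, panel) == 6
        # FI-lab exactly 0.4 (14/35) does not
        rec = make_record(panel, item_ids, n_abnormal=14)
        assert stratify_plus_filab(rec, panel) == 0
        rec = make_record(
            panel, item_ids, stratify_true=("vision", "mobility"), n_abnormal=16
        )
        assert stratify_plus_filab(rec, panel) == 3  # 16/35 ~ 0.457 > 0.4
        # ineligible FI-lab propagates
        rec = make_record(panel, item_ids, n_labs=20)
        assert np.isnan(stratify_plus_filab(rec, panel))

    def test_polypharmacy_counts_categories(self, panel, item_ids):
        assert polypharmacy_score(make_record(panel, item_ids)) == 0
        all_meds = (
            "antihypertensive", "antidiabetic", "antithrombotic",
            "sleep", "antipsychotic", "nsaid",
        )
        assert polypharmacy_score(make_record(panel, item_ids, meds=all_meds)) == 6
        assert (
            polypharmacy_score(
                make_record(panel, item_ids, meds=("antihypertensive", "nsaid"))
            )
            == 2
        )


class TestCci:
    def test_empty_codes(self):
        assert cci_score(set()) == 0

    def test_single_weight_one_condition(self):
        assert cci_score({"I21.0"}) == 1  # myocardial infarction

    def test_unrecognised_codes_ignored(self):
        assert cci_score({"Z00.0", "A09"}) == 0

    def test_hierarchy_metastatic_supersedes_malignancy(self):
        cmap = CCIMap.default()
        w_meta = {c.condition: c.weight for c in cmap.conditions}[
            "metastatic_solid_tumor"
        ]
        assert cci_score({"C18.9"}) == 2
        assert cci_score({"C78.0"}) == w_meta == 6
        assert cci_score({"C18.9", "C78.0"}) == 6  # counted once, higher weight

    def test_hierarchy_severe_liver_and_complicated_diabetes(self):
        assert cci_score({"K70.0", "K72.1"}) == 3
        assert cci_score({"E11.9", "E11.2"}) == 2

    def test_additive_across_conditions(self):
        assert cci_score({"I21.0", "N18.9"}) == 1 + 2


class TestCohortScores:
    def test_vectorised_matches_per_record(self, panel, item_ids):
        records = [
            make_record(panel, item_ids, f"R{i}", sex="male" if i % 2 else "female",
                        n_labs=35 - (i % 13), n_abnormal=i % 11,
                        meds=("sleep",) if i % 3 else (),
                        icd10=("C18.9",) if i % 4 == 0 else ())
            for i in range(40)
        ]
        table = CohortTable.from_records(records, panel, item_ids)
        scored = compute_scores(table)
        for i in range(40):
            rec = table.record(i)
            fi, ratio = fi_lab_score(rec, panel)
            assert scored["measured_ratio"].iloc[i] == pytest.approx(ratio)
            if np.isnan(fi):
                assert np.isnan(scored["fi_lab"].iloc[i])
            else:
                assert scored["fi_lab"].iloc[i] == pytest.approx(fi, abs=1e-12)
            assert scored["stratify"].iloc[i] == stratify_score(rec)
            assert scored["polypharmacy"].iloc[i] == polypharmacy_score(rec)
            assert scored["cci"].iloc[i] == cci_score(rec.icd10_codes)
            fic = fi_clinical_score(rec)
            assert scored["fi_clinical"].iloc[i] == pytest.approx(fic, abs=1e-12)

    def test_mean_fi_lab_converges_to_abnormal_prob(self):
        """With per-analyte abnormal probability p and no missingness the
        cohort mean FI-lab approaches p (law of large numbers)."""
        p = 0.2
        config = SimConfig(n=50_000, seed=77, abnormal_prob=p, missing_prob=0.0)
        table = generate_cohort(config)
        scored = compute_scores(table)
        se = np.sqrt(p * (1 - p) / 35 / config.n)
        assert scored["fi_lab"].mean() == pytest.approx(p, abs=4 * se)

    def test_band_and_binary_agree_on_cohort(self, small_cohort):
        scored = compute_scores(small_cohort)
        ok = scored["fi_lab"].notna()
        assert (
            (scored.loc[ok, "fi_lab_band"] == "high")
            == (scored.loc[ok, "fi_lab_binary"] == 1)
        ).all()
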