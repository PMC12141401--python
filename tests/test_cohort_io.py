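"""Cohort schema validation, round-trip IO, and exclusion-flow accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from pandas.testing import assert_frame_equal

from frailtyfalls.cohort import (
    AdmissionRecord,
    CohortTable,
    ExclusionFlow,
    apply_exclusions,
    read_cohort,
    write_cohort,
)
from frailtyfalls.errors import (
    InclusionViolationError,
    PanelMismatchError,
    SchemaError,
)
from .conftest import make_record


class TestRoundTrip:
    def test_three_row_bundle_round_trips(self, small_cohort, panel, item_ids, tmp_path):
        write_cohort(small_cohort, tmp_path)
        back = read_cohort(tmp_path, panel, item_ids)
        assert len(back) == 3
        assert_frame_equal(back.admissions, small_cohort.admissions)
        assert_frame_equal(back.labs, small_cohort.labs)
        assert_frame_equal(back.deficits, small_cohort.deficits)

    def test_lab_row_order_irrelevant(self, small_cohort, panel, item_ids, tmp_path):
        """Shuffling the long-format lab rows leaves the table unchanged."""
        write_cohort(small_cohort, tmp_path)
        labs = pd.read_csv(tmp_path / "labs.csv")
        shuffled = labs.sample(frac=1.0, random_state=5)
        shuffled.to_csv(tmp_path / "labs.csv", index=False)
        back = read_cohort(tmp_path, panel, item_ids)
        assert_frame_equal(back.labs, small_cohort.labs)

    def test_first_lab_result_wins(self, small_cohort, panel, item_ids, tmp_path):
        """Duplicate results keep the lowest sequence; file order breaks ties."""
        write_cohort(small_cohort, tmp_path)
        labs = pd.read_csv(tmp_path / "labs.csv")
        extra = pd.DataFrame(
            [
                {"admission_id": "A1", "analyte_id": "sodium", "value": 120.0, "sequence": 2},
                {"admission_id": "A2", "analyte_id": "sodium", "value": 99.0, "sequence": 0},
                {"admission_id": "A2", "analyte_id": "sodium", "value": 98.0, "sequence": 0},
            ]
        )
        pd.concat([labs, extra]).to_csv(tmp_path / "labs.csv", index=False)
        back = read_cohort(tmp_path, panel, item_ids)
        a1 = back.admissions["admission_id"] == "A1"
        a2 = back.admissions["admission_id"] == "A2"
        assert back.labs.loc[a1, "sodium"].iloc[0] == small_cohort.labs.loc[
            small_cohort.admissions["admission_id"] == "A1", "sodium"
        ].iloc[0]
        assert back.labs.loc[a2, "sodium"].iloc[0] == 99.0


class TestValidation:
    def test_deficit_outside_domain_rejected(self, panel, item_ids):
        rec = make_record(panel, item_ids, deficits={item_ids[0]: 0.7})
        with pytest.raises(SchemaError, match=r"0, 0\.5, 1"):
            CohortTable.from_records([rec], panel, item_ids)

    def test_unknown_analyte_rejected(self, panel, item_ids):
        from frailtyfalls.cohort import LabResult

        rec = make_record(panel, item_ids)
        rec.labs = rec.labs + (LabResult("not_an_analyte", 1.0),)
        with pytest.raises(PanelMismatchError):
            CohortTable.from_records([rec], panel, item_ids)

    def test_underage_rejected_or_dropped_when_lenient(
        self, panel, item_ids, small_cohort, tmp_path
    ):
        write_cohort(small_cohort, tmp_path)
        adm = pd.read_csv(tmp_path / "admissions.csv")
        adm.loc[0, "age"] = 59
        adm.to_csv(tmp_path / "admissions.csv", index=False)
        with pytest.raises(InclusionViolationError):
            read_cohort(tmp_path, panel, item_ids)
        lenient = read_cohort(tmp_path, panel, item_ids, lenient=True)
        assert len(lenient) == 2
        assert lenient.provenance["dropped_underage"] == 1

    def test_duplicate_admission_id_rejected(self, panel, item_ids):
        recs = [make_record(panel, item_ids, "X"), make_record(panel, item_ids, "X")]
        with pytest.raises(SchemaError, match="duplicate admission_id"):
            CohortTable.from_records(recs, panel, item_ids)


class TestExclusions:
    def test_readmission_boundary_at_30_days(self, panel, item_ids):
        recs = [
            make_record(panel, item_ids, "G30", gap=30),
            make_record(panel, item_ids, "G31", gap=31),
            make_record(panel, item_ids, "IDX", gap=None),
        ]
        table = CohortTable.from_records(recs, panel, item_ids)
        included, flow = apply_exclusions(table)
        kept = set(included.admissions["admission_id"])
        assert kept == {"G31", "IDX"}
        assert flow.readmission_only == 1

    def test_insufficient_labs_excluded(self, small_cohort):
        # A3 has 24/35 measured (< 70%)
        included, flow = apply_exclusions(small_cohort)
        assert "A3" not in set(included.admissions["admission_id"])
        assert flow.insufficient_labs_only == 1
        assert flow.included == 2

    def test_no_exclusions_keeps_everything(self, panel, item_ids):
        table = CohortTable.from_records(
            [make_record(panel, item_ids, f"N{i}") for i in range(4)], panel, item_ids
        )
        included, flow = apply_exclusions(table)
        assert flow.included == len(table) == len(included)

    def test_empty_input_gives_zero_tallies(self, small_cohort):
        empty = small_cohort.subset(np.zeros(3, dtype=bool))
        _, flow = apply_exclusions(empty)
        assert flow == ExclusionFlow(0, 0, 0, 0, 0)

    @given(
        flags=st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=0, max_size=12
        )
    )
    def test_flow_counts_always_sum_to_raw(self, panel, item_ids, flags):
        recs = [
            make_record(
                panel,
                item_ids,
                f"H{i}",
                gap=10 if readmit else None,
                n_labs=20 if short else 35,
            )
            for i, (readmit, short) in enumerate(flags)
        ]
        table = CohortTable.from_records(recs, panel, item_ids)
        _, flow = apply_exclusions(table)
        assert (
            flow.readmission_only
            + flow.insufficient_labs_only
            + flow.both
            + flow.included
            == flow.raw
            == len(flags)
        )
        n_readmit, n_short = sum(f[0] for f in flags), sum(f[1] for f in flags)
        assert flow.both == sum(a and b for a, b in flags)
        assert flow.readmission_only == n_readmit - flow.both
        assert flow.insufficient_labs_only == n_short - flow.both
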