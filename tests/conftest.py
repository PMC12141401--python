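import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from frailtyfalls.cohort import (
    STRATIFY_ITEMS,
    AdmissionRecord,
    CohortTable,
    LabResult,
    ReferencePanel,
    default_item_ids,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return ReferencePanel.default()


@pytest.fixture(scope="session")
def item_ids():
    return default_item_ids()


def make_record(
    panel,
    item_ids,
    admission_id="A1",
    age=75,
    sex="female",
    n_labs=35,
    n_abnormal=0,
    stratify_true=(),
    deficits=None,
    meds=(),
    icd10=(),
    fell=False,
    gap=None,
):
    """Admission with a controlled number of measured/abnormal analytes.

    Abnormal values are placed just above each analyte's upper limit (or
    below the lower limit for upper-open analytes); normal values at the
    interval midpoint.
    """
    labs = []
    for j, analyte in enumerate(panel.analytes[:n_labs]):
        lo, hi = analyte.limits(sex)
        if j < n_abnormal:
            value = hi + 1.0 if hi is not None else lo - 1.0
        else:
            if lo is None:
                value = hi / 2.0
            elif hi is None:
                value = lo + 1.0
            else:
                value = (lo + hi) / 2.0
        labs.append(LabResult(analyte_id=analyte.analyte_id, value=value))
    deficits = deficits if deficits is not None else {i: 0.0 for i in item_ids}
    return AdmissionRecord(
        admission_id=admission_id,
        age=age,
        sex=sex,
        emergency=False,
        labs=tuple(labs),
        stratify_items={k: k in stratify_true for k in STRATIFY_ITEMS},
        fi_clinical_items=deficits,
        med_categories={k: True for k in meds},
        icd10_codes=frozenset(icd10),
        fell=fell,
        readmission_gap_days=gap,
    )


@pytest.fixture()
def small_cohort(panel, item_ids):
    records = [
        make_record(panel, item_ids, "A1", age=72, sex="male", n_abnormal=7,
                    stratify_true=("history_of_falls",), fell=True,
                    meds=("antihypertensive", "nsaid"), icd10=("E11.9",)),
        make_record(panel, item_ids, "A2", age=80, sex="female", n_abnormal=20,
                    stratify_true=("mental_status", "mobility")),
        make_record(panel, item_ids, "A3", age=65, sex="male", n_labs=24),
    ]
    return CohortTable.from_records(records, panel, item_ids)
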