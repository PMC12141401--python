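"""Cohort domain types, schema validation, and delimited-text readers/writers.

The cohort is a table of hospital admissions of adults aged 60 or older:
demographics, the first admission-day laboratory result per analyte, binary
fall-risk assessment items (the five STRATIFY items), graded clinical
deficits (0/0.5/1) for the clinical frailty index, medication-category
flags, ICD-10 diagnosis codes, and the in-hospital fall outcome.

A :class:`CohortTable` keeps three aligned pandas DataFrames:

* ``admissions`` — one row per admission (demographics, STRATIFY items,
  medication flags, ICD-10 code tuples, outcome);
* ``labs`` — a wide admission x analyte matrix of first-test values, with
  ``NaN`` meaning the analyte was not measured (missing results are absent,
  never sentinel values);
* ``deficits`` — a wide admission x item matrix of clinical deficit values
  in {0, 0.5, 1}, ``NaN`` meaning the item was not assessed.

On disk the bundle is three UTF-8 CSV files (``admissions.csv``,
``labs.csv`` in long format, ``deficits.csv`` in long format); reading and
writing round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DataError,
    InclusionViolationError,
    PanelMismatchError,
    SchemaError,
)

STRATIFY_ITEMS = (
    "history_of_falls",
    "mental_status",
    "vision",
    "toileting",
    "mobility",
)

MED_CATEGORIES = (
    "antihypertensive",
    "antidiabetic",
    "antithrombotic",
    "sleep",
    "antipsychotic",
    "nsaid",
)

SEXES = ("male", "female")

#: Readmissions within this many days of the prior discharge are excluded.
READMISSION_WINDOW_DAYS = 30

#: Minimum fraction of panel analytes that must be measured for FI-lab.
FI_LAB_MIN_MEASURED = 0.7


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelAnalyte:
    """One analyte of the FI-lab reference panel.

    Limits are inclusive bounds of the normal interval; at least one of
    ``lower_limit``/``upper_limit`` must be present. ``sex_specific`` maps
    ``"male"``/``"female"`` to ``(lower, upper)`` overrides.
    """

    analyte_id: str
    units: str
    lower_limit: Optional[float] = None
    upper_limit: Optional[float] = None
    sex_specific: Optional[Mapping[str, tuple]] = None

    def limits(self, sex: str) -> tuple:
        """Return the (lower, upper) normal interval for ``sex``."""
        if self.sex_specific and sex in self.sex_specific:
            return self.sex_specific[sex]
        return (self.lower_limit, self.upper_limit)


@dataclass(frozen=True)
class ReferencePanel:
    """Ordered set of panel analytes with their normal intervals."""

    analytes: tuple
    name: str = "panel"

    def __post_init__(self):
        ids = [a.analyte_id for a in self.analytes]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate analyte_id in panel")
        for a in self.analytes:
            for sex in SEXES if a.sex_specific else ():
                lo, hi = a.limits(sex)
                _check_limits(a.analyte_id, lo, hi)
            if not a.sex_specific:
                _check_limits(a.analyte_id, a.lower_limit, a.upper_limit)

    @property
    def ids(self) -> tuple:
        return tuple(a.analyte_id for a in self.analytes)

    @property
    def size(self) -> int:
        return len(self.analytes)

    def __contains__(self, analyte_id: str) -> bool:
        return analyte_id in self.ids

    def analyte(self, analyte_id: str) -> PanelAnalyte:
        for a in self.analytes:
            if a.analyte_id == analyte_id:
                return a
        raise PanelMismatchError(
            f"analyte {analyte_id!r} not in panel {self.name!r}",
            field="analyte_id",
        )

    def limit_arrays(self, sex: str):
        """Vectorised (lower, upper) arrays in panel order; NaN = open bound."""
        lo = np.array(
            [np.nan if (v := a.limits(sex)[0]) is None else v for a in self.analytes]
        )
        hi = np.array(
            [np.nan if (v := a.limits(sex)[1]) is None else v for a in self.analytes]
        )
        return lo, hi

    @classmethod
    def from_yaml(cls, path) -> "ReferencePanel":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ReferencePanel":
        analytes = []
        for entry in raw["analytes"]:
            sex_specific = None
            if "sex_specific" in entry:
                sex_specific = {
                    sex: (lim.get("lower_limit"), lim.get("upper_limit"))
                    for sex, lim in entry["sex_specific"].items()
                }
            analytes.append(
                PanelAnalyte(
                    analyte_id=str(entry["analyte_id"]),
                    units=str(entry.get("units", "")),
                    lower_limit=entry.get("lower_limit"),
                    upper_limit=entry.get("upper_limit"),
                    sex_specific=sex_specific,
                )
            )
        return cls(analytes=tuple(analytes), name=str(raw.get("name", "panel")))

    @classmethod
    def default(cls) -> "ReferencePanel":
        """The bundled 35-analyte admission panel."""
        ref = importlib.resources.files("frailtyfalls.data") / "default_panel.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


def _check_limits(analyte_id, lo, hi):
    if lo is None and hi is None:
        raise SchemaError(
            f"analyte {analyte_id!r} has neither limit", field="limits"
        )
    if lo is not None and hi is not None and not lo < hi:
        raise SchemaError(
            f"analyte {analyte_id!r}: lower_limit must be < upper_limit",
            field="limits",
        )


def default_item_ids() -> tuple:
    """Item ids of the bundled 40-item clinical frailty-index schema."""
    ref = importlib.resources.files("frailtyfalls.data") / "fi_clinical_items.yaml"
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return tuple(str(item["item_id"]) for item in raw["items"])


def load_item_ids(path) -> tuple:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return tuple(str(item["item_id"]) for item in raw["items"])


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabResult:
    """A single measured laboratory result (missing results are absent)."""

    analyte_id: str
    value: float
    collected_on_admission: bool = True


@dataclass
class AdmissionRecord:
    """One hospitalization of a patient aged >= 60."""

    admission_id: str
    age: int
    sex: str
    emergency: bool
    labs: Sequence[LabResult] = field(default_factory=tuple)
    stratify_items: Mapping[str, bool] = field(default_factory=dict)
    fi_clinical_items: Mapping[str, float] = field(default_factory=dict)
    med_categories: Mapping[str, bool] = field(default_factory=dict)
    icd10_codes: frozenset = frozenset()
    fell: bool = False
    admit_date: Optional[str] = None
    readmission_gap_days: Optional[int] = None


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

_BOOL_COLS = ("emergency",) + STRATIFY_ITEMS + MED_CATEGORIES + ("fell",)
_FI_CLINICAL_DOMAIN = (0.0, 0.5, 1.0)


@dataclass
class CohortTable:
    """Validated, order-preserving collection of admissions.

    ``admissions``, ``labs`` and ``deficits`` share a RangeIndex; row ``i``
    of each frame describes the same admission.
    """

    admissions: pd.DataFrame
    labs: pd.DataFrame
    deficits: pd.DataFrame
    panel: ReferencePanel
    item_ids: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.item_ids = tuple(self.item_ids)
        self.validate()

    def __len__(self) -> int:
        return len(self.admissions)

    @property
    def n(self) -> int:
        return len(self.admissions)

    def validate(self) -> None:
        adm = self.admissions
        ids = adm["admission_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SchemaError(
                f"duplicate admission_id {dup!r}", field="admission_id"
            )
        bad_age = adm.index[adm["age"] < 60]
        if len(bad_age):
            raise InclusionViolationError(
                f"age below 60 (admission_id={adm.loc[bad_age[0], 'admission_id']!r})",
                row=int(bad_age[0]),
                field="age",
            )
        bad_sex = adm.index[~adm["sex"].isin(SEXES)]
        if len(bad_sex):
            raise SchemaError(
                f"sex must be one of {SEXES}",
                row=int(bad_sex[0]),
                field="sex",
            )
        for col in STRATIFY_ITEMS:
            if adm[col].isna().any():
                row = int(adm.index[adm[col].isna()][0])
                raise SchemaError(
                    "STRATIFY items may not be missing", row=row, field=col
                )
        unknown = [c for c in self.labs.columns if c not in self.panel.ids]
        if unknown:
            raise PanelMismatchError(
                f"analytes {unknown} not in panel {self.panel.name!r}",
                field="analyte_id",
            )
        lab_values = self.labs.to_numpy(dtype=float)
        if np.isinf(lab_values).any():
            i, j = np.argwhere(np.isinf(lab_values))[0]
            raise DataError(
                f"non-finite lab value for {self.labs.columns[j]!r} at row {i}"
            )
        dvals = self.deficits.to_numpy(dtype=float)
        ok = np.isnan(dvals) | np.isin(dvals, _FI_CLINICAL_DOMAIN)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise SchemaError(
                f"deficit value {dvals[i, j]!r} outside {{0, 0.5, 1}}",
                row=int(i),
                field=str(self.deficits.columns[j]),
            )
        if not (len(adm) == len(self.labs) == len(self.deficits)):
            raise SchemaError("admissions/labs/deficits row counts differ")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[AdmissionRecord],
        panel: ReferencePanel,
        item_ids: Optional[Sequence[str]] = None,
        provenance: Optional[dict] = None,
    ) -> "CohortTable":
        records = list(records)
        item_ids = tuple(item_ids) if item_ids is not None else default_item_ids()
        rows, lab_rows, def_rows = [], [], []
        for i, rec in enumerate(records):
            row = {
                "admission_id": rec.admission_id,
                "age": int(rec.age),
                "sex": rec.sex,
                "emergency": bool(rec.emergency),
                "fell": bool(rec.fell),
                "admit_date": rec.admit_date,
                "readmission_gap_days": rec.readmission_gap_days,
                "icd10_codes": tuple(sorted(rec.icd10_codes)),
            }
            missing = [k for k in STRATIFY_ITEMS if k not in rec.stratify_items]
            if missing:
                raise SchemaError(
                    "STRATIFY items may not be missing", row=i, field=missing[0]
                )
            for k in STRATIFY_ITEMS:
                row[k] = bool(rec.stratify_items[k])
            for k in MED_CATEGORIES:
                row[k] = bool(rec.med_categories.get(k, False))
            rows.append(row)

            lab_row = {}
            seen = set()
            for lab in rec.labs:
                if lab.analyte_id not in panel.ids:
                    raise PanelMismatchError(
                        f"analyte {lab.analyte_id!r} not in panel",
                        row=i,
                        field="analyte_id",
                    )
                if lab.analyte_id in seen:  # first result wins
                    continue
                seen.add(lab.analyte_id)
                lab_row[lab.analyte_id] = float(lab.value)
            lab_rows.append(lab_row)

            for k, v in rec.fi_clinical_items.items():
                if k not in item_ids:
                    raise SchemaError(
                        f"unknown deficit item {k!r}", row=i, field="item_id"
                    )
            def_rows.append({k: float(v) for k, v in rec.fi_clinical_items.items()})

        admissions = pd.DataFrame(rows, columns=_admission_columns())
        admissions["readmission_gap_days"] = admissions["readmission_gap_days"].astype(
            "Float64"
        )
        labs = pd.DataFrame(lab_rows, columns=list(panel.ids), dtype=float)
        deficits = pd.DataFrame(def_rows, columns=list(item_ids), dtype=float)
        return cls(
            admissions=admissions,
            labs=labs,
            deficits=deficits,
            panel=panel,
            item_ids=item_ids,
            provenance=provenance or {"source": "in-memory", "panel": panel.name},
        )

    def record(self, i: int) -> AdmissionRecord:
        """Materialise row ``i`` as an :class:`AdmissionRecord`."""
        row = self.admissions.iloc[i]
        labs = tuple(
            LabResult(analyte_id=a, value=float(v))
            for a, v in self.labs.iloc[i].items()
            if not pd.isna(v)
        )
        deficits = {
            k: float(v) for k, v in self.deficits.iloc[i].items() if not pd.isna(v)
        }
        gap = row["readmission_gap_days"]
        return AdmissionRecord(
            admission_id=row["admission_id"],
            age=int(row["age"]),
            sex=row["sex"],
            emergency=bool(row["emergency"]),
            labs=labs,
            stratify_items={k: bool(row[k]) for k in STRATIFY_ITEMS},
            fi_clinical_items=deficits,
            med_categories={k: bool(row[k]) for k in MED_CATEGORIES},
            icd10_codes=frozenset(row["icd10_codes"]),
            fell=bool(row["fell"]),
            admit_date=None if pd.isna(row["admit_date"]) else row["admit_date"],
            readmission_gap_days=None if pd.isna(gap) else int(gap),
        )

    def subset(self, mask) -> "CohortTable":
        """Row subset preserving order; ``mask`` is boolean or positional."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CohortTable(
            admissions=self.admissions.iloc[idx].reset_index(drop=True),
            labs=self.labs.iloc[idx].reset_index(drop=True),
            deficits=self.deficits.iloc[idx].reset_index(drop=True),
            panel=self.panel,
            item_ids=self.item_ids,
            provenance=dict(self.provenance),
        )


def _admission_columns():
    return (
        ["admission_id", "age", "sex", "emergency"]
        + list(STRATIFY_ITEMS)
        + list(MED_CATEGORIES)
        + ["icd10_codes", "fell", "admit_date", "readmission_gap_days"]
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort bundle (admissions/labs/deficits CSVs) to directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    adm = table.admissions.copy()
    for col in _BOOL_COLS:
        adm[col] = adm[col].astype(int)
    adm["icd10_codes"] = adm["icd10_codes"].map(lambda t: ";".join(t))
    adm.to_csv(path / "admissions.csv", index=False)

    labs_long = (
        table.labs.assign(admission_id=table.admissions["admission_id"].to_numpy())
        .melt(id_vars="admission_id", var_name="analyte_id", value_name="value")
        .dropna(subset=["value"])
    )
    labs_long["sequence"] = 1
    # preserve admission order, then panel order
    order = {aid: k for k, aid in enumerate(table.admissions["admission_id"])}
    panel_order = {a: k for k, a in enumerate(table.panel.ids)}
    labs_long = labs_long.sort_values(
        by=["admission_id", "analyte_id"],
        key=lambda s: s.map(order if s.name == "admission_id" else panel_order),
        kind="stable",
    )
    labs_long[["admission_id", "analyte_id", "value", "sequence"]].to_csv(
        path / "labs.csv", index=False
    )

    deficits_long = (
        table.deficits.assign(admission_id=table.admissions["admission_id"].to_numpy())
        .melt(id_vars="admission_id", var_name="item_id", value_name="value")
        .dropna(subset=["value"])
    )
    item_order = {it: k for k, it in enumerate(table.item_ids)}
    deficits_long = deficits_long.sort_values(
        by=["admission_id", "item_id"],
        key=lambda s: s.map(order if s.name == "admission_id" else item_order),
        kind="stable",
    )
    deficits_long[["admission_id", "item_id", "value"]].to_csv(
        path / "deficits.csv", index=False
    )


def read_cohort(
    path,
    panel: ReferencePanel,
    item_ids: Optional[Sequence[str]] = None,
    lenient: bool = False,
) -> CohortTable:
    """Read and validate a cohort bundle from directory ``path``.

    With ``lenient=True`` rows violating the age-inclusion rule are dropped
    (and counted in provenance) instead of raising.
    """
    path = Path(path)
    item_ids = tuple(item_ids) if item_ids is not None else default_item_ids()

    adm = pd.read_csv(path / "admissions.csv", dtype={"admission_id": str})
    required = set(_admission_columns()) - {"admit_date", "readmission_gap_days"}
    missing_cols = required - set(adm.columns)
    if missing_cols:
        raise SchemaError(f"admissions.csv missing columns {sorted(missing_cols)}")
    if "admit_date" not in adm.columns:
        adm["admit_date"] = None
    if "readmission_gap_days" not in adm.columns:
        adm["readmission_gap_days"] = np.nan

    for col in _BOOL_COLS:
        vals = adm[col]
        if not vals.isin([0, 1]).all():
            row = int(vals.index[~vals.isin([0, 1])][0])
            raise SchemaError("boolean column must be 0/1", row=row, field=col)
        adm[col] = vals.astype(bool)
    adm["icd10_codes"] = (
        adm["icd10_codes"].fillna("").map(
            lambda s: tuple(sorted(c for c in str(s).split(";") if c))
        )
    )
    adm["age"] = adm["age"].astype(int)
    adm["readmission_gap_days"] = adm["readmission_gap_days"].astype("Float64")
    adm["admit_date"] = (
        adm["admit_date"].astype(object).where(adm["admit_date"].notna(), None)
    )

    dropped_underage = 0
    if lenient:
        keep = adm["age"] >= 60
        dropped_underage = int((~keep).sum())
        adm = adm[keep].reset_index(drop=True)

    labs_long = pd.read_csv(path / "labs.csv", dtype={"admission_id": str})
    for col in ("admission_id", "analyte_id", "value"):
        if col not in labs_long.columns:
            raise SchemaError(f"labs.csv missing column {col!r}", field=col)
    unknown = set(labs_long["analyte_id"]) - set(panel.ids)
    if unknown:
        raise PanelMismatchError(
            f"analytes {sorted(unknown)} not in panel {panel.name!r}",
            field="analyte_id",
        )
    if "sequence" not in labs_long.columns:
        labs_long["sequence"] = 1
    # first result per (admission, analyte): lowest sequence, file order on ties
    labs_long = labs_long.sort_values("sequence", kind="stable")
    labs_long = labs_long.drop_duplicates(["admission_id", "analyte_id"], keep="first")
    labs = (
        labs_long.pivot(index="admission_id", columns="analyte_id", values="value")
        .reindex(index=adm["admission_id"], columns=list(panel.ids))
        .reset_index(drop=True)
    )
    labs.columns.name = None

    deficits_long = pd.read_csv(path / "deficits.csv", dtype={"admission_id": str})
    for col in ("admission_id", "item_id", "value"):
        if col not in deficits_long.columns:
            raise SchemaError(f"deficits.csv missing column {col!r}", field=col)
    unknown_items = set(deficits_long["item_id"]) - set(item_ids)
    if unknown_items:
        raise SchemaError(f"unknown deficit items {sorted(unknown_items)}")
    deficits = (
        deficits_long.pivot(index="admission_id", columns="item_id", values="value")
        .reindex(index=adm["admission_id"], columns=list(item_ids))
        .reset_index(drop=True)
    )
    deficits.columns.name = None

    provenance = {"source": str(path), "panel": panel.name}
    if dropped_underage:
        provenance["dropped_underage"] = dropped_underage
    return CohortTable(
        admissions=adm,
        labs=labs,
        deficits=deficits,
        panel=panel,
        item_ids=item_ids,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionFlow:
    """Tally of the exclusion flow; counts always sum to ``raw``."""

    raw: int
    readmission_only: int
    insufficient_labs_only: int
    both: int
    included: int

    def __post_init__(self):
        total = (
            self.readmission_only
            + self.insufficient_labs_only
            + self.both
            + self.included
        )
        if total != self.raw:
            raise ValueError("exclusion-flow counts do not sum to raw count")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def apply_exclusions(raw: CohortTable):
    """Apply the two cohort exclusions and tally the flow.

    Excluded are (a) readmissions within 30 days of the prior discharge
    (``readmission_gap_days`` <= 30; a missing gap marks an index admission)
    and (b) admissions with fewer than 70% of panel analytes measured, so
    that FI-lab cannot be computed.

    Returns ``(included_table, flow)``.
    """
    gap = raw.admissions["readmission_gap_days"].astype(float).to_numpy()
    is_readmit = ~np.isnan(gap) & (gap <= READMISSION_WINDOW_DAYS)

    measured = raw.labs.notna().sum(axis=1).to_numpy()
    ratio = measured / raw.panel.size
    insufficient = ratio < FI_LAB_MIN_MEASURED

    both = is_readmit & insufficient
    a_only = is_readmit & ~insufficient
    b_only = insufficient & ~is_readmit
    keep = ~(is_readmit | insufficient)

    flow = ExclusionFlow(
        raw=len(raw),
        readmission_only=int(a_only.sum()),
        insufficient_labs_only=int(b_only.sum()),
        both=int(both.sum()),
        included=int(keep.sum()),
    )
    return raw.subset(keep), flow
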