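"""Per-admission derived scores.

Implements the deficit-accumulation indices and clinical risk scores used
in the fall-risk analysis:

* **FI-lab** — fraction of measured panel analytes whose first admission
  value deviates from the (inclusive) reference interval; only computed
  when at least 70% of the panel was measured. The *measured ratio* is
  measured analytes / panel size.
* **FI-clinical** — sum of graded clinical deficit values (0/0.5/1)
  divided by the number of items assessed; requires at least 80% of the
  item set assessed.
* **STRATIFY** — sum of the five binary fall-risk items (0-5), with the
  mental-status item using the modified criterion (confusion,
  disorientation, or agitation, not agitation alone).
* **STRATIFY + FI-lab item** — STRATIFY plus one binary item for
  FI-lab > 0.4, a 6-item score (0-6).
* **Polypharmacy score** — count of six medication categories in use (0-6).
* **CCI** — Charlson Comorbidity Index from ICD-10 codes via a weighted
  prefix mapping with the Charlson severity hierarchy.

Boundary convention: a laboratory value exactly equal to a reference limit
is *normal* (deviation means strictly outside the interval), and
eligibility thresholds are exact rational comparisons (25/35 passes the
70% rule, 24/35 fails).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    MED_CATEGORIES,
    STRATIFY_ITEMS,
    AdmissionRecord,
    CohortTable,
    LabResult,
    ReferencePanel,
)
from .errors import DataError, FrailtyFallsError

#: FI-lab banding boundaries: < 0.25 low, 0.25-0.4 mid, > 0.4 high.
FI_LAB_BANDS = (0.25, 0.4)

#: Default FI-lab dichotomisation cut-off (> 0.4 is the deficit).
FI_LAB_CUTOFF = 0.4

INELIGIBLE = float("nan")


# ---------------------------------------------------------------------------
# FI-lab
# ---------------------------------------------------------------------------

def flag_abnormal(result: LabResult, panel: ReferencePanel, sex: str) -> int:
    """Return 1 iff the result lies strictly outside its reference interval."""
    if not np.isfinite(result.value):
        raise DataError(f"non-finite value for analyte {result.analyte_id!r}")
    lo, hi = panel.analyte(result.analyte_id).limits(sex)
    if lo is not None and result.value < lo:
        return 1
    if hi is not None and result.value > hi:
        return 1
    return 0


def fi_lab_score(record: AdmissionRecord, panel: ReferencePanel):
    """FI-lab for one admission: ``(score_or_nan, measured_ratio)``.

    The score is abnormal/measured; NaN signals ineligibility (fewer than
    70% of panel analytes measured).
    """
    measured = len(record.labs)
    ratio = measured / panel.size
    if measured * 10 < panel.size * 7:  # exact 70% rule
        return INELIGIBLE, ratio
    abnormal = sum(flag_abnormal(lab, panel, record.sex) for lab in record.labs)
    return abnormal / measured, ratio


def band_fi_lab(score: float) -> str:
    """Band an FI-lab score: low (< 0.25), mid (0.25-0.4), high (> 0.4)."""
    if not (0.0 <= score <= 1.0):
        raise DataError(f"FI-lab score {score!r} outside [0, 1]")
    if score < FI_LAB_BANDS[0]:
        return "low"
    if score <= FI_LAB_BANDS[1]:
        return "mid"
    return "high"


def binarize_fi_lab(score: float, cutoff: float = FI_LAB_CUTOFF) -> int:
    """Dichotomise FI-lab: 1 iff score strictly exceeds ``cutoff``."""
    return int(score > cutoff)


# ---------------------------------------------------------------------------
# FI-clinical, STRATIFY, polypharmacy
# ---------------------------------------------------------------------------

def fi_clinical_score(record: AdmissionRecord, n_items: int = 40) -> float:
    """Clinical frailty index: sum of deficits / items assessed.

    NaN signals ineligibility (fewer than 80% of the ``n_items`` assessed).
    """
    values = list(record.fi_clinical_items.values())
    assessed = len(values)
    if assessed * 5 < n_items * 4:  # exact 80% rule
        return INELIGIBLE
    return float(sum(values)) / assessed


def stratify_score(record: AdmissionRecord) -> int:
    """Sum of the five STRATIFY items (0-5); all items must be present."""
    missing = [k for k in STRATIFY_ITEMS if k not in record.stratify_items]
    if missing:
        raise DataError(f"missing STRATIFY item {missing[0]!r}")
    return sum(int(bool(record.stratify_items[k])) for k in STRATIFY_ITEMS)


def stratify_plus_filab(record: AdmissionRecord, panel: ReferencePanel) -> float:
    """Six-item score: STRATIFY plus the binary FI-lab > 0.4 item (0-6).

    NaN propagates when FI-lab is ineligible.
    """
    fi, _ = fi_lab_score(record, panel)
    if np.isnan(fi):
        return INELIGIBLE
    return stratify_score(record) + binarize_fi_lab(fi)


def polypharmacy_score(record: AdmissionRecord) -> int:
    """Count of the six medication categories in use (0-6)."""
    return sum(int(bool(record.med_categories.get(k, False))) for k in MED_CATEGORIES)


# ---------------------------------------------------------------------------
# Charlson Comorbidity Index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CCICondition:
    condition: str
    weight: int
    prefixes: tuple
    supersedes: Optional[str] = None


class CCIMap:
    """Weighted ICD-10 prefix mapping for the Charlson Comorbidity Index."""

    def __init__(self, conditions: Iterable[CCICondition], name: str = "cci"):
        self.conditions = tuple(conditions)
        self.name = name
        self._weights = {c.condition: c.weight for c in self.conditions}
        self._superseded_by = {
            c.supersedes: c.condition for c in self.conditions if c.supersedes
        }
        # prefix -> condition, for longest-prefix lookup
        self._prefix_map = {}
        for c in self.conditions:
            for p in c.prefixes:
                self._prefix_map[p] = c.condition
        self._max_prefix_len = max(len(p) for p in self._prefix_map)

    @staticmethod
    def normalize(code: str) -> str:
        return str(code).replace(".", "").strip().upper()

    def conditions_for(self, codes: Iterable[str]) -> set:
        """Conditions hit by any code, after applying the severity hierarchy."""
        hits = set()
        for code in codes:
            norm = self.normalize(code)
            for k in range(min(len(norm), self._max_prefix_len), 0, -1):
                cond = self._prefix_map.get(norm[:k])
                if cond is not None:
                    hits.add(cond)
                    break
        # hierarchy: drop the milder member when its severe counterpart is hit
        for mild, severe in self._superseded_by.items():
            if mild in hits and severe in hits:
                hits.discard(mild)
        return hits

    def score(self, codes: Iterable[str]) -> int:
        return sum(self._weights[c] for c in self.conditions_for(codes))

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CCIMap":
        conditions = [
            CCICondition(
                condition=str(e["condition"]),
                weight=int(e["weight"]),
                prefixes=tuple(str(p).upper() for p in e["prefixes"]),
                supersedes=e.get("supersedes"),
            )
            for e in raw["conditions"]
        ]
        return cls(conditions, name=str(raw.get("name", "cci")))

    @classmethod
    def from_yaml(cls, path) -> "CCIMap":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CCIMap":
        ref = importlib.resources.files("frailtyfalls.data") / "cci_quan_icd10.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


def cci_score(icd10_codes: Iterable[str], code_map: Optional[CCIMap] = None) -> int:
    """Charlson Comorbidity Index from a set of ICD-10 codes.

    Unrecognised codes are ignored; hierarchical conditions (e.g. metastatic
    disease over non-metastatic malignancy) count once at the higher weight.
    """
    code_map = code_map or CCIMap.default()
    return code_map.score(icd10_codes)


# ---------------------------------------------------------------------------
# Cohort-level score table
# ---------------------------------------------------------------------------

def abnormal_matrix(table: CohortTable) -> np.ndarray:
    """Admission x analyte abnormality flags (NaN where not measured)."""
    values = table.labs.to_numpy(dtype=float)
    flags = np.full_like(values, np.nan)
    sex = table.admissions["sex"].to_numpy()
    for s in ("male", "female"):
        rows = sex == s
        if not rows.any():
            continue
        lo, hi = table.panel.limit_arrays(s)
        v = values[rows]
        abnormal = (v < lo) | (v > hi)  # NaN compares False on both sides
        out = abnormal.astype(float)
        out[np.isnan(v)] = np.nan
        flags[rows] = out
    return flags


def compute_scores(
    table: CohortTable,
    cci_map: Optional[CCIMap] = None,
    filab_cutoff: float = FI_LAB_CUTOFF,
) -> pd.DataFrame:
    """Compute the full per-admission score set for a cohort.

    Returns a DataFrame aligned with the cohort rows, with columns
    ``admission_id, fi_lab, measured_ratio, fi_lab_band, fi_lab_binary,
    fi_clinical, stratify, stratify_plus_filab, polypharmacy, cci``.
    Ineligible FI values are NaN; band/binary columns are NaN with them.
    """
    cci_map = cci_map or CCIMap.default()
    adm = table.admissions
    flags = abnormal_matrix(table)
    measured = (~np.isnan(flags)).sum(axis=1)
    abnormal = np.nansum(flags, axis=1)
    ratio = measured / table.panel.size
    eligible = measured * 10 >= table.panel.size * 7
    with np.errstate(invalid="ignore", divide="ignore"):
        fi_lab = np.where(eligible & (measured > 0), abnormal / np.maximum(measured, 1), np.nan)

    if np.nanmin(fi_lab, initial=0.0) < 0 or np.nanmax(fi_lab, initial=0.0) > 1:
        raise FrailtyFallsError("FI-lab outside [0, 1]")

    band = np.full(len(adm), None, dtype=object)
    ok = ~np.isnan(fi_lab)
    band[ok & (fi_lab < FI_LAB_BANDS[0])] = "low"
    band[ok & (fi_lab >= FI_LAB_BANDS[0]) & (fi_lab <= FI_LAB_BANDS[1])] = "mid"
    band[ok & (fi_lab > FI_LAB_BANDS[1])] = "high"
    binary = np.where(ok, (fi_lab > filab_cutoff).astype(float), np.nan)

    dvals = table.deficits.to_numpy(dtype=float)
    n_items = len(table.item_ids)
    assessed = (~np.isnan(dvals)).sum(axis=1)
    fic_eligible = assessed * 5 >= n_items * 4
    with np.errstate(invalid="ignore", divide="ignore"):
        fi_clinical = np.where(
            fic_eligible & (assessed > 0),
            np.nansum(dvals, axis=1) / np.maximum(assessed, 1),
            np.nan,
        )

    stratify = adm[list(STRATIFY_ITEMS)].to_numpy(dtype=bool).sum(axis=1)
    splus = np.where(ok, stratify + binary, np.nan)
    poly = adm[list(MED_CATEGORIES)].to_numpy(dtype=bool).sum(axis=1)
    cci = np.fromiter(
        (cci_map.score(codes) for codes in adm["icd10_codes"]),
        dtype=int,
        count=len(adm),
    )

    return pd.DataFrame(
        {
            "admission_id": adm["admission_id"].to_numpy(),
            "fi_lab": fi_lab,
            "measured_ratio": ratio,
            "fi_lab_band": band,
            "fi_lab_binary": binary,
            "fi_clinical": fi_clinical,
            "stratify": stratify,
            "stratify_plus_filab": splus,
            "polypharmacy": poly,
            "cci": cci,
        }
    )
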