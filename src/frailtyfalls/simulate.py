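"""Synthetic admission-cohort generator.

Emulates the statistical structure of an acute-care geriatric admission
cohort: ages truncated-normal around 73 years, ~63.5% male, a 35-analyte
admission lab panel in which each analyte independently deviates from its
reference interval with configurable probability (population mean 0.31,
matching the emulated cohort's mean FI-lab) and is independently missing
(~13%, giving a measured ratio near 0.87), five STRATIFY items and forty
graded clinical deficits with configurable prevalences, six medication
flags, ICD-10 codes drawn from a small condition list, and a Bernoulli
in-hospital fall outcome from a logistic model on age, sex, STRATIFY and
the two frailty indices, with a marginal event rate near 2.9%.

The fall outcome is driven by the *true* deficit fractions over the full
panel/item set; the observed FI-lab then estimates that signal from the
measured subset, as in real data. Deficits are independent by default; an
optional latent logistic-normal frailty factor (``frailty_sd``) induces
positive correlation between analytes and deficit items.

All randomness flows from ``SimConfig.seed`` through named substreams, one
per generated field, each drawn as a vector over records in row order —
record *i* therefore depends only on its index, never on how many other
records are generated after it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .cohort import (
    MED_CATEGORIES,
    STRATIFY_ITEMS,
    CohortTable,
    ReferencePanel,
    _admission_columns,
    default_item_ids,
)
from .errors import ConfigurationError

#: Substream names in fixed order; each gets its own child SeedSequence.
_STREAMS = (
    "age",
    "sex",
    "latent",
    "abnormal",
    "side",
    "value",
    "lab_missing",
    "stratify",
    "deficit",
    "deficit_missing",
    "meds",
    "icd",
    "outcome",
    "shuffle",
)


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model generating the fall outcome.

    Coefficients are log-odds; the frailty-index terms are per 0.1 unit of
    the index, STRATIFY is per point, age per year. Defaults emulate the
    adjusted associations seen in hospital fall studies (OR ~1.65/point
    STRATIFY, ~1.28 per 0.1 FI-lab, ~1.25 per 0.1 FI-clinical).
    """

    intercept: float = math.log(0.03 / 0.97)
    coef_age_per_year: float = 0.02
    coef_male: float = 0.1
    coef_stratify_per_point: float = math.log(1.65)
    coef_filab_per_0_1: float = math.log(1.28)
    coef_ficlinical_per_0_1: float = math.log(1.25)


_DEFAULT_STRATIFY_PREV = {
    "history_of_falls": 0.135,
    "mental_status": 0.059,
    "vision": 0.074,
    "toileting": 0.070,
    "mobility": 0.084,
}

# representative ICD-10 codes with admission prevalences (tertiary-care mix)
_DEFAULT_CONDITION_CODES = {
    "C18.9": 0.30,
    "C78.0": 0.05,
    "E11.9": 0.18,
    "I50.0": 0.10,
    "I63.9": 0.07,
    "J44.9": 0.08,
    "N18.9": 0.07,
    "F03": 0.04,
    "I21.9": 0.04,
    "K74.0": 0.02,
}


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated cohort (defaults = study conditions)."""

    n: int
    seed: int
    age_mean: float = 73.0
    age_sd: float = 7.3
    age_min: int = 60
    age_max: int = 99
    male_frac: float = 0.635
    #: per-analyte probability of an out-of-range value; scalar applies to all
    abnormal_prob: Union[float, Mapping[str, float]] = 0.31
    #: of out-of-range draws, fraction placed below the lower limit
    low_frac: float = 0.5
    #: per-analyte missingness; scalar applies to all
    missing_prob: Union[float, Mapping[str, float]] = 0.13
    stratify_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STRATIFY_PREV)
    )
    #: per clinical item: P(value=1), P(value=0.5)
    deficit_p_full: float = 0.07
    deficit_p_half: float = 0.08
    deficit_missing_prob: float = 0.0
    med_prevalence: float = 0.2
    condition_codes: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONDITION_CODES)
    )
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    #: when set, the intercept is re-solved so the expected marginal fall
    #: rate matches this value to 1e-4
    target_marginal_rate: Optional[float] = 0.029
    #: SD of the latent logistic-normal frailty factor (0 = independence)
    frailty_sd: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.seed is None:
            raise ConfigurationError("seed is required; no implicit entropy")
        probs = {
            "male_frac": self.male_frac,
            "low_frac": self.low_frac,
            "deficit_p_full": self.deficit_p_full,
            "deficit_p_half": self.deficit_p_half,
            "deficit_missing_prob": self.deficit_missing_prob,
            "med_prevalence": self.med_prevalence,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.deficit_p_full + self.deficit_p_half > 1.0:
            raise ConfigurationError("deficit value probabilities exceed 1")
        if self.target_marginal_rate is not None and not (
            0.0 < self.target_marginal_rate < 1.0
        ):
            raise ConfigurationError("target_marginal_rate must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "outcome_model" in raw:
            raw["outcome_model"] = OutcomeModel(**raw["outcome_model"])
        return cls(**raw)


def _streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.Generator(np.random.Philox(ss))
            for name, ss in zip(_STREAMS, children)}


def _per_analyte(value, panel: ReferencePanel) -> np.ndarray:
    if isinstance(value, Mapping):
        return np.array([float(value.get(a, 0.0)) for a in panel.ids])
    return np.full(panel.size, float(value))


def _generate_arrays(
    config: SimConfig,
    panel: ReferencePanel,
    item_ids,
    n: Optional[int] = None,
    with_values: bool = True,
) -> dict:
    """Draw all cohort fields as vectors over records.

    Returns raw arrays, including the true (pre-missingness) deficit
    fractions that drive the outcome and the observed scores.
    """
    n = int(config.n if n is None else n)
    rng = _streams(config.seed)
    n_items = len(item_ids)

    a, b = (
        (config.age_min - config.age_mean) / config.age_sd,
        (config.age_max + 0.999 - config.age_mean) / config.age_sd,
    )
    age = np.floor(
        truncnorm.rvs(
            a, b, loc=config.age_mean, scale=config.age_sd, size=n,
            random_state=rng["age"],
        )
    ).astype(int)
    male = rng["sex"].random(n) < config.male_frac

    latent = (
        rng["latent"].normal(0.0, config.frailty_sd, size=n)
        if config.frailty_sd > 0
        else np.zeros(n)
    )

    p_abn = _per_analyte(config.abnormal_prob, panel)
    if config.frailty_sd > 0:
        logit_abn = logit(np.clip(p_abn, 1e-12, 1 - 1e-12))
        abn_prob = expit(logit_abn[None, :] + latent[:, None])
    else:
        abn_prob = p_abn[None, :]
    abnormal = rng["abnormal"].random((n, panel.size)) < abn_prob

    p_miss = _per_analyte(config.missing_prob, panel)
    lab_missing = rng["lab_missing"].random((n, panel.size)) < p_miss[None, :]

    values = None
    if with_values:
        values = _draw_lab_values(config, panel, abnormal, male, rng)

    prev = np.array([config.stratify_prevalence[k] for k in STRATIFY_ITEMS])
    prev_adj = expit(logit(np.clip(prev, 1e-12, 1 - 1e-12))[None, :] + latent[:, None])
    stratify_items = rng["stratify"].random((n, len(STRATIFY_ITEMS))) < prev_adj

    u = rng["deficit"].random((n, n_items))
    p1 = expit(
        logit(np.clip(config.deficit_p_full, 1e-12, 1 - 1e-12)) + latent
    )[:, None]
    p1 = np.broadcast_to(p1, (n, n_items))
    deficits = np.zeros((n, n_items))
    deficits[u < p1] = 1.0
    deficits[(u >= p1) & (u < p1 + config.deficit_p_half)] = 0.5
    deficit_missing = (
        rng["deficit_missing"].random((n, n_items)) < config.deficit_missing_prob
    )

    meds = rng["meds"].random((n, len(MED_CATEGORIES))) < config.med_prevalence

    codes = list(config.condition_codes)
    code_p = np.array([config.condition_codes[c] for c in codes])
    code_hits = rng["icd"].random((n, len(codes))) < code_p[None, :]

    # true deficit fractions (pre-missingness) drive the fall outcome
    true_filab = abnormal.mean(axis=1)
    true_ficlinical = deficits.mean(axis=1)
    stratify = stratify_items.sum(axis=1)

    om = config.outcome_model
    lp0 = (
        om.coef_age_per_year * age
        + om.coef_male * male
        + om.coef_stratify_per_point * stratify
        + om.coef_filab_per_0_1 * (true_filab / 0.1)
        + om.coef_ficlinical_per_0_1 * (true_ficlinical / 0.1)
    )
    if config.target_marginal_rate is not None:
        intercept = solve_intercept(lp0, config.target_marginal_rate)
    else:
        intercept = om.intercept
    p_fall = expit(intercept + lp0)
    fell = rng["outcome"].random(n) < p_fall

    # observed FI-lab over the measured subset
    obs_flags = np.where(lab_missing, np.nan, abnormal.astype(float))
    measured = (~lab_missing).sum(axis=1)
    with np.errstate(invalid="ignore"):
        obs_filab = np.where(
            measured > 0, np.nansum(obs_flags, axis=1) / np.maximum(measured, 1), np.nan
        )
    obs_deficits = np.where(deficit_missing, np.nan, deficits)
    assessed = (~deficit_missing).sum(axis=1)
    with np.errstate(invalid="ignore"):
        obs_ficlinical = np.where(
            assessed > 0,
            np.nansum(obs_deficits, axis=1) / np.maximum(assessed, 1),
            np.nan,
        )

    return {
        "n": n,
        "age": age,
        "male": male,
        "abnormal": abnormal,
        "lab_missing": lab_missing,
        "values": values,
        "stratify_items": stratify_items,
        "stratify": stratify,
        "deficits": obs_deficits,
        "meds": meds,
        "code_hits": code_hits,
        "codes": codes,
        "true_filab": true_filab,
        "true_ficlinical": true_ficlinical,
        "obs_filab": obs_filab,
        "obs_ficlinical": obs_ficlinical,
        "intercept": intercept,
        "linear_predictor": intercept + lp0,
        "p_fall": p_fall,
        "fell": fell,
        "measured": measured,
    }


def _draw_lab_values(config, panel, abnormal, male, rng):
    """Place each result inside or outside the (sex-specific) interval.

    Out-of-range values land uniformly on (limit, limit + 0.5 * interval
    width) beyond the violated bound; magnitude is irrelevant because the
    FI-lab coding is binary per analyte.
    """
    n = abnormal.shape[0]
    lo = np.empty((n, panel.size))
    hi = np.empty((n, panel.size))
    for s, mask in (("male", male), ("female", ~male)):
        l, h = panel.limit_arrays(s)
        lo[mask] = l
        hi[mask] = h
    # effective sampling interval for one-sided analytes
    lo_eff = np.where(np.isnan(lo), 0.0, lo)
    hi_eff = np.where(np.isnan(hi), 2.0 * lo_eff, hi)
    width = hi_eff - lo_eff

    # one (n, analyte, 2) block keeps record i's draws a function of i only
    u = rng["value"].random((n, panel.size, 2))
    u_inside, u_out = u[:, :, 0], u[:, :, 1]
    u_side = rng["side"].random((n, panel.size))

    inside = lo_eff + u_inside * width
    go_low = u_side < config.low_frac
    go_low = np.where(np.isnan(lo), False, go_low)  # no lower bound to violate
    go_low = np.where(np.isnan(hi), True, go_low)  # no upper bound to violate
    offset = width * (0.001 + 0.499 * u_out)
    outside = np.where(go_low, lo_eff - offset, hi_eff + offset)
    return np.where(abnormal, outside, inside)


def solve_intercept(lp0: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection for the intercept giving mean(expit(c + lp0)) = target."""
    if not 0.0 < target < 1.0:
        raise ConfigurationError("target rate must lie in (0, 1)")

    def rate(c):
        return float(np.mean(expit(c + lp0)))

    lo_c, hi_c = -60.0, 60.0
    if not rate(lo_c) <= target <= rate(hi_c):
        raise ConfigurationError(
            "target marginal rate unattainable with these coefficients"
        )
    for _ in range(200):
        mid = 0.5 * (lo_c + hi_c)
        r = rate(mid)
        if abs(r - target) <= tol:
            return mid
        if r < target:
            lo_c = mid
        else:
            hi_c = mid
    return 0.5 * (lo_c + hi_c)


def generate_cohort(
    config: SimConfig,
    panel: Optional[ReferencePanel] = None,
    item_ids=None,
) -> CohortTable:
    """Generate a validated cohort table (deterministic given the seed)."""
    panel = panel or ReferencePanel.default()
    item_ids = tuple(item_ids) if item_ids is not None else default_item_ids()
    arr = _generate_arrays(config, panel, item_ids, with_values=True)
    n = arr["n"]

    icd = [
        tuple(sorted(c for c, hit in zip(arr["codes"], hits) if hit))
        for hits in arr["code_hits"]
    ]
    adm = pd.DataFrame(
        {
            "admission_id": [f"S{i + 1:06d}" for i in range(n)],
            "age": arr["age"],
            "sex": np.where(arr["male"], "male", "female"),
            "emergency": _streams(config.seed)["shuffle"].random(n) < 0.259,
            "icd10_codes": icd,
            "fell": arr["fell"],
            "admit_date": [None] * n,
            "readmission_gap_days": pd.array([pd.NA] * n, dtype="Float64"),
        }
    )
    for j, k in enumerate(STRATIFY_ITEMS):
        adm[k] = arr["stratify_items"][:, j]
    for j, k in enumerate(MED_CATEGORIES):
        adm[k] = arr["meds"][:, j]
    adm = adm[_admission_columns()]

    lab_values = np.where(arr["lab_missing"], np.nan, arr["values"])
    labs = pd.DataFrame(lab_values, columns=list(panel.ids))
    deficits = pd.DataFrame(arr["deficits"], columns=list(item_ids))

    return CohortTable(
        admissions=adm,
        labs=labs,
        deficits=deficits,
        panel=panel,
        item_ids=item_ids,
        provenance={
            "source": f"simulated(seed={config.seed}, n={n})",
            "panel": panel.name,
            "intercept": arr["intercept"],
        },
    )


#: score names accepted by :func:`true_auc`
_SCORES = (
    "stratify",
    "fi_lab",
    "fi_clinical",
    "stratify_plus_filab",
    "linear_predictor",
)


def true_auc(
    config: SimConfig,
    score: str,
    n: int = 1_000_000,
    panel: Optional[ReferencePanel] = None,
    item_ids=None,
):
    """Population AUROC of a score under the generating process.

    Estimated by Monte Carlo at sample size ``n``; returns ``(auc, se)``
    with the standard error from the DeLong variance.
    """
    from .discrimination import auc as _auc  # local import avoids a cycle

    if score not in _SCORES:
        raise ConfigurationError(f"unknown score {score!r}; one of {_SCORES}")
    panel = panel or ReferencePanel.default()
    item_ids = tuple(item_ids) if item_ids is not None else default_item_ids()
    arr = _generate_arrays(config, panel, item_ids, n=n, with_values=False)
    if score == "stratify":
        s = arr["stratify"].astype(float)
    elif score == "fi_lab":
        s = arr["obs_filab"]
    elif score == "fi_clinical":
        s = arr["obs_ficlinical"]
    elif score == "stratify_plus_filab":
        s = arr["stratify"] + (arr["obs_filab"] > 0.4)
    else:
        s = arr["linear_predictor"]
    ok = ~np.isnan(s)
    roc = _auc(s[ok], arr["fell"][ok].astype(int))
    return roc.auc, roc.se


def cohort_with_exclusion_margins(
    raw: int,
    readmission_only: int,
    insufficient_labs_only: int,
    both: int,
    seed: int,
    panel: Optional[ReferencePanel] = None,
) -> CohortTable:
    """Cohort built to given exclusion-flow margins.

    The first ``readmission_only + both`` records (after a seeded shuffle)
    carry a readmission gap of at most 30 days; ``insufficient_labs_only +
    both`` records have too few measured analytes for FI-lab.
    """
    if readmission_only + insufficient_labs_only + both > raw:
        raise ConfigurationError("exclusion margins exceed raw count")
    panel = panel or ReferencePanel.default()
    config = SimConfig(n=raw, seed=seed, missing_prob=0.0)
    table = generate_cohort(config, panel=panel)

    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, 104729])))
    order = rng.permutation(raw)
    readmit_rows = order[: readmission_only + both]
    short_rows = np.concatenate(
        [
            order[readmission_only : readmission_only + both],
            order[readmission_only + both : readmission_only + both + insufficient_labs_only],
        ]
    )
    gaps = table.admissions["readmission_gap_days"].copy()
    gaps.iloc[readmit_rows] = rng.integers(0, 31, size=len(readmit_rows)).astype(float)
    table.admissions["readmission_gap_days"] = gaps
    # keep fewer than 70% of analytes measured
    n_keep = int(np.floor(0.7 * panel.size)) - 1
    for i in short_rows:
        keep = rng.choice(panel.size, size=n_keep, replace=False)
        drop = np.setdiff1d(np.arange(panel.size), keep)
        table.labs.iloc[i, drop] = np.nan
    return table


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a new seed."""
    return replace(config, seed=seed)
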