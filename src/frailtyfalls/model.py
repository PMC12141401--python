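"""Logistic fall-risk models.

The analysis fits a family of binomial logistic regressions for the
in-hospital fall outcome, every multivariate specification adjusted for
age and sex:

* ``m1`` — age, sex, STRATIFY (the reference prediction model);
* ``m2`` — m1 + FI-lab (the primary model);
* ``m3`` — age, sex, the 6-item STRATIFY-including-FI-lab score;
* ``m4`` — m1 + FI-clinical;
* ``m5`` — age, sex, FI-lab, FI-clinical (no STRATIFY);
* ``m6`` — m1 + FI-lab + FI-clinical;
* ``uni:<term>`` — single-predictor fits for each score.

Usage follows the Model/Results idiom::

    model = FallRiskModel.from_cohort(cohort, scores, "m2")
    res = model.fit()
    res.odds_ratios()          # ORs per reporting unit with 95% CIs
    res.compare(res_m1)        # DeLong + NRI/IDI against a reference model
    res.validate(B=1000, seed=7)

Odds ratios are reported per point for STRATIFY-type scores and per 0.1
unit for the frailty indices; confidence intervals are Wald
(estimate +/- 1.959964 SE on the log-odds scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import CohortTable
from .discrimination import (
    DelongComparison,
    ReclassResult,
    RocResult,
    Z95,
    auc as roc_auc,
    delong_compare,
    reclassification,
)
from .errors import DataError, FrailtyFallsError

#: reporting unit per term: OR = exp(unit * beta)
DEFAULT_UNITS = {
    "age": 1.0,
    "sex_male": 1.0,
    "stratify": 1.0,
    "fi_lab": 0.1,
    "fi_clinical": 0.1,
    "stratify_plus_filab": 1.0,
    "polypharmacy": 1.0,
    "cci": 1.0,
}

_MODEL_PREDICTORS = {
    "m1": ("age", "sex_male", "stratify"),
    "m2": ("age", "sex_male", "stratify", "fi_lab"),
    "m3": ("age", "sex_male", "stratify_plus_filab"),
    "m4": ("age", "sex_male", "stratify", "fi_clinical"),
    "m5": ("age", "sex_male", "fi_lab", "fi_clinical"),
    "m6": ("age", "sex_male", "stratify", "fi_lab", "fi_clinical"),
}

#: score terms eligible for single-predictor ("univariate") fits
UNIVARIATE_TERMS = ("stratify", "fi_lab", "stratify_plus_filab", "fi_clinical")


@dataclass(frozen=True)
class ModelSpec:
    """A named logistic specification: ordered predictors and the outcome."""

    model_id: str
    predictors: tuple
    outcome: str = "fell"

    @classmethod
    def named(cls, model_id: str, adjust: Sequence[str] = ()) -> "ModelSpec":
        """Look up ``m1``..``m6`` or ``uni:<term>``; ``adjust`` appends
        sensitivity covariates (e.g. polypharmacy, cci)."""
        if model_id in _MODEL_PREDICTORS:
            preds = _MODEL_PREDICTORS[model_id]
        elif model_id.startswith("uni:"):
            term = model_id.split(":", 1)[1]
            if term not in UNIVARIATE_TERMS:
                raise FrailtyFallsError(f"no univariate fit for term {term!r}")
            preds = (term,)
        else:
            raise FrailtyFallsError(f"unknown model_id {model_id!r}")
        extra = tuple(t for t in adjust if t not in preds)
        spec_id = model_id if not extra else f"{model_id}+{'+'.join(extra)}"
        return cls(model_id=spec_id, predictors=preds + extra)


def build_analysis_frame(cohort: CohortTable, scores: pd.DataFrame) -> pd.DataFrame:
    """Merge cohort covariates and derived scores into one modelling frame."""
    adm = cohort.admissions
    if not (adm["admission_id"].to_numpy() == scores["admission_id"].to_numpy()).all():
        scores = scores.set_index("admission_id").loc[adm["admission_id"]].reset_index()
    return pd.DataFrame(
        {
            "admission_id": adm["admission_id"].to_numpy(),
            "fell": adm["fell"].to_numpy(dtype=int),
            "age": adm["age"].to_numpy(dtype=float),
            "sex_male": (adm["sex"] == "male").to_numpy(dtype=float),
            "stratify": scores["stratify"].to_numpy(dtype=float),
            "fi_lab": scores["fi_lab"].to_numpy(dtype=float),
            "fi_clinical": scores["fi_clinical"].to_numpy(dtype=float),
            "stratify_plus_filab": scores["stratify_plus_filab"].to_numpy(dtype=float),
            "polypharmacy": scores["polypharmacy"].to_numpy(dtype=float),
            "cci": scores["cci"].to_numpy(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class FallRiskModel:
    """Binomial logistic model for the in-hospital fall outcome.

    Built from a modelling DataFrame (or a cohort + score table via
    :meth:`from_cohort`); complete cases on the spec's terms are used.
    ``fit()`` returns a :class:`FallRiskResults`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        predictors: Sequence[str],
        outcome: str = "fell",
        model_id: Optional[str] = None,
    ):
        self.spec = ModelSpec(
            model_id=model_id or "+".join(predictors),
            predictors=tuple(predictors),
            outcome=outcome,
        )
        missing = [c for c in (*self.spec.predictors, outcome) if c not in data]
        if missing:
            raise DataError(f"data lacks columns {missing}")
        complete = data[[outcome, *self.spec.predictors]].notna().all(axis=1)
        self.data = data.loc[complete].reset_index(drop=True)
        self.n_dropped = int((~complete).sum())

    @classmethod
    def from_cohort(
        cls,
        cohort: CohortTable,
        scores: pd.DataFrame,
        model_id: str,
        adjust: Sequence[str] = (),
    ) -> "FallRiskModel":
        spec = ModelSpec.named(model_id, adjust)
        frame = build_analysis_frame(cohort, scores)
        return cls(frame, spec.predictors, outcome=spec.outcome, model_id=spec.model_id)

    def fit(self) -> "FallRiskResults":
        y = self.data[self.spec.outcome].to_numpy(dtype=float)
        if len(y) == 0:
            raise DataError("no complete cases for this specification")
        if y.min() == y.max():
            raise DataError("outcome is all-one or all-zero; cannot fit")
        if self.spec.predictors:
            X = sm.add_constant(
                self.data[list(self.spec.predictors)].to_numpy(dtype=float),
                has_constant="add",
            )
        else:  # intercept-only model
            X = np.ones((len(y), 1))
        names = ["const", *self.spec.predictors]
        converged, diagnostic = True, None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=100, tol=1e-10
                )
            params = pd.Series(res.params, index=names)
            cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
            predicted = np.asarray(res.predict(X))
            llf = float(res.llf)
            if not res.converged:
                converged, diagnostic = False, "IRLS did not converge"
            elif np.abs(params.to_numpy()).max() > 50 or np.sqrt(
                np.diag(cov)
            ).max() > 1e4:
                converged = False
                diagnostic = "coefficients diverging; possible perfect separation"
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            converged = False
            diagnostic = f"fit failed: {exc}"
            params = pd.Series(np.nan, index=names)
            cov = pd.DataFrame(np.nan, index=names, columns=names)
            predicted = np.full(len(y), y.mean())
            llf = float("nan")
        return FallRiskResults(
            spec=self.spec,
            model=self,
            params=params,
            cov=cov,
            predicted=predicted,
            llf=llf,
            converged=converged,
            diagnostic=diagnostic,
        )


@dataclass
class FallRiskResults:
    """Fitted logistic model: coefficients, covariance, ORs, predictions."""

    spec: ModelSpec
    model: FallRiskModel
    params: pd.Series
    cov: pd.DataFrame
    predicted: np.ndarray
    llf: float
    converged: bool
    diagnostic: Optional[str] = None

    @property
    def n(self) -> int:
        return len(self.model.data)

    @property
    def events(self) -> int:
        return int(self.model.data[self.spec.outcome].sum())

    @property
    def epv(self) -> float:
        """Events per (non-intercept) fitted variable."""
        return self.events / len(self.spec.predictors)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def outcome(self) -> np.ndarray:
        return self.model.data[self.spec.outcome].to_numpy(dtype=int)

    def linear_predictor(self, data: Optional[pd.DataFrame] = None) -> np.ndarray:
        data = self.model.data if data is None else data
        X = data[list(self.spec.predictors)].to_numpy(dtype=float)
        beta = self.params.to_numpy()
        return beta[0] + X @ beta[1:]

    def predict(self, data: Optional[pd.DataFrame] = None) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(data))

    def odds_ratio(self, term: str, unit: Optional[float] = None):
        """(OR, ci_low, ci_high) for ``term`` per ``unit`` of the predictor."""
        if term not in self.params.index:
            raise DataError(f"term {term!r} not in model {self.spec.model_id!r}")
        if unit is None:
            unit = DEFAULT_UNITS.get(term, 1.0)
        beta, se = self.params[term], self.bse[term]
        return (
            float(np.exp(unit * beta)),
            float(np.exp(unit * (beta - Z95 * se))),
            float(np.exp(unit * (beta + Z95 * se))),
        )

    def odds_ratios(self, units: Optional[Mapping[str, float]] = None) -> pd.DataFrame:
        """Table of ORs with Wald 95% CIs per reporting unit."""
        from scipy.stats import norm

        units = {**DEFAULT_UNITS, **(units or {})}
        rows = []
        for term in self.spec.predictors:
            unit = units.get(term, 1.0)
            or_, lo, hi = self.odds_ratio(term, unit)
            z = self.params[term] / self.bse[term]
            rows.append(
                {
                    "term": term,
                    "unit": unit,
                    "or": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": float(2 * norm.sf(abs(z))),
                }
            )
        return pd.DataFrame(rows)

    def roc(self) -> RocResult:
        return roc_auc(self.predicted, self.outcome)

    def compare(
        self, reference: "FallRiskResults", reclass: bool = True
    ) -> "ModelComparison":
        """DeLong AUROC comparison (and NRI/IDI) against a reference model.

        Both results must be fitted on the same admissions in the same
        order. Set ``reclass=False`` to suppress NRI/IDI, as is done when
        the new model does not contain the reference model's score.
        """
        y_ref = reference.outcome
        y_new = self.outcome
        if len(y_ref) != len(y_new) or (y_ref != y_new).any():
            raise DataError("models were fitted on different admissions")
        dl = delong_compare(reference.predicted, self.predicted, y_new)
        rc = (
            reclassification(reference.predicted, self.predicted, y_new)
            if reclass
            else None
        )
        return ModelComparison(
            reference_id=reference.spec.model_id,
            new_id=self.spec.model_id,
            delong=dl,
            reclass=rc,
        )

    def validate(self, B: int = 1000, seed: int = 0, **kwargs):
        from .validation import validate_results

        return validate_results(self, B=B, seed=seed, **kwargs)

    def summary(self) -> str:
        lines = [
            f"Fall-risk logistic model [{self.spec.model_id}]",
            f"  n = {self.n}, events = {self.events} "
            f"({100 * self.events / self.n:.1f}%), EPV = {self.epv:.1f}",
            f"  converged: {self.converged}"
            + (f" ({self.diagnostic})" if self.diagnostic else ""),
            "",
            f"  {'term':<22}{'unit':>6}{'OR':>8}{'95% CI':>18}{'p':>10}",
        ]
        for _, r in self.odds_ratios().iterrows():
            ci = f"({r['ci_low']:.2f}-{r['ci_high']:.2f})"
            lines.append(
                f"  {r['term']:<22}{r['unit']:>6.1f}{r['or']:>8.2f}{ci:>18}"
                f"{r['p']:>10.3g}"
            )
        if self.converged:
            lines.append(f"\n  AUROC (apparent) = {self.roc().auc:.3f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ModelComparison:
    """Incremental-value comparison of a new model against a reference."""

    reference_id: str
    new_id: str
    delong: DelongComparison
    reclass: Optional[ReclassResult] = None


# alias matching the domain-type name used elsewhere in the docs
ModelFit = FallRiskResults


# ---------------------------------------------------------------------------
# Module-surface helpers
# ---------------------------------------------------------------------------

def fit_logistic(design: pd.DataFrame, outcome, model_id: str = "custom") -> FallRiskResults:
    """Fit a logistic regression of ``outcome`` on the ``design`` columns."""
    data = design.copy()
    data["__y__"] = np.asarray(outcome, dtype=float)
    model = FallRiskModel(
        data, predictors=list(design.columns), outcome="__y__", model_id=model_id
    )
    return model.fit()


def odds_ratio(fit: FallRiskResults, term: str, unit: float = 1.0):
    """OR with Wald 95% CI for ``term`` per ``unit`` of the predictor."""
    return fit.odds_ratio(term, unit)


def run_model_suite(
    cohort: CohortTable,
    scores: pd.DataFrame,
    models: Optional[Iterable[str]] = None,
    adjust: Sequence[str] = (),
) -> dict:
    """Fit the univariate and multivariate suite; returns id -> results.

    Fit errors are caught per model so one failure does not abort the
    suite; failed entries carry ``converged=False`` or the raised error.
    """
    if models is None:
        models = [f"uni:{t}" for t in UNIVARIATE_TERMS] + list(_MODEL_PREDICTORS)
    out = {}
    for model_id in models:
        try:
            out[model_id] = FallRiskModel.from_cohort(
                cohort, scores, model_id, adjust=adjust
            ).fit()
        except FrailtyFallsError as exc:
            warnings.warn(f"model {model_id}: {exc}")
            out[model_id] = None
    return out


def subgroup_suite(
    cohort: CohortTable,
    scores: pd.DataFrame,
    strata: str,
    models: Optional[Iterable[str]] = None,
    age_cut: int = 75,
) -> dict:
    """Run the model suite within subgroups (age < 75 vs >= 75, or sex).

    Strata partition the cohort; the age boundary itself (75) falls in the
    older stratum. Event-free strata are skipped with a warning.
    """
    adm = cohort.admissions
    if strata == "age":
        masks = {
            f"age<{age_cut}": (adm["age"] < age_cut).to_numpy(),
            f"age>={age_cut}": (adm["age"] >= age_cut).to_numpy(),
        }
    elif strata == "sex":
        masks = {
            "male": (adm["sex"] == "male").to_numpy(),
            "female": (adm["sex"] == "female").to_numpy(),
        }
    elif strata == "all":
        masks = {"all": np.ones(len(adm), dtype=bool)}
    else:
        raise FrailtyFallsError(f"unknown stratification {strata!r}")

    out = {}
    for name, mask in masks.items():
        if not mask.any() or not adm.loc[mask, "fell"].any():
            warnings.warn(f"stratum {name!r} empty or event-free; skipped")
            continue
        sub_cohort = cohort.subset(mask)
        sub_scores = scores.loc[mask].reset_index(drop=True)
        out[name] = {
            "n": int(mask.sum()),
            "suite": run_model_suite(sub_cohort, sub_scores, models=models),
        }
    return out
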