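"""Bootstrap internal validation of the fall-risk models.

Implements the Efron/Harrell enhanced-bootstrap optimism correction: for
each of ``B`` resamples (admission-level, with replacement) the model is
refitted, its c-statistic is measured on the resample and on the original
data, and the averaged difference (the optimism) is subtracted from the
apparent c-statistic. The calibration slope is the average, over
resamples, of the coefficient from refitting the outcome on the bootstrap
model's linear predictor evaluated on the original data; a slope below 1
indicates overfitting-driven miscalibration.

Calibration error summaries (mean absolute error and its 0.9 quantile)
come from a locally weighted regression (lowess, span 2/3) of the outcome
on the predicted probability; inside :func:`validate_results` the errors
are taken against the optimism-corrected calibration curve evaluated at
the observed predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError

#: default lowess span on the probability scale
CALIBRATION_SPAN = 2.0 / 3.0


@dataclass(frozen=True)
class CalibrationError:
    """Absolute calibration error summaries against a smoothed curve."""

    mae: float
    median_ae: float
    q90_ae: float
    curve: tuple  # (predicted sorted, smoothed observed)


def _lowess_at(x_eval, x, y, frac):
    """Lowess of y on x, interpolated at ``x_eval`` (constant beyond range)."""
    if np.ptp(x) == 0:  # constant predictions: smoothed curve is the mean
        return np.full(len(np.atleast_1d(x_eval)), float(np.mean(y))), np.column_stack(
            [np.sort(x), np.full(len(x), float(np.mean(y)))]
        )
    fitted = sm.nonparametric.lowess(
        y, x, frac=frac, it=0, delta=0.01 * (np.ptp(x) if np.ptp(x) > 0 else 1.0),
        return_sorted=True,
    )
    return np.interp(x_eval, fitted[:, 0], fitted[:, 1]), fitted


def calibration_error(
    predicted, observed, frac: float = CALIBRATION_SPAN
) -> CalibrationError:
    """Calibration error of predicted probabilities against outcomes.

    The observed event probability is estimated by lowess of the binary
    outcome on the prediction; the per-subject absolute error is
    ``|smoothed - predicted|``.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) < 50:
        raise DataError("fewer than 50 subjects; calibration smoother unreliable")
    if ((predicted <= 0) | (predicted >= 1)).any():
        raise DataError("predicted probabilities must lie strictly in (0, 1)")
    smoothed, fitted = _lowess_at(predicted, predicted, observed, frac)
    ae = np.abs(smoothed - predicted)
    return CalibrationError(
        mae=float(ae.mean()),
        median_ae=float(np.quantile(ae, 0.5)),
        q90_ae=float(np.quantile(ae, 0.9)),
        curve=(fitted[:, 0], fitted[:, 1]),
    )


@dataclass(frozen=True)
class ValidationReport:
    """Apparent vs optimism-corrected performance of one model."""

    model_id: str
    apparent_c: float
    optimism: float
    corrected_c: float
    calibration_slope: float
    mae: float
    median_ae: float
    q90_ae: float
    B: int
    seed: int
    n_nonconverged: int
    unstable: bool

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _refit(results, data):
    """Refit the spec of ``results`` on ``data``; returns results or None."""
    from .model import FallRiskModel

    y = data[results.spec.outcome]
    if y.min() == y.max():
        return None
    refit = FallRiskModel(
        data,
        predictors=results.spec.predictors,
        outcome=results.spec.outcome,
        model_id=results.spec.model_id,
    ).fit()
    return refit if refit.converged else None


def _slope_on(lp: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Coefficient from logistic refit of y on a linear predictor."""
    if np.ptp(lp) == 0:
        return None
    X = sm.add_constant(lp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-10
            )
        except Exception:
            return None
    if not res.converged or abs(res.params[1]) > 50:
        return None
    return float(res.params[1])


def validate_results(
    results,
    B: int = 1000,
    seed: int = 0,
    frac: float = CALIBRATION_SPAN,
    resampler: Optional[Callable[[int, np.random.Generator, int], np.ndarray]] = None,
) -> ValidationReport:
    """Bootstrap optimism correction of a fitted :class:`FallRiskResults`.

    ``resampler(b, rng, n)`` may override the with-replacement resampling
    (used to verify degenerate behaviour). Non-converged resamples are
    skipped and counted; the report is flagged unstable when more than 5%
    fail. Deterministic given ``(B, seed)``.
    """
    from .discrimination import auc as roc_auc

    if not results.converged:
        raise DataError("model must converge on the full data before validation")
    if B < 50:
        warnings.warn("B < 50 gives an unreliable optimism estimate")

    data = results.model.data
    n = len(data)
    y = results.outcome
    p_orig = results.predicted

    apparent_c = roc_auc(p_orig, y).auc
    apparent_curve, _ = _lowess_at(p_orig, p_orig, y, frac)

    rng = np.random.default_rng(seed)
    optimisms, slopes = [], []
    cal_optimism = np.zeros(n)
    n_cal = 0
    n_nonconverged = 0
    for b in range(B):
        idx = resampler(b, rng, n) if resampler else rng.integers(0, n, size=n)
        boot = data.iloc[idx].reset_index(drop=True)
        refit = _refit(results, boot)
        if refit is None:
            n_nonconverged += 1
            continue
        y_boot = refit.outcome
        p_boot = refit.predicted
        c_boot = roc_auc(p_boot, y_boot).auc
        p_on_orig = refit.predict(data)
        c_orig = roc_auc(p_on_orig, y).auc
        optimisms.append(c_boot - c_orig)

        slope = _slope_on(refit.linear_predictor(data), y)
        if slope is not None:
            slopes.append(slope)

        curve_boot, _ = _lowess_at(p_orig, p_boot, y_boot, frac)
        curve_orig, _ = _lowess_at(p_orig, p_on_orig, y, frac)
        cal_optimism += curve_boot - curve_orig
        n_cal += 1

    if not optimisms:
        raise DataError("no bootstrap resample converged")
    optimism = float(np.mean(optimisms))
    corrected_curve = apparent_curve - cal_optimism / max(n_cal, 1)
    ae = np.abs(corrected_curve - p_orig)

    return ValidationReport(
        model_id=results.spec.model_id,
        apparent_c=float(apparent_c),
        optimism=optimism,
        corrected_c=float(apparent_c - optimism),
        calibration_slope=float(np.mean(slopes)) if slopes else float("nan"),
        mae=float(ae.mean()),
        median_ae=float(np.quantile(ae, 0.5)),
        q90_ae=float(np.quantile(ae, 0.9)),
        B=B,
        seed=seed,
        n_nonconverged=n_nonconverged,
        unstable=n_nonconverged > 0.05 * B,
    )


def validate_model(
    model_id: str,
    cohort,
    scores: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    **kwargs,
) -> ValidationReport:
    """Fit a named model on a cohort and bootstrap-validate it."""
    from .model import FallRiskModel

    results = FallRiskModel.from_cohort(cohort, scores, model_id).fit()
    return validate_results(results, B=B, seed=seed, **kwargs)
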