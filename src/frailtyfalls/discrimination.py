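"""ROC discrimination and risk-reclassification metrics.

* :func:`auc` — AUROC by pair counting (Mann-Whitney statistic with half
  credit for ties), its DeLong standard error, and the ROC curve whose
  trapezoidal integral equals the pair statistic.
* :func:`delong_compare` — paired comparison of two correlated AUROCs via
  the DeLong placement-value covariance and a two-sided normal test.
* :func:`continuous_nri` / :func:`idi` — category-free net reclassification
  improvement and integrated discrimination improvement with asymptotic
  standard errors; exact ties in predicted risk count for neither direction.
* :func:`optimal_cutoff` — Youden-index (sensitivity + specificity - 1)
  cutpoint search over observed score midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

from .errors import DataError

Z95 = 1.959964


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise DataError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise DataError("both outcome classes must be present")
    return labels


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components.

    Returns ``(auc, v01, v10)`` where ``v01`` are the event placements
    (length n_pos) and ``v10`` the non-event placements (length n_neg),
    computed with midranks so score ties receive half credit.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = rankdata(np.concatenate([pos, neg]), method="average")
    tx = rankdata(pos, method="average")
    ty = rankdata(neg, method="average")
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    auc_value = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return auc_value, v01, v10


@dataclass(frozen=True)
class RocResult:
    """AUROC with DeLong standard error, CI, and the ROC curve points."""

    auc: float
    se: float
    ci: tuple
    curve: tuple  # (fpr, tpr)
    n_pos: int
    n_neg: int


def auc(scores, labels) -> RocResult:
    """AUROC by pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if np.isnan(scores).any():
        raise DataError("scores contain NaN")
    auc_value, v01, v10 = _placements(scores, labels)
    m, n = len(v01), len(v10)
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v10, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(
        auc=float(auc_value),
        se=se,
        ci=(float(auc_value - Z95 * se), float(auc_value + Z95 * se)),
        curve=(fpr, tpr),
        n_pos=m,
        n_neg=n,
    )


@dataclass(frozen=True)
class DelongComparison:
    """Paired DeLong comparison of two AUROCs on the same subjects."""

    auc_a: float
    auc_b: float
    delta: float  # auc_b - auc_a
    z: float
    p: float
    cov: np.ndarray  # 2x2 covariance of (auc_a, auc_b)
    ci_a: tuple
    ci_b: tuple
    degenerate: bool = False


def delong_compare(scores_a, scores_b, labels) -> DelongComparison:
    """Compare two paired AUROCs with the DeLong covariance estimator."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if len(scores_a) != len(scores_b) or len(scores_a) != len(labels):
        raise DataError("paired scores and labels must have equal length")

    auc_a, v01_a, v10_a = _placements(scores_a, labels)
    auc_b, v01_b, v10_b = _placements(scores_b, labels)
    m, n = len(v01_a), len(v10_a)

    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s01 / m + s10 / n

    delta = auc_b - auc_a
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_delta <= 0:
        return DelongComparison(
            auc_a=float(auc_a),
            auc_b=float(auc_b),
            delta=float(delta),
            z=0.0,
            p=1.0,
            cov=cov,
            ci_a=_wald_ci(auc_a, cov[0, 0]),
            ci_b=_wald_ci(auc_b, cov[1, 1]),
            degenerate=True,
        )
    z = delta / np.sqrt(var_delta)
    p = 2 * norm.sf(abs(z))
    return DelongComparison(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        delta=float(delta),
        z=float(z),
        p=float(p),
        cov=cov,
        ci_a=_wald_ci(auc_a, cov[0, 0]),
        ci_b=_wald_ci(auc_b, cov[1, 1]),
    )


def _wald_ci(est, var):
    se = np.sqrt(max(var, 0.0))
    return (float(est - Z95 * se), float(est + Z95 * se))


# ---------------------------------------------------------------------------
# Reclassification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NriResult:
    """Category-free net reclassification improvement."""

    nri: float
    nri_events: float
    nri_nonevents: float
    se: float
    ci: tuple
    p: float


@dataclass(frozen=True)
class IdiResult:
    """Integrated discrimination improvement."""

    idi: float
    se: float
    ci: tuple
    p: float


@dataclass(frozen=True)
class ReclassResult:
    nri: NriResult
    idi: IdiResult


def _check_probs(p_old, p_new, labels):
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    labels = _check_labels(labels)
    if len(p_old) != len(p_new) or len(p_old) != len(labels):
        raise DataError("p_old, p_new and labels must have equal length")
    if ((p_old < 0) | (p_old > 1) | (p_new < 0) | (p_new > 1)).any():
        raise DataError("probabilities must lie in [0, 1]")
    return p_old, p_new, labels


def continuous_nri(
    p_old,
    p_new,
    labels,
    bootstrap: Optional[int] = None,
    seed: Optional[int] = None,
) -> NriResult:
    """Category-free NRI of the new model over the old.

    ``nri_events`` is P(up | event) - P(down | event) and
    ``nri_nonevents`` is P(down | non-event) - P(up | non-event); exact
    ties count for neither direction. The default CI is asymptotic; with
    ``bootstrap=B`` a percentile bootstrap CI replaces it.
    """
    p_old, p_new, labels = _check_probs(p_old, p_new, labels)
    ev, ne = labels == 1, labels == 0
    up, down = p_new > p_old, p_new < p_old

    def _components(ev_mask, ne_mask):
        n_e, n_n = ev_mask.sum(), ne_mask.sum()
        e = (up[ev_mask].mean() - down[ev_mask].mean()) if n_e else 0.0
        v = (down[ne_mask].mean() - up[ne_mask].mean()) if n_n else 0.0
        return float(e), float(v)

    nri_e, nri_ne = _components(ev, ne)
    nri = nri_e + nri_ne

    n_e, n_n = int(ev.sum()), int(ne.sum())
    pe_up, pe_dn = up[ev].mean(), down[ev].mean()
    pn_up, pn_dn = up[ne].mean(), down[ne].mean()
    var = (pe_up + pe_dn - (pe_up - pe_dn) ** 2) / n_e + (
        pn_dn + pn_up - (pn_dn - pn_up) ** 2
    ) / n_n
    se = float(np.sqrt(max(var, 0.0)))
    p = 2 * norm.sf(abs(nri) / se) if se > 0 else 1.0
    ci = (nri - Z95 * se, nri + Z95 * se)

    if bootstrap:
        rng = np.random.default_rng(seed)
        idx_e, idx_n = np.flatnonzero(ev), np.flatnonzero(ne)
        reps = np.empty(bootstrap)
        for b in range(bootstrap):
            be = rng.choice(idx_e, size=n_e, replace=True)
            bn = rng.choice(idx_n, size=n_n, replace=True)
            e_b = float(up[be].mean() - down[be].mean())
            v_b = float(down[bn].mean() - up[bn].mean())
            reps[b] = e_b + v_b
        ci = tuple(np.quantile(reps, [0.025, 0.975]))

    return NriResult(
        nri=float(nri),
        nri_events=nri_e,
        nri_nonevents=nri_ne,
        se=se,
        ci=(float(ci[0]), float(ci[1])),
        p=float(p),
    )


def idi(p_old, p_new, labels) -> IdiResult:
    """IDI: change in the discrimination slope, new model minus old."""
    p_old, p_new, labels = _check_probs(p_old, p_new, labels)
    d = p_new - p_old
    d_e, d_n = d[labels == 1], d[labels == 0]
    value = float(d_e.mean() - d_n.mean())
    var = (np.var(d_e, ddof=1) / len(d_e) if len(d_e) > 1 else 0.0) + (
        np.var(d_n, ddof=1) / len(d_n) if len(d_n) > 1 else 0.0
    )
    se = float(np.sqrt(var))
    p = 2 * norm.sf(abs(value) / se) if se > 0 else 1.0
    return IdiResult(
        idi=value,
        se=se,
        ci=(value - Z95 * se, value + Z95 * se),
        p=float(p),
    )


def reclassification(p_old, p_new, labels, **nri_kwargs) -> ReclassResult:
    """NRI and IDI of a new risk model over an old one on the same subjects."""
    return ReclassResult(
        nri=continuous_nri(p_old, p_new, labels, **nri_kwargs),
        idi=idi(p_old, p_new, labels),
    )


# ---------------------------------------------------------------------------
# Cutpoint search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden: float


def optimal_cutoff(scores, labels) -> CutoffResult:
    """Youden-optimal cutpoint over midpoints of the observed scores.

    A subject is test-positive when its score strictly exceeds the cutoff.
    Ties on the Youden index break toward the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)

    uniq = np.unique(scores)
    if len(uniq) == 1:
        return CutoffResult(
            cutoff=float(uniq[0]), sensitivity=0.0, specificity=1.0, youden=0.0
        )
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    pos, neg = scores[labels == 1], scores[labels == 0]
    sens = (pos[None, :] > candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] <= candidates[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (lowest) maximiser
    return CutoffResult(
        cutoff=float(candidates[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden=float(j[best]),
    )
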