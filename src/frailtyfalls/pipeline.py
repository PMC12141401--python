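"""End-to-end study pipeline.

Orchestrates the full analysis on either a simulated or an ingested
cohort: exclusions -> score computation -> baseline descriptives ->
logistic model suite -> discrimination/reclassification comparisons ->
bootstrap internal validation, writing a deterministic report bundle of
CSV tables plus a JSON run manifest.

Numbers are written at full precision in the machine-readable tables; the
formatting layer (percentages to one decimal, ORs/AUCs to two or three
decimals) only touches the human-readable columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import __version__
from .cohort import (
    CohortTable,
    ReferencePanel,
    apply_exclusions,
    default_item_ids,
    load_item_ids,
    read_cohort,
)
from .discrimination import optimal_cutoff
from .errors import FrailtyFallsError
from .model import FallRiskModel, run_model_suite, subgroup_suite
from .scores import compute_scores
from .simulate import SimConfig, generate_cohort
from .validation import validate_model

DEFAULT_COMPARISONS = (("m1", "m2"), ("m1", "m3"), ("m1", "m4"), ("m1", "m5"), ("m1", "m6"))

#: terms that count as "containing the reference score" for NRI/IDI
_STRATIFY_TERMS = ("stratify", "stratify_plus_filab")


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    input: Union[SimConfig, str]
    seed: int
    panel: Optional[str] = None
    item_set: Optional[str] = None
    models: Sequence[str] = tuple(f"m{i}" for i in range(1, 7))
    comparisons: Sequence[tuple] = DEFAULT_COMPARISONS
    B: int = 1000
    subgroups: bool = False
    sensitivity: dict = field(default_factory=dict)
    filab_cutoff: float = 0.4
    plot: bool = False

    def __post_init__(self):
        models = set(self.models)
        for ref, new in self.comparisons:
            if ref not in models or new not in models:
                raise FrailtyFallsError(
                    f"comparison ({ref}, {new}) references a model not in `models`"
                )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if isinstance(raw.get("input"), dict):
            sim = dict(raw["input"])
            if "outcome_model" in sim:
                from .simulate import OutcomeModel

                sim["outcome_model"] = OutcomeModel(**sim["outcome_model"])
            raw["input"] = SimConfig(**sim)
        if "comparisons" in raw:
            raw["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
        return cls(**raw)

    def digest(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def descriptives(cohort: CohortTable, scores: pd.DataFrame):
    """Baseline characteristics table and Spearman correlation table.

    Continuous variables report mean +/- SD and median (IQR, linear-
    interpolation quantiles); binaries report count (%). Returns
    ``(table1, correlations)`` DataFrames.
    """
    adm = cohort.admissions
    n = len(adm)
    rows = []

    def cont(name, values):
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])
        rows.append(
            {
                "variable": name,
                "kind": "continuous",
                "mean": values.mean(),
                "sd": values.std(ddof=1) if len(values) > 1 else 0.0,
                "median": q2,
                "q1": q1,
                "q3": q3,
                "count": np.nan,
                "pct": np.nan,
                "display": f"{values.mean():.2f} ± {values.std(ddof=1) if len(values) > 1 else 0.0:.2f}; "
                f"{q2:g} ({q1:g}-{q3:g})",
            }
        )

    def binary(name, mask):
        count = int(np.asarray(mask).sum())
        pct = 100.0 * count / n
        rows.append(
            {
                "variable": name,
                "kind": "binary",
                "mean": np.nan,
                "sd": np.nan,
                "median": np.nan,
                "q1": np.nan,
                "q3": np.nan,
                "count": count,
                "pct": pct,
                "display": f"{count} ({pct:.1f}%)",
            }
        )

    binary("participants", np.ones(n, dtype=bool))
    cont("age", adm["age"])
    binary("male_sex", adm["sex"] == "male")
    binary("emergency", adm["emergency"])
    cont("stratify", scores["stratify"])
    for item in (
        "history_of_falls",
        "mental_status",
        "vision",
        "toileting",
        "mobility",
    ):
        binary(f"stratify_{item}", adm[item])
    cont("fi_lab", scores["fi_lab"])
    cont("measured_ratio", scores["measured_ratio"])
    cont("fi_clinical", scores["fi_clinical"])
    cont("polypharmacy", scores["polypharmacy"])
    cont("cci", scores["cci"])
    for band in ("low", "mid", "high"):
        binary(f"fi_lab_band_{band}", scores["fi_lab_band"] == band)
    binary("in_hospital_falls", adm["fell"])

    table1 = pd.DataFrame(rows)

    pairs = [
        ("fi_lab", "age"),
        ("fi_lab", "cci"),
        ("fi_lab", "stratify"),
        ("fi_lab", "fi_clinical"),
        ("stratify", "fi_clinical"),
    ]
    frame = pd.DataFrame(
        {
            "age": adm["age"].to_numpy(dtype=float),
            "cci": scores["cci"].to_numpy(dtype=float),
            "stratify": scores["stratify"].to_numpy(dtype=float),
            "fi_lab": scores["fi_lab"].to_numpy(dtype=float),
            "fi_clinical": scores["fi_clinical"].to_numpy(dtype=float),
        }
    )
    corr_rows = []
    for a, b in pairs:
        ok = frame[[a, b]].notna().all(axis=1)
        rho, p = spearmanr(frame.loc[ok, a], frame.loc[ok, b])
        corr_rows.append({"var_a": a, "var_b": b, "rho": float(rho), "p": float(p)})
    return table1, pd.DataFrame(corr_rows)


# ---------------------------------------------------------------------------
# Study runner
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig, out_dir) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory results (cohort, flow, scores,
    suite, comparisons, validation) and the paths written. Raises on stage
    failure after writing stage-level diagnostics to the run log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg):
        log_lines.append(msg)

    try:
        bundle = _run_stages(config, out, log)
        log("status: complete")
    except Exception as exc:
        log(f"status: partial - {type(exc).__name__}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
        raise
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return bundle


def _run_stages(config: StudyConfig, out: Path, log) -> dict:
    panel = ReferencePanel.from_yaml(config.panel) if config.panel else ReferencePanel.default()
    item_ids = load_item_ids(config.item_set) if config.item_set else default_item_ids()

    # stage: input
    if isinstance(config.input, SimConfig):
        raw = generate_cohort(config.input, panel=panel, item_ids=item_ids)
        log(f"input: simulated cohort n={len(raw)} (seed={config.input.seed})")
    else:
        raw = read_cohort(config.input, panel, item_ids=item_ids)
        log(f"input: read {len(raw)} admissions from {config.input}")

    # stage: exclusions
    cohort, flow = apply_exclusions(raw)
    log(
        "exclusions: raw={raw} readmission_only={readmission_only} "
        "insufficient_labs_only={insufficient_labs_only} both={both} "
        "included={included}".format(**flow.as_dict())
    )
    pd.DataFrame([flow.as_dict()]).to_csv(out / "exclusion_flow.csv", index=False)

    # stage: scores
    scores = compute_scores(cohort, filab_cutoff=config.filab_cutoff)
    scores.to_csv(out / "scores.csv", index=False)
    events = int(cohort.admissions["fell"].sum())
    fall_rate = 100.0 * events / len(cohort)
    log(f"scores: n={len(cohort)} events={events} fall_rate={fall_rate:.1f}%")

    # stage: descriptives
    table1, correlations = descriptives(cohort, scores)
    table1.to_csv(out / "table1.csv", index=False)
    correlations.to_csv(out / "correlations.csv", index=False)

    # stage: models
    suite = run_model_suite(cohort, scores, models=list(config.models))
    or_rows = []
    for model_id, res in suite.items():
        if res is None:
            continue
        tab = res.odds_ratios()
        tab.insert(0, "model", model_id)
        tab["n"] = res.n
        tab["events"] = res.events
        tab["epv"] = res.epv
        tab["converged"] = res.converged
        or_rows.append(tab)
    table2 = pd.concat(or_rows, ignore_index=True)
    table2.to_csv(out / "table2.csv", index=False)
    if "m2" in suite and suite["m2"] is not None:
        log(f"models: primary model EPV = {suite['m2'].epv:.1f}")

    # stage: comparisons
    comp_rows = []
    for ref_id, new_id in config.comparisons:
        ref, new = suite.get(ref_id), suite.get(new_id)
        if ref is None or new is None or not (ref.converged and new.converged):
            log(f"comparison ({ref_id},{new_id}): skipped (unfit model)")
            continue
        with_reclass = any(t in _STRATIFY_TERMS for t in new.spec.predictors)
        cmp_ = new.compare(ref, reclass=with_reclass)
        row = {
            "reference": ref_id,
            "model": new_id,
            "auc_ref": cmp_.delong.auc_a,
            "auc": cmp_.delong.auc_b,
            "auc_ci_low": cmp_.delong.ci_b[0],
            "auc_ci_high": cmp_.delong.ci_b[1],
            "delta_auc": cmp_.delong.delta,
            "delong_p": cmp_.delong.p,
        }
        if cmp_.reclass is not None:
            nri, idi_ = cmp_.reclass.nri, cmp_.reclass.idi
            row.update(
                nri=nri.nri,
                nri_events=nri.nri_events,
                nri_nonevents=nri.nri_nonevents,
                nri_ci_low=nri.ci[0],
                nri_ci_high=nri.ci[1],
                nri_p=nri.p,
                idi=idi_.idi,
                idi_ci_low=idi_.ci[0],
                idi_ci_high=idi_.ci[1],
                idi_p=idi_.p,
            )
        else:  # reference score absent from the new model
            row.update({k: "n/a" for k in (
                "nri", "nri_events", "nri_nonevents", "nri_ci_low",
                "nri_ci_high", "nri_p", "idi", "idi_ci_low", "idi_ci_high",
                "idi_p",
            )})
        comp_rows.append(row)
    table3 = pd.DataFrame(comp_rows)
    table3.to_csv(out / "table3.csv", index=False)

    # stage: validation
    val_rows = []
    for model_id in config.models:
        res = suite.get(model_id)
        if res is None or not res.converged:
            continue
        report = validate_model(
            model_id, cohort, scores, B=config.B, seed=config.seed
        )
        val_rows.append(report.as_dict())
    validation_table = pd.DataFrame(val_rows)
    validation_table.to_csv(out / "validation.csv", index=False)

    # stage: subgroups / sensitivity
    extras = {}
    if config.subgroups:
        sub_rows = []
        for strata in ("age", "sex"):
            for name, entry in subgroup_suite(
                cohort, scores, strata, models=["m1", "m2"]
            ).items():
                for model_id, res in entry["suite"].items():
                    if res is None or not res.converged:
                        continue
                    sub_rows.append(
                        {
                            "stratum": name,
                            "model": model_id,
                            "n": entry["n"],
                            "events": res.events,
                            "auc": res.roc().auc,
                        }
                    )
        extras["subgroups"] = pd.DataFrame(sub_rows)
        extras["subgroups"].to_csv(out / "subgroups.csv", index=False)
    if config.sensitivity.get("cutoff_scan"):
        ok = scores["fi_lab"].notna()
        cut = optimal_cutoff(
            scores.loc[ok, "fi_lab"], cohort.admissions.loc[ok, "fell"].astype(int)
        )
        pd.DataFrame([dataclasses.asdict(cut)]).to_csv(
            out / "cutoff_scan.csv", index=False
        )
        extras["cutoff_scan"] = cut
        log(f"cutoff scan: Youden-optimal FI-lab cutoff = {cut.cutoff:.3f}")
    adjust = [t for t in ("polypharmacy", "cci") if config.sensitivity.get(t)]
    if adjust:
        adj_rows = []
        for term in adjust:
            res = FallRiskModel.from_cohort(cohort, scores, "m2", adjust=(term,)).fit()
            tab = res.odds_ratios()
            tab.insert(0, "model", res.spec.model_id)
            adj_rows.append(tab)
        extras["sensitivity_adjusted"] = pd.concat(adj_rows, ignore_index=True)
        extras["sensitivity_adjusted"].to_csv(out / "sensitivity.csv", index=False)

    if config.plot:
        _roc_plot(suite, out / "roc.svg")

    manifest = {
        "package": "frailtyfalls",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "B": config.B,
        "n_raw": len(raw),
        "n_included": len(cohort),
        "events": events,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    return {
        "cohort": cohort,
        "flow": flow,
        "scores": scores,
        "table1": table1,
        "correlations": correlations,
        "suite": suite,
        "table2": table2,
        "table3": table3,
        "validation": validation_table,
        "manifest": manifest,
        "out_dir": out,
        **extras,
    }


def _roc_plot(suite, path):
    import matplotlib

    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "frailtyfalls"  # deterministic ids
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for model_id in ("m1", "m3"):
        res = suite.get(model_id)
        if res is None or not res.converged:
            continue
        roc = res.roc()
        ax.plot(*roc.curve, label=f"{model_id} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
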