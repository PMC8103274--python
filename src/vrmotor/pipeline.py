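"""End-to-end orchestration: simulate -> score -> quantify -> analyze -> report.

The analysis layer (:func:`analyze_cohort`) is pure and in-memory; the
pipeline (:func:`run_pipeline`) adds deterministic on-disk artifacts: a
cohort CSV, per-patient trace/trajectory/log CSVs, feature CSVs, and a
machine-readable (JSON) plus human-readable (Markdown) evaluation report
whose regeneration under the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .errors import AnalysisError, VRMotorError
from .features import clinical_table, spect_feature_table, vr_feature_table
from .spect import DEFAULT_Z_THRESHOLD, abnormality_filter
from .stats import (
    compare_auc,
    fit_logistic,
    fit_svm_classifier,
    fit_svm_regressor,
    laterality_ttest,
)
from .synthetic import CohortConfig, generate_cohort
from .vr_scoring import SpillRule

log = logging.getLogger("vrmotor")


class StageError(VRMotorError):
    """A pipeline stage failed; the message names the stage (and patient)."""


@dataclass(frozen=True)
class AnalysisParams:
    """Every tunable knob of the scoring + statistics layers."""

    tilt_threshold_deg: float = 30.0
    drain_s: float = 0.25
    time_mode: str = "mean"
    trim_s: float = 3.0
    segment_len: int = 256
    overlap: float = 0.5
    window: str = "hann"
    band: tuple[float, float] = (0.5, 12.0)
    noise_floor: float = 0.0
    log_power: bool = True
    z_threshold: float = DEFAULT_Z_THRESHOLD
    ttest_mode: str = "two_sample"
    svm_c: float = 1.0
    svr_epsilon: float = 0.1
    cv_folds: int = 5
    holdout_frac: float = 0.30
    vr_missing_rate: float = 16 / 44
    analysis_seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: a cohort source plus all analysis parameters."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    out_dir: str = "vrmotor_run"
    write_traces: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cohort_raw = raw.get("cohort", {})
        for key in ("updrs_link", "vr_effect", "spect_effect"):
            if key in cohort_raw and isinstance(cohort_raw[key], dict):
                sub_cls = type(getattr(CohortConfig(), key))
                cohort_raw[key] = sub_cls(**cohort_raw[key])
        for tup_key in ("age_range",):
            if tup_key in cohort_raw:
                cohort_raw[tup_key] = tuple(cohort_raw[tup_key])
        params_raw = dict(raw.get("params", {}))
        if "band" in params_raw:
            params_raw["band"] = tuple(params_raw["band"])
        return cls(
            cohort=CohortConfig(**cohort_raw),
            params=AnalysisParams(**params_raw),
            out_dir=raw.get("out_dir", "vrmotor_run"),
            write_traces=bool(raw.get("write_traces", True)),
        )


def _to_native(obj):
    """Recursively convert numpy scalars/arrays for JSON serialisation."""
    if isinstance(obj, dict):
        return {str(k): _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    return obj


@dataclass
class EvalReport:
    """Structured evaluation mirroring the five study tables."""

    table1: dict
    table2: dict
    table3: dict
    table4: dict
    table5: dict
    exclusions: dict
    params: dict
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _to_native(
            {
                "table1_cohort": self.table1,
                "table2_laterality": self.table2,
                "table3_classification": self.table3,
                "table4_logistic": self.table4,
                "table5_regression": self.table5,
                "exclusions": self.exclusions,
                "params": self.params,
                "extras": self.extras,
            }
        )


def _mean_sd(values) -> dict:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {"mean": None, "sd": None, "n": 0}
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "n": int(v.size),
    }


def _table1(clin: pd.DataFrame) -> dict:
    n = len(clin)
    updrs = clin["updrs3"].astype(float)
    return {
        "n": n,
        "male": int(clin["male"].sum()),
        "female": int(n - clin["male"].sum()),
        "age": {**_mean_sd(clin["age"]), "range": [float(clin["age"].min()), float(clin["age"].max())]},
        "updrs3": {**_mean_sd(updrs), "range": [float(updrs.min()), float(updrs.max())]},
        "updrs3_gt10": int(clin["cid"].sum()),
        "pd_meds": int(clin["pd_meds"].sum()),
        "right_handed": int(clin["right_handed"].sum()),
        "hy": _mean_sd(clin["hy"]),
        "moca": _mean_sd(clin["moca"]),
    }


#: (label, right column, left column) pairs for the laterality table
LATERALITY_VARS = [
    ("spect_striatum_sbr", "sbr_striatum_right", "sbr_striatum_left"),
    ("spect_caudate_sbr", "sbr_caudate_right", "sbr_caudate_left"),
    ("spect_putamen_sbr", "sbr_putamen_right", "sbr_putamen_left"),
    ("spect_pc_ratio", "pc_ratio_right", "pc_ratio_left"),
    ("vr_time_s", "vr_time_right", "vr_time_left"),
    ("vr_adl_score", "vr_adl_right", "vr_adl_left"),
    ("vr_posture_freq_hz", "posture_freq_right", "posture_freq_left"),
    ("vr_posture_power", "posture_power_right", "posture_power_left"),
    ("vr_rest_freq_hz", "rest_freq_right", "rest_freq_left"),
    ("vr_rest_power", "rest_power_right", "rest_power_left"),
]


def _table2(vr_raw: pd.DataFrame, spect: pd.DataFrame, mode: str) -> dict:
    merged = spect.join(vr_raw, how="outer")
    out = {}
    for label, rcol, lcol in LATERALITY_VARS:
        if rcol not in merged.columns:
            continue
        right = merged[rcol].dropna()
        left = merged[lcol].dropna()
        entry = {"right": _mean_sd(right), "left": _mean_sd(left)}
        if len(right) >= 2 and len(left) >= 2:
            if mode == "paired":
                both = merged[[lcol, rcol]].dropna()
                res = laterality_ttest(both[lcol], both[rcol], mode="paired")
            else:
                res = laterality_ttest(left, right, mode=mode)
            entry["t"] = res.t
            entry["p"] = res.p
        out[label] = entry
    return out


def _roc_dict(ev) -> dict:
    return {
        "auc": ev.roc.auc,
        "auc_se": ev.roc.auc_se,
        "ci95": list(ev.roc.ci95),
        "n_pos": ev.roc.n_pos,
        "n_neg": ev.roc.n_neg,
    }


def analyze_cohort(patients, params: AnalysisParams = AnalysisParams()) -> EvalReport:
    """Run the full statistical comparison on an in-memory cohort.

    Stages: SPECT abnormality gate; missing-completely-at-random VR dropout;
    VR scoring (trial-2 tremor spectra, slicing times, ADL spills); laterality
    t-tests; linear SVM classification of the CID label (resubstitution and
    stratified K-fold) for VR, SPECT and SPECT+medication feature sets with
    correlated-AUC comparisons against VR; logistic regression; and linear
    SVM regression of UPDRS-III with a stratified hold-out.
    """
    measures = {p.record.patient_id: p.measures for p in patients}
    try:
        included, excluded = abnormality_filter(measures, params.z_threshold)
    except AnalysisError as exc:
        raise StageError(f"quantify: {exc}") from exc
    enrolled = [p for p in patients if p.record.patient_id in set(included)]
    if not enrolled:
        raise StageError("quantify: every scan was normal; nothing to analyze")
    log.info("abnormality gate: %d generated, %d enrolled, %d excluded (normal scans: %s)",
             len(patients), len(enrolled), len(excluded), excluded)

    rng = np.random.default_rng(params.analysis_seed)
    missing_mask = rng.random(len(enrolled)) < params.vr_missing_rate
    vr_missing_ids = [p.record.patient_id for p, m in zip(enrolled, missing_mask) if m]
    vr_patients = [p for p, m in zip(enrolled, missing_mask) if not m]
    log.info("VR dropout (MCAR %.2f): %d of %d without VR data: %s",
             params.vr_missing_rate, len(vr_missing_ids), len(enrolled), vr_missing_ids)

    try:
        vr_raw = vr_feature_table(
            vr_patients,
            tilt_threshold_deg=params.tilt_threshold_deg,
            spill_rule=SpillRule(params.drain_s),
            time_mode=params.time_mode,
            trim_s=params.trim_s,
            segment_len=params.segment_len,
            overlap=params.overlap,
            window=params.window,
            band=params.band,
            noise_floor=params.noise_floor,
            log_power=False,
        )
    except (AnalysisError, VRMotorError) as exc:
        raise StageError(f"score: {exc}") from exc
    vr_model = vr_raw.copy()
    if params.log_power:
        for col in vr_model.columns:
            if "_power_" in col:
                vr_model[col] = np.log10(vr_model[col] + 1e-12)

    spect_feats = spect_feature_table(
        {p.record.patient_id: p.measures for p in enrolled}
    )
    clin = clinical_table([p.record for p in enrolled])
    labels_all = clin["cid"].astype(int)

    report_params = {
        **dataclasses.asdict(params),
        "band": list(params.band),
    }
    table1 = _table1(clin)
    table2 = _table2(vr_raw, spect_feats, params.ttest_mode)

    # --- classification -----------------------------------------------------
    vr_X = vr_model.dropna()
    vr_y = labels_all.loc[vr_X.index]
    spect_X = spect_feats.dropna()
    spect_y = labels_all.loc[spect_X.index]
    spect_meds_X = spect_X.join(clin["pd_meds"].astype(float))

    try:
        vr_resub = fit_svm_classifier(vr_X, vr_y, cv_folds=0, seed=params.analysis_seed, C=params.svm_c)
        vr_cv = fit_svm_classifier(vr_X, vr_y, cv_folds=params.cv_folds, seed=params.analysis_seed, C=params.svm_c)
        spect_cv = fit_svm_classifier(spect_X, spect_y, cv_folds=params.cv_folds, seed=params.analysis_seed, C=params.svm_c)
        spect_meds_cv = fit_svm_classifier(spect_meds_X, spect_y, cv_folds=params.cv_folds, seed=params.analysis_seed, C=params.svm_c)
    except AnalysisError as exc:
        raise StageError(f"analyze/classification: {exc}") from exc

    vr_scores = pd.Series(vr_cv.scores, index=vr_X.index)
    spect_scores = pd.Series(spect_cv.scores, index=spect_X.index)
    spect_meds_scores = pd.Series(spect_meds_cv.scores, index=spect_X.index)
    common = vr_scores.index.intersection(spect_scores.index)
    table3 = {
        "vr_no_cv": _roc_dict(vr_resub),
        "vr": _roc_dict(vr_cv),
        "spect": _roc_dict(spect_cv),
        "spect_meds": _roc_dict(spect_meds_cv),
    }
    y_common = labels_all.loc[common]
    if y_common.nunique() == 2 and len(common) >= 4:
        for name, other in (("spect", spect_scores), ("spect_meds", spect_meds_scores)):
            cmp = compare_auc(vr_scores.loc[common], other.loc[common], y_common)
            table3[name]["p_vs_vr"] = cmp.p
            table3[name]["auc_diff_vs_vr_common"] = cmp.diff
    roc_curves = {
        name: {"fpr": list(ev.roc.fpr), "tpr": list(ev.roc.tpr)}
        for name, ev in (
            ("vr_no_cv", vr_resub),
            ("vr", vr_cv),
            ("spect", spect_cv),
            ("spect_meds", spect_meds_cv),
        )
    }

    # --- logistic regression ------------------------------------------------
    table4: dict = {}
    logit_ids = common
    design = pd.DataFrame(
        {
            "age": clin["age"].astype(float),
            "male": clin["male"].astype(float),
            "right_hand_dominance": clin["right_handed"].astype(float),
            "pd_meds": clin["pd_meds"].astype(float),
        }
    ).loc[logit_ids]
    design["vr_svm_score"] = vr_scores.loc[logit_ids]
    design["spect_svm_score"] = spect_scores.loc[logit_ids]
    dropped_const = [c for c in design.columns if design[c].nunique() <= 1]
    design = design.drop(columns=dropped_const)
    try:
        fit = fit_logistic(design, labels_all.loc[logit_ids])
        table4 = {
            "features": {
                str(k): {
                    "beta": float(fit.table.loc[k, "beta"]),
                    "se": float(fit.table.loc[k, "se"]),
                    "odds_ratio": float(fit.table.loc[k, "odds_ratio"]),
                    "p_value": float(fit.table.loc[k, "p_value"]),
                }
                for k in fit.table.index
            },
            "n": int(len(logit_ids)),
            "converged": fit.converged,
            "separation": fit.separation,
            "dropped_constant_columns": dropped_const,
        }
    except AnalysisError as exc:
        table4 = {"error": str(exc), "dropped_constant_columns": dropped_const}

    # --- SVM regression of UPDRS-III ---------------------------------------
    updrs = clin["updrs3"].astype(float)
    table5 = {}
    scatter = {}
    for name, X in (
        ("vr", vr_model),
        ("spect", spect_feats),
        ("spect_meds", spect_feats.join(clin["pd_meds"].astype(float))),
    ):
        try:
            ev = fit_svm_regressor(
                X,
                updrs.loc[X.index],
                holdout_frac=params.holdout_frac,
                seed=params.analysis_seed,
                C=params.svm_c,
                epsilon=params.svr_epsilon,
            )
        except AnalysisError as exc:
            raise StageError(f"analyze/regression[{name}]: {exc}") from exc
        table5[name] = {
            "mse": ev.mse_resub,
            "n_dropped_missing": ev.n_dropped_missing,
            **{
                s.split: {
                    "n": s.n,
                    "r_squared": s.r_squared,
                    "p_value": s.p_value,
                    "r_squared_sse": s.r_squared_sse,
                }
                for s in ev.splits.values()
            },
        }
        scatter[name] = {
            "observed": list(ev.predictions["observed"]),
            "predicted": list(ev.predictions["predicted_all"]),
        }

    exclusions = {
        "n_generated": len(patients),
        "n_enrolled": len(enrolled),
        "normal_scan_ids": list(excluded),
        "vr_missing_ids": vr_missing_ids,
        "n_vr_complete": len(vr_patients),
    }
    return EvalReport(
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        table5=table5,
        exclusions=exclusions,
        params=report_params,
        extras={"roc_curves": roc_curves, "regression_scatter": scatter},
    )


# ---------------------------------------------------------------------------
# Markdown rendering


def _f(x, digits=4) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return f"{x:.{digits}g}"


def render_markdown(report: EvalReport) -> str:
    d = report.to_dict()
    out = ["# VR motor-dysfunction vs SPECT evaluation report", ""]
    t1 = d["table1_cohort"]
    out += ["## Table 1 - cohort summary", ""]
    out += [f"- Enrolled: {t1['n']} (male {t1['male']}, female {t1['female']})"]
    out += [
        f"- Age: {_f(t1['age']['mean'])} +/- {_f(t1['age']['sd'])} "
        f"({_f(t1['age']['range'][0])}-{_f(t1['age']['range'][1])})"
    ]
    out += [
        f"- UPDRS-III: {_f(t1['updrs3']['mean'])} +/- {_f(t1['updrs3']['sd'])} "
        f"({_f(t1['updrs3']['range'][0])}-{_f(t1['updrs3']['range'][1])}); "
        f">10 in {t1['updrs3_gt10']}/{t1['n']}"
    ]
    out += [f"- PD medication: {t1['pd_meds']}/{t1['n']}; right-handed: {t1['right_handed']}/{t1['n']}"]
    out += [
        f"- H&Y: {_f(t1['hy']['mean'])} +/- {_f(t1['hy']['sd'])}; "
        f"MoCA: {_f(t1['moca']['mean'])} +/- {_f(t1['moca']['sd'])}",
        "",
    ]
    out += ["## Table 2 - laterality (mean +/- SD, Student's t-test)", ""]
    out += ["| variable | right | left | p |", "|---|---|---|---|"]
    for var, e in d["table2_laterality"].items():
        r, l = e["right"], e["left"]
        out += [
            f"| {var} | {_f(r['mean'])} +/- {_f(r['sd'])} (n={r['n']}) "
            f"| {_f(l['mean'])} +/- {_f(l['sd'])} (n={l['n']}) | {_f(e.get('p'))} |"
        ]
    out += ["", "## Table 3 - CID classification (SVM, ROC)", ""]
    out += ["| feature set | AUC | 95% CI | SE | p vs VR |", "|---|---|---|---|---|"]
    for name, e in d["table3_classification"].items():
        ci = e["ci95"]
        out += [
            f"| {name} | {_f(e['auc'])} | ({_f(ci[0])}, {_f(ci[1])}) "
            f"| {_f(e['auc_se'])} | {_f(e.get('p_vs_vr'))} |"
        ]
    out += ["", "## Table 4 - logistic regression for CID", ""]
    t4 = d["table4_logistic"]
    if "features" in t4:
        out += ["| feature | beta | SE | OR | p |", "|---|---|---|---|---|"]
        for name, e in t4["features"].items():
            out += [
                f"| {name} | {_f(e['beta'])} | {_f(e['se'])} "
                f"| {_f(e['odds_ratio'])} | {_f(e['p_value'])} |"
            ]
        out += [
            "",
            f"n = {t4['n']}; converged = {t4['converged']}; "
            f"separation flagged = {t4['separation']}",
        ]
    else:
        out += [f"logistic regression unavailable: {t4.get('error')}"]
    out += ["", "## Table 5 - UPDRS-III regression (SVM)", ""]
    out += [
        "| feature set | MSE (resub) | split | N | R^2 | p |",
        "|---|---|---|---|---|---|",
    ]
    for name, e in d["table5_regression"].items():
        for splitname in ("all", "train", "test"):
            s = e[splitname]
            out += [
                f"| {name} | {_f(e['mse'])} | {splitname} | {s['n']} "
                f"| {_f(s['r_squared'])} | {_f(s['p_value'])} |"
            ]
    ex = d["exclusions"]
    out += [
        "",
        "## Exclusions",
        "",
        f"- Generated: {ex['n_generated']}; enrolled (abnormal scan): {ex['n_enrolled']}",
        f"- Normal scans excluded: {ex['normal_scan_ids']}",
        f"- VR data missing: {ex['vr_missing_ids']}",
        "",
    ]
    return "\n".join(out)


# ---------------------------------------------------------------------------
# disk pipeline


def run_pipeline(config: RunConfig):
    """Simulate, score, quantify, analyze and write the full artifact set.

    Returns (report, out_dir).  Deterministic: identical config (incl. all
    seeds) gives byte-identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        patients = generate_cohort(config.cohort)
    except VRMotorError as exc:
        raise StageError(f"simulate: {exc}") from exc

    vio.write_cohort_csv(patients, out / "cohort.csv")
    if config.write_traces:
        traces_dir = out / "traces"
        traces_dir.mkdir(exist_ok=True)
        for p in patients:
            pid = p.record.patient_id
            for (hand, cond, trial), trace in p.traces.items():
                vio.write_trace_csv(
                    trace, traces_dir / vio.trace_filename(pid, hand, cond, trial)
                )
            for hand, attempts in p.adl.items():
                for a in attempts:
                    vio.write_adl_csv(a, traces_dir / f"{pid}_{hand}_adl{a.attempt_index}.csv")
            for hand, logs in p.slicing.items():
                for s in logs:
                    vio.write_slice_log_csv(
                        s, traces_dir / f"{pid}_{hand}_slice{s.attempt_index}.csv"
                    )

    report = analyze_cohort(patients, config.params)
    vio.write_measures_csv({p.record.patient_id: p.measures for p in patients}, out / "spect_measures.csv")
    write_report(report, out)
    return report, out


def write_report(report: EvalReport, out_dir) -> None:
    out = Path(out_dir)
    vio.write_json(report.to_dict(), out / "report.json")
    (out / "report.md").write_text(render_markdown(report), encoding="utf-8")
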