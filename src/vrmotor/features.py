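"""Assembly of per-patient analysis tables from raw session data.

Bridges the raw modality outputs (kinematic traces, tilt trajectories,
slicing logs, SPECT measures) and the statistical layer: each function
returns a pandas DataFrame indexed by patient id whose columns are the
named features fed to the SVM/logistic models.

Protocol rules enforced here: only the *second* tremor trial per hand and
condition enters the spectral analysis, and each hand contributes exactly
five ADL attempts and two slicing attempts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import tremor
from .errors import AnalysisError
from .vr_scoring import SpillRule, make_hand_summary

ANALYSIS_TRIAL = 2  # second trial per hand/condition is the one analysed

#: floor added before log-transforming spectral powers (m^2/Hz)
POWER_LOG_FLOOR = 1e-12

VR_COLUMNS = [
    "vr_time_left",
    "vr_time_right",
    "vr_adl_left",
    "vr_adl_right",
    "rest_power_left",
    "rest_power_right",
    "rest_freq_left",
    "rest_freq_right",
    "posture_power_left",
    "posture_power_right",
    "posture_freq_left",
    "posture_freq_right",
]

SPECT_COLUMNS = [
    "sbr_striatum_left",
    "sbr_striatum_right",
    "sbr_caudate_left",
    "sbr_caudate_right",
    "sbr_putamen_left",
    "sbr_putamen_right",
    "pc_ratio_left",
    "pc_ratio_right",
]


def patient_vr_features(
    traces: dict,
    adl: dict,
    slicing: dict,
    tilt_threshold_deg: float = 30.0,
    spill_rule: SpillRule = SpillRule(),
    time_mode: str = "mean",
    trim_s: float = tremor.DEFAULT_TRIM_S,
    segment_len: int = 256,
    overlap: float = 0.5,
    window: str = "hann",
    band: tuple[float, float] = tremor.DEFAULT_BAND,
    noise_floor: float = 0.0,
    log_power: bool = True,
) -> dict:
    """All VR-derived features for one patient.

    ``traces`` maps (hand, condition, trial) to a KinematicTrace; only
    trial ``ANALYSIS_TRIAL`` is consumed.  Spectral peak powers are
    log10-transformed by default (they span orders of magnitude, and the
    linear models downstream standardise columns).
    """
    row: dict[str, float] = {}
    for hand in ("left", "right"):
        summary = make_hand_summary(
            hand,
            slicing[hand],
            adl[hand],
            time_mode=time_mode,
            threshold_deg=tilt_threshold_deg,
            spill_rule=spill_rule,
        )
        row[f"vr_time_{hand}"] = summary.vr_time
        row[f"vr_adl_{hand}"] = summary.vr_adl_score
        for cond in ("rest", "posture"):
            key = (hand, cond, ANALYSIS_TRIAL)
            if key not in traces:
                raise AnalysisError(f"missing trial-{ANALYSIS_TRIAL} trace for {key}")
            feats = tremor.trace_features(
                traces[key],
                trim_s=trim_s,
                segment_len=segment_len,
                overlap=overlap,
                window=window,
                band=band,
                noise_floor=noise_floor,
            )
            power = feats.peak_power
            if log_power:
                power = float(np.log10(power + POWER_LOG_FLOOR))
            row[f"{cond}_power_{hand}"] = power
            row[f"{cond}_freq_{hand}"] = feats.dominant_frequency
    return row


def vr_feature_table(patients, **kwargs) -> pd.DataFrame:
    """VR feature matrix for a list of SyntheticPatient (or alike) objects."""
    rows = {
        p.record.patient_id: patient_vr_features(p.traces, p.adl, p.slicing, **kwargs)
        for p in patients
    }
    return pd.DataFrame.from_dict(rows, orient="index")[VR_COLUMNS]


def spect_feature_table(measures_by_id: dict) -> pd.DataFrame:
    """SPECT feature matrix from patient-id -> SpectMeasures."""
    rows = {}
    for pid, m in measures_by_id.items():
        rows[pid] = {
            "sbr_striatum_left": m.sbr_striatum_left,
            "sbr_striatum_right": m.sbr_striatum_right,
            "sbr_caudate_left": m.sbr_caudate_left,
            "sbr_caudate_right": m.sbr_caudate_right,
            "sbr_putamen_left": m.sbr_putamen_left,
            "sbr_putamen_right": m.sbr_putamen_right,
            "pc_ratio_left": m.putamen_caudate_ratio_left,
            "pc_ratio_right": m.putamen_caudate_ratio_right,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[SPECT_COLUMNS]


def clinical_table(records) -> pd.DataFrame:
    """Demographics/clinical DataFrame from PatientRecord objects."""
    rows = {
        r.patient_id: {
            "age": r.age,
            "male": r.male,
            "right_handed": r.right_handed,
            "pd_meds": r.pd_meds,
            "updrs3": r.updrs3,
            "hy": r.hy,
            "moca": r.moca,
            "cid": r.cid,
        }
        for r in records
    }
    return pd.DataFrame.from_dict(rows, orient="index")
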