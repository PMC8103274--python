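"""CSV round-trip readers/writers for every on-disk artifact.

All files are RFC-4180 CSV, UTF-8, '.' decimal, with exact schema headers.
Floats are written with Python's shortest round-trip repr, so
``read(write(x)) == x`` holds bit-for-bit for every field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceError, VRMotorError
from .spect import RegionCounts, SpectMeasures
from .stats import PatientRecord
from .synthetic import LatentPatientState
from .tremor import KinematicTrace
from .vr_scoring import ADLAttempt, SliceEvent, SliceSessionLog

TRACE_COLUMNS = ["t", "x", "y", "z", "qw", "qx", "qy", "qz"]

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "male",
    "right_handed",
    "pd_meds",
    "updrs3",
    "hy",
    "moca",
    "severity",
    "side_asymmetry",
    "true_tremor_amp",
    "true_tremor_freq",
    "striatum_left",
    "striatum_right",
    "caudate_left",
    "caudate_right",
    "putamen_left",
    "putamen_right",
    "reference",
]


class ParseError(VRMotorError):
    """A CSV file violates its schema; the message carries the line number."""


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: line 1: expected header {','.join(expected)}, "
            f"got {','.join(map(str, df.columns))}"
        )


def _fmt(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "1" if v else "0"
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, np.integer):
        return str(int(v))
    return str(v)


def _write_rows(path, header: list[str], rows) -> None:
    lines = [",".join(header)]
    lines += [",".join(_fmt(v) for v in row) for row in rows]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# kinematic traces


def write_trace_csv(trace: KinematicTrace, path) -> None:
    rows = (
        (trace.t[i], *trace.pos[i], *trace.quat[i]) for i in range(trace.t.size)
    )
    _write_rows(path, TRACE_COLUMNS, rows)


def read_trace_csv(path, hand: str, condition: str, trial_index: int) -> KinematicTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    t = df["t"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ParseError(f"{path}: line {bad[0] + 3}: non-monotone timestamp")
    try:
        return KinematicTrace(
            hand=hand,
            condition=condition,
            trial_index=trial_index,
            t=t,
            pos=df[["x", "y", "z"]].to_numpy(float),
            quat=df[["qw", "qx", "qy", "qz"]].to_numpy(float),
        )
    except TraceError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def trace_filename(patient_id: str, hand: str, condition: str, trial: int) -> str:
    return f"{patient_id}_{hand}_{condition}_{trial}.csv"


# ---------------------------------------------------------------------------
# ADL tilt trajectories and slicing logs


ADL_COLUMNS = ["t", "tilt_deg"]


def write_adl_csv(attempt: ADLAttempt, path) -> None:
    _write_rows(path, ADL_COLUMNS, zip(attempt.t, attempt.tilt_deg))


def read_adl_csv(path, hand: str, attempt_index: int, mug_index: int | None = None) -> ADLAttempt:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ADL_COLUMNS, path)
    return ADLAttempt(
        hand=hand,
        attempt_index=attempt_index,
        mug_index=mug_index if mug_index is not None else attempt_index,
        t=df["t"].to_numpy(float),
        tilt_deg=df["tilt_deg"].to_numpy(float),
    )


SLICE_COLUMNS = ["t", "event", "item"]


def write_slice_log_csv(log: SliceSessionLog, path) -> None:
    rows = ((e.t, e.kind, e.item if e.item is not None else "") for e in log.events)
    _write_rows(path, SLICE_COLUMNS, rows)


def read_slice_log_csv(path, hand: str, attempt_index: int) -> SliceSessionLog:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require_columns(df, SLICE_COLUMNS, path)
    events = tuple(
        SliceEvent(float(r.t), str(r.event), str(r.item) if r.item else None)
        for r in df.itertuples()
    )
    return SliceSessionLog(hand=hand, attempt_index=attempt_index, events=events)


# ---------------------------------------------------------------------------
# cohort table (one row per patient)


def write_cohort_csv(patients, path) -> None:
    """One row per synthetic patient: record + latent state + VOI counts."""
    rows = []
    for p in patients:
        r, l, c = p.record, p.latent, p.counts
        rows.append(
            (
                r.patient_id,
                r.age,
                r.male,
                r.right_handed,
                r.pd_meds,
                r.updrs3,
                r.hy,
                r.moca,
                l.severity,
                l.side_asymmetry,
                l.true_tremor_amp,
                l.true_tremor_freq,
                c.striatum_left,
                c.striatum_right,
                c.caudate_left,
                c.caudate_right,
                c.putamen_left,
                c.putamen_right,
                c.reference,
            )
        )
    _write_rows(path, COHORT_COLUMNS, rows)


def read_cohort_csv(path) -> list[tuple[PatientRecord, LatentPatientState, RegionCounts]]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, COHORT_COLUMNS, path)
    out = []
    for r in df.itertuples():
        record = PatientRecord(
            patient_id=str(r.patient_id),
            age=float(r.age),
            male=bool(r.male),
            right_handed=bool(r.right_handed),
            pd_meds=bool(r.pd_meds),
            updrs3=int(r.updrs3),
            hy=float(r.hy),
            moca=int(r.moca),
        )
        latent = LatentPatientState(
            patient_id=str(r.patient_id),
            severity=float(r.severity),
            side_asymmetry=float(r.side_asymmetry),
            true_tremor_amp=float(r.true_tremor_amp),
            true_tremor_freq=float(r.true_tremor_freq),
        )
        counts = RegionCounts(
            striatum_left=float(r.striatum_left),
            striatum_right=float(r.striatum_right),
            caudate_left=float(r.caudate_left),
            caudate_right=float(r.caudate_right),
            putamen_left=float(r.putamen_left),
            putamen_right=float(r.putamen_right),
            reference=float(r.reference),
        )
        out.append((record, latent, counts))
    return out


# ---------------------------------------------------------------------------
# feature matrices and SPECT measures


def write_feature_csv(features: pd.DataFrame, path) -> None:
    header = ["patient_id", *features.columns]
    rows = ((idx, *row) for idx, row in zip(features.index, features.to_numpy()))
    _write_rows(path, header, rows)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "patient_id":
        raise ParseError(f"{path}: line 1: first column must be patient_id")
    return df.set_index("patient_id")


MEASURE_FIELDS = [f.strip() for f in SpectMeasures.__dataclass_fields__]


def write_measures_csv(measures_by_id: dict, path) -> None:
    header = ["patient_id", *MEASURE_FIELDS]
    rows = (
        (pid, *[getattr(m, f) for f in MEASURE_FIELDS])
        for pid, m in measures_by_id.items()
    )
    _write_rows(path, header, rows)


def read_measures_csv(path) -> dict:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["patient_id", *MEASURE_FIELDS], path)
    return {
        str(r.patient_id): SpectMeasures(
            **{f: float(getattr(r, f)) for f in MEASURE_FIELDS}
        )
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# reports


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
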