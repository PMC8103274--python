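"""Seeded synthetic cohort of parkinsonian patients.

A single latent severity S in [0, 1] drives every modality: the expected
UPDRS-III motor score (monotone power link), tremor amplitude, slicing
slowness, mug-tilt instability, and the striatal binding decline measured by
SPECT.  VR-derived quantities receive low independent noise and SPECT
receives high independent noise, so the simulated cohorts show the
strong-VR/weak-SPECT coupling pattern typical of this population: the
default SPECT coupling is calibrated so the severity-SBR correlation is weak
(|r| around 0.2, the order reported for dopamine-transporter binding vs
motor score in large PD cohorts), while VR measures track severity tightly.

Lateralisation: one shared signed asymmetry per patient lowers the putamen
SBR on the affected hemisphere and raises tremor amplitude and tilt
instability on the contralateral hand.

Everything is a pure function of (config, seed): identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .spect import (
    NormativeIndex,
    RegionCounts,
    SpectMeasures,
    load_normative_table,
    quantify,
)
from .stats import PatientRecord
from .tremor import KinematicTrace
from .vr_scoring import ADLAttempt, SliceEvent, SliceSessionLog, FOOD_ITEMS

HANDS = ("left", "right")
CONDITIONS = ("rest", "posture")
N_TRIALS = 2
N_ADL_PER_HAND = 5
N_SLICE_PER_HAND = 2


@dataclass(frozen=True)
class UpdrsLink:
    """Monotone map from latent severity to the expected UPDRS-III score.

    expected(S) = updrs_max * S**gamma, with gamma chosen so that, under a
    uniform severity distribution, the fraction of patients above the CID
    threshold (10 points) equals ``cid_prevalence``.
    """

    updrs_max: float = 53.0
    cid_prevalence: float = 0.57
    noise_sd: float = 3.0
    cid_threshold: float = 10.0

    @property
    def gamma(self) -> float:
        return math.log(self.cid_threshold / self.updrs_max) / math.log(
            1.0 - self.cid_prevalence
        )

    def expected(self, s: float) -> float:
        return self.updrs_max * s**self.gamma


@dataclass(frozen=True)
class VREffect:
    """Coefficients tying severity to the VR measures."""

    tremor_amp_max: float = 0.004  # m; amplitude at S=1 (quadratic in S)
    tremor_band: tuple[float, float] = (2.0, 6.0)  # Hz
    trace_noise_sd: float = 5e-4  # m white positional noise on traces
    slicing_base_s: float = 40.0  # slicing duration at S=0
    slicing_slope_s: float = 70.0  # extra seconds per unit severity
    adl_instability_rad: float = 0.8  # stationary tilt RMS at S=1, radians


@dataclass(frozen=True)
class SpectEffect:
    """Coefficients tying severity to striatal binding (weak by default)."""

    caudate_base: float = 2.1  # caudate SBR at S=0
    caudate_slope: float = 0.5  # SBR decline per unit severity
    ratio_base: float = 0.95  # putamen/caudate ratio at S=0
    ratio_slope: float = 0.08
    ratio_noise_sd: float = 0.09
    asymmetry_min: float = 0.05  # |side_asymmetry| range
    asymmetry_max: float = 0.35


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of a synthetic cohort.

    Demographic defaults mirror a typical movement-disorder referral
    population (age 64.5 +/- 12.4, ~48% male, ~86% right-handed, ~27% on PD
    medication, 57% above the CID threshold).
    """

    n_patients: int = 50
    age_mean: float = 64.5
    age_sd: float = 12.4
    age_range: tuple[float, float] = (36.0, 85.0)
    frac_male: float = 21 / 44
    frac_right_handed: float = 38 / 44
    frac_pd_meds: float = 12 / 44
    severity_alpha: float = 1.0  # severity ~ Beta(alpha, beta); (1,1)=uniform
    severity_beta: float = 1.0
    updrs_link: UpdrsLink = field(default_factory=UpdrsLink)
    vr_effect: VREffect = field(default_factory=VREffect)
    spect_effect: SpectEffect = field(default_factory=SpectEffect)
    vr_noise_sd: float = 12.0  # s; slicing-duration noise
    spect_noise_sd: float = 0.65  # SBR units; per-side caudate noise
    trace_duration_s: float = 10.0
    trace_rate_hz: float = 90.0
    adl_duration_s: float = 8.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("frac_male", "frac_right_handed", "frac_pd_meds"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("vr_noise_sd", "spect_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.updrs_link.noise_sd < 0:
            raise ConfigError("updrs_link.noise_sd must be >= 0")
        if not 0 < self.updrs_link.cid_prevalence < 1:
            raise ConfigError("updrs_link.cid_prevalence must lie in (0, 1)")
        if self.updrs_link.updrs_max <= self.updrs_link.cid_threshold:
            raise ConfigError("updrs_link.updrs_max must exceed the CID threshold")
        if self.severity_alpha <= 0 or self.severity_beta <= 0:
            raise ConfigError("severity_alpha/severity_beta must be positive")
        if self.trace_duration_s <= 0 or self.trace_rate_hz <= 0:
            raise ConfigError("trace_duration_s and trace_rate_hz must be positive")
        lo, hi = self.vr_effect.tremor_band
        if not 0 < lo < hi:
            raise ConfigError("vr_effect.tremor_band must be an increasing positive pair")
        if self.vr_effect.tremor_amp_max < 0 or self.vr_effect.trace_noise_sd < 0:
            raise ConfigError("vr_effect amplitudes/noise must be >= 0")
        if not 0 <= self.spect_effect.asymmetry_min <= self.spect_effect.asymmetry_max <= 1:
            raise ConfigError("spect_effect asymmetry range must satisfy 0 <= min <= max <= 1")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, rng_seed=int(seed))


@dataclass(frozen=True)
class LatentPatientState:
    """Unobserved ground truth behind one simulated patient."""

    patient_id: str
    severity: float  # S in [0, 1]
    side_asymmetry: float  # signed; >0 = right hemisphere more affected
    true_tremor_amp: float  # m, hand-averaged
    true_tremor_freq: float  # Hz


@dataclass(frozen=True)
class SyntheticPatient:
    """One complete simulated patient across all modalities."""

    record: PatientRecord
    latent: LatentPatientState
    traces: dict  # (hand, condition, trial_index) -> KinematicTrace
    adl: dict  # hand -> list[ADLAttempt] (length 5)
    slicing: dict  # hand -> list[SliceSessionLog] (length 2)
    counts: RegionCounts
    measures: SpectMeasures


def simulate_tremor_trace(
    amp: float,
    freq: float,
    duration: float = 10.0,
    rate: float = 90.0,
    noise_sd: float = 5e-4,
    seed: int = 0,
    axis: int = 0,
    drift_amp: float = 0.0,
    hand: str = "right",
    condition: str = "posture",
    trial_index: int = 1,
) -> KinematicTrace:
    """Sinusoidal tremor + white noise + optional slow drift, on one axis.

    Produces ``round(duration*rate)`` samples on an exact uniform grid.  With
    ``amp=0, noise_sd=0, drift_amp=0`` the position is constant.
    """
    if duration <= 0 or rate <= 0:
        raise ConfigError("duration and rate must be positive")
    if amp < 0 or noise_sd < 0:
        raise ConfigError("amp and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    pos = np.tile(np.array([0.10, 1.10, 0.45]), (n, 1))  # resting hand position, m
    phase = rng.uniform(0, 2 * math.pi)
    pos[:, axis] += amp * np.sin(2 * math.pi * freq * t + phase)
    if drift_amp > 0:
        drift_phase = rng.uniform(0, 2 * math.pi)
        drift = drift_amp * np.sin(2 * math.pi * 0.08 * t + drift_phase)
        drift += drift_amp / max(duration, 1e-9) * t  # slow linear wander
        pos[:, axis] += drift
    if noise_sd > 0:
        pos += rng.normal(0.0, noise_sd, size=(n, 3))
    return KinematicTrace(
        hand=hand, condition=condition, trial_index=trial_index, t=t, pos=pos
    )


def simulate_adl_trajectory(
    instability: float,
    duration: float = 8.0,
    rate: float = 90.0,
    seed: int = 0,
    mean_reversion: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mug-tilt time series (degrees from vertical) during one carry.

    The tilt is the absolute value of a mean-zero Ornstein-Uhlenbeck process
    whose stationary RMS is ``instability`` (radians), so both the number
    and the total duration of threshold exceedances grow stochastically with
    instability.  ``instability=0`` gives an identically upright mug.
    """
    if instability < 0:
        raise ConfigError("instability must be >= 0")
    if duration <= 0 or rate <= 0:
        raise ConfigError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if instability == 0:
        return t, np.zeros(n)
    dt = 1.0 / rate
    a = math.exp(-mean_reversion * dt)
    innov_sd = instability * math.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, instability)  # start in the stationary law
    x = sps.lfilter([1.0], [1.0, -a], eps)
    tilt = np.minimum(np.abs(np.degrees(x)), 180.0)
    return t, tilt


def simulate_slice_log(
    total_s: float, seed: int = 0, hand: str = "right", attempt_index: int = 1
) -> SliceSessionLog:
    """Event log of one slicing attempt lasting ``total_s`` seconds."""
    if total_s <= 0:
        raise ConfigError("total_s must be positive")
    rng = np.random.default_rng(seed)
    cut_times = np.sort(rng.uniform(0.1 * total_s, 0.98 * total_s, size=len(FOOD_ITEMS)))
    events = [SliceEvent(0.0, "session_start")]
    events += [
        SliceEvent(float(tc), "item_cut", item)
        for tc, item in zip(cut_times, FOOD_ITEMS)
    ]
    events.append(SliceEvent(float(total_s), "session_end"))
    return SliceSessionLog(hand=hand, attempt_index=attempt_index, events=tuple(events))


def _contra(hand_side: str) -> str:
    return "left" if hand_side == "right" else "right"


def _simulate_patient(
    config: CohortConfig, pid: str, rng: np.random.Generator, normative
) -> SyntheticPatient:
    link, vre, spe = config.updrs_link, config.vr_effect, config.spect_effect

    s = float(rng.beta(config.severity_alpha, config.severity_beta))
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd), *config.age_range))
    male = bool(rng.random() < config.frac_male)
    right_handed = bool(rng.random() < config.frac_right_handed)
    pd_meds = bool(rng.random() < config.frac_pd_meds)

    updrs3 = int(np.clip(round(link.expected(s) + rng.normal(0, link.noise_sd)), 0, 132))
    hy = float(np.clip(round(2.5 * s - 0.2 + rng.normal(0, 0.4)), 0, 5))
    moca = int(np.clip(round(27 - 7 * s + rng.normal(0, 4)), 0, 30))

    # lateralisation: affected hemisphere and its magnitude
    asym_mag = float(rng.uniform(spe.asymmetry_min, spe.asymmetry_max))
    affected = "right" if rng.random() < 0.5 else "left"
    side_asymmetry = asym_mag if affected == "right" else -asym_mag
    worse_hand = _contra(affected)  # motor signs are contralateral

    freq = float(rng.uniform(*vre.tremor_band))
    base_amp = vre.tremor_amp_max * s * s
    amp = {
        worse_hand: base_amp * (1.0 + asym_mag),
        _contra(worse_hand): base_amp * (1.0 - asym_mag),
    }

    traces = {}
    for hand in HANDS:
        for cond in CONDITIONS:
            for trial in range(1, N_TRIALS + 1):
                traces[(hand, cond, trial)] = simulate_tremor_trace(
                    amp=amp[hand],
                    freq=freq,
                    duration=config.trace_duration_s,
                    rate=config.trace_rate_hz,
                    noise_sd=vre.trace_noise_sd,
                    seed=int(rng.integers(2**31)),
                    drift_amp=0.02,
                    hand=hand,
                    condition=cond,
                    trial_index=trial,
                )

    adl = {}
    for hand in HANDS:
        lat = 1.0 + (0.5 * asym_mag if hand == worse_hand else -0.5 * asym_mag)
        instability = vre.adl_instability_rad * s * lat
        attempts = []
        for k in range(1, N_ADL_PER_HAND + 1):
            t, tilt = simulate_adl_trajectory(
                instability,
                duration=config.adl_duration_s,
                rate=config.trace_rate_hz,
                seed=int(rng.integers(2**31)),
            )
            attempts.append(
                ADLAttempt(hand=hand, attempt_index=k, mug_index=k, t=t, tilt_deg=tilt)
            )
        adl[hand] = attempts

    slicing = {}
    for hand in HANDS:
        lat = 1.0 + (0.3 * asym_mag if hand == worse_hand else -0.3 * asym_mag)
        logs = []
        for k in range(1, N_SLICE_PER_HAND + 1):
            total = max(
                5.0,
                vre.slicing_base_s
                + vre.slicing_slope_s * s * lat
                + rng.normal(0, config.vr_noise_sd),
            )
            logs.append(
                simulate_slice_log(
                    float(total), seed=int(rng.integers(2**31)), hand=hand, attempt_index=k
                )
            )
        slicing[hand] = logs

    # SPECT: per-side SBR ground truth -> VOI mean counts
    sbr = {}
    for side in ("left", "right"):
        caud = max(0.05, spe.caudate_base - spe.caudate_slope * s + rng.normal(0, config.spect_noise_sd))
        ratio = spe.ratio_base - spe.ratio_slope * s + rng.normal(0, spe.ratio_noise_sd)
        ratio = float(np.clip(ratio, 0.3, 1.3))
        if side == affected:
            ratio *= 1.0 - asym_mag
        put = caud * ratio
        stri = 0.45 * caud + 0.55 * put
        sbr[side] = {"caudate": caud, "putamen": put, "striatum": stri}
    reference = float(rng.normal(50.0, 4.0))
    counts = RegionCounts(
        striatum_left=reference * (1 + sbr["left"]["striatum"]),
        striatum_right=reference * (1 + sbr["right"]["striatum"]),
        caudate_left=reference * (1 + sbr["left"]["caudate"]),
        caudate_right=reference * (1 + sbr["right"]["caudate"]),
        putamen_left=reference * (1 + sbr["left"]["putamen"]),
        putamen_right=reference * (1 + sbr["right"]["putamen"]),
        reference=reference,
    )
    measures = quantify(counts, age, normative)

    record = PatientRecord(
        patient_id=pid,
        age=age,
        male=male,
        right_handed=right_handed,
        pd_meds=pd_meds,
        updrs3=updrs3,
        hy=hy,
        moca=moca,
    )
    latent = LatentPatientState(
        patient_id=pid,
        severity=s,
        side_asymmetry=side_asymmetry,
        true_tremor_amp=base_amp,
        true_tremor_freq=freq,
    )
    return SyntheticPatient(
        record=record,
        latent=latent,
        traces=traces,
        adl=adl,
        slicing=slicing,
        counts=counts,
        measures=measures,
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Simulate a full cohort; a pure function of the config (incl. seed)."""
    config.validate()
    normative = NormativeIndex(load_normative_table())
    ss = np.random.SeedSequence(config.rng_seed)
    children = ss.spawn(config.n_patients)
    width = max(3, len(str(config.n_patients)))
    patients = []
    for i, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        pid = f"P{i:0{width}d}"
        patients.append(_simulate_patient(config, pid, rng, normative))
    return patients
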