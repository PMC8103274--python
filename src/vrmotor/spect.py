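"""Striatal dopamine-transporter SPECT semiquantification.

Starting from volume-of-interest mean counts (striatum, caudate, putamen and
an occipital/background reference, per hemisphere), this module computes
specific binding ratios SBR = target/reference - 1, putamen-to-caudate
ratios, and age-matched z-scores against a normative table, and applies the
enrolment gate used for cohort selection: a scan is "normal" (excluded) when
the putamen z-score on both sides stays above the abnormality threshold.

The shipped normative table (``data/normative_synthetic.csv``) is synthetic:
plausible healthy means with a mild age decline, standing in for proprietary
scanner databases, and editable by the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import AnalysisError

SIDES = ("left", "right")
REGIONS = ("striatum", "caudate", "putamen")

#: default z threshold: a putamen z-score above this on BOTH sides reads as a
#: normal scan.
DEFAULT_Z_THRESHOLD = -2.0


@dataclass(frozen=True)
class RegionCounts:
    """Per-hemisphere VOI mean counts/voxel plus the shared background."""

    striatum_left: float
    striatum_right: float
    caudate_left: float
    caudate_right: float
    putamen_left: float
    putamen_right: float
    reference: float

    def __post_init__(self):
        for name in (
            "striatum_left",
            "striatum_right",
            "caudate_left",
            "caudate_right",
            "putamen_left",
            "putamen_right",
            "reference",
        ):
            if getattr(self, name) <= 0:
                raise AnalysisError(f"RegionCounts.{name} must be positive")


@dataclass(frozen=True)
class SpectMeasures:
    """Semiquantitative uptake measures for one patient."""

    sbr_striatum_left: float
    sbr_striatum_right: float
    sbr_caudate_left: float
    sbr_caudate_right: float
    sbr_putamen_left: float
    sbr_putamen_right: float
    putamen_caudate_ratio_left: float
    putamen_caudate_ratio_right: float
    z_striatum_left: float = math.nan
    z_striatum_right: float = math.nan
    z_caudate_left: float = math.nan
    z_caudate_right: float = math.nan
    z_putamen_left: float = math.nan
    z_putamen_right: float = math.nan

    def sbr(self, region: str, side: str) -> float:
        return getattr(self, f"sbr_{region}_{side}")

    def z(self, region: str, side: str) -> float:
        return getattr(self, f"z_{region}_{side}")


def compute_sbr(target_mean: float, reference_mean: float) -> float:
    """Specific binding ratio: target/reference - 1."""
    if reference_mean <= 0:
        raise AnalysisError("reference_mean must be positive")
    if target_mean < 0:
        raise AnalysisError("target_mean must be nonnegative")
    return target_mean / reference_mean - 1.0


def compute_zscore(sbr: float, norm_mean: float, norm_sd: float) -> float:
    """Age-matched z-score: (SBR - normative mean)/normative SD."""
    if norm_sd <= 0:
        raise AnalysisError("norm_sd must be positive")
    return (sbr - norm_mean) / norm_sd


def putamen_caudate_ratio(putamen: float, caudate: float) -> float:
    """Posterior/anterior striatal gradient; reduced early in disease.

    By default both arguments are SBRs; raw mean counts work identically.
    """
    if caudate <= 0:
        raise AnalysisError("caudate denominator must be positive")
    return putamen / caudate


def load_normative_table(path=None) -> pd.DataFrame:
    """Load a normative SBR table (region, side, age band, mean, SD).

    Without ``path`` the bundled synthetic table is used.
    """
    if path is None:
        src = resources.files("vrmotor").joinpath("data/normative_synthetic.csv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    required = {"region", "side", "age_min", "age_max", "mean_sbr", "sd_sbr"}
    missing = required - set(table.columns)
    if missing:
        raise AnalysisError(f"normative table missing columns: {sorted(missing)}")
    if (table["sd_sbr"] <= 0).any():
        raise AnalysisError("normative table sd_sbr values must be positive")
    return table


class NormativeIndex:
    """Array-backed view of a normative table for fast repeated lookups."""

    def __init__(self, table: pd.DataFrame):
        self.table = table
        self._bands = {}
        for (region, side), rows in table.groupby(["region", "side"]):
            rows = rows.sort_values("age_min")
            self._bands[(region, side)] = (
                rows["age_min"].to_numpy(float),
                rows["age_max"].to_numpy(float),
                rows["mean_sbr"].to_numpy(float),
                rows["sd_sbr"].to_numpy(float),
            )

    def lookup(self, region: str, side: str, age: float) -> tuple[float, float]:
        """(mean, SD) for the band containing ``age``; nearest band if outside."""
        try:
            lo, hi, mean, sd = self._bands[(region, side)]
        except KeyError:
            raise AnalysisError(f"no normative entry for {region}/{side}") from None
        inside = (lo <= age) & (age < hi)
        if inside.any():
            k = int(np.argmax(inside))
        else:
            k = int(np.argmin(np.abs((lo + hi) / 2 - age)))
        return float(mean[k]), float(sd[k])


def normative_lookup(
    table: pd.DataFrame | NormativeIndex, region: str, side: str, age: float
) -> tuple[float, float]:
    """(mean, SD) for the age band containing ``age``; nearest band if outside."""
    if not isinstance(table, NormativeIndex):
        table = NormativeIndex(table)
    return table.lookup(region, side, age)


def quantify(
    counts: RegionCounts,
    age: float,
    normative: pd.DataFrame | NormativeIndex | None = None,
) -> SpectMeasures:
    """Full semiquantification of one scan: SBRs, ratios and z-scores."""
    if normative is None:
        normative = load_normative_table()
    if not isinstance(normative, NormativeIndex):
        normative = NormativeIndex(normative)
    sbr = {
        (r, s): compute_sbr(getattr(counts, f"{r}_{s}"), counts.reference)
        for r in REGIONS
        for s in SIDES
    }
    z = {}
    for (r, s), v in sbr.items():
        m, sd = normative_lookup(normative, r, s, age)
        z[(r, s)] = compute_zscore(v, m, sd)
    return SpectMeasures(
        sbr_striatum_left=sbr[("striatum", "left")],
        sbr_striatum_right=sbr[("striatum", "right")],
        sbr_caudate_left=sbr[("caudate", "left")],
        sbr_caudate_right=sbr[("caudate", "right")],
        sbr_putamen_left=sbr[("putamen", "left")],
        sbr_putamen_right=sbr[("putamen", "right")],
        putamen_caudate_ratio_left=putamen_caudate_ratio(
            sbr[("putamen", "left")], sbr[("caudate", "left")]
        ),
        putamen_caudate_ratio_right=putamen_caudate_ratio(
            sbr[("putamen", "right")], sbr[("caudate", "right")]
        ),
        z_striatum_left=z[("striatum", "left")],
        z_striatum_right=z[("striatum", "right")],
        z_caudate_left=z[("caudate", "left")],
        z_caudate_right=z[("caudate", "right")],
        z_putamen_left=z[("putamen", "left")],
        z_putamen_right=z[("putamen", "right")],
    )


def is_scan_normal(measures: SpectMeasures, z_threshold: float = DEFAULT_Z_THRESHOLD) -> bool:
    """True when both putamen z-scores sit above the abnormality threshold."""
    zl, zr = measures.z_putamen_left, measures.z_putamen_right
    if math.isnan(zl) or math.isnan(zr):
        raise AnalysisError("putamen z-scores missing")
    return min(zl, zr) > z_threshold


def abnormality_filter(
    cohort: dict, z_threshold: float = DEFAULT_Z_THRESHOLD
) -> tuple[list, list]:
    """Partition patient ids into (included, excluded) by the scan gate.

    ``cohort`` maps patient id -> :class:`SpectMeasures`.  A patient is
    excluded iff the scan is normal (both putamen z-scores above threshold);
    insertion order is preserved.
    """
    included, excluded = [], []
    for pid, m in cohort.items():
        try:
            normal = is_scan_normal(m, z_threshold)
        except AnalysisError as exc:
            raise AnalysisError(f"patient {pid}: {exc}") from exc
        (excluded if normal else included).append(pid)
    return included, excluded
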