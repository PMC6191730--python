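"""Region-of-interest time-activity curves and the 3-grade classification.

Curves are background-corrected counts per pixel per second, decay
corrected to the start of their acquisition segment, sampled at frame
mid-points.  A curve is graded by the z-statistic of its least-squares
slope: significantly negative = grade 1 (declining), indeterminate =
grade 2 (flat), significantly positive = grade 3 (rising).  A rising
pharyngeal curve reflects recurrent reflux outrunning oesophageal
clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .render import DynamicStudy, scaled_zones


class GeometryError(ValueError):
    """ROI outside the image bounds or otherwise inconsistent."""


@dataclass
class ROISet:
    """Named pixel regions on the dynamic matrix.

    ``regions`` maps a name to an (N, 2) integer array of (row, col)
    pixels.  Regions must be pairwise disjoint and non-empty; the
    background region must not overlap any organ zone.
    """

    regions: dict
    matrix: int = 64

    def __post_init__(self) -> None:
        occupancy = np.zeros((self.matrix, self.matrix), dtype=bool)
        for name, pix in self.regions.items():
            pix = np.asarray(pix, dtype=int)
            if pix.ndim != 2 or pix.shape[1] != 2 or len(pix) == 0:
                raise GeometryError(f"region {name!r} must be a non-empty (N, 2) pixel list")
            if pix.min() < 0 or pix.max() >= self.matrix:
                raise GeometryError(f"region {name!r} has pixels outside the {self.matrix}x{self.matrix} matrix")
            self.regions[name] = pix
            if occupancy[pix[:, 0], pix[:, 1]].any():
                raise GeometryError(f"region {name!r} overlaps another region")
            occupancy[pix[:, 0], pix[:, 1]] = True

    @classmethod
    def from_rectangles(cls, rects: dict, matrix: int = 64) -> "ROISet":
        """Build from half-open (row0, row1, col0, col1) rectangles."""
        regions = {}
        for name, (r0, r1, c0, c1) in rects.items():
            rr, cc = np.mgrid[r0:r1, c0:c1]
            regions[name] = np.column_stack([rr.ravel(), cc.ravel()])
        return cls(regions=regions, matrix=matrix)

    def mask(self, name: str) -> np.ndarray:
        m = np.zeros((self.matrix, self.matrix), dtype=bool)
        pix = self.regions[name]
        m[pix[:, 0], pix[:, 1]] = True
        return m


def default_roi_set(matrix: int = 64) -> ROISet:
    """The ROI set matching the simulator's schematic anatomy: pharynx,
    oesophageal thirds, stomach, and a lateral-chest background strip."""
    zones = scaled_zones(matrix)
    rects = {
        name: zones[name]
        for name in ("pharynx", "upper", "mid", "lower", "stomach", "background")
    }
    return ROISet.from_rectangles(rects, matrix=matrix)


@dataclass
class TimeActivityCurve:
    """Background- and decay-corrected mean counts/pixel/second vs time."""

    roi_name: str
    times: np.ndarray    # frame mid-point seconds from segment start
    values: np.ndarray   # may be negative after background subtraction
    posture: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class CurveGrade:
    """Grade 1 declining / 2 flat / 3 rising, with the fitted slope."""

    grade: int
    slope: float        # counts.px^-1.s^-1 per minute
    slope_se: float
    label: str


_LABELS = {1: "declining", 2: "flat", 3: "rising"}


def roi_frame_means(study: DynamicStudy, rois: ROISet, roi_name: str) -> np.ndarray:
    """Uncorrected mean counts per pixel in one ROI, per frame."""
    if roi_name not in rois.regions:
        raise KeyError(f"unknown ROI {roi_name!r}")
    if len(study.frames) == 0:
        raise ValueError("study has no frames")
    if rois.matrix != study.frames.shape[1]:
        raise GeometryError("ROI matrix does not match the study matrix")
    pix = rois.regions[roi_name]
    return study.frames[:, pix[:, 0], pix[:, 1]].mean(axis=1)


def extract_tac(
    study: DynamicStudy,
    rois: ROISet,
    roi_name: str,
    background_name: str = "background",
) -> TimeActivityCurve:
    """Extract one background-corrected, decay-corrected TAC.

    Per frame: (mean organ counts/pixel - mean background counts/pixel)
    divided by the frame duration, then decay-corrected to the start of
    the acquisition segment.  Times are frame mid-points in seconds.
    """
    organ = roi_frame_means(study, rois, roi_name)
    background = roi_frame_means(study, rois, background_name)
    dt = study.frame_seconds
    mids = study.frame_times + 0.5 * dt
    correction = 1.0 / study.protocol.decay_factor(mids / 60.0)
    values = (organ - background) / dt * correction
    return TimeActivityCurve(
        roi_name=roi_name, times=mids, values=values, posture=study.posture
    )


def linear_fit(times_minutes: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and its standard error."""
    res = stats.linregress(times_minutes, values)
    return float(res.slope), float(res.stderr)


def grade_curve(tac: TimeActivityCurve, z_crit: float = 2.0) -> CurveGrade:
    """Grade a TAC by the z-statistic of its least-squares slope.

    ``z = slope / SE(slope)``; grade 3 if z > z_crit, grade 1 if
    z < -z_crit, else grade 2.  A noiseless exactly-flat curve has zero
    slope and SE and is graded 2.
    """
    if len(tac.values) < 4:
        raise ValueError("grading needs at least 4 points")
    t_min = tac.times / 60.0
    if np.ptp(t_min) == 0:
        raise ValueError("zero variance in time")
    slope, se = linear_fit(t_min, tac.values)
    if se == 0 or not math.isfinite(se):
        # perfectly collinear data: grade by the sign of the exact slope
        z = math.inf * np.sign(slope) if slope != 0 else 0.0
    else:
        z = slope / se
    if z > z_crit:
        grade = 3
    elif z < -z_crit:
        grade = 1
    else:
        grade = 2
    return CurveGrade(grade=grade, slope=slope, slope_se=se, label=_LABELS[grade])


#: Sentinel returned when gastric clearance never reaches half.
NOT_REACHED = math.inf


def gastric_half_clearance(tac: TimeActivityCurve) -> float:
    """Gastric half-clearance time in minutes from a stomach TAC.

    Fits a single exponential ``A exp(-k t)`` to the decay-corrected
    stomach curve and returns ln(2)/k; returns the ``NOT_REACHED``
    sentinel (inf) if the fitted rate is not positive.
    """
    t_min = tac.times / 60.0
    if t_min[-1] - t_min[0] < 10.0:
        raise ValueError("stomach TAC must span at least 10 minutes")
    v0 = float(np.mean(tac.values[: max(1, len(tac.values) // 10)]))
    if v0 <= 0:
        raise ValueError("initial stomach activity must be positive")

    def model(t, a, k):
        return a * np.exp(-k * t)

    # log-linear start values from the positive samples
    pos = tac.values > 0
    k0 = 0.0
    if pos.sum() >= 2:
        b = np.polyfit(t_min[pos], np.log(tac.values[pos]), 1)[0]
        k0 = max(-b, 1e-4)
    try:
        popt, _ = optimize.curve_fit(
            model, t_min, tac.values, p0=(v0, k0 or 1e-3), maxfev=10000
        )
    except RuntimeError:
        return NOT_REACHED
    k = float(popt[1])
    if k <= 0:
        return NOT_REACHED
    return math.log(2.0) / k


def pharynx_background_ratio(
    pharynx_means: np.ndarray, background_means: np.ndarray
) -> tuple[np.ndarray, float]:
    """Ratio of uncorrected pharyngeal to background counts/pixel.

    Returns the per-frame ratios and the whole-study summary (the
    maximum over frames).  A summary near 1 means the pharynx never held
    activity above body background.
    """
    pharynx_means = np.asarray(pharynx_means, dtype=float)
    background_means = np.asarray(background_means, dtype=float)
    if pharynx_means.shape != background_means.shape or pharynx_means.size == 0:
        raise ValueError("pharynx and background series must have equal nonzero length")
    if np.any(background_means <= 0):
        raise ValueError("background mean must be positive in every frame")
    ratios = pharynx_means / background_means
    return ratios, float(ratios.max())
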