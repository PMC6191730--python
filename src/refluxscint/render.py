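"""Render compartment activities into gamma-camera count images.

The anatomy is a fixed schematic layout on the 64x64 dynamic matrix
(scaled x4 for the 256x256 delayed matrix): pharynx at the top, the three
oesophageal thirds stacked in the midline, the stomach lower-left, two
lung fields flanking the mediastinum and a lateral-chest background strip
on the right.  Expected pixel counts are compartment activity x frame
duration x a sensitivity constant, spread uniformly over the zone, plus a
uniform body-background term; realized counts are Poisson.  Lung zones
receive counts only from the lungs compartment, with a configurable
fraction concentrated in the hilar (main-airway) strips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import ActivitySeries
from .protocol import AcquisitionProtocol

#: Zone rectangles on the 64x64 matrix as (row0, row1, col0, col1),
#: half-open, row-major with origin top-left.
ZONES_64 = {
    "pharynx": (2, 7, 27, 37),
    "upper": (9, 20, 29, 35),
    "mid": (21, 32, 29, 35),
    "lower": (33, 44, 29, 35),
    "stomach": (45, 60, 8, 30),
    "lung_left": (10, 38, 8, 24),
    "lung_right": (10, 38, 40, 56),
    "hilum_left": (14, 26, 19, 23),
    "hilum_right": (14, 26, 41, 45),
    "background": (16, 34, 58, 63),
}

#: Default camera sensitivity: whole-zone count rate per MBq in a
#: compartment (collimator + attenuation lumped together).
SENSITIVITY_CPS_PER_MBQ = 25.0

#: Uniform body-background count rate per pixel per second on the 64x64
#: matrix.  Scaled by (64/matrix)^2 on other matrices so the whole-body
#: background rate is matrix-independent.
BACKGROUND_CPS_PER_PIXEL_64 = 0.1

#: Fraction of lung activity concentrated in the hilar strips.
HILAR_FRACTION = 0.7


def scaled_zones(matrix: int) -> dict:
    """Zone rectangles scaled from the 64x64 reference to ``matrix``."""
    if matrix % 64:
        raise ValueError("matrix must be a multiple of 64")
    f = matrix // 64
    return {k: tuple(f * v for v in rect) for k, rect in ZONES_64.items()}


def zone_mask(matrix: int, name: str) -> np.ndarray:
    r0, r1, c0, c1 = scaled_zones(matrix)[name]
    m = np.zeros((matrix, matrix), dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


@dataclass
class DynamicStudy:
    """A timed stack of gamma-camera frames for one posture."""

    posture: str
    frames: np.ndarray          # (n, matrix, matrix) integer counts
    frame_times: np.ndarray     # seconds from segment start (frame starts)
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.frame_times):
            raise ValueError("frames and frame_times length mismatch")
        if np.any(self.frames < 0):
            raise ValueError("counts must be non-negative")
        dt = np.diff(self.frame_times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("frame_times must be uniformly increasing")

    @property
    def frame_seconds(self) -> float:
        if self.posture == "upright":
            return self.protocol.upright_frame_seconds
        return self.protocol.supine_frame_seconds


@dataclass
class DelayedImage:
    """Delayed static image for aspiration assessment."""

    pixels: np.ndarray          # (matrix, matrix) integer counts
    acquisition_time_minutes: float  # since colloid administration
    protocol: AcquisitionProtocol = None

    def __post_init__(self) -> None:
        if np.any(self.pixels < 0):
            raise ValueError("counts must be non-negative")


def expected_frame(
    activities: dict,
    matrix: int,
    duration_s: float,
    sensitivity: float = SENSITIVITY_CPS_PER_MBQ,
    background_rate: float = BACKGROUND_CPS_PER_PIXEL_64,
    hilar_fraction: float = HILAR_FRACTION,
) -> np.ndarray:
    """Expected (Poisson-mean) count image for one frame.

    ``activities`` maps compartment name to physically decayed MBq at the
    frame mid-point.
    """
    zones = scaled_zones(matrix)
    bg = background_rate * (64.0 / matrix) ** 2
    img = np.full((matrix, matrix), bg * duration_s, dtype=float)

    def paint(rect, amount):
        r0, r1, c0, c1 = rect
        area = (r1 - r0) * (c1 - c0)
        img[r0:r1, c0:c1] += amount * sensitivity * duration_s / area

    for name in ("pharynx", "upper", "mid", "lower", "stomach"):
        paint(zones[name], activities.get(name, 0.0))
    lungs = activities.get("lungs", 0.0)
    if lungs:
        for side in ("left", "right"):
            paint(zones[f"hilum_{side}"], 0.5 * hilar_fraction * lungs)
            paint(zones[f"lung_{side}"], 0.5 * (1.0 - hilar_fraction) * lungs)
    return img


def render_frames(
    series: ActivitySeries,
    protocol: AcquisitionProtocol | None = None,
    seed: int | np.random.Generator = 0,
    sensitivity: float = SENSITIVITY_CPS_PER_MBQ,
    background_rate: float = BACKGROUND_CPS_PER_PIXEL_64,
    hilar_fraction: float = HILAR_FRACTION,
) -> tuple[DynamicStudy, DynamicStudy, DelayedImage]:
    """Render a full study (upright + supine dynamics, delayed static).

    Deterministic given the seed.  Compartment activities are physically
    decayed before rendering.
    """
    protocol = protocol or series.protocol or AcquisitionProtocol()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    decayed = {name: series.decayed(name) for name in series.activity}
    times = series.times_minutes

    def index_of(t: float) -> int:
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) > 1e-9:
            raise ValueError(f"activity series does not cover t={t} min")
        return i

    studies = []
    for posture in ("upright", "supine"):
        mids = protocol.frame_midpoints_minutes(posture)
        dur = (
            protocol.upright_frame_seconds
            if posture == "upright"
            else protocol.supine_frame_seconds
        )
        frames = np.empty(
            (len(mids), protocol.dynamic_matrix, protocol.dynamic_matrix), dtype=np.int64
        )
        for k, t in enumerate(mids):
            acts = {name: decayed[name][index_of(t)] for name in decayed}
            mu = expected_frame(
                acts, protocol.dynamic_matrix, dur, sensitivity, background_rate, hilar_fraction
            )
            frames[k] = rng.poisson(mu)
        studies.append(
            DynamicStudy(
                posture=posture,
                frames=frames,
                frame_times=protocol.frame_start_times(posture),
                protocol=protocol,
            )
        )

    i = index_of(protocol.delayed_minutes)
    acts = {name: decayed[name][i] for name in decayed}
    mu = expected_frame(
        acts,
        protocol.delayed_matrix,
        protocol.delayed_duration_seconds,
        sensitivity,
        background_rate,
        hilar_fraction,
    )
    delayed = DelayedImage(
        pixels=rng.poisson(mu).astype(np.int64),
        acquisition_time_minutes=protocol.delayed_time_minutes,
        protocol=protocol,
    )
    return studies[0], studies[1], delayed
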