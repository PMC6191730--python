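"""Pulmonary aspiration detection on the delayed image.

A transverse line profile is taken through the hilar regions of the
delayed static image; the call is positive when the peak lung count
density exceeds twice the body background (read strictly: ratio must be
> threshold).  The profile row defaults to the row within the hilar band
that maximizes summed lung-zone counts, which makes the choice
reproducible and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .render import DelayedImage, scaled_zones


class GeometryError(ValueError):
    pass


@dataclass
class LineProfile:
    """Counts per pixel along one image row (optionally band-averaged)."""

    row: int
    band: int                 # number of rows averaged (odd)
    values: np.ndarray        # one value per column
    background_level: float   # mean counts/pixel of the reference region

    def __post_init__(self) -> None:
        if len(self.values) < 16:
            raise ValueError("profile path must be at least 16 pixels")


@dataclass(frozen=True)
class AspirationCall:
    positive: bool
    max_ratio: float
    side: str                 # left | right | both | none
    row: int
    threshold: float


def background_level(image: DelayedImage, background_pixels: np.ndarray) -> float:
    """Mean counts/pixel over the reference (lateral chest) region."""
    pix = np.asarray(background_pixels, dtype=int)
    if pix.size == 0:
        raise ValueError("background region must be non-empty")
    return float(image.pixels[pix[:, 0], pix[:, 1]].mean())


def line_profile(
    image: DelayedImage,
    row: int,
    background_pixels: np.ndarray,
    band: int = 1,
) -> LineProfile:
    """Extract a transverse count-density profile through ``row``.

    With ``band`` > 1 the profile is the mean over a band of that many
    rows centred on ``row`` (band must be odd and fit in the image).
    """
    n = image.pixels.shape[0]
    if not 0 <= row < n:
        raise GeometryError(f"row {row} outside image of {n} rows")
    if band < 1 or band % 2 == 0:
        raise ValueError("band must be a positive odd integer")
    half = band // 2
    if row - half < 0 or row + half >= n:
        raise GeometryError("band extends outside the image")
    values = image.pixels[row - half : row + half + 1, :].mean(axis=0)
    level = background_level(image, background_pixels)
    if level <= 0:
        raise ValueError("background level must be positive")
    return LineProfile(row=row, band=band, values=values, background_level=level)


def select_hilar_row(image: DelayedImage, band: int = 9) -> int:
    """Row within the hilar band maximizing band-summed lung-zone counts."""
    matrix = image.pixels.shape[0]
    zones = scaled_zones(matrix)
    r0, r1, _, _ = zones["hilum_left"]
    cols = np.r_[
        np.arange(*zones["lung_left"][2:]), np.arange(*zones["lung_right"][2:])
    ]
    half = band // 2
    best_row, best_sum = r0, -1.0
    for row in range(max(r0, half), min(r1, matrix - half)):
        s = image.pixels[row - half : row + half + 1][:, cols].sum()
        if s > best_sum:
            best_row, best_sum = row, s
    return best_row


def detect_aspiration(
    profile: LineProfile,
    lung_columns: dict | None = None,
    threshold: float = 2.0,
    matrix: int | None = None,
) -> AspirationCall:
    """Call aspiration from a line profile.

    ``max_ratio`` is the maximum profile value over lung-zone columns
    divided by the background level; the call is positive iff strictly
    greater than ``threshold``.  ``lung_columns`` maps 'left'/'right' to
    half-open column ranges; by default the schematic lung zones of the
    matrix inferred from the profile length are used.
    """
    if profile.background_level <= 0:
        raise ValueError("background level must be positive")
    if lung_columns is None:
        m = matrix or len(profile.values)
        zones = scaled_zones(m)
        lung_columns = {
            "left": zones["lung_left"][2:],
            "right": zones["lung_right"][2:],
        }
    ratios = {}
    for side, (c0, c1) in lung_columns.items():
        ratios[side] = float(profile.values[c0:c1].max() / profile.background_level)
    max_ratio = max(ratios.values())
    exceeding = [s for s, r in ratios.items() if r > threshold]
    if len(exceeding) == 2:
        side = "both"
    elif exceeding:
        side = exceeding[0]
    else:
        side = "none"
    return AspirationCall(
        positive=max_ratio > threshold,
        max_ratio=max_ratio,
        side=side,
        row=profile.row,
        threshold=threshold,
    )


def call_aspiration(
    image: DelayedImage,
    threshold: float = 2.0,
    band: int = 9,
) -> AspirationCall:
    """End-to-end call on a delayed image with the default conventions:
    hilar row selection, band-averaged profile, lateral-chest background."""
    matrix = image.pixels.shape[0]
    zones = scaled_zones(matrix)
    r0, r1, c0, c1 = zones["background"]
    rr, cc = np.mgrid[r0:r1, c0:c1]
    bg_pixels = np.column_stack([rr.ravel(), cc.ravel()])
    row = select_hilar_row(image, band=band)
    profile = line_profile(image, row, bg_pixels, band=band)
    return detect_aspiration(profile, threshold=threshold, matrix=matrix)
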