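"""Gamma-camera acquisition protocol for the reflux study.

The study has three imaging segments: an upright dynamic acquisition
immediately after the Tc-99m DTPA swallow, a supine dynamic acquisition,
and a delayed static image acquired two hours after an oral Tc-99m
colloid dose to look for pulmonary aspiration of refluxate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Physical half-life of Tc-99m in hours.
TC99M_HALF_LIFE_HOURS = 6.0067


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and matrix parameters of the acquisition.

    Times within a dynamic segment are seconds from the start of that
    segment; absolute study time is minutes from the DTPA swallow.
    Frame intervals are half-open ``[t, t + dt)``.
    """

    upright_frame_seconds: float = 15.0
    upright_duration_seconds: float = 120.0
    supine_frame_seconds: float = 30.0
    supine_duration_seconds: float = 1800.0
    dynamic_matrix: int = 64
    delayed_matrix: int = 256
    #: Delay of the static image after the colloid dose.
    delayed_time_minutes: float = 120.0
    #: Time of the oral colloid dose, minutes after the DTPA swallow
    #: (upright segment + supine segment).
    colloid_time_minutes: float = 32.0
    #: Exposure of the delayed static image.
    delayed_duration_seconds: float = 600.0
    isotope_half_life_hours: float = TC99M_HALF_LIFE_HOURS

    def __post_init__(self) -> None:
        for name in (
            "upright_frame_seconds",
            "upright_duration_seconds",
            "supine_frame_seconds",
            "supine_duration_seconds",
            "delayed_duration_seconds",
            "isotope_half_life_hours",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.upright_duration_seconds % self.upright_frame_seconds:
            raise ValueError("upright duration must be a multiple of frame time")
        if self.supine_duration_seconds % self.supine_frame_seconds:
            raise ValueError("supine duration must be a multiple of frame time")

    @property
    def n_upright_frames(self) -> int:
        return int(round(self.upright_duration_seconds / self.upright_frame_seconds))

    @property
    def n_supine_frames(self) -> int:
        return int(round(self.supine_duration_seconds / self.supine_frame_seconds))

    @property
    def supine_start_minutes(self) -> float:
        """Start of the supine segment, minutes after the swallow."""
        return self.upright_duration_seconds / 60.0

    @property
    def delayed_minutes(self) -> float:
        """Absolute time of the delayed image, minutes after the swallow."""
        return self.colloid_time_minutes + self.delayed_time_minutes

    def frame_start_times(self, posture: str) -> np.ndarray:
        """Frame start times in seconds from the segment start."""
        if posture == "upright":
            n, dt = self.n_upright_frames, self.upright_frame_seconds
        elif posture == "supine":
            n, dt = self.n_supine_frames, self.supine_frame_seconds
        else:
            raise ValueError(f"unknown posture {posture!r}")
        return np.arange(n) * dt

    def frame_midpoints_minutes(self, posture: str) -> np.ndarray:
        """Absolute frame mid-point times in minutes from the swallow."""
        if posture == "upright":
            start, dt = 0.0, self.upright_frame_seconds
        else:
            start, dt = self.supine_start_minutes, self.supine_frame_seconds
        return start + (self.frame_start_times(posture) + 0.5 * dt) / 60.0

    def decay_factor(self, t_minutes) -> np.ndarray:
        """Fraction of activity remaining after ``t_minutes`` of physical decay."""
        return np.power(2.0, -np.asarray(t_minutes, dtype=float) / (self.isotope_half_life_hours * 60.0))
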