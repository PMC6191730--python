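"""Compartmental tracer-kinetics simulator for a reflux study.

A six-compartment model stands in for the physiology the gamma camera
images: stomach, lower/mid/upper oesophagus, pharynx and lungs.  The
swallowed bolus reaches the stomach within the first frame (a small
residual fraction lingers in the pharynx and oesophagus after the water
flush and clears like refluxate).  The stomach empties first-order with a
configurable half-time.  Reflux events arrive as a Poisson process at a
posture-specific rate; each event instantaneously carries a fraction of
the current gastric activity up to the patient's maximum reflux height,
distributing it over the traversed compartments.  Oesophageal and
pharyngeal activity returns to the stomach first-order at the clearance
rate (low clearance = ineffective oesophageal motility).  During
pharyngeal events a fixed fraction of the pharyngeal deposit is aspirated
irreversibly into the lungs.  All simulation is done decay-free; physical
decay of Tc-99m is applied when activities are sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionProtocol

COMPARTMENTS = ("pharynx", "upper", "mid", "lower", "stomach", "lungs")

#: Ordinal reflux heights, lowest to highest.
HEIGHTS = ("lower", "mid", "upper", "pharynx")

#: Compartments traversed by an event of each maximum height.
_TRAVERSED = {
    "lower": ("lower",),
    "mid": ("lower", "mid"),
    "upper": ("lower", "mid", "upper"),
    "pharynx": ("lower", "mid", "upper", "pharynx"),
}

#: The topmost compartment of an event receives double weight: the bolus
#: comes to rest at its maximum height, the rest is pass-through coating.
_TOP_WEIGHT = 2.0

#: Split of the post-swallow residual over pharynx/oesophagus.
_RESIDUAL_SHARES = {"pharynx": 0.30, "upper": 0.30, "mid": 0.20, "lower": 0.20}


@dataclass(frozen=True)
class KineticsParams:
    """Ground-truth simulator parameters for one patient."""

    gastric_half_time: float = 25.2          # minutes
    reflux_event_rate_upright: float = 0.0   # events / min
    reflux_event_rate_supine: float = 0.0    # events / min
    max_reflux_height: str = "pharynx"
    reflux_fraction: float = 0.08            # of gastric activity per event
    clearance_rate: float = 0.25             # 1 / min, back toward the stomach
    aspiration_fraction: float = 0.0         # of pharyngeal deposit, to lungs
    administered_activity: float = 50.0      # MBq
    residual_fraction: float = 0.04          # of bolus left above the stomach

    def validate(self) -> None:
        vals = {
            "gastric_half_time": self.gastric_half_time,
            "reflux_event_rate_upright": self.reflux_event_rate_upright,
            "reflux_event_rate_supine": self.reflux_event_rate_supine,
            "reflux_fraction": self.reflux_fraction,
            "clearance_rate": self.clearance_rate,
            "aspiration_fraction": self.aspiration_fraction,
            "administered_activity": self.administered_activity,
            "residual_fraction": self.residual_fraction,
        }
        for name, v in vals.items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.gastric_half_time <= 0:
            raise ValueError("gastric_half_time must be > 0")
        if self.reflux_event_rate_upright < 0 or self.reflux_event_rate_supine < 0:
            raise ValueError("reflux event rates must be >= 0")
        if not 0.0 <= self.reflux_fraction <= 1.0:
            raise ValueError("reflux_fraction must be in [0, 1]")
        if self.clearance_rate < 0:
            raise ValueError("clearance_rate must be >= 0")
        if not 0.0 <= self.aspiration_fraction <= 1.0:
            raise ValueError("aspiration_fraction must be in [0, 1]")
        if not 40.0 <= self.administered_activity <= 60.0:
            raise ValueError("administered_activity must be in [40, 60] MBq")
        if not 0.0 <= self.residual_fraction < 1.0:
            raise ValueError("residual_fraction must be in [0, 1)")
        if self.max_reflux_height not in HEIGHTS:
            raise ValueError(f"max_reflux_height must be one of {HEIGHTS}")
        if self.aspiration_fraction > 0 and self.max_reflux_height != "pharynx":
            raise ValueError("aspiration requires max_reflux_height='pharynx'")


@dataclass
class ActivitySeries:
    """Per-compartment activity sampled at frame mid-points.

    ``activity`` holds decay-corrected (decay-free) MBq; ``decayed()``
    applies Tc-99m physical decay for rendering.  ``administered`` is the
    total activity put into the system up to each sample time (DTPA, plus
    the colloid dose once given), so that decay-corrected conservation
    can be checked: sum over compartments + ``emptied`` == administered.
    """

    times_minutes: np.ndarray
    activity: dict = field(default_factory=dict)  # name -> MBq array
    emptied: np.ndarray = None
    administered: np.ndarray = None
    protocol: AcquisitionProtocol = None

    def decayed(self, name: str) -> np.ndarray:
        return self.activity[name] * self.protocol.decay_factor(self.times_minutes)

    def at_time(self, t_minutes: float) -> dict:
        i = int(np.argmin(np.abs(self.times_minutes - t_minutes)))
        if abs(self.times_minutes[i] - t_minutes) > 1e-6:
            raise KeyError(f"time {t_minutes} min was not sampled")
        return {name: self.activity[name][i] for name in COMPARTMENTS}

    def total(self) -> np.ndarray:
        """Decay-corrected total including the emptied (intestinal) outflow."""
        return sum(self.activity[n] for n in COMPARTMENTS) + self.emptied


def _propagate(state: dict, dt: float, k_clear: float, k_empty: float) -> None:
    """Advance the between-event linear dynamics by ``dt`` minutes in place.

    Oesophageal compartments drain to the stomach at ``k_clear``; the
    stomach empties at ``k_empty``.  Closed-form solution of the coupled
    linear system; the emptied amount is recovered by conservation.
    """
    if dt <= 0:
        return
    e_names = ("pharynx", "upper", "mid", "lower")
    e0 = sum(state[n] for n in e_names)
    decay_c = math.exp(-k_clear * dt)
    decay_e = math.exp(-k_empty * dt)
    if abs(k_empty - k_clear) > 1e-12:
        transfer = k_clear * e0 * (decay_c - decay_e) / (k_empty - k_clear)
    else:
        transfer = k_clear * e0 * dt * decay_c
    total0 = sum(state[n] for n in COMPARTMENTS) + state["emptied"]
    for n in e_names:
        state[n] *= decay_c
    state["stomach"] = state["stomach"] * decay_e + transfer
    state["emptied"] = total0 - sum(state[n] for n in COMPARTMENTS)


def _reflux_event(state: dict, params: KineticsParams) -> None:
    """Apply one instantaneous reflux event in place."""
    moved = params.reflux_fraction * state["stomach"]
    if moved <= 0:
        return
    state["stomach"] -= moved
    traversed = _TRAVERSED[params.max_reflux_height]
    weights = np.ones(len(traversed))
    weights[-1] = _TOP_WEIGHT
    shares = moved * weights / weights.sum()
    for name, share in zip(traversed, shares):
        if name == "pharynx" and params.aspiration_fraction > 0:
            aspirated = params.aspiration_fraction * share
            state["lungs"] += aspirated
            share -= aspirated
        state[name] += share
    state["n_events"] += 1


def simulate_kinetics(
    params: KineticsParams,
    protocol: AcquisitionProtocol | None = None,
    seed: int | np.random.Generator = 0,
) -> ActivitySeries:
    """Simulate one patient's tracer kinetics over the full study.

    Returns activities at every dynamic frame mid-point of both postures
    plus the delayed time point, in decay-free MBq.  Deterministic given
    the seed (or Generator).
    """
    params.validate()
    protocol = protocol or AcquisitionProtocol()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t_sup = protocol.supine_start_minutes
    t_col = protocol.colloid_time_minutes
    t_end = protocol.delayed_minutes
    # Posture segments with their event rates: upright, supine, upright again
    # between the colloid dose and the delayed image.
    segments = [
        (0.0, t_sup, params.reflux_event_rate_upright),
        (t_sup, t_col, params.reflux_event_rate_supine),
        (t_col, t_end, params.reflux_event_rate_upright),
    ]
    events = []
    for a, b, rate in segments:
        n = rng.poisson(rate * (b - a))
        events.extend(rng.uniform(a, b, size=n))
    events.sort()

    sample_times = np.concatenate(
        [
            protocol.frame_midpoints_minutes("upright"),
            protocol.frame_midpoints_minutes("supine"),
            [t_end],
        ]
    )

    a0 = params.administered_activity
    state = {n: 0.0 for n in COMPARTMENTS}
    state["emptied"] = 0.0
    state["n_events"] = 0
    for name, share in _RESIDUAL_SHARES.items():
        state[name] = params.residual_fraction * a0 * share
    state["stomach"] = a0 * (1.0 - params.residual_fraction)

    k_empty = math.log(2.0) / params.gastric_half_time
    k_clear = params.clearance_rate

    # Merge events, the colloid dose and sample times into one timeline.
    timeline = [(t, "event") for t in events]
    timeline.append((t_col, "colloid"))
    timeline.extend((t, i) for i, t in enumerate(sample_times))
    # Samples sort after events/colloid at identical times (ints > strs is not
    # defined, so key on a tag rank instead).
    rank = {"event": 0, "colloid": 1}
    timeline.sort(key=lambda x: (x[0], rank.get(x[1], 2)))

    out = {name: np.empty(len(sample_times)) for name in COMPARTMENTS}
    emptied = np.empty(len(sample_times))
    administered = np.empty(len(sample_times))
    given = a0
    t_now = 0.0
    for t, tag in timeline:
        _propagate(state, t - t_now, k_clear, k_empty)
        t_now = t
        if tag == "event":
            _reflux_event(state, params)
        elif tag == "colloid":
            state["stomach"] += a0
            given += a0
        else:
            for name in COMPARTMENTS:
                out[name][tag] = state[name]
            emptied[tag] = state["emptied"]
            administered[tag] = given

    return ActivitySeries(
        times_minutes=sample_times,
        activity=out,
        emptied=emptied,
        administered=administered,
        protocol=protocol,
    )
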