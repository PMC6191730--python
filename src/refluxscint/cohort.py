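"""Synthetic patient cohort generator.

Generates ground-truth patient records (symptom class, oesophageal
motility grade, LOS pressure, 24-h pH covariates, aspiration status) and
the tracer-kinetics parameters that drive each patient's simulated
images.  Defaults reproduce the study cohort marginals: 250 patients,
72 GORD / 178 LPR, aspiration 10/72 and 58/178, severe IOM 35% (LPR) vs
17% (GORD), normal motility 27% vs 49%, pH categories 25/78/147, and LOS
pressure lognormal with mean 6.3 / median 2.3 mmHg.

Within-patient covariate couplings are induced by a Gaussian copula:
a latent motility severity variable drives the IOM grade, is correlated
with the aspiration indicator (tetrachoric correlation solved so the
realized Pearson phi matches the configured per-class target) and with a
latent reflux-intensity variable, so that poor motility, vigorous reflux
and aspiration co-occur the way the clinical data describe.  Kinetics are
derived from the same latents, which makes curve grade and lung uptake
emergent properties rather than labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .kinetics import KineticsParams

IOM_GRADES = ("normal", "mild", "moderate", "severe")
PH_CATEGORIES = ("normal", "weakly_acidic", "abnormal")


class ConfigError(ValueError):
    """Inconsistent cohort configuration; names the offending field."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's ground-truth covariates."""

    patient_id: str
    symptom_class: str            # GORD | LPR
    age: float                    # years, 20-85
    sex: str                      # F | M
    iom_grade: str                # normal | mild | moderate | severe
    los_pressure: float           # mmHg
    proximal_acid_pct: float      # % of 24 h with pH < 4
    distal_acid_pct: float
    ph_category: str              # normal | weakly_acidic | abnormal
    episode_min_ph: float         # representative episode nadir pH
    true_aspiration: bool


@dataclass(frozen=True)
class CohortConfig:
    """Cohort marginals and coupling targets."""

    n_total: int = 250
    n_gord: int = 72
    n_lpr: int = 178
    aspiration_prob_gord: float = 10.0 / 72.0
    aspiration_prob_lpr: float = 58.0 / 178.0
    #: P(severe IOM) per symptom class.
    severe_iom_prob: dict = field(
        default_factory=lambda: {"GORD": 0.17, "LPR": 0.35}
    )
    #: P(normal motility) per symptom class.
    normal_motility_prob: dict = field(
        default_factory=lambda: {"GORD": 0.49, "LPR": 0.27}
    )
    #: (location, scale) of LOS pressure on the log scale.
    los_lognormal_params: tuple = (math.log(2.3), 1.42)
    #: P(normal), P(weakly acidic), P(abnormal) for the 24-h pH study.
    ph_category_probs: tuple = (25.0 / 250.0, 78.0 / 250.0, 147.0 / 250.0)
    #: Target Pearson correlations for the copula couplings.
    covariate_correlations: dict = field(
        default_factory=lambda: {
            "proximal_distal_acid": 0.32,
            "iom_aspiration_gord": 0.21,
            "iom_aspiration_lpr": 0.54,
            "iom_reflux": 0.60,
        }
    )
    female_fraction: float = 155.0 / 250.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_total <= 0:
            raise ConfigError("n_total must be positive")
        if self.n_gord + self.n_lpr != self.n_total:
            raise ConfigError("n_gord + n_lpr must equal n_total")
        if self.n_gord < 0 or self.n_lpr < 0:
            raise ConfigError("n_gord and n_lpr must be non-negative")
        for name in ("aspiration_prob_gord", "aspiration_prob_lpr", "female_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        if abs(sum(self.ph_category_probs) - 1.0) > 1e-9:
            raise ConfigError("ph_category_probs must sum to 1")
        for cls in ("GORD", "LPR"):
            p_sev = self.severe_iom_prob.get(cls)
            p_norm = self.normal_motility_prob.get(cls)
            if p_sev is None or p_norm is None:
                raise ConfigError(f"severe_iom_prob/normal_motility_prob missing {cls}")
            if not (0 <= p_sev <= 1 and 0 <= p_norm <= 1 and p_sev + p_norm <= 1):
                raise ConfigError(f"IOM probabilities inconsistent for {cls}")


def classify_ph(episode_ph: "np.ndarray | list") -> str:
    """Classify one reflux episode by its nadir pH.

    Acid reflux is a fall below pH 4; weakly acid is a nadir >= 4 but
    < 7; non-acid stays at or above pH 7.
    """
    values = np.asarray(episode_ph, dtype=float)
    if values.size == 0:
        raise ValueError("episode pH sequence must be non-empty")
    if np.any(values < 0) or np.any(values > 14):
        raise ValueError("pH values must lie in [0, 14]")
    nadir = values.min()
    if nadir < 4.0:
        return "acid"
    if nadir < 7.0:
        return "weakly_acid"
    return "non_acid"


def _bvn_upper(q1: float, q2: float, rho: float) -> float:
    """P(Z1 > q1, Z2 > q2) for standard bivariate normal with corr rho."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    return 1.0 - stats.norm.cdf(q1) - stats.norm.cdf(q2) + mvn.cdf([q1, q2])


@lru_cache(maxsize=64)
def _tetrachoric_rho(p1: float, p2: float, target_phi: float) -> float:
    """Latent normal correlation so two thresholded indicators with
    marginals ``p1``/``p2`` have Pearson correlation ``target_phi``."""
    q1, q2 = stats.norm.ppf(1.0 - p1), stats.norm.ppf(1.0 - p2)
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def phi(rho):
        return (_bvn_upper(q1, q2, rho) - p1 * p2) / denom - target_phi

    return optimize.brentq(phi, -0.995, 0.995, xtol=1e-10)


@lru_cache(maxsize=16)
def _lognormal_rho(sigma1: float, sigma2: float, target_r: float) -> float:
    """Latent correlation giving Pearson ``target_r`` between two
    lognormals with log-scale SDs sigma1, sigma2 (closed form)."""
    denom = math.sqrt(
        (math.exp(sigma1**2) - 1.0) * (math.exp(sigma2**2) - 1.0)
    )
    return math.log(1.0 + target_r * denom) / (sigma1 * sigma2)


# Log-scale parameters of the % acid-exposure marginals (distal exposure
# is typically several-fold higher than proximal).
_PROX_ACID_LOG = (math.log(2.0), 1.0)
_DIST_ACID_LOG = (math.log(8.0), 0.9)

#: Oesophageal clearance rate (1/min) by IOM grade: ineffective motility
#: means slow return of refluxate to the stomach.
_CLEARANCE_BY_IOM = {"normal": 0.35, "mild": 0.20, "moderate": 0.10, "severe": 0.04}

#: P(maximum reflux height) per class for non-aspirators, ordered
#: (lower, mid, upper, pharynx).  LPR is defined by pharyngeal reach.
_HEIGHT_PROBS = {
    "LPR": (0.05, 0.10, 0.25, 0.60),
    "GORD": (0.25, 0.30, 0.30, 0.15),
}
_HEIGHT_NAMES = ("lower", "mid", "upper", "pharynx")

#: Nadir-pH sampling range per 24-h pH category, consistent with the
#: episode classification rule.
_PH_RANGE = {"normal": (7.0, 8.0), "weakly_acidic": (4.0, 6.9), "abnormal": (1.0, 3.9)}

#: Baseline supine reflux-event rate (events/min) on the log scale.
_REFLUX_RATE_LOG = (math.log(0.18), 0.7)
#: Minimum supine event rate for aspirators: aspiration requires
#: recurrent pharyngeal reflux to carry tracer into the airways.
_ASPIRATOR_RATE_FLOOR = 0.2


def _iom_cutpoints(cfg: CohortConfig, cls: str) -> np.ndarray:
    """Latent-normal cutpoints for the 4 IOM grades of one class."""
    p_norm = cfg.normal_motility_prob[cls]
    p_sev = cfg.severe_iom_prob[cls]
    rest = 1.0 - p_norm - p_sev
    probs = np.array([p_norm, rest / 2.0, rest / 2.0, p_sev])
    return stats.norm.ppf(np.cumsum(probs)[:-1])


def generate_patient(
    index: int, cls: str, cfg: CohortConfig, rng: np.random.Generator
) -> tuple[PatientRecord, KineticsParams]:
    """Draw one patient from the configured cohort distribution."""
    corr = cfg.covariate_correlations
    p_asp = cfg.aspiration_prob_gord if cls == "GORD" else cfg.aspiration_prob_lpr
    phi_target = corr[f"iom_aspiration_{cls.lower()}"]

    z_iom = rng.standard_normal()
    # Aspiration indicator correlated with motility severity.
    if 0 < p_asp < 1 and cfg.severe_iom_prob[cls] not in (0.0, 1.0):
        rho = _tetrachoric_rho(cfg.severe_iom_prob[cls], p_asp, phi_target)
    else:
        rho = 0.0
    z_asp = rho * z_iom + math.sqrt(1.0 - rho**2) * rng.standard_normal()
    aspirates = bool(p_asp > 0 and z_asp > stats.norm.ppf(1.0 - p_asp))

    cuts = _iom_cutpoints(cfg, cls)
    iom_grade = IOM_GRADES[int(np.searchsorted(cuts, z_iom))]

    a = corr["iom_reflux"]
    z_reflux = a * z_iom + math.sqrt(1.0 - a**2) * rng.standard_normal()

    # pH covariates.  Proximal acid exposure is weakly loaded on the
    # aspiration latent: refluxate that reaches the airways also bathes
    # the proximal probe, making proximal (but not distal) acid exposure
    # a marginal predictor of aspiration.
    rho_acid = _lognormal_rho(_PROX_ACID_LOG[1], _DIST_ACID_LOG[1], corr["proximal_distal_acid"])
    b = corr.get("aspiration_proximal_acid", 0.25)
    z_prox = b * z_asp + math.sqrt(1.0 - b**2) * rng.standard_normal()
    z_dist = rho_acid * z_prox + math.sqrt(1.0 - rho_acid**2) * rng.standard_normal()
    proximal_acid = math.exp(_PROX_ACID_LOG[0] + _PROX_ACID_LOG[1] * z_prox)
    distal_acid = math.exp(_DIST_ACID_LOG[0] + _DIST_ACID_LOG[1] * z_dist)

    ph_category = PH_CATEGORIES[rng.choice(3, p=np.asarray(cfg.ph_category_probs))]
    episode_min_ph = rng.uniform(*_PH_RANGE[ph_category])

    loc, scale = cfg.los_lognormal_params
    los = math.exp(loc + scale * rng.standard_normal())

    age = float(np.clip(rng.normal(60.0, 13.0), 20.0, 85.0))
    sex = "F" if rng.random() < cfg.female_fraction else "M"

    record = PatientRecord(
        patient_id=f"P{index:04d}",
        symptom_class=cls,
        age=age,
        sex=sex,
        iom_grade=iom_grade,
        los_pressure=los,
        proximal_acid_pct=proximal_acid,
        distal_acid_pct=distal_acid,
        ph_category=ph_category,
        episode_min_ph=episode_min_ph,
        true_aspiration=aspirates,
    )

    # --- kinetics derived from the same latents ---
    clearance = _CLEARANCE_BY_IOM[iom_grade] * math.exp(0.2 * rng.standard_normal())
    rate_supine = math.exp(_REFLUX_RATE_LOG[0] + _REFLUX_RATE_LOG[1] * z_reflux)
    rate_supine = min(rate_supine, 1.2)
    if aspirates:
        rate_supine = max(rate_supine, _ASPIRATOR_RATE_FLOOR)
        height = "pharynx"
        asp_fraction = rng.uniform(0.08, 0.25)
    else:
        height = _HEIGHT_NAMES[rng.choice(4, p=np.asarray(_HEIGHT_PROBS[cls]))]
        asp_fraction = 0.0

    kinetics = KineticsParams(
        gastric_half_time=float(np.clip(25.2 * math.exp(0.25 * rng.standard_normal()), 10.0, 60.0)),
        reflux_event_rate_upright=0.5 * rate_supine,
        reflux_event_rate_supine=rate_supine,
        max_reflux_height=height,
        reflux_fraction=rng.uniform(0.05, 0.12),
        clearance_rate=clearance,
        aspiration_fraction=asp_fraction,
        administered_activity=rng.uniform(40.0, 60.0),
    )
    return record, kinetics


def patient_seed_sequence(master_seed: int, index: int) -> np.random.SeedSequence:
    """Documented substream scheme: entropy = (master seed, patient index),
    so cohorts are extensible without reshuffling earlier patients."""
    return np.random.SeedSequence(entropy=(master_seed, index))


def generate_cohort(config: CohortConfig | None = None):
    """Generate the full cohort as a list of (PatientRecord, KineticsParams).

    Deterministic given ``config.seed``; class counts are exact.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    cohort = []
    for i in range(cfg.n_total):
        cls = "GORD" if i < cfg.n_gord else "LPR"
        rng = np.random.default_rng(patient_streams(cfg.seed, i)[0])
        cohort.append(generate_patient(i, cls, cfg, rng))
    return cohort


def patient_streams(master_seed: int, index: int) -> list:
    """Three per-patient child streams: covariates, kinetics, rendering."""
    return patient_seed_sequence(master_seed, index).spawn(3)


def cohort_with_seed(config: CohortConfig | None, seed: int) -> CohortConfig:
    """Copy of ``config`` (or the defaults) with a different master seed."""
    return replace(config or CohortConfig(), seed=seed)
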