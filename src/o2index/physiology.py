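"""Minimal oxygen-transport state model.

The latent patient state couples whole-body oxygen consumption (VO2), cardiac
output (CO), hemoglobin, and arterial saturation through the Fick principle:

    SvO2 = SaO2 - VO2 / (CO * 10 * 1.34 * Hgb)

so mixed venous saturation is a derived quantity, never a free state. Blood
flow comes from a pulse-pressure stroke-volume law (Liljestrand-Zander form)
scaled by a patient-specific vascular gain ``k_sv``, times heart rate. Free
states drift as mean-reverting Ornstein-Uhlenbeck (OU) processes, which gives
the estimator an explicit model of slow physiological wander and lets
information from sparse labs decay at a controlled timescale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import yaml

from .streams import ChannelKind

__all__ = [
    "PhysioState",
    "PhysioParams",
    "arterial_o2_content",
    "stroke_volume",
    "fick_svo2",
    "cardiac_output",
    "propagate",
    "predict_observation",
    "ou_step_coefficients",
]

#: mL of O2 bound per gram of hemoglobin at full saturation (Hufner constant).
O2_CAPACITY_ML_PER_G = 1.34


@dataclass
class PhysioParams:
    """Model constants, OU dynamics, noise model and priors. Units in key names."""

    o2_capacity_ml_per_g: float = O2_CAPACITY_ML_PER_G
    svo2_threshold_pct: float = 50.0

    # OU mean-reversion timescales (hours) for the free states
    vo2_tau_hours: float = 2.0
    ksv_tau_hours: float = 12.0
    hgb_tau_hours: float = 24.0
    sao2_tau_hours: float = 1.0
    co_tau_hours: float = 2.0       # used only when pressure/HR drivers are absent

    # stationary OU standard deviations, as fractions of the state mean
    vo2_sd_frac: float = 0.30
    ksv_sd_frac: float = 0.20
    hgb_sd_frac: float = 0.10
    sao2_sd_frac: float = 0.03
    co_sd_frac: float = 0.20

    # observation noise (measurement model)
    spo2_sd_pct: float = 1.5
    svo2_lab_sd_pct: float = 1.0
    svo2_cont_sd_pct: float = 2.0
    hgb_lab_sd_g_dl: float = 0.3
    ci_cont_sd_l_min_m2: float = 0.25
    ci_aperiodic_sd_l_min_m2: float = 0.20
    # continuous-channel errors are autocorrelated, not white at 5 s; their
    # per-sample SDs are inflated by sqrt(decorrelation interval / cadence)
    # (default: 3 min at 5 s sampling -> sqrt(36) = 6) when assimilated
    cont_obs_sd_inflation: float = 6.0

    # hierarchical VO2 baseline: each particle carries its own attractor,
    # itself mean-reverting slowly toward the population value, so the filter
    # can learn a patient's resting oxygen consumption instead of asserting it
    vo2_mean_tau_hours: float = 36.0
    vo2_mean_sd_frac: float = 0.20
    vo2_mean_prior_sigma_log: float = 0.20

    # priors for filter initialization
    co_prior_median_l_min: float = 5.0
    co_prior_sigma_log: float = 0.25
    vo2_prior_median_ml_min: float = 250.0
    vo2_prior_sigma_log: float = 0.15  # local spread around each baseline
    hgb_prior_sd_g_dl: float = 1.0
    hgb_default_g_dl: float = 12.0
    sao2_prior_sd_frac: float = 0.02

    # particle filter controls
    n_particles: int = 2000
    ess_fraction: float = 0.5
    # Liu-West shrinkage kernel applied at resampling: particles shrink
    # toward the weighted mean by a = sqrt(1 - h^2) and receive h * ensemble-SD
    # Gaussian noise, preserving the posterior mean and variance while
    # regenerating diversity (h = 0 disables the kernel; degenerate states
    # stay exactly degenerate)
    resample_bandwidth: float = 0.1

    # gating / data-availability policy
    staleness_s: float = 60.0
    hgb_max_age_h: float = 24.0

    # auxiliary physiology
    temp_vo2_pct_per_degc: float = 10.0   # VO2 mean inflation per deg C above 37
    age_ksv_slope_per_year: float = -0.003  # relative k_sv prior shift per year from 64
    bsa_default_m2: float = 1.9

    def validate(self) -> None:
        for name in (
            "spo2_sd_pct", "svo2_lab_sd_pct", "svo2_cont_sd_pct", "hgb_lab_sd_g_dl",
            "ci_cont_sd_l_min_m2", "ci_aperiodic_sd_l_min_m2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("vo2_sd_frac", "ksv_sd_frac", "hgb_sd_frac", "sao2_sd_frac", "co_sd_frac"):
            if getattr(self, name) < 0:  # zero volatility = frozen state, allowed
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.svo2_threshold_pct < 100.0):
            raise ValueError("svo2_threshold_pct must lie strictly inside (0, 100)")
        if self.n_particles < 100:
            raise ValueError("n_particles must be at least 100")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhysioParams":
        data = yaml.safe_load(Path(path).read_text())
        p = cls(**data)
        p.validate()
        return p

    # observation SD lookup by channel kind
    def obs_sd(self, kind: ChannelKind) -> float:
        return {
            ChannelKind.SPO2: self.spo2_sd_pct,
            ChannelKind.SVO2_LAB: self.svo2_lab_sd_pct,
            ChannelKind.SVO2_CONT: self.svo2_cont_sd_pct,
            ChannelKind.HGB_LAB: self.hgb_lab_sd_g_dl,
            ChannelKind.CI_CONT: self.ci_cont_sd_l_min_m2,
            ChannelKind.CI_APERIODIC: self.ci_aperiodic_sd_l_min_m2,
        }[kind]


@dataclass
class PhysioState:
    """Latent oxygen-transport state at one instant.

    ``svo2_frac`` is derived through the Fick closure and is refreshed by
    :func:`propagate`; it is stored for convenience, never free.
    """

    co_l_min: float
    vo2_ml_min: float
    hgb_g_dl: float
    sao2_frac: float
    k_sv: float
    svo2_frac: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.co_l_min <= 0:
            raise ValueError("co_l_min must be positive")
        if self.vo2_ml_min < 0:
            raise ValueError("vo2_ml_min must be non-negative")
        if not (0.0 <= self.sao2_frac <= 1.0):
            raise ValueError("sao2_frac must lie in [0, 1]")
        if self.hgb_g_dl <= 0:
            raise ValueError("hgb_g_dl must be positive")
        if self.k_sv <= 0:
            raise ValueError("k_sv must be positive")
        self.svo2_frac = fick_svo2(self.sao2_frac, self.vo2_ml_min, self.co_l_min, self.hgb_g_dl)


def arterial_o2_content(
    hgb_g_dl: float, sao2_frac: float, params: PhysioParams | None = None
) -> float:
    """Arterial O2 content CaO2 = 1.34 * Hgb * SaO2, in mL O2 per dL blood.

    The dissolved-oxygen term (0.003 * PaO2) is omitted: arterial partial
    pressure is not among the model inputs and the term is <2% at normoxia.
    """
    if hgb_g_dl <= 0:
        raise ValueError("hgb_g_dl must be positive")
    cap = params.o2_capacity_ml_per_g if params is not None else O2_CAPACITY_ML_PER_G
    return cap * hgb_g_dl * sao2_frac


def stroke_volume(sbp_mmhg: float, dbp_mmhg: float, k_sv: float) -> float:
    """Pulse-pressure stroke volume, Liljestrand-Zander form.

    SV = k_sv * 100 * (SBP - DBP) / (SBP + DBP), so k_sv = 1 corresponds to
    ~20 mL at 120/80. The gain ``k_sv`` absorbs patient-specific vascular
    compliance and is learnable by the estimator.
    """
    if k_sv <= 0:
        raise ValueError("k_sv must be positive")
    if dbp_mmhg < 0 or sbp_mmhg < dbp_mmhg:
        raise ValueError("require sbp >= dbp >= 0")
    if sbp_mmhg + dbp_mmhg == 0:
        raise ValueError("sbp + dbp must be positive")
    return k_sv * 100.0 * (sbp_mmhg - dbp_mmhg) / (sbp_mmhg + dbp_mmhg)


def fick_svo2(
    sao2_frac,
    vo2_ml_min,
    co_l_min,
    hgb_g_dl,
    params: PhysioParams | None = None,
):
    """Mixed venous saturation from the Fick principle (vectorized).

    SvO2 = SaO2 - VO2 / (CO * 10 * 1.34 * Hgb); the factor 10 converts
    content per dL to per L. Result clamped to [0, SaO2]: extraction cannot
    exceed delivery nor be negative.
    """
    co = np.asarray(co_l_min, dtype=float)
    hgb = np.asarray(hgb_g_dl, dtype=float)
    if np.any(co <= 0):
        raise ValueError("co_l_min must be positive")
    if np.any(hgb <= 0):
        raise ValueError("hgb_g_dl must be positive")
    cap = params.o2_capacity_ml_per_g if params is not None else O2_CAPACITY_ML_PER_G
    sao2 = np.asarray(sao2_frac, dtype=float)
    svo2 = sao2 - np.asarray(vo2_ml_min, dtype=float) / (co * 10.0 * cap * hgb)
    svo2 = np.clip(svo2, 0.0, sao2)
    if svo2.ndim == 0:
        return float(svo2)
    return svo2


def cardiac_output(hr_bpm: float, sv_ml: float) -> float:
    """CO (L/min) = HR * SV / 1000."""
    if hr_bpm < 0 or sv_ml < 0:
        raise ValueError("hr_bpm and sv_ml must be non-negative")
    return hr_bpm * sv_ml / 1000.0


def ou_step_coefficients(tau_hours: float, stationary_sd: float, dt_s: float) -> tuple[float, float]:
    """Exact-discretization coefficients (phi, q) for one OU step of ``dt_s``.

    x' = mu + phi * (x - mu) + q * xi with xi ~ N(0, 1); phi = exp(-dt/tau)
    and q = sd_stat * sqrt(1 - phi^2), so the stationary SD is preserved for
    any step size.
    """
    phi = math.exp(-dt_s / (tau_hours * 3600.0))
    q = stationary_sd * math.sqrt(max(0.0, 1.0 - phi * phi))
    return phi, q


# free-state ordering used by array-based OU propagation
_FREE_STATES = ("vo2_ml_min", "hgb_g_dl", "sao2_frac", "k_sv", "co_l_min")


def ou_coefficient_table(
    params: PhysioParams, means: dict[str, float], dt_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mu, phi, q) arrays over the free states, in ``_FREE_STATES`` order."""
    taus = {
        "vo2_ml_min": params.vo2_tau_hours,
        "hgb_g_dl": params.hgb_tau_hours,
        "sao2_frac": params.sao2_tau_hours,
        "k_sv": params.ksv_tau_hours,
        "co_l_min": params.co_tau_hours,
    }
    sd_fracs = {
        "vo2_ml_min": params.vo2_sd_frac,
        "hgb_g_dl": params.hgb_sd_frac,
        "sao2_frac": params.sao2_sd_frac,
        "k_sv": params.ksv_sd_frac,
        "co_l_min": params.co_sd_frac,
    }
    mu = np.array([means[k] for k in _FREE_STATES])
    phi = np.empty(len(_FREE_STATES))
    q = np.empty(len(_FREE_STATES))
    for i, k in enumerate(_FREE_STATES):
        phi[i], q[i] = ou_step_coefficients(taus[k], sd_fracs[k] * abs(mu[i]), dt_s)
    return mu, phi, q


def propagate(
    state: PhysioState,
    dt_s: float,
    params: PhysioParams,
    rng: np.random.Generator,
    means: dict[str, float] | None = None,
) -> PhysioState:
    """One stochastic OU step of every free state; SvO2 re-derived via Fick.

    ``means`` supplies the OU attractors; by default each state reverts to its
    current value's prior-typical mean (the state itself), which makes the
    zero-volatility step the identity. Pass explicit means to model reversion.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if means is None:
        means = {k: getattr(state, k) for k in _FREE_STATES}
    mu, phi, q = ou_coefficient_table(params, means, dt_s)
    x = np.array([getattr(state, k) for k in _FREE_STATES])
    x = mu + phi * (x - mu) + q * rng.standard_normal(len(x))
    vals = dict(zip(_FREE_STATES, x))
    # re-impose invariants
    vals["vo2_ml_min"] = max(0.0, vals["vo2_ml_min"])
    vals["hgb_g_dl"] = max(1e-6, vals["hgb_g_dl"])
    vals["sao2_frac"] = min(1.0, max(0.0, vals["sao2_frac"]))
    vals["k_sv"] = max(1e-9, vals["k_sv"])
    vals["co_l_min"] = max(1e-6, vals["co_l_min"])
    return PhysioState(
        co_l_min=vals["co_l_min"],
        vo2_ml_min=vals["vo2_ml_min"],
        hgb_g_dl=vals["hgb_g_dl"],
        sao2_frac=vals["sao2_frac"],
        k_sv=vals["k_sv"],
    )


#: channels the state model can independently predict (everything else is an
#: exogenous driver of the flow pathway, not an observation)
PREDICTABLE_KINDS = frozenset(
    {
        ChannelKind.SPO2,
        ChannelKind.SVO2_LAB,
        ChannelKind.SVO2_CONT,
        ChannelKind.HGB_LAB,
        ChannelKind.CI_CONT,
        ChannelKind.CI_APERIODIC,
    }
)


def predict_observation(
    state: PhysioState,
    kind: ChannelKind,
    params: PhysioParams,
    bsa_m2: float | None = None,
) -> tuple[float, float]:
    """Model-implied measurement mean and noise SD for an observable channel.

    Heart rate and pressures are exogenous drivers of the cardiac-output
    pathway rather than predicted observations, so asking for them is a
    contract violation.
    """
    if kind not in PREDICTABLE_KINDS:
        raise ValueError(f"channel {kind.value} is not predicted by the state model")
    bsa = bsa_m2 if bsa_m2 is not None else params.bsa_default_m2
    if kind is ChannelKind.SPO2:
        mean = 100.0 * state.sao2_frac
    elif kind in (ChannelKind.SVO2_LAB, ChannelKind.SVO2_CONT):
        mean = 100.0 * state.svo2_frac
    elif kind is ChannelKind.HGB_LAB:
        mean = state.hgb_g_dl
    else:  # CI channels
        mean = state.co_l_min / bsa
    return mean, params.obs_sd(kind)
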