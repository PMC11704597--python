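"""Recursive Bayesian state estimation over the oxygen-transport model.

A bootstrap particle filter with systematic resampling carries a weighted
ensemble of latent states along the 5-second grid. Heart rate and arterial
pressures act as exogenous drivers of each particle's cardiac-output pathway
(pulse-pressure stroke volume times heart rate); pulse oximetry, hemoglobin
labs, cardiac-index channels and venous-saturation sources enter as Gaussian
observations that reweight the ensemble. The reported index at time t is the
posterior probability that mixed venous saturation is at or below the
configured critical threshold; it is withheld (missing) wherever the minimum
data set is not available.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .physiology import PhysioParams, PhysioState, ou_coefficient_table, _FREE_STATES
from .streams import (
    ChannelKind,
    PatientRecord,
    ScenarioMask,
    SCENARIOS,
    apply_scenario,
)

__all__ = ["Posterior", "IndexTrace", "init_posterior", "assimilate", "index_value", "run_filter", "write_trace_csv", "read_trace_csv"]

log = logging.getLogger(__name__)

# row indices into the (6, N) ensemble array; the sixth row is each
# particle's own VO2 attractor (hierarchical baseline)
IVO2, IHGB, ISAO2, IKSV, ICO, IMVO2 = range(6)
N_ROWS = 6
assert _FREE_STATES == ("vo2_ml_min", "hgb_g_dl", "sao2_frac", "k_sv", "co_l_min")

@dataclass
class Posterior:
    """Weighted particle ensemble over the latent state at one time point.

    ``states`` is a (6, N) array: VO2, Hgb, SaO2, k_sv, CO, plus each
    particle's own VO2 baseline attractor; ``svo2`` holds the derived venous
    saturation. ``means`` are the per-run global OU attractors, fixed at
    initialization (VO2 reverts to the per-particle baseline instead).
    """

    time: float
    states: np.ndarray
    svo2: np.ndarray
    weights: np.ndarray
    means: dict[str, float]
    bsa_m2: float = 1.9

    def __post_init__(self) -> None:
        n = self.states.shape[1]
        if n < 100:
            raise ValueError("posterior needs at least 100 particles")
        if self.states.shape[0] != N_ROWS or self.svo2.shape != (n,) or self.weights.shape != (n,):
            raise ValueError("inconsistent ensemble array shapes")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a simplex")

    @property
    def n_particles(self) -> int:
        return self.states.shape[1]

    def particle(self, i: int) -> PhysioState:
        return PhysioState(
            co_l_min=float(self.states[ICO, i]),
            vo2_ml_min=float(self.states[IVO2, i]),
            hgb_g_dl=float(self.states[IHGB, i]),
            sao2_frac=float(self.states[ISAO2, i]),
            k_sv=float(self.states[IKSV, i]),
        )

    def mean_state(self) -> dict[str, float]:
        w = self.weights
        out = {k: float(w @ self.states[i]) for i, k in enumerate(_FREE_STATES)}
        out["vo2_baseline_ml_min"] = float(w @ self.states[IMVO2])
        out["svo2_frac"] = float(w @ self.svo2)
        return out


@dataclass
class IndexTrace:
    """P(SvO2 <= threshold) on the regular grid; NaN marks gated-off times."""

    times: np.ndarray
    values: np.ndarray
    threshold_pct: float
    mean_svo2_pct: np.ndarray | None = None
    mean_vo2_ml_min: np.ndarray | None = None
    mean_co_l_min: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values[np.isfinite(self.values)]
        if v.size:
            if v.min() < -1e-9 or v.max() > 1.0 + 1e-9:
                raise ValueError("index values must lie in [0, 1]")
            np.clip(self.values, 0.0, 1.0, out=self.values)

    def coverage(self) -> float:
        """Fraction of grid times with a reported index."""
        return float(np.isfinite(self.values).mean()) if self.values.size else 0.0


def _clip_states(X: np.ndarray) -> None:
    np.maximum(X[IVO2], 0.0, out=X[IVO2])
    np.maximum(X[IHGB], 1e-6, out=X[IHGB])
    np.clip(X[ISAO2], 0.0, 1.0, out=X[ISAO2])
    np.maximum(X[IKSV], 1e-9, out=X[IKSV])
    np.maximum(X[ICO], 1e-6, out=X[ICO])
    np.maximum(X[IMVO2], 1.0, out=X[IMVO2])


def _ou_vectors(params: PhysioParams, means: dict[str, float], dt_s: float):
    """(mu, phi, q) over the six ensemble rows for one step of ``dt_s``."""
    from .physiology import ou_step_coefficients

    mu5, phi5, q5 = ou_coefficient_table(params, means, dt_s)
    vo2_c = means["vo2_ml_min"]
    phi_m, q_m = ou_step_coefficients(
        params.vo2_mean_tau_hours, params.vo2_mean_sd_frac * vo2_c, dt_s
    )
    mu = np.append(mu5, vo2_c)
    phi = np.append(phi5, phi_m)
    q = np.append(q5, q_m)
    return mu, phi, q


def _fick_rows(X: np.ndarray, cap: float) -> np.ndarray:
    svo2 = X[ISAO2] - X[IVO2] / (X[ICO] * (10.0 * cap) * X[IHGB])
    np.clip(svo2, 0.0, X[ISAO2], out=svo2)
    return svo2


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = weights.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def init_posterior(
    record: PatientRecord, params: PhysioParams, rng: np.random.Generator, t0: float = 0.0
) -> Posterior:
    """Draw the prior ensemble, centered on the record's earliest labs/vitals.

    CO is lognormal around its prior median (age-shifted), VO2 lognormal
    around 250 mL/min, hemoglobin normal around the first lab (default 12
    g/dL if none), SaO2 normal around the first pulse-oximetry value. The
    vascular gain k_sv is back-solved so each particle's CO matches the first
    available pressure/heart-rate readings.
    """
    n = params.n_particles
    df = record.samples

    def first_value(kind: ChannelKind) -> float | None:
        sub = df[df["channel"] == kind.value]
        return float(sub["value"].iloc[0]) if len(sub) else None

    hgb_c = first_value(ChannelKind.HGB_LAB) or params.hgb_default_g_dl
    spo2 = first_value(ChannelKind.SPO2)
    sao2_c = min(1.0, max(0.5, spo2 / 100.0)) if spo2 is not None else 0.97
    age_shift = 1.0 + params.age_ksv_slope_per_year * (record.age_years - 64.0)
    co_c = params.co_prior_median_l_min * max(0.5, age_shift)
    vo2_c = params.vo2_prior_median_ml_min

    X = np.empty((N_ROWS, n))
    X[IMVO2] = vo2_c * np.exp(params.vo2_mean_prior_sigma_log * rng.standard_normal(n))
    X[IVO2] = X[IMVO2] * np.exp(params.vo2_prior_sigma_log * rng.standard_normal(n))
    X[IHGB] = hgb_c + params.hgb_prior_sd_g_dl * rng.standard_normal(n)
    X[ISAO2] = sao2_c + params.sao2_prior_sd_frac * rng.standard_normal(n)
    X[ICO] = co_c * np.exp(params.co_prior_sigma_log * rng.standard_normal(n))

    hr, sbp, dbp = (first_value(k) for k in (ChannelKind.HR, ChannelKind.ABP_SYS, ChannelKind.ABP_DIA))
    if hr and sbp and dbp and sbp > dbp:
        sv_unit = 100.0 * (sbp - dbp) / (sbp + dbp)  # mL at k_sv = 1
        X[IKSV] = X[ICO] * 1000.0 / (hr * sv_unit)
        ksv_c = co_c * 1000.0 / (hr * sv_unit)
    else:
        ksv_c = 2.0
        X[IKSV] = ksv_c * X[ICO] / co_c
    _clip_states(X)
    svo2 = _fick_rows(X, params.o2_capacity_ml_per_g)
    means = {
        "vo2_ml_min": vo2_c,
        "hgb_g_dl": hgb_c,
        "sao2_frac": sao2_c,
        "k_sv": ksv_c,
        "co_l_min": co_c,
    }
    w = np.full(n, 1.0 / n)
    return Posterior(t0, X, svo2, w, means, record.bsa_m2)


def _step(
    X: np.ndarray,
    w: np.ndarray,
    params: PhysioParams,
    rng: np.random.Generator,
    mu: np.ndarray,
    phi: np.ndarray,
    q: np.ndarray,
    drivers: tuple[float, float, float] | None,
    obs: list[tuple[int, float, float]],
    cap: float,
    ess_min: float,
    bandwidth: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """One propagate/assimilate cycle on raw arrays. Returns (X, w, svo2, skipped)."""
    z = rng.standard_normal(X.shape)
    X = X.copy()
    # baseline and the other slow states revert to the global attractors ...
    for r in range(1, N_ROWS):
        X[r] = mu[r] + phi[r] * (X[r] - mu[r]) + q[r] * z[r]
    # ... while VO2 reverts to each particle's own baseline
    X[IVO2] = X[IMVO2] + phi[IVO2] * (X[IVO2] - X[IMVO2]) + q[IVO2] * z[IVO2]
    _clip_states(X)
    if drivers is not None:
        hr, sbp, dbp = drivers
        X[ICO] = hr * X[IKSV] * (100.0 * (sbp - dbp) / (sbp + dbp)) / 1000.0
        np.maximum(X[ICO], 1e-6, out=X[ICO])
    svo2 = _fick_rows(X, cap)
    skipped = False
    if obs:
        logl = np.zeros(X.shape[1])
        for row, y, sd in obs:
            pred = svo2 * 100.0 if row == -1 else (X[row] * (100.0 if row == ISAO2 else 1.0))
            z = (y - pred) / sd
            logl -= 0.5 * z * z
        wn = w * np.exp(logl - logl.max())
        s = wn.sum()
        if s > 0 and np.isfinite(s):
            w = wn / s
        else:  # all likelihoods underflow: skip update, keep prior weights
            skipped = True
    ess = 1.0 / (w @ w)
    if ess < ess_min:
        m = X @ w
        sd = np.sqrt(np.maximum((X * X) @ w - m * m, 0.0))
        a = math.sqrt(1.0 - bandwidth * bandwidth)
        idx = _systematic_resample(w, rng)
        X = a * X[:, idx] + (1 - a) * m[:, None] + (bandwidth * sd)[:, None] * rng.standard_normal(X.shape)
        _clip_states(X)
        svo2 = _fick_rows(X, cap)
        w = np.full(X.shape[1], 1.0 / X.shape[1])
    return X, w, svo2, skipped


def _obs_row(kind: ChannelKind) -> int:
    """Ensemble row whose (scaled) value predicts the observation; -1 = SvO2."""
    return {
        ChannelKind.SPO2: ISAO2,
        ChannelKind.SVO2_CONT: -1,
        ChannelKind.SVO2_LAB: -1,
        ChannelKind.HGB_LAB: IHGB,
        ChannelKind.CI_CONT: ICO,
        ChannelKind.CI_APERIODIC: ICO,
    }[kind]


def assimilate(
    post: Posterior,
    observations: dict[ChannelKind, float],
    t: float,
    params: PhysioParams,
    rng: np.random.Generator,
    drivers: tuple[float, float, float] | None = None,
) -> Posterior:
    """Advance the posterior to time ``t`` and absorb the observations there.

    ``observations`` maps observable channel kinds to measured values;
    ``drivers`` optionally carries (heart rate, systolic, diastolic) which
    deterministically update each particle's cardiac-output pathway. With no
    observations this is pure propagation and the weights are untouched.
    """
    if t < post.time:
        raise ValueError(f"time regression: posterior at t={post.time}, update at t={t}")
    dt = t - post.time
    cap = params.o2_capacity_ml_per_g
    mu, phi, q = _ou_vectors(params, post.means, max(dt, 1e-9))
    if dt == 0:
        phi = np.ones_like(phi)
        q = np.zeros_like(q)
    cont_kinds = {ChannelKind.SPO2, ChannelKind.SVO2_CONT, ChannelKind.CI_CONT}
    obs = []
    for kind, y in observations.items():
        row = _obs_row(kind)  # raises KeyError for non-observable kinds
        sd = params.obs_sd(kind)
        if kind in cont_kinds:
            sd *= params.cont_obs_sd_inflation
        if kind is ChannelKind.CI_CONT or kind is ChannelKind.CI_APERIODIC:
            obs.append((row, y * post.bsa_m2, sd * post.bsa_m2))  # compare in CO units
        else:
            obs.append((row, y, sd))
    X, w, svo2, _ = _step(
        post.states.copy(),
        post.weights.copy(),
        params,
        rng,
        mu,
        phi,
        q,
        drivers,
        obs,
        cap,
        ess_min=params.ess_fraction * post.n_particles,
        bandwidth=params.resample_bandwidth,
    )
    return Posterior(t, X, svo2, w, post.means, post.bsa_m2)


def index_value(post: Posterior, threshold_pct: float) -> float:
    """Posterior probability that SvO2 (in %) is at or below the threshold."""
    return float(post.weights @ (post.svo2 * 100.0 <= threshold_pct))


# ---------------------------------------------------------------------------
# full-record filtering


def _grid_array(df: pd.DataFrame, kind: ChannelKind, n_grid: int, dt_s: float) -> np.ndarray:
    """Last-observation-per-bin values of one channel on the grid (NaN = missing)."""
    sub = df[df["channel"] == kind.value]
    out = np.full(n_grid, np.nan)
    if len(sub):
        idx = np.floor(sub["time_s"].to_numpy() / dt_s).astype(int)
        keep = idx < n_grid
        out[idx[keep]] = sub["value"].to_numpy()[keep]  # later rows overwrite: last obs wins
    return out


def _ffill_with_age(vals: np.ndarray, max_age_steps: float) -> np.ndarray:
    """Forward-fill, masking entries older than ``max_age_steps`` back to NaN."""
    n = vals.size
    present = np.isfinite(vals)
    last = np.where(present, np.arange(n), -1)
    np.maximum.accumulate(last, out=last)
    out = np.where(last >= 0, vals[np.maximum(last, 0)], np.nan)
    age = np.arange(n) - last
    out[(last < 0) | (age > max_age_steps)] = np.nan
    return out


def run_filter(
    record: PatientRecord,
    params: PhysioParams,
    mask: ScenarioMask | str = "baseline",
    rng: np.random.Generator | int | None = None,
    dt_s: float = 5.0,
    engine: str = "numba",
) -> IndexTrace:
    """Filter a whole record under a monitoring scenario; emit the index trace.

    The record is grid-binned (last observation per bin), the scenario mask is
    applied, and the particle filter is stepped along the grid. The index is
    reported only where the minimum data set is fresh; elsewhere the trace is
    NaN (the filter keeps assimilating through gated-off stretches, output is
    merely withheld). Same seed and inputs give an identical trace.
    """
    if isinstance(mask, str):
        mask = SCENARIOS[mask]
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rec = apply_scenario(record, mask)
    df = rec.samples
    duration = record.duration_s()
    n_grid = int(math.floor(duration / dt_s)) + 1 if duration > 0 else 0
    times = np.arange(n_grid) * dt_s
    thr = params.svo2_threshold_pct
    meta = {"mask": mask.name, "n_particles": params.n_particles, "dt_s": dt_s}
    if n_grid == 0:
        return IndexTrace(times, np.full(0, np.nan), thr, np.full(0, np.nan), metadata=meta)

    stale_steps = params.staleness_s / dt_s
    raw = {k: _grid_array(df, k, n_grid, dt_s) for k in CONT_FILTER_KINDS}
    hr_f = _ffill_with_age(raw[ChannelKind.HR], stale_steps)
    sbp_f = _ffill_with_age(raw[ChannelKind.ABP_SYS], stale_steps)
    dbp_f = _ffill_with_age(raw[ChannelKind.ABP_DIA], stale_steps)
    map_f = _ffill_with_age(raw[ChannelKind.ABP_MEAN], stale_steps)
    spo2_f = _ffill_with_age(raw[ChannelKind.SPO2], stale_steps)
    cvp_f = _ffill_with_age(raw[ChannelKind.CVP], stale_steps)
    temp_f = _ffill_with_age(raw[ChannelKind.TEMP], 8 * 3600.0 / dt_s)

    # hemoglobin freshness from lab timestamps (aperiodic, so not on the grid)
    hgb_times = df[df["channel"] == ChannelKind.HGB_LAB.value]["time_s"].to_numpy()
    last_hgb = np.full(n_grid, -np.inf)
    if hgb_times.size:
        pos = np.searchsorted(hgb_times, times, side="right") - 1
        last_hgb = np.where(pos >= 0, hgb_times[np.maximum(pos, 0)], -np.inf)
    hgb_fresh = (times - last_hgb) <= params.hgb_max_age_h * 3600.0

    abp_ok = (np.isfinite(sbp_f) & np.isfinite(dbp_f)) | np.isfinite(map_f)
    gated = (
        np.isfinite(spo2_f) & np.isfinite(hr_f) & abp_ok & np.isfinite(cvp_f) & hgb_fresh
    )

    values = np.full(n_grid, np.nan)
    mean_svo2 = np.full(n_grid, np.nan)
    mean_vo2 = np.full(n_grid, np.nan)
    mean_co = np.full(n_grid, np.nan)
    if not gated.any():
        log.info("record %s never satisfies the minimum data set; empty trace", record.patient_id)
        return IndexTrace(times, values, thr, mean_svo2, metadata=meta)

    # aperiodic observations attach to the first grid time at/after their stamp
    aper_obs: dict[int, list[tuple[int, float, float]]] = {}
    for kind in (ChannelKind.SVO2_LAB, ChannelKind.CI_APERIODIC, ChannelKind.HGB_LAB):
        sub = df[df["channel"] == kind.value]
        row = _obs_row(kind)
        sd = params.obs_sd(kind)
        for t, y in zip(sub["time_s"].to_numpy(), sub["value"].to_numpy()):
            i = int(math.ceil(t / dt_s))
            if i >= n_grid:
                continue
            if kind is ChannelKind.CI_APERIODIC:
                aper_obs.setdefault(i, []).append((row, y * rec.bsa_m2, sd * rec.bsa_m2))
            else:
                aper_obs.setdefault(i, []).append((row, y, sd))

    start = int(np.argmax(gated))
    post0 = init_posterior(rec, params, rng, t0=times[start])
    X, w, svo2 = post0.states.copy(), post0.weights.copy(), post0.svo2.copy()
    means, bsa = post0.means, rec.bsa_m2
    cap = params.o2_capacity_ml_per_g
    mu, phi, q = _ou_vectors(params, means, dt_s)
    ess_min = params.ess_fraction * params.n_particles
    bandwidth = params.resample_bandwidth
    tcoef = params.temp_vo2_pct_per_degc / 100.0

    # per-grid precomputations (vectorized over time, outside the particle loop)
    with np.errstate(invalid="ignore", divide="ignore"):
        vo2_mult = np.where(
            np.isfinite(temp_f), 1.0 + tcoef * np.maximum(0.0, temp_f - 37.0), 1.0
        )
        # CO per unit k_sv when the pulse-pressure pathway is drivable
        co_gain = hr_f * (100.0 * (sbp_f - dbp_f) / (sbp_f + dbp_f)) / 1000.0
    drv_ok = np.isfinite(co_gain) & (sbp_f > dbp_f)
    spo2_raw = raw[ChannelKind.SPO2]
    svo2c_raw = raw[ChannelKind.SVO2_CONT]
    ci_raw = raw[ChannelKind.CI_CONT]
    spo2_ok = np.isfinite(spo2_raw)
    svo2c_ok = np.isfinite(svo2c_raw)
    ci_ok = np.isfinite(ci_raw)
    infl = params.cont_obs_sd_inflation
    sd_spo2 = params.spo2_sd_pct * infl
    sd_svo2c = params.svo2_cont_sd_pct * infl
    sd_ci = params.ci_cont_sd_l_min_m2 * infl * bsa
    thr_frac = thr / 100.0
    n_skipped = 0

    if engine == "numba":
        from ._kernel import filter_chunk

        flat: list[tuple[int, int, float, float]] = []
        for i in sorted(aper_obs):
            for row, y, sd in aper_obs[i]:
                flat.append((i, row, y, sd))
        obs_step = np.array([f[0] for f in flat], dtype=np.int64)
        obs_row = np.array([f[1] for f in flat], dtype=np.int64)
        obs_y = np.array([f[2] for f in flat], dtype=np.float64)
        obs_sd = np.array([f[3] for f in flat], dtype=np.float64)
        co_gain_nan = np.where(drv_ok, co_gain, np.nan)
        ci_co_raw = ci_raw * bsa
        n = X.shape[1]
        optr = int(np.searchsorted(obs_step, start))
        chunk = 512
        for c0 in range(start, n_grid, chunk):
            c1 = min(c0 + chunk, n_grid)
            m = c1 - c0
            z_prop = rng.standard_normal((m, N_ROWS * n))
            # fresh jitter pool per chunk; resampling fires on a minority of
            # steps, so a third-size wrapping pool covers it cheaply
            z_jit = rng.standard_normal((max(8, m // 3), N_ROWS * n))
            u_res = rng.random(m)
            optr, _, skipped = filter_chunk(
                X, w, svo2, mu, phi, q, vo2_mult, co_gain_nan,
                spo2_raw, svo2c_raw, ci_co_raw, sd_spo2, sd_svo2c, sd_ci,
                obs_step, obs_row, obs_y, obs_sd,
                gated, c0, c1, thr_frac, 10.0 * cap, ess_min, bandwidth,
                z_prop, z_jit, u_res, 0, optr, values, mean_svo2, mean_vo2, mean_co,
            )
            n_skipped += skipped
        if n_skipped:
            log.warning("%d likelihood-underflow updates skipped for %s", n_skipped, record.patient_id)
        meta["n_skipped_updates"] = int(n_skipped)
        return IndexTrace(times, values, thr, mean_svo2, mean_vo2, mean_co, meta)

    n = X.shape[1]
    mu_col = mu[1:, None].copy()
    phi_col = phi[1:, None]
    q_col = q[1:, None]
    tmp5 = np.empty((N_ROWS - 1, n))
    t1 = np.empty(n)
    logl = np.empty(n)
    wn = np.empty(n)
    chunk = 256
    noise = np.empty((chunk, N_ROWS, n))
    phi0, q0 = phi[IVO2], q[IVO2]

    for i in range(start, n_grid):
        k = (i - start) % chunk
        if k == 0:
            noise[...] = rng.standard_normal(noise.shape)
        # OU propagation in place: slow states revert to global attractors
        Xs = X[1:]
        np.subtract(Xs, mu_col, out=Xs)
        np.multiply(Xs, phi_col, out=Xs)
        np.multiply(q_col, noise[k, 1:], out=tmp5)
        np.add(Xs, tmp5, out=Xs)
        np.add(Xs, mu_col, out=Xs)
        # VO2 reverts to each particle's own (temperature-scaled) baseline
        np.multiply(X[IMVO2], vo2_mult[i], out=t1)
        np.subtract(X[IVO2], t1, out=X[IVO2])
        np.multiply(X[IVO2], phi0, out=X[IVO2])
        np.add(X[IVO2], t1, out=X[IVO2])
        np.multiply(noise[k, IVO2], q0, out=t1)
        np.add(X[IVO2], t1, out=X[IVO2])
        _clip_states(X)
        if drv_ok[i]:
            np.multiply(X[IKSV], co_gain[i], out=X[ICO])
            np.maximum(X[ICO], 1e-6, out=X[ICO])
        # Fick closure into svo2 buffer
        np.multiply(X[ICO], 10.0 * cap, out=t1)
        np.multiply(t1, X[IHGB], out=t1)
        np.divide(X[IVO2], t1, out=t1)
        np.subtract(X[ISAO2], t1, out=svo2)
        np.minimum(svo2, X[ISAO2], out=svo2)
        np.maximum(svo2, 0.0, out=svo2)
        # Gaussian log-likelihood of every present observation
        any_obs = False
        if spo2_ok[i]:
            np.multiply(X[ISAO2], 100.0, out=t1)
            np.subtract(t1, spo2_raw[i], out=t1)
            np.multiply(t1, 1.0 / sd_spo2, out=t1)
            np.multiply(t1, t1, out=logl)
            any_obs = True
        else:
            logl.fill(0.0)
        if svo2c_ok[i]:
            np.multiply(svo2, 100.0, out=t1)
            np.subtract(t1, svo2c_raw[i], out=t1)
            np.multiply(t1, 1.0 / sd_svo2c, out=t1)
            np.multiply(t1, t1, out=t1)
            logl += t1
            any_obs = True
        if ci_ok[i]:
            np.subtract(X[ICO], ci_raw[i] * bsa, out=t1)
            np.multiply(t1, 1.0 / sd_ci, out=t1)
            np.multiply(t1, t1, out=t1)
            logl += t1
            any_obs = True
        extra = aper_obs.get(i)
        if extra is not None:
            for row, y, sd in extra:
                pred = svo2 * 100.0 if row == -1 else (X[row] * (100.0 if row == ISAO2 else 1.0))
                t1[:] = (pred - y) / sd
                np.multiply(t1, t1, out=t1)
                logl += t1
            any_obs = True
        if any_obs:
            np.multiply(logl, -0.5, out=logl)
            logl -= logl.max()
            np.exp(logl, out=logl)
            np.multiply(w, logl, out=wn)
            s = wn.sum()
            if s > 0 and np.isfinite(s):
                np.divide(wn, s, out=w)
            else:
                n_skipped += 1
            if 1.0 / (w @ w) < ess_min:
                mr = X @ w
                sdr = np.sqrt(np.maximum((X * X) @ w - mr * mr, 0.0))
                a = math.sqrt(1.0 - bandwidth * bandwidth)
                idx = _systematic_resample(w, rng)
                X = a * X[:, idx] + (1 - a) * mr[:, None] + (bandwidth * sdr)[:, None] * rng.standard_normal(X.shape)
                _clip_states(X)
                np.multiply(X[ICO], 10.0 * cap, out=t1)
                np.multiply(t1, X[IHGB], out=t1)
                np.divide(X[IVO2], t1, out=t1)
                np.subtract(X[ISAO2], t1, out=svo2)
                np.minimum(svo2, X[ISAO2], out=svo2)
                np.maximum(svo2, 0.0, out=svo2)
                w.fill(1.0 / n)
        if gated[i]:
            values[i] = w @ (svo2 <= thr_frac)
            mean_svo2[i] = 100.0 * (w @ svo2)
            mean_vo2[i] = w @ X[IVO2]
            mean_co[i] = w @ X[ICO]
    if n_skipped:
        log.warning("%d likelihood-underflow updates skipped for %s", n_skipped, record.patient_id)
    meta["n_skipped_updates"] = n_skipped
    return IndexTrace(times, values, thr, mean_svo2, mean_vo2, mean_co, meta)


CONT_FILTER_KINDS = (
    ChannelKind.SPO2,
    ChannelKind.HR,
    ChannelKind.ABP_SYS,
    ChannelKind.ABP_DIA,
    ChannelKind.ABP_MEAN,
    ChannelKind.CVP,
    ChannelKind.TEMP,
    ChannelKind.CI_CONT,
    ChannelKind.SVO2_CONT,
)


def write_trace_csv(
    trace: IndexTrace, patient_id: str, path: str | Path, sidecar: str | Path | None = None
) -> None:
    """CSV `patient_id,time_s,index` (missing index = empty field) + JSON sidecar."""
    df = pd.DataFrame({"patient_id": patient_id, "time_s": trace.times, "index": trace.values})
    df.to_csv(path, index=False)
    if sidecar is not None:
        Path(sidecar).write_text(json.dumps({"threshold_pct": trace.threshold_pct, **trace.metadata}, indent=2))


def read_trace_csv(path: str | Path, threshold_pct: float = 50.0) -> IndexTrace:
    df = pd.read_csv(path)
    return IndexTrace(df["time_s"].to_numpy(float), df["index"].to_numpy(float), threshold_pct)
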