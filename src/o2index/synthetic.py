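"""Virtual CVICU patient generator.

Each virtual patient carries a latent oxygen-transport trajectory — VO2,
hemoglobin, arterial saturation, vascular gain, plus vital-sign baselines —
evolving as mean-reverting AR(1) (discretized Ornstein-Uhlenbeck) wander
around patient-specific baselines. Scripted acute events (hemorrhage,
hypoxemia, fever, low cardiac output) shift the relevant OU attractors for
their duration with a faster acute-response timescale, producing sustained
episodes of low mixed-venous saturation. True SvO2 is always the Fick
closure of the latent state, so the generator and the estimator share the
same physiologic ground rules while differing in dynamics — deliberate model
mismatch. Channels are emitted on the 5-second grid with per-kind Gaussian
sensor noise; co-oximetry labs are drawn at random times; availability of
continuous oximetry and cardiac-index monitoring matches a realistic adult
CVICU mix (roughly half of patients each).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .physiology import fick_svo2
from .streams import ChannelKind, PatientRecord

__all__ = ["CohortSpec", "GroundTruth", "SyntheticCohort", "simulate_patient", "simulate_cohort"]

EVENT_TYPES = ("hemorrhage", "hypoxemia", "fever", "low_output")


@dataclass
class CohortSpec:
    """Study-design knobs for a synthetic cohort.

    Defaults emulate an adult CVICU validation cohort: 1-5 co-oximetry labs
    per patient (median 3), ~25% of labs at or below the 50% threshold,
    continuous oximetry in ~48% and continuous cardiac index in ~45% of
    patients, ages spanning the 54-73 interquartile band.
    """

    n_patients: int = 100
    record_hours: float = 48.0
    dt_s: float = 5.0
    labs_min: int = 1
    labs_max: int = 5
    target_prevalence_pos: float = 0.25
    svo2_threshold_pct: float = 50.0
    seed: int = 0

    # acute-event model: arrival rates (per hour) and mean durations (hours)
    event_rates_per_h: dict = field(
        default_factory=lambda: {"hemorrhage": 0.02, "hypoxemia": 0.03, "fever": 0.03, "low_output": 0.04}
    )
    event_mean_duration_h: dict = field(
        default_factory=lambda: {"hemorrhage": 3.0, "hypoxemia": 1.5, "fever": 4.0, "low_output": 3.0}
    )
    event_magnitude_scale: float = 1.0   # auto-tuned by simulate_cohort
    response_tau_h: float = 0.7          # acute episodes develop on this timescale
    forced_events: Sequence[tuple] | None = None  # (type, start_h, duration_h, severity)

    # multiplies all latent-process volatilities / all sensor noise SDs
    process_noise_scale: float = 1.0
    sensor_noise_scale: float = 1.0

    # sensor noise SDs per channel (channel units)
    sensor_sd: dict = field(
        default_factory=lambda: {
            ChannelKind.SPO2: 0.8,
            ChannelKind.HR: 1.0,
            ChannelKind.ABP_SYS: 2.0,
            ChannelKind.ABP_DIA: 1.5,
            ChannelKind.ABP_MEAN: 1.5,
            ChannelKind.CVP: 1.0,
            ChannelKind.TEMP: 0.1,
            ChannelKind.CI_CONT: 0.15,
            ChannelKind.SVO2_CONT: 1.5,
            ChannelKind.SVO2_LAB: 1.0,
            ChannelKind.HGB_LAB: 0.2,
            ChannelKind.CI_APERIODIC: 0.2,
        }
    )

    # monitoring availability (fractions of patients)
    frac_svo2_cont: float = 0.48
    frac_ci_cont: float = 0.45
    frac_ci_aperiodic: float = 0.23

    hgb_lab_interval_h: float = 12.0
    ci_aperiodic_interval_h: float = 4.0
    # telemetry dropout (per continuous channel): gap arrivals per hour, mean gap seconds
    dropout_rate_per_h: float = 0.0
    dropout_mean_s: float = 120.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 < self.target_prevalence_pos < 1.0):
            raise ValueError("target_prevalence_pos must lie in (0, 1)")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.labs_min < 1 or self.labs_max < self.labs_min:
            raise ValueError("need 1 <= labs_min <= labs_max")


@dataclass
class GroundTruth:
    """Dense latent trajectories plus true SvO2 (%) on the 5-second grid."""

    patient_id: str
    frame: pd.DataFrame  # time_s, vo2, hgb, sao2, ksv, hr, sbp, dbp, cvp, temp, co, svo2_pct

    def svo2_pct(self) -> np.ndarray:
        return self.frame["svo2_pct"].to_numpy()


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    records: list[PatientRecord]
    truths: list[GroundTruth]
    summary: dict

    def __iter__(self):
        return iter(zip(self.records, self.truths))


# latent states simulated as AR(1); (baseline tau hours, within-patient stationary SD)
_SIM_STATES = {
    "vo2": (2.0, None),    # SD set as fraction of baseline below
    "hgb": (24.0, None),
    "sao2": (1.0, None),
    "ksv": (12.0, None),
    "hr": (0.5, 5.0),
    "sbp": (0.5, 6.0),
    "dbp": (0.5, 4.0),
    "cvp": (1.0, 1.5),
    "temp": (2.0, 0.15),
}
_FRAC_SD = {"vo2": 0.08, "hgb": 0.03, "sao2": 0.01, "ksv": 0.05}


def _ar1_piecewise(
    mu: np.ndarray, tau_h: np.ndarray, sd: float, x0: float, dt_s: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) path with piecewise-constant mean and timescale, exact OU discretization."""
    n = mu.size
    out = np.empty(n)
    change = np.flatnonzero((np.diff(mu) != 0) | (np.diff(tau_h) != 0)) + 1
    bounds = np.r_[0, change, n]
    x = x0
    for a, b in zip(bounds[:-1], bounds[1:]):
        phi = np.exp(-dt_s / (tau_h[a] * 3600.0))
        q = sd * np.sqrt(1.0 - phi * phi)
        seg = q * rng.standard_normal(b - a) if sd > 0 else np.zeros(b - a)
        dev = lfilter([1.0], [1.0, -phi], seg, zi=[phi * (x - mu[a])])[0]
        out[a:b] = mu[a] + dev
        x = out[b - 1]
    return out


def _draw_events(spec: CohortSpec, rng: np.random.Generator) -> list[tuple[str, float, float, float]]:
    """(type, start_h, duration_h, severity) episodes over the record."""
    if spec.forced_events is not None:
        return [tuple(e) for e in spec.forced_events]
    events = []
    for etype in EVENT_TYPES:
        rate = spec.event_rates_per_h.get(etype, 0.0)
        if rate <= 0:
            continue
        # start the arrival process before admission so an episode can be
        # ongoing at t = 0 (stationary coverage even for short records)
        t = -3.0 * spec.event_mean_duration_h[etype] + rng.exponential(1.0 / rate)
        while t < spec.record_hours:
            dur = rng.exponential(spec.event_mean_duration_h[etype])
            sev = rng.uniform(0.6, 1.0)
            events.append((etype, t, dur, sev))
            t += dur + rng.exponential(1.0 / rate)
    return events


def simulate_patient(
    spec: CohortSpec, rng: np.random.Generator, patient_id: str = "p0"
) -> tuple[PatientRecord, GroundTruth]:
    """One virtual admission: channel streams, labs, and dense ground truth."""
    spec.validate()
    dt = spec.dt_s
    n = int(round(spec.record_hours * 3600.0 / dt))
    times = np.arange(n) * dt

    age = rng.uniform(54.4, 73.3)
    bsa = float(np.clip(rng.normal(1.9, 0.2), 1.4, 2.4))

    base = {
        "vo2": float(240.0 * np.exp(0.15 * rng.standard_normal())),
        "hgb": float(np.clip(rng.normal(11.5, 1.3), 7.0, 16.0)),
        "sao2": float(np.clip(rng.normal(0.965, 0.01), 0.90, 0.995)),
        "hr": float(np.clip(rng.normal(85.0, 10.0), 50.0, 130.0)),
        "sbp": float(np.clip(rng.normal(115.0, 12.0), 85.0, 160.0)),
        "cvp": float(np.clip(rng.normal(9.0, 3.0), 2.0, 20.0)),
        "temp": float(rng.normal(37.0, 0.3)),
    }
    base["dbp"] = float(np.clip(rng.normal(62.0, 8.0), 40.0, base["sbp"] - 15.0))
    co_base = float(np.clip(rng.normal(5.0, 0.8), 3.0, 8.0))
    sv_unit = 100.0 * (base["sbp"] - base["dbp"]) / (base["sbp"] + base["dbp"])
    base["ksv"] = co_base * 1000.0 / (base["hr"] * sv_unit)

    # per-state mean and timescale arrays, then event shifts
    mu = {k: np.full(n, base[k]) for k in _SIM_STATES}
    tau = {k: np.full(n, _SIM_STATES[k][0]) for k in _SIM_STATES}
    s = spec.event_magnitude_scale
    for etype, start_h, dur_h, sev in _draw_events(spec, rng):
        a = int(np.clip(start_h * 3600.0 / dt, 0, n))
        b = int(np.clip((start_h + dur_h) * 3600.0 / dt, 0, n))
        if b <= a:
            continue
        m = sev * s
        if etype == "hemorrhage":
            mu["hgb"][a:b] *= max(0.30, 1.0 - 0.35 * m)
            mu["hr"][a:b] += 25.0 * m
            mu["sbp"][a:b] -= 20.0 * m
            mu["dbp"][a:b] += 5.0 * m
            acute = ("hgb", "hr", "sbp", "dbp")
        elif etype == "hypoxemia":
            mu["sao2"][a:b] = np.maximum(0.55, mu["sao2"][a:b] - 0.12 * m)
            acute = ("sao2",)
        elif etype == "fever":
            mu["temp"][a:b] += 1.6 * m
            mu["vo2"][a:b] *= min(2.2, 1.0 + 0.40 * m)
            acute = ("temp", "vo2")
        else:  # low_output
            mu["ksv"][a:b] *= max(0.25, 1.0 - 0.40 * m)
            acute = ("ksv",)
        for k in acute:
            tau[k][a:b] = spec.response_tau_h
    np.maximum(mu["sbp"], mu["dbp"] + 10.0, out=mu["sbp"])

    traj = {}
    for k in _SIM_STATES:
        sd = _FRAC_SD[k] * base[k] if k in _FRAC_SD else _SIM_STATES[k][1]
        sd *= spec.process_noise_scale
        traj[k] = _ar1_piecewise(mu[k], tau[k], sd, base[k], dt, rng)
    np.clip(traj["sao2"], 0.0, 1.0, out=traj["sao2"])
    np.maximum(traj["hgb"], 2.0, out=traj["hgb"])
    np.maximum(traj["ksv"], 0.05, out=traj["ksv"])
    np.maximum(traj["hr"], 20.0, out=traj["hr"])
    np.maximum(traj["sbp"], traj["dbp"] + 5.0, out=traj["sbp"])
    np.maximum(traj["dbp"], 20.0, out=traj["dbp"])

    sv = traj["ksv"] * 100.0 * (traj["sbp"] - traj["dbp"]) / (traj["sbp"] + traj["dbp"])
    co = np.maximum(traj["hr"] * sv / 1000.0, 0.3)
    svo2 = fick_svo2(traj["sao2"], traj["vo2"], co, traj["hgb"])

    truth = GroundTruth(
        patient_id,
        pd.DataFrame(
            {"time_s": times, **{k: traj[k] for k in _SIM_STATES}, "co": co, "svo2_pct": 100.0 * svo2}
        ),
    )

    # --- emission ---
    noise = {k: spec.sensor_noise_scale * v for k, v in spec.sensor_sd.items()}
    has_svo2c = rng.random() < spec.frac_svo2_cont
    has_cic = rng.random() < spec.frac_ci_cont
    has_cia = rng.random() < spec.frac_ci_aperiodic

    def emit_cont(kind: ChannelKind, signal: np.ndarray, lo=None, hi=None) -> pd.DataFrame:
        vals = signal + noise[kind] * rng.standard_normal(n)
        if lo is not None or hi is not None:
            vals = np.clip(vals, lo, hi)
        keep = np.ones(n, dtype=bool)
        if spec.dropout_rate_per_h > 0:
            t = rng.exponential(3600.0 / spec.dropout_rate_per_h)
            while t < times[-1]:
                gap = rng.exponential(spec.dropout_mean_s)
                keep &= ~((times >= t) & (times < t + gap))
                t += gap + rng.exponential(3600.0 / spec.dropout_rate_per_h)
        return pd.DataFrame({"time_s": times[keep], "channel": kind.value, "value": vals[keep]})

    frames = [
        emit_cont(ChannelKind.SPO2, 100.0 * traj["sao2"], 0.0, 100.0),
        emit_cont(ChannelKind.HR, traj["hr"], 0.0, None),
        emit_cont(ChannelKind.ABP_SYS, traj["sbp"]),
        emit_cont(ChannelKind.ABP_DIA, traj["dbp"]),
        emit_cont(ChannelKind.ABP_MEAN, (traj["sbp"] + 2.0 * traj["dbp"]) / 3.0),
        emit_cont(ChannelKind.CVP, traj["cvp"]),
        emit_cont(ChannelKind.TEMP, traj["temp"]),
    ]
    if has_svo2c:
        frames.append(emit_cont(ChannelKind.SVO2_CONT, 100.0 * svo2, 0.0, 100.0))
    if has_cic:
        frames.append(emit_cont(ChannelKind.CI_CONT, co / bsa))

    def truth_at(sig: np.ndarray, t: float) -> float:
        return float(sig[min(int(t / dt), n - 1)])

    rows = []
    # hemoglobin labs: at admission and every interval thereafter (gating requires <24 h)
    t = 0.0
    while t < spec.record_hours * 3600.0:
        val = truth_at(traj["hgb"], t) + noise[ChannelKind.HGB_LAB] * rng.standard_normal()
        rows.append((t, ChannelKind.HGB_LAB.value, max(2.0, val)))
        t += spec.hgb_lab_interval_h * 3600.0
    # mixed-venous co-oximetry labs at uniform-random times past the first hour
    n_labs = int(rng.integers(spec.labs_min, spec.labs_max + 1))
    dur = spec.record_hours * 3600.0
    lab_lo = 3600.0 if dur - 3600.0 >= 600.0 else 0.25 * dur
    lab_times = np.sort(rng.uniform(lab_lo, dur - dt, size=n_labs))
    for t in lab_times:
        val = truth_at(100.0 * svo2, t) + noise[ChannelKind.SVO2_LAB] * rng.standard_normal()
        rows.append((float(t), ChannelKind.SVO2_LAB.value, float(np.clip(val, 0.0, 100.0))))
    if has_cia:
        t = rng.uniform(0.5, 1.5) * 3600.0
        while t < dur:
            val = truth_at(co, t) / bsa + noise[ChannelKind.CI_APERIODIC] * rng.standard_normal()
            rows.append((float(t), ChannelKind.CI_APERIODIC.value, max(0.2, val)))
            t += spec.ci_aperiodic_interval_h * 3600.0 * rng.uniform(0.8, 1.2)
    frames.append(pd.DataFrame(rows, columns=["time_s", "channel", "value"]))

    samples = pd.concat(frames, ignore_index=True).sort_values("time_s", kind="stable")
    record = PatientRecord(patient_id, age, bsa, samples.reset_index(drop=True))
    return record, truth


def _realized_prevalence(records: Sequence[PatientRecord], threshold_pct: float) -> tuple[int, int]:
    pos = total = 0
    for r in records:
        labs = r.of_kind(ChannelKind.SVO2_LAB)["value"].to_numpy()
        total += labs.size
        pos += int((labs <= threshold_pct).sum())
    return pos, total


def _simulate_batch(
    spec: CohortSpec, children: Sequence[np.random.SeedSequence]
) -> tuple[list, list]:
    records, truths = [], []
    for i, child in enumerate(children):
        rec, tr = simulate_patient(spec, np.random.default_rng(child), patient_id=f"{spec.seed}-p{i:03d}")
        records.append(rec)
        truths.append(tr)
    return records, truths


def simulate_cohort(spec: CohortSpec, tune: bool = True, max_bisect: int = 20) -> SyntheticCohort:
    """Simulate the cohort, auto-tuning event magnitude to the target prevalence.

    Tuning bisects the event-magnitude scale on pilot batches (event rates
    stay fixed, so episode counts stay realistic) until the realized fraction
    of positive labs is within +/-0.05 of the target, then simulates the full
    cohort at the tuned scale with the cohort seed.
    """
    spec.validate()
    scale = spec.event_magnitude_scale
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    pilot_cache: dict = {}
    if tune:
        # pilot = leading patients of the cohort itself (common random numbers,
        # so realized prevalence is a deterministic monotone function of scale)
        n_pilot = min(spec.n_patients, 64)

        def realized(s: float) -> float:
            trial = replace(spec, event_magnitude_scale=s)
            recs, trs = _simulate_batch(trial, children[:n_pilot])
            pilot_cache.clear()
            pilot_cache[s] = (recs, trs)
            pos, tot = _realized_prevalence(recs, spec.svo2_threshold_pct)
            return pos / tot if tot else 0.0

        lo, hi = 0.1, 4.0
        f = realized(scale)
        steps = 0
        while abs(f - spec.target_prevalence_pos) > 0.03 and steps < max_bisect:
            if f < spec.target_prevalence_pos:
                lo = scale
            else:
                hi = scale
            scale = 0.5 * (lo + hi)
            f = realized(scale)
            steps += 1
        if abs(f - spec.target_prevalence_pos) > 0.05:
            warnings.warn(
                f"prevalence tuning stopped at scale={scale:.3f} with realized fraction {f:.3f} "
                f"(target {spec.target_prevalence_pos})"
            )
    tuned = replace(spec, event_magnitude_scale=scale)
    if scale in pilot_cache:
        records, truths = pilot_cache[scale]
        rec_rest, tr_rest = _simulate_batch(tuned, children[len(records):])
        records = records + rec_rest
        truths = truths + tr_rest
    else:
        records, truths = _simulate_batch(tuned, children)

    pos, tot = _realized_prevalence(records, spec.svo2_threshold_pct)
    labs_per_patient = [len(r.of_kind(ChannelKind.SVO2_LAB)) for r in records]
    n_grid = int(round(spec.record_hours * 3600.0 / spec.dt_s))
    missing = {}
    for kind in (ChannelKind.SPO2, ChannelKind.HR, ChannelKind.ABP_SYS, ChannelKind.CVP):
        have = sum(len(r.of_kind(kind)) for r in records)
        missing[kind.value] = 1.0 - have / (n_grid * len(records))
    summary = {
        "n_patients": spec.n_patients,
        "n_labs": tot,
        "n_pos_labs": pos,
        "positive_lab_fraction": pos / tot if tot else float("nan"),
        "labs_per_patient_median": float(np.median(labs_per_patient)),
        "event_magnitude_scale": scale,
        "channel_missingness": missing,
    }
    return SyntheticCohort(tuned, records, truths, summary)
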