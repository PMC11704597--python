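"""Validation protocol: window averaging, ROC analysis, bootstrap, scenarios.

Each venous-saturation lab is a gold-standard reference: the index trace is
averaged over the 30 minutes leading up to — but excluding — the lab's
timestamp, the lab is dichotomized at the critical threshold (<= threshold is
positive, i.e. inadequate oxygen delivery), and the (window mean, label)
pairs feed an ROC sweep over all distinct index values. The area under the
curve is computed by trapezoidal integration (identically the tie-corrected
Mann-Whitney concordance) with percentile-bootstrap confidence intervals.
Scenario evaluation repeats this under each channel mask; labs are always
taken from the unmasked record — masking blinds the estimator, not the
reference standard.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import IndexTrace, run_filter
from .streams import ChannelKind, PatientRecord, ScenarioMask, SCENARIOS
from .physiology import PhysioParams

__all__ = [
    "ReferencePair",
    "ROCResult",
    "window_mean",
    "dichotomize",
    "build_pairs",
    "roc_curve",
    "auc_trapezoid",
    "bootstrap_ci",
    "evaluate_scenarios",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferencePair:
    """One gold-standard lab paired with the pre-lab window-mean index."""

    patient_id: str
    lab_time_s: float
    window_mean_index: float
    svo2_lab_pct: float
    label: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.window_mean_index <= 1.0):
            raise ValueError("window_mean_index must lie in [0, 1]")


@dataclass
class ROCResult:
    """Operating points, trapezoidal AUC and bookkeeping for one ROC sweep."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci_95: tuple[float, float] | None = None
    n_dropped: int = 0


def window_mean(trace: IndexTrace, lab_time_s: float, width_s: float = 1800.0) -> float:
    """Mean index over [lab_time - width, lab_time); NaN if no coverage.

    The sample at the lab's own timestamp is excluded — the window must not
    see the measurement it is judged against.
    """
    if width_s <= 0:
        raise ValueError("width_s must be positive")
    sel = (trace.times >= lab_time_s - width_s) & (trace.times < lab_time_s)
    vals = trace.values[sel]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def dichotomize(svo2_lab_pct: float, threshold_pct: float = 50.0) -> bool:
    """Positive (inadequate oxygen delivery) iff the lab is <= the threshold."""
    if not (0.0 <= svo2_lab_pct <= 100.0):
        raise ValueError("svo2_lab_pct must lie in [0, 100]")
    return svo2_lab_pct <= threshold_pct


def build_pairs(
    record: PatientRecord,
    trace: IndexTrace,
    threshold_pct: float = 50.0,
    width_s: float = 1800.0,
) -> tuple[list[ReferencePair], int]:
    """Pair every venous-saturation lab in the record with its window mean.

    Labs whose window holds no reported index are dropped (and counted) —
    the mechanism behind per-scenario differences in evaluable-lab counts.
    Labs come from the *unmasked* record passed here.
    """
    labs = record.samples[record.samples["channel"] == ChannelKind.SVO2_LAB.value]
    pairs: list[ReferencePair] = []
    dropped = 0
    for t, v in zip(labs["time_s"].to_numpy(), labs["value"].to_numpy()):
        wm = window_mean(trace, t, width_s)
        if np.isnan(wm):
            dropped += 1
            continue
        pairs.append(ReferencePair(record.patient_id, float(t), wm, float(v), dichotomize(v, threshold_pct)))
    return pairs, dropped


def _scores_labels(pairs: Sequence[ReferencePair]) -> tuple[np.ndarray, np.ndarray]:
    s = np.array([p.window_mean_index for p in pairs], dtype=float)
    y = np.array([p.label for p in pairs], dtype=bool)
    return s, y


def roc_curve(pairs: Sequence[ReferencePair], n_dropped: int = 0) -> ROCResult:
    """ROC sweep over every distinct index value (score >= threshold -> positive).

    Tied scores collapse to a single operating point; the (0,0) and (1,1)
    endpoints are always included. Requires at least one pair of each class.
    """
    s, y = _scores_labels(pairs)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0:
        raise ValueError("no positive pairs: ROC undefined without the positive class")
    if n_neg == 0:
        raise ValueError("no negative pairs: ROC undefined without the negative class")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # keep only the last index of each tied block of scores
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # guaranteed by construction, keep explicit
        fpr = np.r_[fpr, 1.0]
        tpr = np.r_[tpr, 1.0]
        thresholds = np.r_[thresholds, -np.inf]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr, tpr, thresholds, auc, n_pos, n_neg, n_dropped=n_dropped)


def auc_trapezoid(roc: ROCResult) -> float:
    """Trapezoidal area under the operating points (sorted by FPR)."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC with average ranks for ties — equals the trapezoidal
    area over the tie-collapsed ROC; used as the fast path inside the
    bootstrap."""
    r = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = r[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_ci(
    pairs: Sequence[ReferencePair],
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
    cluster_by_patient: bool = False,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling pairs with replacement.

    Degenerate one-class resamples are redrawn (capped at 10*B attempts).
    ``cluster_by_patient`` resamples whole patients instead of pairs, for
    cohorts where within-patient labs are correlated.
    """
    if B < 100:
        warnings.warn(f"B={B} bootstrap resamples is small; intervals will be noisy")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s, y = _scores_labels(pairs)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 pairs per class for a bootstrap CI")
    if cluster_by_patient:
        pids = np.array([p.patient_id for p in pairs])
        groups = [np.flatnonzero(pids == pid) for pid in pd.unique(pids)]
    aucs = np.empty(B)
    attempts = 0
    b = 0
    while b < B:
        if attempts >= 10 * B:
            raise RuntimeError("too many degenerate (one-class) bootstrap resamples")
        attempts += 1
        if cluster_by_patient:
            gi = rng.integers(0, len(groups), size=len(groups))
            idx = np.concatenate([groups[g] for g in gi])
        else:
            idx = rng.integers(0, s.size, size=s.size)
        yb = y[idx]
        if yb.all() or not yb.any():
            continue
        aucs[b] = _auc_rank(s[idx], yb)
        b += 1
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def evaluate_scenarios(
    cohort: Iterable[tuple[PatientRecord, object]] | Iterable[PatientRecord],
    params: PhysioParams,
    scenarios: Sequence[str] = ("baseline", "A", "B", "C"),
    seed: int | None = 0,
    B: int = 1000,
    cluster_by_patient: bool = False,
    dt_s: float = 5.0,
) -> pd.DataFrame:
    """Run the full protocol per scenario; one table row per scenario.

    ``cohort`` is an iterable of PatientRecord (or (record, ground_truth)
    tuples, truth ignored here). For each scenario the filter is re-run with
    a scenario-specific seed stream, pairs are built against the unmasked
    labs, and AUC with bootstrap CI is reported.
    """
    records = [c[0] if isinstance(c, tuple) else c for c in cohort]
    ss = np.random.SeedSequence(seed)
    child = {name: s for name, s in zip(scenarios, ss.spawn(len(scenarios) + 1))}
    boot_seed = ss.spawn(1)[0]
    rows = []
    for name in scenarios:
        mask = SCENARIOS[name]
        pairs: list[ReferencePair] = []
        dropped = 0
        streams = child[name].spawn(len(records))
        for rec, s in zip(records, streams):
            trace = run_filter(rec, params, mask, np.random.default_rng(s), dt_s=dt_s)
            p, d = build_pairs(rec, trace, params.svo2_threshold_pct)
            pairs.extend(p)
            dropped += d
        if not pairs:
            log.warning("scenario %s: no evaluable labs (all windows empty)", name)
            continue
        roc = roc_curve(pairs, n_dropped=dropped)
        ci = bootstrap_ci(pairs, B=B, rng=np.random.default_rng(boot_seed), cluster_by_patient=cluster_by_patient)
        rows.append(
            {
                "scenario": name,
                "auc": roc.auc,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "n_pos": roc.n_pos,
                "n_total": roc.n_pos + roc.n_neg,
                "n_dropped": dropped,
            }
        )
    return pd.DataFrame(rows, columns=["scenario", "auc", "ci_lo", "ci_hi", "n_pos", "n_total", "n_dropped"])
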