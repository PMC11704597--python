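"""Multichannel patient records: data model, I/O, discretization, gating, masking.

A patient admission is a long-format collection of timestamped samples across
bedside-monitor channels (5-second cadence) and aperiodic laboratory results.
This module owns the channel taxonomy, the 5-second regularization grid, the
minimum-data-set gating rule that decides when an index value may be reported,
and the channel-masking "scenarios" that emulate sparser monitoring setups
(no venous oximetry, no pulmonary-artery-catheter data, or neither).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ChannelKind",
    "CONTINUOUS_KINDS",
    "APERIODIC_KINDS",
    "Sample",
    "PatientRecord",
    "ScenarioMask",
    "SCENARIOS",
    "regularize",
    "minimum_dataset_ok",
    "apply_scenario",
    "read_record_csv",
    "write_record_csv",
    "read_cohort_csv",
    "write_cohort_csv",
]


class ChannelKind(str, enum.Enum):
    """Channel taxonomy for monitored streams and laboratory results."""

    SPO2 = "SPO2"              # pulse oximetry, %
    HR = "HR"                  # heart rate, beats/min
    ABP_SYS = "ABP_SYS"        # invasive arterial pressure, systolic, mm Hg
    ABP_DIA = "ABP_DIA"        # diastolic, mm Hg
    ABP_MEAN = "ABP_MEAN"      # mean arterial pressure, mm Hg
    CVP = "CVP"                # central venous pressure, mm Hg
    TEMP = "TEMP"              # core temperature, deg C
    CI_CONT = "CI_CONT"        # continuous cardiac index, L/min/m^2
    CI_APERIODIC = "CI_APERIODIC"  # thermodilution cardiac index, L/min/m^2
    SVO2_CONT = "SVO2_CONT"    # continuous venous oximetry, %
    SVO2_LAB = "SVO2_LAB"      # mixed-venous co-oximetry lab, %
    HGB_LAB = "HGB_LAB"        # hemoglobin lab, g/dL

    @property
    def is_continuous(self) -> bool:
        return self in CONTINUOUS_KINDS


CONTINUOUS_KINDS = frozenset(
    {
        ChannelKind.SPO2,
        ChannelKind.HR,
        ChannelKind.ABP_SYS,
        ChannelKind.ABP_DIA,
        ChannelKind.ABP_MEAN,
        ChannelKind.CVP,
        ChannelKind.TEMP,
        ChannelKind.CI_CONT,
        ChannelKind.SVO2_CONT,
    }
)
APERIODIC_KINDS = frozenset(
    {ChannelKind.CI_APERIODIC, ChannelKind.SVO2_LAB, ChannelKind.HGB_LAB}
)

# value sanity bounds per channel (inclusive); None = only finiteness required
_VALUE_BOUNDS: dict[ChannelKind, tuple[float | None, float | None]] = {
    ChannelKind.SPO2: (0.0, 100.0),
    ChannelKind.SVO2_CONT: (0.0, 100.0),
    ChannelKind.SVO2_LAB: (0.0, 100.0),
    ChannelKind.HR: (0.0, None),
    ChannelKind.HGB_LAB: (1e-9, None),
}


@dataclass(frozen=True)
class Sample:
    """One timestamped measurement on one channel."""

    time_s: float
    kind: ChannelKind
    value: float

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"sample time must be non-negative, got {self.time_s}")
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.kind.value}")
        lo, hi = _VALUE_BOUNDS.get(self.kind, (None, None))
        if lo is not None and self.value < lo:
            raise ValueError(f"{self.kind.value} value {self.value} below {lo}")
        if hi is not None and self.value > hi:
            raise ValueError(f"{self.kind.value} value {self.value} above {hi}")


_SAMPLE_COLUMNS = ["time_s", "channel", "value"]


def _samples_frame(samples) -> pd.DataFrame:
    """Normalize samples (DataFrame or iterable of Sample) to the long frame."""
    if isinstance(samples, pd.DataFrame):
        df = samples.loc[:, _SAMPLE_COLUMNS].copy()
        ch = df["channel"]
        if len(ch) and isinstance(ch.iloc[0], ChannelKind):
            df["channel"] = ch.map(lambda c: c.value)
    else:
        rows = [(s.time_s, s.kind.value, s.value) for s in samples]
        df = pd.DataFrame(rows, columns=_SAMPLE_COLUMNS)
    bad = set(map(str, pd.unique(df["channel"]))) - {k.value for k in ChannelKind}
    if bad:
        raise ValueError(f"unknown channel kind(s): {sorted(bad)}")
    if df["time_s"].dtype != np.float64:
        df["time_s"] = df["time_s"].astype(float)
    if df["value"].dtype != np.float64:
        df["value"] = df["value"].astype(float)
    return df.reset_index(drop=True)


@dataclass
class PatientRecord:
    """All channels and labs for a single admission.

    Samples are kept as a long-format DataFrame (``time_s, channel, value``),
    time-sorted. ``bsa_m2`` converts cardiac index to cardiac output.
    """

    patient_id: str
    age_years: float = 64.0
    bsa_m2: float = 1.9
    samples: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_SAMPLE_COLUMNS))

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.bsa_m2 <= 0:
            raise ValueError("bsa_m2 must be positive")
        self.samples = _samples_frame(self.samples)
        t = self.samples["time_s"].to_numpy()
        if t.size and np.any(np.diff(t) < 0):
            i = int(np.argmax(np.diff(t) < 0)) + 1
            row = self.samples.iloc[i]
            raise ValueError(
                "samples not time-sorted: sample "
                f"#{i} ({row['channel']} at t={row['time_s']} s) precedes its predecessor"
            )

    def of_kind(self, kind: ChannelKind) -> pd.DataFrame:
        return self.samples[self.samples["channel"] == kind.value]

    def kinds(self) -> set[ChannelKind]:
        return {ChannelKind(c) for c in self.samples["channel"].unique()}

    def duration_s(self) -> float:
        if len(self.samples) == 0:
            return 0.0
        return float(self.samples["time_s"].iloc[-1])


@dataclass(frozen=True)
class ScenarioMask:
    """Named set of channel kinds withheld from the estimator.

    The named scenarios emulate monitoring setups:
    A  — no venous oximetry of any kind (thermodilution-only PAC);
    B  — no PAC-derived data (no CI, no continuous oximetry) but aperiodic
         venous-saturation labs still arrive;
    C  — central line only: no CI and no venous saturation from any source.
    """

    name: str
    blocked_kinds: frozenset[ChannelKind]


SCENARIOS: dict[str, ScenarioMask] = {
    "baseline": ScenarioMask("baseline", frozenset()),
    "A": ScenarioMask("A", frozenset({ChannelKind.SVO2_LAB, ChannelKind.SVO2_CONT})),
    "B": ScenarioMask(
        "B",
        frozenset({ChannelKind.CI_CONT, ChannelKind.CI_APERIODIC, ChannelKind.SVO2_CONT}),
    ),
    "C": ScenarioMask(
        "C",
        frozenset(
            {
                ChannelKind.CI_CONT,
                ChannelKind.CI_APERIODIC,
                ChannelKind.SVO2_CONT,
                ChannelKind.SVO2_LAB,
            }
        ),
    ),
}


def regularize(record: PatientRecord, dt_s: float = 5.0) -> PatientRecord:
    """Report every continuous channel on the uniform grid {0, dt, 2dt, ...}.

    Within each half-open bin [k*dt, (k+1)*dt) the last observation wins
    (real-time causality); empty bins stay missing — nothing is imputed.
    Aperiodic samples pass through untouched.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    df = record.samples
    is_cont = df["channel"].isin([k.value for k in CONTINUOUS_KINDS])
    cont = df[is_cont].copy()
    aper = df[~is_cont]
    if len(cont):
        cont["time_s"] = np.floor(cont["time_s"].to_numpy() / dt_s) * dt_s
        # stable sort preserved from the record, so tail(1) is the last obs in bin
        cont = cont.groupby(["channel", "time_s"], as_index=False, sort=False).tail(1)
    out = pd.concat([cont, aper], ignore_index=True)
    out = out.sort_values("time_s", kind="stable").reset_index(drop=True)
    return PatientRecord(record.patient_id, record.age_years, record.bsa_m2, out)


def apply_scenario(record: PatientRecord, mask: ScenarioMask) -> PatientRecord:
    """Drop every sample whose kind the scenario blocks; all else untouched."""
    blocked = {k.value for k in mask.blocked_kinds}
    kept = record.samples[~record.samples["channel"].isin(blocked)].reset_index(drop=True)
    return PatientRecord(record.patient_id, record.age_years, record.bsa_m2, kept)


def _latest_time_at_or_before(df: pd.DataFrame, kind: ChannelKind, t: float) -> float | None:
    sub = df[(df["channel"] == kind.value) & (df["time_s"] <= t)]
    if len(sub) == 0:
        return None
    return float(sub["time_s"].iloc[-1])


def minimum_dataset_ok(
    record: PatientRecord,
    t: float,
    staleness_s: float = 60.0,
    hgb_max_age_h: float = 24.0,
) -> bool:
    """True iff the minimum data set is available at time ``t``.

    Requires fresh (<= ``staleness_s`` old) grid values for pulse oximetry,
    heart rate, arterial pressure (systolic+diastolic, or mean alone) and
    central venous pressure, plus a hemoglobin lab within the past
    ``hgb_max_age_h`` hours. Missing data yields False, never an exception.
    """
    df = record.samples

    def fresh(kind: ChannelKind) -> bool:
        lt = _latest_time_at_or_before(df, kind, t)
        return lt is not None and (t - lt) <= staleness_s

    abp_ok = (fresh(ChannelKind.ABP_SYS) and fresh(ChannelKind.ABP_DIA)) or fresh(
        ChannelKind.ABP_MEAN
    )
    if not (fresh(ChannelKind.SPO2) and fresh(ChannelKind.HR) and abp_ok and fresh(ChannelKind.CVP)):
        return False
    hgb_t = _latest_time_at_or_before(df, ChannelKind.HGB_LAB, t)
    return hgb_t is not None and (t - hgb_t) <= hgb_max_age_h * 3600.0


# ---------------------------------------------------------------------------
# CSV dialect: long-format samples `patient_id,time_s,channel,value` plus a
# per-patient header table `patient_id,age_years,bsa_m2`.

def write_record_csv(record: PatientRecord, path: str | Path) -> None:
    df = record.samples.copy()
    df.insert(0, "patient_id", record.patient_id)
    df.to_csv(path, index=False)


def read_record_csv(
    path: str | Path, patient_id: str | None = None, age_years: float = 64.0, bsa_m2: float = 1.9
) -> PatientRecord:
    df = pd.read_csv(path)
    if patient_id is not None:
        df = df[df["patient_id"] == patient_id]
    elif df["patient_id"].nunique() > 1:
        raise ValueError("multiple patients in file; pass patient_id")
    pid = str(df["patient_id"].iloc[0])
    return PatientRecord(pid, age_years, bsa_m2, df[_SAMPLE_COLUMNS])


def write_cohort_csv(records: Iterable[PatientRecord], samples_path: str | Path, header_path: str | Path) -> None:
    frames, head = [], []
    for r in records:
        df = r.samples.copy()
        df.insert(0, "patient_id", r.patient_id)
        frames.append(df)
        head.append((r.patient_id, r.age_years, r.bsa_m2))
    pd.concat(frames, ignore_index=True).to_csv(samples_path, index=False)
    pd.DataFrame(head, columns=["patient_id", "age_years", "bsa_m2"]).to_csv(header_path, index=False)


def read_cohort_csv(samples_path: str | Path, header_path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(samples_path)
    head = pd.read_csv(header_path).set_index("patient_id")
    records = []
    for pid, sub in df.groupby("patient_id", sort=False):
        h = head.loc[pid]
        records.append(
            PatientRecord(str(pid), float(h["age_years"]), float(h["bsa_m2"]), sub[_SAMPLE_COLUMNS])
        )
    return records
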