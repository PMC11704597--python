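"""Shared fixtures: small records, parameter sets, and the cohort study.

The multi-seed scenario study is expensive (thousands of filter runs), so it
is computed once per session and shared by the calibration, scenario-ordering
and information-monotonicity tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from o2index import CohortSpec, PatientRecord, PhysioParams
from o2index.study import scenario_study

try:  # register a deterministic hypothesis profile when hypothesis is present
    from hypothesis import settings, HealthCheck

    settings.register_profile(
        "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def constant_record(
    *,
    hours: float = 1.0,
    dt: float = 5.0,
    spo2: float = 97.0,
    hr: float = 80.0,
    sbp: float = 120.0,
    dbp: float = 80.0,
    cvp: float = 8.0,
    hgb: float = 12.0,
    extra_rows: list[tuple[float, str, float]] | None = None,
    patient_id: str = "const",
) -> PatientRecord:
    """Flat vitals on the full grid plus an admission hemoglobin lab."""
    times = np.arange(int(round(hours * 3600 / dt))) * dt
    rows = []
    for t in times:
        rows += [
            (t, "SPO2", spo2),
            (t, "HR", hr),
            (t, "ABP_SYS", sbp),
            (t, "ABP_DIA", dbp),
            (t, "CVP", cvp),
        ]
    rows.append((0.0, "HGB_LAB", hgb))
    rows.extend(extra_rows or [])
    df = pd.DataFrame(rows, columns=["time_s", "channel", "value"]).sort_values(
        "time_s", kind="stable"
    )
    return PatientRecord(patient_id, 64.0, 1.9, df)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params_small():
    return PhysioParams(n_particles=500)


@pytest.fixture(scope="session")
def cohort_study():
    """Five-seed, four-scenario study on 100-patient synthetic cohorts.

    Records are 4 h long (a deliberate problem-size reduction relative to the
    48 h generator default; event rates, noise levels and the prevalence
    target are untouched) with the filter at 500 particles.
    """
    spec = CohortSpec(n_patients=100, record_hours=4.0)
    params = PhysioParams(n_particles=500)
    return scenario_study(spec, params, seeds=(0, 1, 2, 3, 4))
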