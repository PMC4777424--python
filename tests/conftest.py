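"""Shared fixtures: a small simulated cohort and synthetic record tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hbforecast import (
    PatientProfile,
    SimulationConfig,
    apply_inclusion_criteria,
    build_records,
    simulate_cohort,
)
from hbforecast.records import RECORD_COLUMNS


def make_profile(**overrides) -> PatientProfile:
    """A plausible dialysis patient with deterministic latent parameters."""
    fields = dict(
        patient_id="P0", age=60.0, sex="male", height=170.0, dry_weight=70.0,
        vintage=3.0, diabetes=0, vascular_access="fistula", modality="HDF",
        esa_sensitivity=0.12, rbc_lifespan=75.0, maturation_lag=13.0,
        baseline_production=0.08,
        followup_start="2006-01-02", followup_end="2007-01-02",
    )
    fields.update(overrides)
    return PatientProfile(**fields)


@pytest.fixture(scope="session")
def profile_factory():
    return make_profile


@pytest.fixture(scope="session")
def small_cohort():
    """20 patients over 2 years — enough structure for integration checks."""
    return simulate_cohort(SimulationConfig(n_patients=20, calendar_days=730, seed=123))


@pytest.fixture(scope="session")
def small_records(small_cohort):
    kept, _ = apply_inclusion_criteria(small_cohort.profiles, small_cohort.doses)
    return build_records(small_cohort, kept)


def synthetic_linear_records(n: int, seed: int, noise_sd: float = 0.0,
                             n_patients: int = 50) -> pd.DataFrame:
    """Records whose target is an exact linear function of three features.

    delta_hb = 0.4 + 0.002*esa_future - 0.25*(hb_t - 11) + 0.001*iron_dose_90d
    (+ optional Gaussian noise) — a noiseless learnability benchmark.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    start = pd.Timestamp("2006-01-15")
    rows = []
    for i in range(n):
        pid = f"S{i % n_patients:03d}"
        t = start + pd.Timedelta(days=30 * (i // n_patients))
        hb_t = rng.uniform(8, 14)
        esa_future = rng.uniform(0, 1000)
        iron_90 = rng.uniform(0, 1200)
        delta = (0.4 + 0.002 * esa_future - 0.25 * (hb_t - 11.0) + 0.001 * iron_90
                 + (rng.normal(0, noise_sd) if noise_sd else 0.0))
        rows.append({
            "record_id": f"{pid}:{t.strftime('%Y-%m-%d')}:{i}",
            "patient_id": pid, "anchor_date": t, "hb_t": hb_t,
            "age": rng.uniform(30, 85), "sex": rng.choice(["female", "male"]),
            "height": rng.uniform(150, 185),
            "vintage": rng.uniform(0.3, 12), "diabetes": int(rng.random() < 0.3),
            "modality": rng.choice(["LFHD", "HFHD", "HDF"]),
            "vascular_access": rng.choice(["fistula", "graft", "catheter"]),
            "duration": rng.uniform(210, 245), "sessions_per_week": 3.0,
            "ektv_mean": rng.uniform(1.0, 1.8), "ektv_sd": rng.uniform(0.05, 0.3),
            "pre_weight": 72.0, "post_weight": 70.0,
            "esa_dose_90d": rng.uniform(0, 1000), "iron_dose_90d": iron_90,
            "ferritin": rng.uniform(100, 800), "tsat": rng.uniform(15, 40),
            "albumin": rng.uniform(3.2, 4.6), "phosphate": rng.uniform(3, 7),
            "crp": rng.uniform(0, 4),
            "esa_future": esa_future, "iron_future": rng.uniform(0, 1200),
            "target_date": t + pd.Timedelta(days=90),
            "delta_hb": delta, "valid": True,
        })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@pytest.fixture(scope="session")
def linear_records():
    return synthetic_linear_records(2000, seed=77)
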