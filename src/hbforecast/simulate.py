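"""Mechanistic synthetic cohorts of hemodialysis patients on IV darbepoetin and iron.

The generator emulates the longitudinal structure of an in-center hemodialysis
EHR extract: static patient covariates, thrice-weekly dialysis sessions,
weekly IV drug administrations, monthly/quarterly laboratory panels and dated
adverse events, with hemoglobin (Hb) responding to dosing through a simple
erythropoiesis kinetic:

* IV darbepoetin decays exponentially (default half-life 1 day) giving a
  daily *exposure*;
* marrow production responds to the exposure ``maturation_lag`` days earlier
  (erythrocyte development takes about 13 days) through a saturating Emax
  curve, gated by iron availability (TSAT);
* circulating Hb is the running sum of the last ``rbc_lifespan`` days of
  production (red cells survive roughly 60-90 days in ESRD), so Hb integrates
  the previous ~3 months of dosing with declining potency.

A protocol controller adjusts the weekly darbepoetin/iron dose whenever the
observed monthly Hb leaves the target band, which induces the dose-Hb
correlation (and Hb cycling) seen in real cohorts.  Adverse events
(hospitalization, transfusion, intercurrent events) add signed persistent
steps to true Hb; laboratory errors corrupt a single observation.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatientProfile",
    "SimulationConfig",
    "Cohort",
    "esa_exposure",
    "simulate_hb_trajectory",
    "observe_labs",
    "simulate_cohort",
]

HB_FLOOR = 3.0
HB_CEIL = 20.0

#: days of warm-up before follow-up so state (exposure, iron store, marrow
#: output ring buffer) starts near its operating point
_BURN_IN_PAD = 40
_MAX_LIFESPAN = 120
_MAX_LAG = 30

DOSE_COLUMNS = ["patient_id", "date", "drug", "amount", "route"]
LAB_COLUMNS = ["patient_id", "date", "analyte", "value"]
SESSION_COLUMNS = ["patient_id", "date", "duration", "ektv", "pre_weight", "post_weight"]
EVENT_COLUMNS = ["patient_id", "date", "etype", "hb_effect"]
PROFILE_COLUMNS = [
    "patient_id", "age", "sex", "height", "dry_weight", "vintage", "diabetes",
    "vascular_access", "modality", "esa_sensitivity", "rbc_lifespan",
    "maturation_lag", "baseline_production", "followup_start", "followup_end",
]


@dataclass
class PatientProfile:
    """Static covariates plus the latent response parameters of one patient."""

    patient_id: str
    age: float
    sex: str                    # 'female' | 'male'
    height: float               # cm
    dry_weight: float           # kg
    vintage: float              # years on dialysis at follow-up start
    diabetes: int               # 0/1
    vascular_access: str        # 'fistula' | 'graft' | 'catheter'
    modality: str               # 'LFHD' | 'HFHD' | 'HDF'
    esa_sensitivity: float      # marrow output (g/dL-day units) at full stimulation
    rbc_lifespan: float         # days, in [30, 120]
    maturation_lag: float       # days from stimulation to red-cell release
    baseline_production: float  # endogenous output, g/dL-day units
    followup_start: pd.Timestamp
    followup_end: pd.Timestamp

    def __post_init__(self) -> None:
        if not 30 <= self.rbc_lifespan <= 120:
            raise ValueError(f"rbc_lifespan {self.rbc_lifespan} outside [30, 120]")
        if self.maturation_lag < 0:
            raise ValueError("maturation_lag must be >= 0")
        if self.esa_sensitivity < 0:
            raise ValueError("esa_sensitivity must be >= 0")
        self.followup_start = pd.Timestamp(self.followup_start)
        self.followup_end = pd.Timestamp(self.followup_end)
        if self.followup_end <= self.followup_start:
            raise ValueError("followup_end must be after followup_start")


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults emulate the study population.

    Covariate defaults follow the published baseline table of the cohort the
    generator emulates (age 62 +/- 15 y, 39% female, eKt/V 1.38 +/- 0.39,
    session length 226 +/- 14 min, ...); dosing defaults put the median
    weekly darbepoetin dose near 20 ug.  ``noise_sd_lab`` defaults to the
    commonly quoted +/- 0.5 g/dL intra-individual Hb assay variability.
    """

    n_patients: int = 100
    calendar_days: int = 3 * 365
    start_date: str = "2006-01-02"      # a Monday; sessions run Mon/Wed/Fri
    seed: int = 0

    # observation / scheduling
    noise_sd_lab: float = 0.5           # g/dL, Gaussian, Hb only
    quarterly_analytes: tuple = ("albumin", "phosphate", "CRP")

    # adverse events, per patient-year
    event_rates: dict = field(default_factory=lambda: {
        "hospitalization": 0.6,
        "transfusion": 0.15,
        "intercurrent": 0.4,
        "lab_error": 0.15,
    })

    # kinetics
    half_life: float = 1.0              # days, IV darbepoetin
    response_form: str = "emax"         # 'emax' | 'linear'
    emax_k: float = 4.0                 # ug-equivalent exposure at half-max
    iron_limitation: bool = True
    tsat_halfmax: float = 20.0          # % TSAT below which production is limited
    iron_loss_rate: float = 0.005       # fraction of the iron store lost per day
    hb_scale: float = 1.0               # g/dL per unit of summed production

    # protocol controller
    target_band: tuple = (10.0, 12.0)   # g/dL
    esa_step: float = 2.5               # ug change of the weekly dose (doubled when
                                        # Hb is more than 1 g/dL outside the band)
    esa_max: float = 200.0              # ug weekly cap
    iron_step: float = 25.0             # mg change of the weekly dose
    iron_max: float = 150.0             # mg weekly cap

    # covariate distributions
    age_mean: float = 62.0
    age_sd: float = 15.0
    female_frac: float = 0.39
    height_mean: float = 163.0
    height_sd: float = 8.8
    weight_mean: float = 67.8
    weight_sd: float = 13.0
    vintage_mean: float = 3.1
    vintage_sd: float = 4.2
    incident_frac: float = 0.03         # patients with < 90 d vintage
    diabetes_frac: float = 0.32
    modality_fracs: tuple = (0.01, 0.41, 0.58)   # LFHD / HFHD / HDF
    access_fracs: tuple = (0.60, 0.15, 0.25)     # fistula / graft / catheter
    duration_mean: float = 226.0
    duration_sd: float = 14.0
    ektv_mean: float = 1.38
    ektv_sd: float = 0.25
    short_followup_frac: float = 0.20   # patients leaving before 6 months
    no_esa_frac: float = 0.10           # patients starting without darbepoetin

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.calendar_days <= 0:
            raise ValueError("calendar_days must be > 0")
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")
        if self.noise_sd_lab < 0:
            raise ValueError("noise_sd_lab must be >= 0")
        for etype, rate in self.event_rates.items():
            if rate < 0:
                raise ValueError(f"event rate for {etype!r} must be >= 0")
        if self.response_form not in ("emax", "linear"):
            raise ValueError(f"unknown response_form {self.response_form!r}")
        lo, hi = self.target_band
        if not lo < hi:
            raise ValueError("target_band must satisfy low < high")
        if self.esa_step < 0 or self.iron_step < 0:
            raise ValueError("controller steps must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["target_band"] = list(d["target_band"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        for key in ("target_band", "modality_fracs", "access_fracs", "quarterly_analytes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Cohort:
    """The five longitudinal tables of one simulated (or imported) cohort."""

    profiles: pd.DataFrame
    doses: pd.DataFrame
    labs: pd.DataFrame
    sessions: pd.DataFrame
    events: pd.DataFrame
    config: SimulationConfig | None = None

    _TABLES = ("profiles", "doses", "labs", "sessions", "events")

    def save(self, outdir: str | Path) -> None:
        """Write the five CSV tables (ISO-8601 dates) plus a config sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            df = getattr(self, name).copy()
            for col in ("date", "followup_start", "followup_end"):
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
            df.to_csv(outdir / f"{name}.csv", index=False)
        if self.config is not None:
            (outdir / "config.json").write_text(self.config.to_json() + "\n")

    @classmethod
    def load(cls, indir: str | Path) -> "Cohort":
        indir = Path(indir)
        tables = {}
        for name in cls._TABLES:
            df = pd.read_csv(indir / f"{name}.csv")
            for col in ("date", "followup_start", "followup_end"):
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col])
            tables[name] = df
        cfg_path = indir / "config.json"
        config = SimulationConfig.from_json(cfg_path.read_text()) if cfg_path.exists() else None
        return cls(config=config, **tables)


# ---------------------------------------------------------------------------
# drug exposure
# ---------------------------------------------------------------------------

def _as_days(value, origin) -> float:
    """Days between value and origin; ints/floats pass through unchanged."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    return float((pd.Timestamp(value) - pd.Timestamp(origin)) / pd.Timedelta(days=1))


def esa_exposure(doses, day, half_life: float = 1.0) -> float:
    """Circulating ug-equivalent exposure on ``day`` from past IV doses.

    Each dose of amount ``a`` given ``dt >= 0`` days before ``day``
    contributes ``a * 2**(-dt / half_life)``; later doses contribute nothing.
    ``doses`` may be a DataFrame with ``date``/``amount`` columns or an
    iterable of ``(date, amount)`` pairs; dates may be calendar dates or
    plain day numbers.
    """
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    if isinstance(doses, pd.DataFrame):
        pairs = list(zip(doses["date"], doses["amount"]))
    else:
        pairs = list(doses)
    if not pairs:
        return 0.0
    origin = pairs[0][0]
    day_d = _as_days(day, origin)
    total = 0.0
    for when, amount in pairs:
        dt = day_d - _as_days(when, origin)
        if dt >= 0:
            total += float(amount) * 2.0 ** (-dt / half_life)
    return total


# ---------------------------------------------------------------------------
# erythropoiesis state machine
# ---------------------------------------------------------------------------

class _Erythro:
    """Per-day state: exposure decay, iron store, production ring buffer."""

    def __init__(self, profile: PatientProfile, cfg: SimulationConfig,
                 iron_store0: float = 900.0):
        self.decay = 2.0 ** (-1.0 / cfg.half_life)
        self.lag = int(round(profile.maturation_lag))
        self.lifespan = int(round(profile.rbc_lifespan))
        self.sens = profile.esa_sensitivity
        self.base = profile.baseline_production
        self.emax = cfg.response_form == "emax"
        self.k = cfg.emax_k
        self.iron_limitation = cfg.iron_limitation
        self.tsat_halfmax = cfg.tsat_halfmax
        self.iron_loss = cfg.iron_loss_rate
        self.scale = cfg.hb_scale

        self.exposure = 0.0
        self.exp_hist: deque = deque([0.0] * (self.lag + 1), maxlen=self.lag + 1)
        self.store = iron_store0            # mg of available iron
        self.prod_buf = np.zeros(self.lifespan)
        self.prod_sum = 0.0
        self.idx = 0

    def iron_markers(self) -> tuple[float, float]:
        """(TSAT %, ferritin ug/L) implied by the current iron store."""
        tsat = 45.0 * self.store / (self.store + 900.0)
        ferritin = 0.4 * self.store
        return tsat, ferritin

    def step(self, darbe_ug: float, iron_mg: float) -> float:
        """Advance one day; returns the kinetic Hb (before event steps/clamp)."""
        self.exposure = self.exposure * self.decay + darbe_ug
        self.exp_hist.append(self.exposure)
        e_lag = self.exp_hist[0]
        self.store = self.store * (1.0 - self.iron_loss) + iron_mg
        tsat, _ = self.iron_markers()

        if self.emax:
            g = e_lag / (e_lag + self.k)
        else:
            g = e_lag
        iron_factor = min(1.0, tsat / self.tsat_halfmax) if self.iron_limitation else 1.0
        production = self.base + self.sens * g * iron_factor
        if not np.isfinite(production):
            raise FloatingPointError("non-finite production; check configuration")

        self.prod_sum += production - self.prod_buf[self.idx]
        self.prod_buf[self.idx] = production
        self.idx = (self.idx + 1) % self.lifespan
        return self.scale * self.prod_sum


def _add_event_ramp(series: np.ndarray, idx: int, effect: float, lifespan: int) -> None:
    """Add an event's Hb contribution: full step at idx, linear decay over lifespan."""
    n = len(series)
    end = min(n, idx + lifespan)
    days = np.arange(idx, end)
    series[idx:end] += effect * (1.0 - (days - idx) / lifespan)


def _daily_amounts(doses: pd.DataFrame, origin: pd.Timestamp, d0: int, n: int,
                   drug: str) -> np.ndarray:
    """Amount-per-day array covering relative days [d0, d0 + n)."""
    out = np.zeros(n)
    if doses is None or len(doses) == 0:
        return out
    sub = doses[doses["drug"] == drug] if "drug" in doses.columns else doses
    for when, amount in zip(sub["date"], sub["amount"]):
        if amount < 0:
            raise ValueError("dose amounts must be >= 0")
        day = int(round(_as_days(when, origin)))
        if d0 <= day < d0 + n:
            out[day - d0] += float(amount)
    return out


def simulate_hb_trajectory(profile: PatientProfile, doses: pd.DataFrame | None,
                           events: pd.DataFrame | None,
                           config: SimulationConfig) -> pd.Series:
    """Open-loop daily true-Hb series over follow-up for given dose/event tables.

    Runs the daily recursion

    ``production(d) = baseline + sensitivity * g(exposure(d - lag)) * iron_factor(d)``
    ``Hb(d) = scale * sum(production over the trailing rbc_lifespan days) + event steps``

    from well before follow-up start (state zero-initialised at the earliest
    dose or ``rbc_lifespan + lag`` days back, whichever is earlier), clamped
    to [3, 20] g/dL.  Hospitalization/transfusion/intercurrent events add
    their full ``hb_effect`` on the event day, decaying linearly to zero
    over one rbc_lifespan (transfused cells die off; event-related losses
    recover); ``lab_error`` events do not touch the true series.
    """
    config.validate()
    origin = profile.followup_start
    n_days = int(round(_as_days(profile.followup_end, origin)))
    d0 = -(int(round(profile.rbc_lifespan)) + int(round(profile.maturation_lag)) + _BURN_IN_PAD)
    if doses is not None and len(doses):
        first = min(int(round(_as_days(w, origin))) for w in doses["date"])
        d0 = min(d0, first)
    n_total = n_days - d0

    darbe = _daily_amounts(doses, origin, d0, n_total, "darbepoetin")
    iron = _daily_amounts(doses, origin, d0, n_total, "iron")

    lifespan = int(round(profile.rbc_lifespan))
    step_series = np.zeros(n_total)
    if events is not None and len(events):
        for _, ev in events.iterrows():
            if ev["etype"] == "lab_error":
                continue
            day = int(round(_as_days(ev["date"], origin)))
            if d0 <= day < n_days:
                _add_event_ramp(step_series, day - d0, float(ev["hb_effect"]), lifespan)

    state = _Erythro(profile, config)
    hb = np.empty(n_days)
    for i in range(n_total):
        kin = state.step(darbe[i], iron[i])
        d = d0 + i
        if d >= 0:
            hb[d] = float(np.clip(kin + step_series[i], HB_FLOOR, HB_CEIL))
    index = origin + pd.to_timedelta(np.arange(n_days), unit="D")
    return pd.Series(hb, index=index, name="hb_true")


def observe_labs(true_hb: pd.Series, config: SimulationConfig,
                 rng: np.random.Generator, patient_id: str = "P0",
                 lab_day: int = 15, events: pd.DataFrame | None = None) -> pd.DataFrame:
    """Monthly Hb observations from a daily true series.

    One observation per calendar month on ``lab_day`` (skipped if outside the
    series), equal to the true Hb plus Gaussian noise of sd
    ``config.noise_sd_lab``.  A ``lab_error`` event replaces the observation
    of its month with ``true + hb_effect`` and no measurement noise, so the
    recorded value is exactly the aberrant value the event encodes.
    """
    config.validate()
    lab_error_months = {}
    if events is not None and len(events):
        sub = events[events["etype"] == "lab_error"]
        for _, ev in sub.iterrows():
            ts = pd.Timestamp(ev["date"])
            lab_error_months[(ts.year, ts.month)] = float(ev["hb_effect"])

    rows = []
    index = pd.DatetimeIndex(true_hb.index)
    months = sorted(set(zip(index.year, index.month)))
    for year, month in months:
        try:
            when = pd.Timestamp(year=year, month=month, day=lab_day)
        except ValueError:
            continue
        if when not in true_hb.index:
            continue
        truth = float(true_hb.loc[when])
        if (year, month) in lab_error_months:
            value = truth + lab_error_months[(year, month)]
        else:
            value = truth + rng.normal(0.0, config.noise_sd_lab)
        rows.append((patient_id, when, "Hb", value))
    return pd.DataFrame(rows, columns=LAB_COLUMNS)


# ---------------------------------------------------------------------------
# closed-loop cohort generation
# ---------------------------------------------------------------------------

def _sample_profile(pid: str, cfg: SimulationConfig, rng: np.random.Generator,
                    start: pd.Timestamp) -> tuple[PatientProfile, dict]:
    """Draw one patient's covariates and latent response parameters."""
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 18, 95))
    sex = "female" if rng.random() < cfg.female_frac else "male"
    height = float(rng.normal(cfg.height_mean, cfg.height_sd))
    dry_weight = float(np.clip(rng.normal(cfg.weight_mean, cfg.weight_sd), 40, 140))
    if rng.random() < cfg.incident_frac:
        vintage = float(rng.uniform(0.0, 0.2))
    else:
        vintage = float(max(0.25, abs(rng.normal(cfg.vintage_mean, cfg.vintage_sd))))
    diabetes = int(rng.random() < cfg.diabetes_frac)
    modality = rng.choice(["LFHD", "HFHD", "HDF"], p=cfg.modality_fracs)
    access = rng.choice(["fistula", "graft", "catheter"], p=cfg.access_fracs)

    no_esa = rng.random() < cfg.no_esa_frac
    if no_esa:
        baseline = float(rng.uniform(0.13, 0.16))
        darbe0 = 0.0
    else:
        baseline = float(rng.uniform(0.06, 0.12))
        darbe0 = float(np.clip(5 * round(20.0 * np.exp(rng.normal(0, 0.5)) / 5), 5, 60))

    if rng.random() < cfg.short_followup_frac:
        n_days = int(rng.integers(60, 200))
    else:
        n_days = cfg.calendar_days

    profile = PatientProfile(
        patient_id=pid,
        age=age, sex=sex, height=height, dry_weight=dry_weight,
        vintage=vintage, diabetes=diabetes,
        vascular_access=str(access), modality=str(modality),
        esa_sensitivity=float(np.exp(rng.normal(np.log(0.13), 0.35))),
        rbc_lifespan=float(rng.uniform(60, 90)),
        maturation_lag=13.0,
        baseline_production=baseline,
        followup_start=start,
        followup_end=start + pd.Timedelta(days=n_days),
    )
    extras = {
        "darbe0": darbe0,
        "iron0": float(rng.choice([0.0, 25.0, 50.0], p=[0.25, 0.5, 0.25])),
        "lab_day": int(rng.integers(3, 28)),
        "duration_p": float(rng.normal(cfg.duration_mean, cfg.duration_sd)),
        "ektv_p": float(np.clip(rng.normal(cfg.ektv_mean, cfg.ektv_sd), 0.8, 2.2)),
        "albumin_p": float(rng.normal(4.0, 0.3)),
        "phosphate_p": float(np.clip(rng.normal(4.9, 1.0), 2.0, 9.0)),
        "crp_p": float(np.clip(rng.normal(1.5, 1.0), 0.0, 5.0)),
    }
    return profile, extras


def _sample_events(cfg: SimulationConfig, rng: np.random.Generator,
                   n_days: int) -> list[dict]:
    """Pre-draw adverse events: Poisson counts, uniform dates, signed sizes."""
    years = n_days / 365.25
    out = []
    for etype, rate in sorted(cfg.event_rates.items()):
        for _ in range(rng.poisson(rate * years)):
            day = int(rng.integers(0, n_days))
            if etype == "hospitalization":
                effect = -float(rng.uniform(0.5, 3.0))
            elif etype == "transfusion":
                effect = float(rng.uniform(1.0, 4.0))
            elif etype == "intercurrent":
                effect = -float(rng.uniform(0.3, 1.5))
            else:  # lab_error: aberrant recorded value, low or high
                if rng.random() < 0.5:
                    effect = float(rng.uniform(5.5, 8.0))    # target value, resolved later
                else:
                    effect = float(rng.uniform(15.0, 18.0))
            out.append({"etype": etype, "day": day, "effect": effect})
    out.sort(key=lambda e: (e["day"], e["etype"]))
    return out


def _simulate_patient(profile: PatientProfile, extras: dict, cfg: SimulationConfig,
                      rng: np.random.Generator, cal: dict, cal_offset: int):
    """Closed-loop simulation of one patient; returns per-table row lists."""
    pid = profile.patient_id
    origin = profile.followup_start
    n_days = int(round(_as_days(profile.followup_end, origin)))
    lab_day = extras["lab_day"]
    darbe_level, iron_level = extras["darbe0"], extras["iron0"]
    lo, hi = cfg.target_band

    events = _sample_events(cfg, rng, n_days)
    lifespan = int(round(profile.rbc_lifespan))
    step_series = np.zeros(n_days)
    lab_error_by_month: dict[tuple, dict] = {}
    event_rows = []
    for ev in events:
        when = origin + pd.Timedelta(days=ev["day"])
        if ev["etype"] == "lab_error":
            lab_error_by_month[(when.year, when.month)] = ev
            ev["date"] = when
        else:
            _add_event_ramp(step_series, ev["day"], ev["effect"], lifespan)
            event_rows.append((pid, when, ev["etype"], ev["effect"]))

    state = _Erythro(profile, cfg)
    burn_in = state.lifespan + state.lag + _BURN_IN_PAD
    weekday = cal["weekday"]
    dom = cal["dom"]

    dose_rows, lab_rows, session_rows = [], [], []
    hb_true = np.empty(n_days)
    month_idx = {}

    for d in range(-burn_in, n_days):
        ci = cal_offset + d
        wd = weekday[ci]
        darbe_today = darbe_level if wd == 0 and darbe_level > 0 else 0.0
        iron_today = iron_level if wd == 0 and iron_level > 0 else 0.0
        kin = state.step(darbe_today, iron_today)
        if d < 0:
            continue

        when = origin + pd.Timedelta(days=d)
        if darbe_today > 0:
            dose_rows.append((pid, when, "darbepoetin", darbe_today, "IV"))
        if iron_today > 0:
            dose_rows.append((pid, when, "iron", iron_today, "IV"))

        hb = float(np.clip(kin + step_series[d], HB_FLOOR, HB_CEIL))
        hb_true[d] = hb

        if wd in (0, 2, 4):  # Mon/Wed/Fri dialysis sessions
            post = profile.dry_weight + rng.normal(0.0, 0.4)
            pre = post + max(0.0, rng.normal(2.4, 0.6))
            session_rows.append((
                pid, when,
                float(max(120.0, rng.normal(extras["duration_p"], 8.0))),
                float(max(0.5, rng.normal(extras["ektv_p"], 0.12))),
                float(pre), float(post),
            ))

        if dom[ci] == lab_day:
            key = (when.year, when.month)
            month_idx[key] = month_idx.get(key, 0)
            lab_err = lab_error_by_month.get(key)
            if lab_err is not None:
                obs = lab_err["effect"]            # aberrant recorded value
                lab_err["true_at_obs"] = hb
            else:
                obs = hb + rng.normal(0.0, cfg.noise_sd_lab)
            lab_rows.append((pid, when, "Hb", float(obs)))

            tsat, ferritin = state.iron_markers()
            tsat_obs = float(max(2.0, tsat + rng.normal(0.0, 1.5)))
            lab_rows.append((pid, when, "TSAT", tsat_obs))
            lab_rows.append((pid, when, "ferritin",
                             float(max(5.0, ferritin * np.exp(rng.normal(0.0, 0.1))))))
            if len(month_idx) % 3 == 1:            # quarterly panel
                lab_rows.append((pid, when, "albumin",
                                 float(extras["albumin_p"] + rng.normal(0.0, 0.15))))
                lab_rows.append((pid, when, "phosphate",
                                 float(max(1.0, extras["phosphate_p"] + rng.normal(0.0, 0.4)))))
                lab_rows.append((pid, when, "CRP",
                                 float(max(0.0, extras["crp_p"] + rng.normal(0.0, 0.3)))))

            # protocol controller: one step per monthly panel, doubled far
            # outside the band
            if obs < lo:
                step = cfg.esa_step * (2.0 if obs < lo - 1.0 else 1.0)
                darbe_level = min(cfg.esa_max, darbe_level + step)
            elif obs > hi:
                step = cfg.esa_step * (2.0 if obs > hi + 1.0 else 1.0)
                darbe_level = max(0.0, darbe_level - step)
            if tsat_obs < 20.0:
                iron_level = min(cfg.iron_max, iron_level + cfg.iron_step)
            elif tsat_obs > 35.0:
                iron_level = max(0.0, iron_level - cfg.iron_step)

    # lab_error hb_effect is the step applied to the observed value only
    for (year, month), ev in lab_error_by_month.items():
        true_at_obs = ev.get("true_at_obs")
        if true_at_obs is not None:
            event_rows.append((pid, ev["date"], "lab_error", ev["effect"] - true_at_obs))

    return dose_rows, lab_rows, session_rows, sorted(event_rows, key=lambda r: r[1])


def _calendar(start: pd.Timestamp, pad: int, n_days: int) -> tuple[dict, int]:
    """Precompute weekday / day-of-month arrays for days [-pad, n_days)."""
    idx = pd.date_range(start - pd.Timedelta(days=pad), periods=pad + n_days, freq="D")
    return {"weekday": idx.weekday.to_numpy(), "dom": idx.day.to_numpy()}, pad


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort; bit-for-bit reproducible per seed."""
    config.validate()
    start = pd.Timestamp(config.start_date)
    cal, cal_offset = _calendar(start, _MAX_LIFESPAN + _MAX_LAG + _BURN_IN_PAD,
                                config.calendar_days + 1)

    ss = np.random.SeedSequence(config.seed)
    profile_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    patient_seeds = ss.spawn(config.n_patients)

    profile_rows, all_doses, all_labs, all_sessions, all_events = [], [], [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        profile, extras = _sample_profile(pid, config, profile_rng, start)
        rng = np.random.Generator(np.random.PCG64(patient_seeds[i]))
        doses, labs, sessions, events = _simulate_patient(
            profile, extras, config, rng, cal, cal_offset)
        profile_rows.append([getattr(profile, c) for c in PROFILE_COLUMNS])
        all_doses += doses
        all_labs += labs
        all_sessions += sessions
        all_events += events

    return Cohort(
        profiles=pd.DataFrame(profile_rows, columns=PROFILE_COLUMNS),
        doses=pd.DataFrame(all_doses, columns=DOSE_COLUMNS),
        labs=pd.DataFrame(all_labs, columns=LAB_COLUMNS),
        sessions=pd.DataFrame(all_sessions, columns=SESSION_COLUMNS),
        events=pd.DataFrame(all_events, columns=EVENT_COLUMNS),
        config=config,
    )
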