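"""Seedable synthetic cohort generator.

Emulates the structure of warehouse-extracted hospital data for
vaso-occlusive crisis stays: patients with demographics and comorbidity
history, stays with admission/discharge timestamps and coded flags, and
irregularly sampled longitudinal measurements with known ground-truth mean
trajectories.  Contaminant stays carrying each exclusion trigger are
planted at configurable rates so the downstream selection and estimation
stages can be scored against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PiecewiseLinear",
    "TrajectoryTruth",
    "SamplingIntensity",
    "SimulationConfig",
    "CohortTables",
    "default_truths",
    "sample_measurement_times",
    "generate_cohort",
    "plant_threshold_spikes",
]

EXCLUSION_RULES = (
    "missing_inclusion_code",
    "icu",
    "severity",
    "transfusion",
    "complication",
)

PATIENT_ID_FMT = "P{:05d}"
STAY_ID_FMT = "S{:06d}"


@dataclass(frozen=True)
class PiecewiseLinear:
    """Continuous piecewise-linear function of hours since admission."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values) or len(self.times) < 1:
            raise ValueError("times and values must be equal-length, non-empty")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.times, self.values)


@dataclass(frozen=True)
class TrajectoryTruth:
    """Ground-truth generating model for one measured variable.

    ``mean_function`` maps hours since admission (defined on [0, 240]) to
    the expected value; a sinusoidal day/night term with amplitude
    ``circadian_amplitude`` (24 h period, peak at 18:00 on a per-stay
    random admission clock) and an additive per-stay random intercept with
    standard deviation ``between_stay_sd`` are superposed, plus i.i.d.
    residual noise.
    """

    variable: str
    mean_function: Callable[[np.ndarray], np.ndarray]
    circadian_amplitude: float = 0.0
    between_stay_sd: float = 0.0
    residual_sd: float = 0.0
    unit: str = ""

    def __post_init__(self) -> None:
        if self.circadian_amplitude < 0:
            raise ValueError("circadian_amplitude must be >= 0")
        if self.between_stay_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def default_truths() -> tuple[TrajectoryTruth, ...]:
    """Generating models mirroring the published trend descriptions.

    Hemoglobin drifts 9.5 to 8.5 g/dL over five days; white cells spike
    above 12e9/L then settle near 10; eosinophils double from 0.2 to
    0.4e9/L by day five; CRP climbs to a ~60 mg/L plateau then declines
    slowly; temperature holds near 37 degC with a day/night cycle;
    platelets stay in the low 300s.
    """
    day = 24.0
    return (
        TrajectoryTruth(
            "hemoglobin",
            PiecewiseLinear((0.0, 5 * day, 10 * day), (9.5, 8.5, 8.5)),
            between_stay_sd=1.4,
            residual_sd=0.3,
            unit="g/dL",
        ),
        TrajectoryTruth(
            "wbc",
            PiecewiseLinear((0.0, 6.0, 2 * day, 10 * day), (12.2, 12.8, 10.0, 10.0)),
            between_stay_sd=2.5,
            residual_sd=1.0,
            unit="1e9/L",
        ),
        TrajectoryTruth(
            "neutrophils",
            PiecewiseLinear((0.0, 6.0, 2 * day, 10 * day), (8.8, 9.3, 7.0, 7.0)),
            between_stay_sd=2.0,
            residual_sd=0.8,
            unit="1e9/L",
        ),
        TrajectoryTruth(
            "eosinophils",
            PiecewiseLinear((0.0, 5 * day, 10 * day), (0.2, 0.4, 0.4)),
            between_stay_sd=0.1,
            residual_sd=0.05,
            unit="1e9/L",
        ),
        TrajectoryTruth(
            "crp",
            PiecewiseLinear((0.0, 2 * day, 4 * day, 10 * day), (15.0, 60.0, 60.0, 40.0)),
            between_stay_sd=20.0,
            residual_sd=8.0,
            unit="mg/L",
        ),
        TrajectoryTruth(
            "temperature",
            PiecewiseLinear((0.0, 10 * day), (37.0, 37.0)),
            circadian_amplitude=0.25,
            between_stay_sd=0.2,
            residual_sd=0.15,
            unit="degC",
        ),
        TrajectoryTruth(
            "platelets",
            PiecewiseLinear((0.0, 10 * day), (310.0, 340.0)),
            between_stay_sd=80.0,
            residual_sd=20.0,
            unit="1e9/L",
        ),
    )


@dataclass(frozen=True)
class SamplingIntensity:
    """Expected measurement density, denser early in the stay.

    ``early_per_day`` applies within the first ``early_window_hours``,
    ``late_per_day`` afterwards.  ``at_admission`` forces one measurement
    at t = 0 regardless of the random draws.
    """

    early_per_day: float = 6.0
    late_per_day: float = 2.0
    early_window_hours: float = 48.0
    at_admission: bool = True

    def __post_init__(self) -> None:
        if self.early_per_day < 0 or self.late_per_day < 0:
            raise ValueError("sampling rates must be >= 0")
        if self.early_window_hours <= 0:
            raise ValueError("early_window_hours must be > 0")


def sample_measurement_times(
    duration_hours: float,
    intensity: SamplingIntensity,
    rng: np.random.Generator,
) -> np.ndarray:
    """Strictly increasing measurement times in hours within [0, duration].

    Piecewise-homogeneous Poisson process: one rate over the early window,
    a second (typically lower) rate afterwards.
    """
    if duration_hours <= 0:
        raise ValueError("duration_hours must be > 0")
    early_end = min(duration_hours, intensity.early_window_hours)
    n_early = rng.poisson(intensity.early_per_day / 24.0 * early_end)
    times = [rng.uniform(0.0, early_end, size=n_early)]
    if duration_hours > early_end:
        n_late = rng.poisson(
            intensity.late_per_day / 24.0 * (duration_hours - early_end)
        )
        times.append(rng.uniform(early_end, duration_hours, size=n_late))
    t = np.concatenate(times)
    if intensity.at_admission:
        t = np.append(t, 0.0)
    return np.unique(t)  # sorted, strictly increasing


def _mean_normalized(probs: Sequence[float], support: np.ndarray) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != support.shape or np.any(p < 0) or p.sum() <= 0:
        raise ValueError("invalid probability vector")
    return p / p.sum()


def _default_stays_per_patient_probs() -> tuple[float, ...]:
    # geometric-ish on 1..10, median 2 stays
    return tuple(0.6 ** (k - 1) for k in range(1, 11))


def _default_duration_probs() -> tuple[float, ...]:
    # shifted binomial on 1..10 days with mean 1 + 9p = 4.4
    from math import comb

    p = 3.4 / 9.0
    return tuple(comb(9, k) * p**k * (1 - p) ** (9 - k) for k in range(10))


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 150
    stays_per_patient_probs: tuple[float, ...] = field(
        default_factory=_default_stays_per_patient_probs
    )
    stay_duration_probs: tuple[float, ...] = field(
        default_factory=_default_duration_probs
    )
    intensity: SamplingIntensity = field(default_factory=SamplingIntensity)
    contamination_rates: Mapping[str, float] = field(
        default_factory=lambda: {rule: 0.04 for rule in EXCLUSION_RULES}
    )
    oud_rate: float = 0.03
    complication_codes: tuple[str, ...] = ("A41.9", "I26.0", "J18.9")
    truths: tuple[TrajectoryTruth, ...] = field(default_factory=default_truths)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        rates = dict(self.contamination_rates)
        unknown = set(rates) - set(EXCLUSION_RULES)
        if unknown:
            raise ValueError(f"unknown contamination rules: {sorted(unknown)}")
        if any(not 0 <= r <= 1 for r in rates.values()) or not 0 <= self.oud_rate <= 1:
            raise ValueError("contamination rates must be in [0, 1]")
        if sum(rates.values()) > 1:
            raise ValueError("stay-level contamination rates must sum to <= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class CohortTables:
    patients: pd.DataFrame
    stays: pd.DataFrame
    measurements: pd.DataFrame
    truth_log: pd.DataFrame


_PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "genotype",
    "age_at_first_admission",
    "steady_state_hb",
    "acute_chest_syndrome",
    "avascular_necrosis",
    "retinopathy",
    "leg_ulcer",
    "stroke",
    "dialysis",
    "pulmonary_hypertension",
    "priapism",
]
_STAY_COLUMNS = [
    "stay_id",
    "patient_id",
    "admission",
    "discharge",
    "icu_flag",
    "severity_level",
    "transfusion_flag",
    "icd_codes",
    "drugs",
    "planted_exclusion",
]
_MEASUREMENT_COLUMNS = ["stay_id", "variable", "time_hours", "value", "unit"]
_TRUTH_COLUMNS = [
    "stay_id",
    "variable",
    "stay_intercept",
    "admission_clock_hour",
    "duration_hours",
]

_COMORBIDITY_RATES = {
    "acute_chest_syndrome": 0.68,
    "avascular_necrosis": 0.23,
    "retinopathy": 0.12,
    "leg_ulcer": 0.06,
    "stroke": 0.04,
    "dialysis": 0.012,
    "pulmonary_hypertension": 0.018,
}


def _empty_tables() -> CohortTables:
    return CohortTables(
        patients=pd.DataFrame(columns=_PATIENT_COLUMNS),
        stays=pd.DataFrame(columns=_STAY_COLUMNS),
        measurements=pd.DataFrame(columns=_MEASUREMENT_COLUMNS),
        truth_log=pd.DataFrame(columns=_TRUTH_COLUMNS),
    )


def _draw_patients(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    sex = np.where(rng.random(n) < 0.53, "female", "male")
    genotype = np.where(rng.random(n) < 0.74, "SS", "other")
    records: dict[str, np.ndarray | list] = {
        "patient_id": [PATIENT_ID_FMT.format(i + 1) for i in range(n)],
        "sex": sex,
        "genotype": genotype,
        "age_at_first_admission": np.round(rng.normal(28.0, 8.0, n).clip(18, 70), 1),
        "steady_state_hb": np.round(
            np.where(
                genotype == "SS", rng.normal(8.5, 0.8, n), rng.normal(10.0, 0.8, n)
            ).clip(4, 14),
            1,
        ),
    }
    for flag, rate in _COMORBIDITY_RATES.items():
        records[flag] = rng.random(n) < rate
    records["priapism"] = (sex == "male") & (rng.random(n) < 0.17)
    return pd.DataFrame(records, columns=_PATIENT_COLUMNS)


def _plant_rule(u: float, rates: Mapping[str, float]) -> str:
    cum = 0.0
    for rule in EXCLUSION_RULES:
        cum += rates.get(rule, 0.0)
        if u < cum:
            return rule
    return ""


def generate_cohort(config: SimulationConfig) -> CohortTables:
    """Generate patients, stays, measurements and a ground-truth log.

    Fully deterministic given ``config.seed``.  Every measurement time lies
    within its stay; each contaminant stay carries exactly the flag or code
    its planted exclusion rule tests; the truth log records the per-stay
    random intercept and admission clock hour for every variable, which is
    sufficient to score trajectory recovery.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_patients == 0:
        return _empty_tables()

    patients = _draw_patients(config, rng)
    oud_flags = rng.random(config.n_patients) < config.oud_rate
    rates = dict(config.contamination_rates)

    stay_rows: list[dict] = []
    m_stay: list[str] = []
    m_var: list[str] = []
    m_time: list[np.ndarray] = []
    m_value: list[np.ndarray] = []
    m_unit: list[str] = []
    truth_rows: list[dict] = []
    base = pd.Timestamp("2010-01-04 09:00:00")
    stay_counter = 0
    duration_support = np.arange(1, 11)
    dur_probs = _mean_normalized(config.stay_duration_probs, duration_support.astype(float))
    stays_support = np.arange(1, 11)
    stays_probs = _mean_normalized(
        config.stays_per_patient_probs, stays_support.astype(float)
    )
    sorted_truths = sorted(config.truths, key=lambda tr: tr.variable)

    for i, patient in patients.iterrows():
        n_stays = int(rng.choice(stays_support, p=stays_probs))
        admission = base + pd.Timedelta(days=int(rng.integers(0, 2000)))
        oud_via_drug = bool(rng.random() < 0.5)
        for j in range(n_stays):
            stay_counter += 1
            stay_id = STAY_ID_FMT.format(stay_counter)
            duration_days = int(rng.choice(duration_support, p=dur_probs))
            duration_hours = duration_days * 24.0 + float(rng.uniform(-6.0, 6.0))
            # whole minutes so timestamps survive a seconds-precision round trip
            duration_minutes = max(int(round(duration_hours * 60.0)), 24 * 60)
            duration_hours = duration_minutes / 60.0
            admission = admission + pd.Timedelta(
                days=int(rng.integers(20, 200)), hours=float(rng.uniform(0, 24))
            )
            admission = admission.floor("min")
            discharge = admission + pd.Timedelta(minutes=duration_minutes)

            rule = _plant_rule(float(rng.random()), rates)
            if oud_flags[i] and j == 0:
                rule = "oud"  # patient-level trigger; keep the stay otherwise clean
            icd = [] if rule == "missing_inclusion_code" else ["D57.0"]
            drugs = ["morphine", "acetaminophen"]
            severity = int(rng.integers(1, 3))
            icu = False
            transfusion = False
            if rule == "icu":
                icu = True
            elif rule == "severity":
                severity = int(rng.integers(3, 5))
            elif rule == "transfusion":
                transfusion = True
            elif rule == "complication":
                icd.append(str(rng.choice(list(config.complication_codes))))
            elif rule == "missing_inclusion_code":
                icd.append("M54.5")
            elif rule == "oud":
                if oud_via_drug:
                    drugs.append("methadone")
                else:
                    icd.append("F11.2")

            stay_rows.append(
                {
                    "stay_id": stay_id,
                    "patient_id": patient["patient_id"],
                    "admission": admission,
                    "discharge": discharge,
                    "icu_flag": icu,
                    "severity_level": severity,
                    "transfusion_flag": transfusion,
                    "icd_codes": ";".join(icd),
                    "drugs": ";".join(drugs),
                    "planted_exclusion": rule,
                }
            )

            clock_hour = float(rng.uniform(0.0, 24.0))
            for truth in sorted_truths:
                t = sample_measurement_times(duration_hours, config.intensity, rng)
                intercept = (
                    float(rng.normal(0.0, truth.between_stay_sd))
                    if truth.between_stay_sd > 0
                    else 0.0
                )
                values = np.asarray(truth.mean_function(t), dtype=float) + intercept
                if truth.circadian_amplitude > 0:
                    phase = 2 * np.pi * ((clock_hour + t) - 18.0) / 24.0
                    values = values + truth.circadian_amplitude * np.cos(phase)
                if truth.residual_sd > 0:
                    values = values + rng.normal(0.0, truth.residual_sd, size=t.size)
                m_stay.extend([stay_id] * t.size)
                m_var.extend([truth.variable] * t.size)
                m_time.append(t)
                m_value.append(np.asarray(values, dtype=float))
                m_unit.extend([truth.unit] * t.size)
                truth_rows.append(
                    {
                        "stay_id": stay_id,
                        "variable": truth.variable,
                        "stay_intercept": intercept,
                        "admission_clock_hour": clock_hour,
                        "duration_hours": duration_hours,
                    }
                )

    stays = pd.DataFrame(stay_rows, columns=_STAY_COLUMNS)
    if m_stay:
        measurements = pd.DataFrame(
            {
                "stay_id": m_stay,
                "variable": m_var,
                "time_hours": np.concatenate(m_time),
                "value": np.concatenate(m_value),
                "unit": m_unit,
            },
            columns=_MEASUREMENT_COLUMNS,
        )
    else:
        measurements = pd.DataFrame(columns=_MEASUREMENT_COLUMNS)
    truth_log = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return CohortTables(patients, stays, measurements, truth_log)


def plant_threshold_spikes(
    measurements: pd.DataFrame,
    stays: pd.DataFrame,
    variable: str,
    rate: float,
    spike_value: float,
    window: tuple[float, float] = (0.0, 24.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Add one extreme measurement to a random fraction of stays.

    Each stay independently receives, with probability ``rate``, an extra
    point of value ``spike_value`` at a uniform time inside ``window``.
    Returns the augmented measurement table and the boolean planted mask
    aligned with ``stays``, for calibration scoring.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    stay_ids = stays["stay_id"].to_numpy()
    planted = rng.random(len(stay_ids)) < rate
    t = rng.uniform(window[0], window[1], size=int(planted.sum()))
    extra = pd.DataFrame(
        {
            "stay_id": stay_ids[planted],
            "variable": variable,
            "time_hours": t,
            "value": spike_value,
            "unit": "",
        },
        columns=_MEASUREMENT_COLUMNS,
    )
    combined = pd.concat([measurements, extra], ignore_index=True)
    return combined, planted
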