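"""YAML configuration loading for the simulator and the full run."""

from __future__ import annotations

from pathlib import Path

import yaml

from .cohort import FilterConfig
from .synthetic import (
    PiecewiseLinear,
    SamplingIntensity,
    SimulationConfig,
    TrajectoryTruth,
    default_truths,
)
from .trajectory import TrajectoryConfig

__all__ = ["load_simulation_config", "load_filter_config", "load_trajectory_config"]


def _truth_from_dict(d: dict) -> TrajectoryTruth:
    pts = d["points"]
    return TrajectoryTruth(
        variable=d["variable"],
        mean_function=PiecewiseLinear(
            tuple(float(p[0]) for p in pts), tuple(float(p[1]) for p in pts)
        ),
        circadian_amplitude=float(d.get("circadian_amplitude", 0.0)),
        between_stay_sd=float(d.get("between_stay_sd", 0.0)),
        residual_sd=float(d.get("residual_sd", 0.0)),
        unit=str(d.get("unit", "")),
    )


def load_simulation_config(path: str | Path | None) -> SimulationConfig:
    if path is None:
        return SimulationConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("n_patients", "seed", "oud_rate"):
        if key in raw:
            kwargs[key] = raw[key]
    if "stays_per_patient_probs" in raw:
        kwargs["stays_per_patient_probs"] = tuple(raw["stays_per_patient_probs"])
    if "stay_duration_probs" in raw:
        kwargs["stay_duration_probs"] = tuple(raw["stay_duration_probs"])
    if "contamination_rates" in raw:
        kwargs["contamination_rates"] = dict(raw["contamination_rates"])
    if "complication_codes" in raw:
        kwargs["complication_codes"] = tuple(raw["complication_codes"])
    if "intensity" in raw:
        kwargs["intensity"] = SamplingIntensity(**raw["intensity"])
    kwargs["truths"] = (
        tuple(_truth_from_dict(t) for t in raw["truths"])
        if "truths" in raw
        else default_truths()
    )
    return SimulationConfig(**kwargs)


def load_filter_config(path: str | Path | None) -> FilterConfig:
    if path is None:
        return FilterConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw = raw.get("filters", raw)
    kwargs = {}
    for key in ("inclusion_code", "oud_code_prefix", "duration_percentile"):
        if key in raw:
            kwargs[key] = raw[key]
    if "oud_drugs" in raw:
        kwargs["oud_drugs"] = frozenset(raw["oud_drugs"])
    if "complication_codes" in raw:
        kwargs["complication_codes"] = frozenset(raw["complication_codes"])
    return FilterConfig(**kwargs)


def load_trajectory_config(path: str | Path | None) -> TrajectoryConfig:
    if path is None:
        return TrajectoryConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw = raw.get("trajectories", raw)
    allowed = {
        "grid_step",
        "max_time",
        "spline_degree",
        "knot_spacing",
        "penalty_order",
        "n_bootstrap",
        "ci_level",
        "min_support",
        "cv_folds",
        "seed",
    }
    kwargs = {k: raw[k] for k in allowed if k in raw}
    if "smoothing_search" in raw:
        kwargs["smoothing_search"] = tuple(float(x) for x in raw["smoothing_search"])
    return TrajectoryConfig(**kwargs)
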