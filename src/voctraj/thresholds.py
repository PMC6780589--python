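"""Above/under-threshold proportion analysis over windows of the stay."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta

from .cohort import stay_duration_days

__all__ = [
    "ThresholdQuery",
    "ThresholdResult",
    "NoDataError",
    "proportion_crossing",
    "standard_queries",
]

DEFAULT_CRP_NORMAL_LIMIT = 5.0  # mg/L, laboratory upper reference limit


class NoDataError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdQuery:
    """One threshold question over a time window of the stay.

    ``window`` is half-open [t_start, t_end) in hours since admission;
    ``t_end = None`` means the end of each stay.  ``direction``
    ``"at_or_above"`` tests value >= threshold (thresholds are reached
    inclusively), ``"below"`` tests value < threshold.  ``aggregation``
    decides whether any (``ever_in_window``) or every
    (``always_in_window``) in-window measurement must satisfy the test.
    """

    name: str
    variable: str
    threshold: float
    direction: str = "at_or_above"
    window: tuple[float, float | None] = (0.0, None)
    aggregation: str = "ever_in_window"

    def __post_init__(self) -> None:
        if self.direction not in ("at_or_above", "below"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.aggregation not in ("ever_in_window", "always_in_window"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        t0, t1 = self.window
        if t1 is not None and not t0 < t1:
            raise ValueError("window must satisfy t_start < t_end")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass(frozen=True)
class ThresholdResult:
    query: ThresholdQuery
    numerator: int
    denominator: int
    n_excluded: int
    ci_low: float
    ci_high: float

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator

    def to_dict(self) -> dict:
        return {
            "name": self.query.name,
            "variable": self.query.variable,
            "threshold": self.query.threshold,
            "direction": self.query.direction,
            "window_start_hours": self.query.window[0],
            "window_end_hours": self.query.window[1],
            "aggregation": self.query.aggregation,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "n_excluded": self.n_excluded,
            "proportion": self.proportion,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def proportion_crossing(
    measurements: pd.DataFrame,
    stays: pd.DataFrame,
    query: ThresholdQuery,
) -> ThresholdResult:
    """Fraction of stays whose in-window measurements satisfy the query.

    Stays with no measurement inside the window are excluded from the
    denominator and counted in ``n_excluded``; an empty denominator raises
    :class:`NoDataError`.
    """
    durations_h = pd.Series(
        stay_duration_days(stays).to_numpy() * 24.0,
        index=stays["stay_id"].to_numpy(),
    )
    sub = measurements.loc[
        (measurements["variable"] == query.variable)
        & measurements["stay_id"].isin(durations_h.index)
    ]
    t0, t1 = query.window
    numerator = 0
    denominator = 0
    by_stay = dict(tuple(sub.groupby("stay_id"))) if not sub.empty else {}
    for stay_id in durations_h.index:
        grp = by_stay.get(stay_id)
        end = durations_h[stay_id] if t1 is None else t1
        if grp is None:
            continue
        t = grp["time_hours"].astype(float).to_numpy()
        # closed at the stay end: "throughout the stay" includes discharge
        in_window = (t >= t0) & ((t <= end) if t1 is None else (t < end))
        if not in_window.any():
            continue
        v = grp["value"].astype(float).to_numpy()[in_window]
        hits = v >= query.threshold if query.direction == "at_or_above" else v < query.threshold
        ok = bool(hits.any()) if query.aggregation == "ever_in_window" else bool(hits.all())
        denominator += 1
        numerator += int(ok)
    n_excluded = len(durations_h) - denominator
    if denominator == 0:
        raise NoDataError(
            f"no stay has a {query.variable!r} measurement in window "
            f"[{t0}, {t1 if t1 is not None else 'stay end'})"
        )
    low, high = _clopper_pearson(numerator, denominator)
    return ThresholdResult(query, numerator, denominator, n_excluded, low, high)


def standard_queries(
    crp_normal_limit: float = DEFAULT_CRP_NORMAL_LIMIT,
) -> tuple[ThresholdQuery, ThresholdQuery, ThresholdQuery]:
    """The three preconfigured clinical threshold questions.

    CRP reaching 100 mg/L within the first day, CRP still normal from 48 h
    on, and temperature ever reaching 38 degC at any point of the stay.
    """
    return (
        ThresholdQuery(
            name="crp_ge_100_first_day",
            variable="crp",
            threshold=100.0,
            direction="at_or_above",
            window=(0.0, 24.0),
            aggregation="ever_in_window",
        ),
        ThresholdQuery(
            name="crp_normal_after_48h",
            variable="crp",
            threshold=crp_normal_limit,
            direction="below",
            window=(48.0, None),
            aggregation="ever_in_window",
        ),
        ThresholdQuery(
            name="temperature_ge_38_whole_stay",
            variable="temperature",
            threshold=38.0,
            direction="at_or_above",
            window=(0.0, None),
            aggregation="ever_in_window",
        ),
    )
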