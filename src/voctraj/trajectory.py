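"""Averaged-trajectory estimation for irregularly sampled stay data.

The estimator pools all measurements of one variable across stays on a
time-since-admission axis, fits a penalized B-spline (P-spline: B-spline
basis with a difference penalty on the coefficients) whose smoothing
weight is chosen by cross-validation over stays, and quantifies
uncertainty with a cluster bootstrap that resamples whole stays.  The
evaluation grid is truncated wherever too few stays still contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import LinAlgError, solve

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryConfig",
    "TrajectoryEstimate",
    "InsufficientDataError",
    "align_measurements",
    "fit_mean_trajectory",
    "bootstrap_band",
    "estimate_trajectory",
]


class InsufficientDataError(ValueError):
    pass


def _default_smoothing_search() -> tuple[float, ...]:
    return tuple(np.logspace(-2.0, 4.0, 13))


@dataclass(frozen=True)
class TrajectoryConfig:
    grid_step: float = 6.0
    max_time: float = 240.0
    spline_degree: int = 3
    knot_spacing: float = 12.0
    penalty_order: int = 2
    smoothing_search: tuple[float, ...] = field(default_factory=_default_smoothing_search)
    n_bootstrap: int = 500
    ci_level: float = 0.95
    min_support: int = 10
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_bootstrap < 100:
            raise ValueError("n_bootstrap must be >= 100")
        if self.grid_step <= 0 or self.max_time <= 0 or self.knot_spacing <= 0:
            raise ValueError("grid_step, max_time and knot_spacing must be > 0")
        if self.spline_degree < 1 or self.penalty_order < 1:
            raise ValueError("spline_degree and penalty_order must be >= 1")
        if not self.smoothing_search:
            raise ValueError("smoothing_search must be non-empty")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(0.0, self.max_time + 1e-9, self.grid_step)


@dataclass
class TrajectoryEstimate:
    variable: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    support: np.ndarray
    n_stays: int
    n_points: int
    smoothing: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hours": self.grid,
                "time_days": self.grid / 24.0,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
                "support": self.support,
            }
        )


def align_measurements(
    measurements: pd.DataFrame,
    stays: pd.DataFrame,
    variable: str,
    max_time: float = 240.0,
) -> pd.DataFrame:
    """Pool one variable's measurements on the hours-since-admission axis.

    Accepts either a ``time_hours`` offset column or an absolute
    ``timestamp`` column (joined against stay admissions).  Points beyond
    ``max_time`` are dropped with a logged count; an absent variable yields
    an empty result with a warning rather than an error.
    """
    sub = measurements.loc[measurements["variable"] == variable]
    if sub.empty:
        logger.warning("variable %r has no measurements", variable)
        return pd.DataFrame(columns=["stay_id", "t", "value"])
    if "time_hours" in sub.columns and sub["time_hours"].notna().all():
        t = sub["time_hours"].astype(float).to_numpy()
        stay_ids = sub["stay_id"].to_numpy()
        values = sub["value"].astype(float).to_numpy()
    else:
        adm = pd.to_datetime(stays.set_index("stay_id")["admission"])
        merged = sub.join(adm.rename("admission"), on="stay_id")
        t = (
            (pd.to_datetime(merged["timestamp"]) - merged["admission"])
            .dt.total_seconds()
            .to_numpy()
            / 3600.0
        )
        stay_ids = merged["stay_id"].to_numpy()
        values = merged["value"].astype(float).to_numpy()
    keep = t <= max_time
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d %s points beyond %.0f h", n_dropped, variable, max_time
        )
    out = pd.DataFrame({"stay_id": stay_ids[keep], "t": t[keep], "value": values[keep]})
    return out.sort_values(["stay_id", "t", "value"], kind="mergesort").reset_index(
        drop=True
    )


def _knot_vector(cfg: TrajectoryConfig) -> np.ndarray:
    k = cfg.spline_degree
    interior = np.arange(cfg.knot_spacing, cfg.max_time, cfg.knot_spacing)
    return np.concatenate(
        [np.zeros(k + 1), interior, np.full(k + 1, cfg.max_time)]
    )


def _design(t: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    x = np.clip(t, knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def _penalty_matrix(n_coef: int, order: int) -> np.ndarray:
    d = np.diff(np.eye(n_coef), n=order, axis=0)
    return d.T @ d


def _solve_pspline(
    gram: np.ndarray, moment: np.ndarray, lam: float, penalty: np.ndarray
) -> np.ndarray:
    lhs = gram + lam * penalty
    try:
        return solve(lhs, moment, assume_a="pos")
    except LinAlgError:
        return np.linalg.lstsq(lhs, moment, rcond=None)[0]


def _stay_blocks(
    pooled: pd.DataFrame, knots: np.ndarray, degree: int
) -> tuple[list[str], list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Per-stay Gram blocks so that resampled fits are cheap sums."""
    ids, grams, moments, designs = [], [], [], []
    for stay_id, grp in pooled.groupby("stay_id", sort=True):
        b = _design(grp["t"].to_numpy(), knots, degree)
        y = grp["value"].to_numpy()
        ids.append(stay_id)
        designs.append((b, y))
        grams.append(b.T @ b)
        moments.append(b.T @ y)
    return ids, grams, moments, designs


def _cross_validate(
    pooled: pd.DataFrame,
    knots: np.ndarray,
    cfg: TrajectoryConfig,
    penalty: np.ndarray,
) -> float:
    lams = np.asarray(cfg.smoothing_search, dtype=float)
    if lams.size == 1:
        return float(lams[0])
    ids, grams, moments, designs = _stay_blocks(pooled, knots, cfg.spline_degree)
    n_stays = len(ids)
    k_folds = min(cfg.cv_folds, n_stays)
    rng = np.random.default_rng(cfg.seed)
    fold_of = np.repeat(np.arange(k_folds), int(np.ceil(n_stays / k_folds)))[:n_stays]
    rng.shuffle(fold_of)
    gram_total = np.sum(grams, axis=0)
    moment_total = np.sum(moments, axis=0)
    sse = np.zeros(lams.size)
    for fold in range(k_folds):
        in_fold = [i for i in range(n_stays) if fold_of[i] == fold]
        if not in_fold or len(in_fold) == n_stays:
            continue
        gram_tr = gram_total - np.sum([grams[i] for i in in_fold], axis=0)
        moment_tr = moment_total - np.sum([moments[i] for i in in_fold], axis=0)
        b_te = np.vstack([designs[i][0] for i in in_fold])
        y_te = np.concatenate([designs[i][1] for i in in_fold])
        for j, lam in enumerate(lams):
            beta = _solve_pspline(gram_tr, moment_tr, lam, penalty)
            resid = y_te - b_te @ beta
            sse[j] += float(resid @ resid)
    return float(lams[int(np.argmin(sse))])


def fit_mean_trajectory(
    pooled: pd.DataFrame,
    cfg: TrajectoryConfig,
    smoothing: float | None = None,
    variable: str = "",
) -> tuple[BSpline, float]:
    """Fit the penalized-spline mean curve to pooled (stay, t, value) points.

    Returns the fitted spline (callable on [0, max_time]) and the smoothing
    weight used.  When ``smoothing`` is None it is selected by K-fold
    cross-validation over stays.
    """
    knots = _knot_vector(cfg)
    n_coef = len(knots) - cfg.spline_degree - 1
    n_points = len(pooled)
    min_required = max(10, n_coef)
    if n_points < min_required:
        raise InsufficientDataError(
            f"variable {variable or '<unnamed>'!r}: {n_points} points "
            f"< required {min_required}"
        )
    penalty = _penalty_matrix(n_coef, cfg.penalty_order)
    if smoothing is None:
        smoothing = _cross_validate(pooled, knots, cfg, penalty)
    t = pooled["t"].to_numpy(dtype=float)
    y = pooled["value"].to_numpy(dtype=float)
    if smoothing == 0.0:
        # unpenalized: plain least squares on the basis
        b = _design(t, knots, cfg.spline_degree)
        beta = np.linalg.lstsq(b, y, rcond=None)[0]
    else:
        b = _design(t, knots, cfg.spline_degree)
        beta = _solve_pspline(b.T @ b, b.T @ y, smoothing, penalty)
    return BSpline(knots, beta, cfg.spline_degree, extrapolate=False), float(smoothing)


def bootstrap_band(
    pooled: pd.DataFrame,
    cfg: TrajectoryConfig,
    grid: np.ndarray,
    smoothing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise percentile band from a cluster bootstrap over stays.

    Whole stays are resampled with replacement ``n_bootstrap`` times and
    the curve refit each time with the smoothing weight held fixed;
    the band is the pointwise empirical (1-ci)/2 and 1-(1-ci)/2 quantiles.
    """
    knots = _knot_vector(cfg)
    n_coef = len(knots) - cfg.spline_degree - 1
    penalty = _penalty_matrix(n_coef, cfg.penalty_order)
    ids, grams, moments, _ = _stay_blocks(pooled, knots, cfg.spline_degree)
    n_stays = len(ids)
    if n_stays < 2:
        raise InsufficientDataError(
            "cluster bootstrap requires at least 2 distinct stays"
        )
    grams_arr = np.stack(grams)
    moments_arr = np.stack(moments)
    basis_grid = _design(np.asarray(grid, dtype=float), knots, cfg.spline_degree)
    rng = np.random.default_rng(cfg.seed)
    curves = np.empty((cfg.n_bootstrap, len(grid)))
    for b in range(cfg.n_bootstrap):
        counts = np.bincount(
            rng.integers(0, n_stays, size=n_stays), minlength=n_stays
        ).astype(float)
        gram = np.tensordot(counts, grams_arr, axes=1)
        moment = counts @ moments_arr
        beta = _solve_pspline(gram, moment, smoothing, penalty)
        curves[b] = basis_grid @ beta
    alpha = 1.0 - cfg.ci_level
    lower = np.quantile(curves, alpha / 2, axis=0)
    upper = np.quantile(curves, 1 - alpha / 2, axis=0)
    return lower, upper


def _support_counts(pooled: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
    """Stays whose observed span [first, last measurement] covers each grid time."""
    spans = pooled.groupby("stay_id")["t"].agg(["min", "max"])
    lo = spans["min"].to_numpy()[:, None]
    hi = spans["max"].to_numpy()[:, None]
    g = np.asarray(grid)[None, :]
    return ((lo <= g) & (g <= hi)).sum(axis=0).astype(int)


def estimate_trajectory(
    measurements: pd.DataFrame,
    stays: pd.DataFrame,
    variable: str,
    cfg: TrajectoryConfig | None = None,
) -> TrajectoryEstimate:
    """Full estimate: align, fit, bootstrap band, support truncation."""
    cfg = cfg or TrajectoryConfig()
    pooled = align_measurements(measurements, stays, variable, cfg.max_time)
    if pooled.empty:
        raise InsufficientDataError(f"variable {variable!r} has no measurements")

    full_grid = cfg.grid
    support = _support_counts(pooled, full_grid)
    ok = support >= cfg.min_support
    if not ok.any():
        raise InsufficientDataError(
            f"variable {variable!r}: no grid point reaches min_support="
            f"{cfg.min_support}"
        )
    i0 = int(np.argmax(ok))
    i1 = i0
    while i1 + 1 < len(full_grid) and ok[i1 + 1]:
        i1 += 1
    grid = full_grid[i0 : i1 + 1]
    support = support[i0 : i1 + 1]

    curve, smoothing = fit_mean_trajectory(pooled, cfg, variable=variable)
    mean = np.asarray(curve(grid), dtype=float)
    lower, upper = bootstrap_band(pooled, cfg, grid, smoothing)
    # percentile bands can cross the point estimate on sparse tails; enforce order
    lower = np.minimum(lower, mean)
    upper = np.maximum(upper, mean)
    return TrajectoryEstimate(
        variable=variable,
        grid=grid,
        mean=mean,
        lower=lower,
        upper=upper,
        support=support,
        n_stays=int(pooled["stay_id"].nunique()),
        n_points=int(len(pooled)),
        smoothing=smoothing,
    )
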