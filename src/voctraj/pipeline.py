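"""End-to-end orchestration: simulate or load, select, estimate, report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import io as vio
from .cohort import FilterConfig, select_cohort
from .stats import build_table_one, table_one_frame
from .synthetic import SimulationConfig, generate_cohort
from .thresholds import NoDataError, proportion_crossing, standard_queries
from .trajectory import InsufficientDataError, TrajectoryConfig, estimate_trajectory

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_full_analysis", "plot_trajectory"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: Path
    patients_csv: Path | None = None
    stays_csv: Path | None = None
    measurements_csv: Path | None = None
    simulate: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    trajectories: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    variables: tuple[str, ...] | None = None  # None = all present
    crp_normal_limit: float = 5.0
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not self.simulate and not (
            self.patients_csv and self.stays_csv and self.measurements_csv
        ):
            raise ValueError("either set simulate=True or provide the three CSV paths")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def plot_trajectory(estimate, out_path: Path) -> None:
    """Mean curve with shaded band, time in days, support on a twin axis."""
    fig, ax = plt.subplots(figsize=(7, 4))
    days = estimate.grid / 24.0
    ax.plot(days, estimate.mean, color="C0", lw=2, label="mean")
    ax.fill_between(
        days, estimate.lower, estimate.upper, color="C0", alpha=0.25, label="95% band"
    )
    ax.set_xlabel("Time since admission (days)")
    ax.set_ylabel(estimate.variable)
    ax2 = ax.twinx()
    ax2.plot(days, estimate.support, color="grey", ls=":", lw=1)
    ax2.set_ylabel("stays contributing", color="grey")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write all artifacts plus a checksum manifest.

    Returns the manifest dictionary.  Deterministic for a fixed seed.
    Variables without enough data are skipped with a logged reason; an
    empty selected cohort skips the downstream stages and reports why.
    """
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {"seed": cfg.seed, "status": "ok", "skipped": [], "outputs": {}}

    # --- load or simulate -------------------------------------------------
    try:
        if cfg.simulate:
            sim = cfg.simulation.with_seed(cfg.seed)
            tables = generate_cohort(sim)
            patients, stays, measurements = (
                tables.patients,
                tables.stays,
                tables.measurements,
            )
            vio.write_patients(patients, out / "patients.csv")
            vio.write_stays(stays, out / "stays.csv")
            vio.write_measurements(measurements, out / "measurements.csv")
            written += [out / "patients.csv", out / "stays.csv", out / "measurements.csv"]
        else:
            patients = vio.read_patients(cfg.patients_csv)
            stays = vio.read_stays(cfg.stays_csv)
            measurements = vio.read_measurements(cfg.measurements_csv)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineError("input", str(exc)) from exc

    # --- cohort selection -------------------------------------------------
    try:
        included, report = select_cohort(stays, patients, cfg.filters)
    except Exception as exc:
        raise PipelineError("cohort_selection", str(exc)) from exc
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out / "filter_report.txt").write_text(report.to_text() + "\n")
    vio.write_stays(included, out / "included_stays.csv")
    written += [
        out / "filter_report.json",
        out / "filter_report.txt",
        out / "included_stays.csv",
    ]

    if included.empty:
        manifest["status"] = "empty_cohort"
        manifest["skipped"].append(
            {"stage": "all_downstream", "reason": "no stay survived the exclusion cascade"}
        )
        logger.warning("empty cohort after selection: downstream stages skipped")
    else:
        kept_meas = measurements.loc[
            measurements["stay_id"].isin(included["stay_id"])
        ].reset_index(drop=True)

        # --- trajectories -------------------------------------------------
        variables = (
            list(cfg.variables)
            if cfg.variables
            else sorted(kept_meas["variable"].unique())
        )
        traj_cfg = cfg.trajectories
        if traj_cfg.seed != cfg.seed:
            from dataclasses import replace

            traj_cfg = replace(traj_cfg, seed=cfg.seed)
        for var in variables:
            try:
                est = estimate_trajectory(kept_meas, included, var, traj_cfg)
            except InsufficientDataError as exc:
                manifest["skipped"].append({"stage": f"trajectory:{var}", "reason": str(exc)})
                logger.info("skipping %s: %s", var, exc)
                continue
            csv_path = out / f"trajectory_{var}.csv"
            est.to_frame().to_csv(csv_path, index=False)
            written.append(csv_path)
            if cfg.make_figures:
                fig_path = out / f"trajectory_{var}.png"
                plot_trajectory(est, fig_path)
                written.append(fig_path)

        # --- thresholds ---------------------------------------------------
        results = []
        for query in standard_queries(cfg.crp_normal_limit):
            try:
                results.append(proportion_crossing(kept_meas, included, query).to_dict())
            except NoDataError as exc:
                manifest["skipped"].append(
                    {"stage": f"threshold:{query.name}", "reason": str(exc)}
                )
        if results:
            pd.DataFrame(results).to_csv(out / "threshold_results.csv", index=False)
            (out / "threshold_results.json").write_text(json.dumps(results, indent=2))
            written += [out / "threshold_results.csv", out / "threshold_results.json"]

        # --- table one ----------------------------------------------------
        first_stay_patients = patients.loc[
            patients["patient_id"].isin(included["patient_id"])
        ].reset_index(drop=True)
        rows = build_table_one(first_stay_patients)
        table_one_frame(rows).to_csv(out / "table_one.csv", index=False)
        written.append(out / "table_one.csv")

    for path in written:
        manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
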