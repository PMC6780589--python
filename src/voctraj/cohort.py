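"""Cohort selection: ordered inclusion/exclusion filters with a flowchart report.

The filters are applied in a fixed order — inclusion by diagnosis code,
patient-level opioid-use-disorder exclusion, then the stay-level
complicated-stay exclusions (ICU, coded severity 3-4, transfusion,
complication diagnosis), and finally the duration-percentile rule computed
on the stays that survive everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "FilterStep",
    "FilterReport",
    "IntegrityError",
    "select_cohort",
    "duration_filter",
    "stay_duration_days",
]


class IntegrityError(ValueError):
    """Referential-integrity violation between stays and patients."""


@dataclass(frozen=True)
class FilterConfig:
    inclusion_code: str = "D57.0"
    oud_code_prefix: str = "F11"
    oud_drugs: frozenset[str] = frozenset({"methadone", "buprenorphine"})
    complication_codes: frozenset[str] = frozenset({"A41.9", "I26.0", "J18.9"})
    duration_percentile: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.duration_percentile < 1:
            raise ValueError("duration_percentile must be in (0, 1)")


@dataclass(frozen=True)
class FilterStep:
    name: str
    stays_removed: int
    stays_remaining: int


@dataclass
class FilterReport:
    n_input: int
    steps: list[FilterStep] = field(default_factory=list)
    duration_cutoff_days: float | None = None

    @property
    def n_output(self) -> int:
        return self.steps[-1].stays_remaining if self.steps else self.n_input

    def add(self, name: str, removed: int, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1].stays_remaining:
            raise ValueError("remaining counts must be non-increasing")
        self.steps.append(FilterStep(name, removed, remaining))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "duration_cutoff_days": self.duration_cutoff_days,
            "steps": [
                {
                    "name": s.name,
                    "stays_removed": s.stays_removed,
                    "stays_remaining": s.stays_remaining,
                }
                for s in self.steps
            ],
        }

    def to_text(self) -> str:
        lines = [f"Input stays: {self.n_input}"]
        for s in self.steps:
            lines.append(
                f"  - {s.name}: removed {s.stays_removed}, remaining {s.stays_remaining}"
            )
        if self.duration_cutoff_days is not None:
            lines.append(f"Duration cutoff: {self.duration_cutoff_days:.2f} days")
        lines.append(f"Included stays: {self.n_output}")
        return "\n".join(lines)


def _split_codes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return [c.strip() for c in str(cell).split(";") if c.strip()]


def stay_duration_days(stays: pd.DataFrame) -> pd.Series:
    """Fractional-day stay durations from the admission/discharge timestamps."""
    adm = pd.to_datetime(stays["admission"])
    dis = pd.to_datetime(stays["discharge"])
    return (dis - adm).dt.total_seconds() / 86400.0


def duration_filter(
    stays: pd.DataFrame, percentile: float = 0.90
) -> tuple[pd.DataFrame, float]:
    """Drop stays strictly longer than the given duration percentile.

    The cutoff is the linearly interpolated percentile of the input stays'
    fractional-day durations; only stays with duration strictly greater
    than the cutoff are removed, so ties at the cutoff are kept.
    """
    if len(stays) == 0:
        raise ValueError("duration_filter requires a non-empty stay set")
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0, 1)")
    durations = stay_duration_days(stays)
    cutoff = float(np.percentile(durations.to_numpy(), 100 * percentile))
    kept = stays.loc[durations.to_numpy() <= cutoff]
    return kept, cutoff


def _oud_patient_ids(stays: pd.DataFrame, cfg: FilterConfig) -> set[str]:
    drugs_lower = frozenset(d.lower() for d in cfg.oud_drugs)
    flagged: set[str] = set()
    for _, row in stays.iterrows():
        codes = _split_codes(row["icd_codes"])
        drugs = {d.lower() for d in _split_codes(row["drugs"])}
        if any(c.startswith(cfg.oud_code_prefix) for c in codes) or (
            drugs & drugs_lower
        ):
            flagged.add(row["patient_id"])
    return flagged


def select_cohort(
    stays: pd.DataFrame,
    patients: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the full ordered exclusion cascade and report per-step counts.

    Opioid-use disorder is detected over *all* stays of a patient (the
    trigger code or drug may sit on a stay that itself fails inclusion) and
    removes every stay of that patient.  The duration percentile is
    computed on the survivors of all previous steps.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(stays))
    if len(stays):
        unknown = set(stays["patient_id"]) - set(patients["patient_id"])
        if unknown:
            raise IntegrityError(
                f"stays reference unknown patient_ids: {sorted(unknown)[:5]}"
            )

    current = stays

    def _step(name: str, keep_mask: np.ndarray) -> None:
        nonlocal current
        kept = current.loc[keep_mask]
        report.add(name, int(len(current) - len(kept)), int(len(kept)))
        current = kept

    if len(current) == 0:
        for name in (
            "inclusion_code",
            "opioid_use_disorder",
            "icu",
            "severity_3_4",
            "transfusion",
            "complication_code",
            "duration_percentile",
        ):
            report.add(name, 0, 0)
        return current, report

    codes = current["icd_codes"].map(_split_codes)
    _step(
        "inclusion_code",
        codes.map(lambda cs: cfg.inclusion_code in cs).to_numpy(),
    )

    oud_patients = _oud_patient_ids(stays, cfg)
    _step(
        "opioid_use_disorder",
        ~current["patient_id"].isin(oud_patients).to_numpy(),
    )

    _step("icu", ~current["icu_flag"].astype(bool).to_numpy())
    _step("severity_3_4", (current["severity_level"].astype(int) < 3).to_numpy())
    _step("transfusion", ~current["transfusion_flag"].astype(bool).to_numpy())

    comp = frozenset(cfg.complication_codes)
    _step(
        "complication_code",
        current["icd_codes"]
        .map(lambda cell: not (set(_split_codes(cell)) & comp))
        .to_numpy(),
    )

    if len(current):
        kept, cutoff = duration_filter(current, cfg.duration_percentile)
        report.duration_cutoff_days = cutoff
        report.add(
            "duration_percentile", int(len(current) - len(kept)), int(len(kept))
        )
        current = kept
    else:
        report.add("duration_percentile", 0, 0)

    return current.reset_index(drop=True), report
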