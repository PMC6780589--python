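from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

STAY_COLUMNS = [
    "stay_id",
    "patient_id",
    "admission",
    "discharge",
    "icu_flag",
    "severity_level",
    "transfusion_flag",
    "icd_codes",
    "drugs",
]


def make_stay(
    stay_id,
    patient_id,
    duration_days=3.0,
    admission="2012-03-01 10:00:00",
    icu=False,
    severity=1,
    transfusion=False,
    icd="D57.0",
    drugs="morphine",
):
    adm = pd.Timestamp(admission)
    return {
        "stay_id": stay_id,
        "patient_id": patient_id,
        "admission": adm,
        "discharge": adm + pd.Timedelta(days=duration_days),
        "icu_flag": icu,
        "severity_level": severity,
        "transfusion_flag": transfusion,
        "icd_codes": icd,
        "drugs": drugs,
    }


def stays_frame(rows):
    return pd.DataFrame(rows, columns=STAY_COLUMNS)


def patients_frame(patient_ids, **overrides):
    n = len(patient_ids)
    base = {
        "patient_id": list(patient_ids),
        "sex": ["female"] * n,
        "genotype": ["SS"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def selection_fixture():
    """Eight stays: one violating each pre-percentile rule, two clean."""
    rows = [
        make_stay("s_no_code", "p1", icd="M54.5"),
        make_stay("s_oud", "p2", icd="D57.0;F11.2"),
        make_stay("s_icu", "p3", icu=True),
        make_stay("s_sev", "p4", severity=3),
        make_stay("s_transf", "p5", transfusion=True),
        make_stay("s_compl", "p6", icd="D57.0;A41.9"),
        make_stay("s_clean1", "p7"),
        make_stay("s_clean2", "p8"),
    ]
    stays = stays_frame(rows)
    patients = patients_frame([f"p{i}" for i in range(1, 9)])
    return stays, patients


def _set_first_true(n: int, k: int) -> list[bool]:
    return [i < k for i in range(n)]


@pytest.fixture(scope="session")
def table1_patients():
    """164 patients replicating the published baseline-table marginals.

    Per genotype group: sex split, comorbidity counts and male-only
    priapism counts all match the printed per-group numerators, so every
    2x2 built from this frame equals the printed one.
    """
    groups = []
    specs = {
        # genotype: (n, n_female, flag counts, priapism among males)
        "SS": (121, 63, 13),
        "other": (43, 24, 0),
    }
    flag_counts = {
        "acute_chest_syndrome": {"SS": 93, "other": 18},
        "avascular_necrosis": {"SS": 23, "other": 14},
        "retinopathy": {"SS": 12, "other": 7},
        "leg_ulcer": {"SS": 9, "other": 1},
        "stroke": {"SS": 3, "other": 3},
        "dialysis": {"SS": 1, "other": 1},
        "pulmonary_hypertension": {"SS": 2, "other": 1},
    }
    rng = np.random.default_rng(42)
    pid = 0
    for geno, (n, n_female, n_priapism) in specs.items():
        df = pd.DataFrame(
            {
                "patient_id": [f"t1_{pid + i:03d}" for i in range(n)],
                "genotype": geno,
                "sex": ["female"] * n_female + ["male"] * (n - n_female),
                "age_at_first_admission": rng.normal(28, 7, n).round(1),
                "steady_state_hb": rng.normal(9 if geno == "SS" else 10, 0.8, n).round(1),
            }
        )
        pid += n
        for flag, counts in flag_counts.items():
            df[flag] = _set_first_true(n, counts[geno])
        priapism = np.zeros(n, dtype=bool)
        male_idx = np.flatnonzero((df["sex"] == "male").to_numpy())
        priapism[male_idx[:n_priapism]] = True
        df["priapism"] = priapism
        groups.append(df)
    return pd.concat(groups, ignore_index=True)
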