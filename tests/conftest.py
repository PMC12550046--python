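"""Shared fixtures: synthetic cohorts and maps reused across test modules.

The heavier objects (the standard planted-effect cohort and the 100-seed
null calibration) are session-scoped so that every test module sees the
same simulated study.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest

from pallidomap.mapping import (
    MappingCohort,
    extract_spot,
    loo_fit,
    loo_predict,
    voxelwise_tmap,
)
from pallidomap.synthetic_data import (
    SyntheticConfig,
    generate_cohort,
    table1_fixture,
)

#: seed of the standard synthetic cohort used throughout the suite
STD_SEED = 1
N_NULL_SEEDS = 100


@pytest.fixture(scope="session")
def table1_records():
    return table1_fixture()


@pytest.fixture(scope="session")
def std_cohort():
    """The standard planted-effect cohort (n=60, default config)."""
    return generate_cohort(SyntheticConfig(), seed=STD_SEED)


@pytest.fixture(scope="session")
def std_mapping(std_cohort):
    """Mapping cohort + full-cohort stat map + sour spot of the standard cohort."""
    mc = MappingCohort.from_vtas(
        [r.patient_id for r in std_cohort.records],
        std_cohort.vta_sets,
        std_cohort.severity,
        std_cohort.grid,
    )
    statmap = voxelwise_tmap(
        std_cohort.vta_sets, std_cohort.severity, grid=std_cohort.grid
    )
    sour = extract_spot(statmap, "sour")
    return {"cohort": mc, "statmap": statmap, "sour": sour}


@pytest.fixture(scope="session")
def loo_results(std_mapping):
    mc = std_mapping["cohort"]
    return {"fit": loo_fit(mc), "predict": loo_predict(mc)}


@pytest.fixture(scope="session")
def null_calibration():
    """Leave-one-out behaviour over 100 null cohorts (planted effect = 0).

    Returns per-seed records of: whether the full-cohort map retained any
    cluster, the voxel-level fit R^2, and whether the patient-level LOOCV
    correlation was significantly positive.
    """
    cfg = replace(SyntheticConfig(), effect_beta=0.0)
    any_cluster, fit_r2, pred_sig_pos = [], [], []
    for s in range(N_NULL_SEEDS):
        cohort = generate_cohort(cfg, seed=10_000 + s)
        mc = MappingCohort.from_vtas(
            [r.patient_id for r in cohort.records],
            cohort.vta_sets,
            cohort.severity,
            cohort.grid,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            statmap = voxelwise_tmap(
                cohort.vta_sets, cohort.severity, grid=cohort.grid
            )
            spot = extract_spot(statmap, "sour")
            fit = loo_fit(mc)
            pred = loo_predict(mc)
        any_cluster.append(spot.n_voxels > 0)
        fit_r2.append(fit["r2"])
        pred_sig_pos.append(pred["p"] < 0.05 and pred.get("r", 0.0) > 0)
    return {
        "any_cluster": np.asarray(any_cluster),
        "fit_r2": np.asarray(fit_r2),
        "pred_sig_pos": np.asarray(pred_sig_pos),
    }
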