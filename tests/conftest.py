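"""Shared fixtures: small synthetic datasets and a reference single-drug fit."""

import dataclasses

import numpy as np
import pytest

from qtconc import (
    CorrectionSpec,
    build_analysis_records,
    compute_all_baselines,
    estimate_population_exponent,
    read_concentration_table,
    read_ecg_table,
)
from qtconc.exposure_model import ExposureModelFit, CellIntercept
from qtconc.data_schema_io import CellKey
from qtconc.synthetic_data import GeneratorTruth, StudyPlan, generate_study, regimen_map

#: SE back-derived from the printed 90% CI (1.28, 1.94) of the 1.61 slope;
#: used only to build fixture fits that mirror the published single-drug model
PRETOMANID_SLOPE = 1.61
PRETOMANID_SE = (1.94 - 1.28) / (2 * 1.6448536269514722)
M2_SLOPE = 19.3
M2_SE = (23.3 - 15.2) / (2 * 1.6448536269514722)


def make_reference_fit(analytes=("pretomanid",), cov=None) -> ExposureModelFit:
    """An ExposureModelFit carrying the published slope estimates/SEs."""
    table = {"pretomanid": (PRETOMANID_SLOPE, PRETOMANID_SE), "M2": (M2_SLOPE, M2_SE)}
    slopes = {a: table[a] for a in analytes}
    if cov is None:
        cov = np.diag([table[a][1] ** 2 for a in analytes])
    return ExposureModelFit(
        analytes=tuple(analytes),
        slopes=slopes,
        slope_cov=np.asarray(cov, dtype=float),
        baseline_coef=-0.305,
        baseline_coef_se=0.02,
        median_bqtc=405.0,
        intercepts={CellKey("REF", "W4", "2h"): CellIntercept(3.9, 100, 4.0)},
        omega=9.58,
        sigma=10.2,
        loglik=0.0,
        n_obs=100,
        n_subjects=50,
        n_fixed_params=len(analytes) + 2,
    )


@pytest.fixture(scope="session")
def reference_fit() -> ExposureModelFit:
    return make_reference_fit()


@pytest.fixture(scope="session")
def default_truth() -> GeneratorTruth:
    return GeneratorTruth()


@pytest.fixture(scope="session")
def small_truth() -> GeneratorTruth:
    """A compact two-study design for fast pipeline tests."""
    return dataclasses.replace(
        GeneratorTruth(),
        design=(
            StudyPlan("A", 60, ("pretomanid",), (2.0, 4.0, 8.0)),
            StudyPlan("B", 40, ("pretomanid", "M2", "bedaquiline", "linezolid"), (4.0, 16.0)),
        ),
        seed=42,
    )


def run_pipeline_from_tables(truth: GeneratorTruth, analytes, tmp_path, **fit_kwargs):
    """Full pipeline (tables -> correction -> records -> fit) for tests."""
    from qtconc import fit_exposure_model

    ecg_df, pk_df, _ = generate_study(truth)
    ecg_path, pk_path = tmp_path / "ecg.csv", tmp_path / "pk.csv"
    ecg_df.to_csv(ecg_path, index=False)
    pk_df.to_csv(pk_path, index=False)
    ecgs = read_ecg_table(ecg_path)
    concs = read_concentration_table(pk_path)
    pairs = [
        (float(np.mean(o.qt_values)), float(np.mean(o.hr_values)))
        for o in ecgs
        if o.phase == "pretreatment"
    ]
    spec = estimate_population_exponent(pairs)
    baselines, _ = compute_all_baselines(ecgs, spec)
    records, exclusions = build_analysis_records(ecgs, concs, baselines, spec, regimen_map(truth))
    fit = fit_exposure_model(records, analytes, **fit_kwargs)
    return spec, records, exclusions, fit
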