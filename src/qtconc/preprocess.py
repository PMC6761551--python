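"""Construction of the modeling dataset.

Three steps turn raw ECG and concentration tables into analysis records:

1. replicate averaging — each replicate QT is corrected to QTc first, then
   the corrected values (and heart rates) are averaged arithmetically;
2. subject baselines — the unweighted mean of the per-timepoint averaged QTc
   over a subject's pretreatment observations (screening, day -1, day-1
   predose; 1-5 timepoints depending on study);
3. time-matching — an on-treatment ECG enters the analysis only when a valid
   concentration is present, at the same study/visit/time-postdose cell, for
   *every* analyte in that subject's regimen.  Analytes outside the regimen
   are carried as 0.  Every exclusion is recorded with a machine-readable
   reason.

Concentrations below the quantification limit are expected to be encoded as
0 upstream; a missing (empty/NA) concentration is not valid and fails the
match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_schema_io import (
    ANALYTES,
    AnalysisRecord,
    DrugConcentration,
    EcgObservation,
)
from .qt_correction import CorrectionSpec, correct_qt

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubjectBaseline:
    """A subject's pretreatment baseline QTc and the number of ECGs behind it."""

    subject_id: str
    baseline_qtc: float
    n_ecgs_used: int


@dataclass(frozen=True)
class Exclusion:
    """One dropped ECG (or subject) with the reason it failed to enter the model."""

    subject_id: str
    study_id: str
    visit_id: str
    time_postdose_label: str
    reason: str


def average_triplicates(obs: EcgObservation, spec: CorrectionSpec) -> tuple[float, float]:
    """Correct each replicate, then average: returns (mean QTc ms, mean HR bpm)."""
    qtc = correct_qt(np.array(obs.qt_values), np.array(obs.hr_values), spec)
    return float(np.mean(qtc)), float(np.mean(obs.hr_values))


def compute_baseline(
    pretreatment_obs: list[EcgObservation], spec: CorrectionSpec
) -> SubjectBaseline:
    """Baseline QTc: unweighted mean of per-timepoint averaged QTc values."""
    obs = [o for o in pretreatment_obs if o.phase == "pretreatment"]
    if not obs:
        raise ValueError("no pretreatment observations; subject has no baseline")
    subject_ids = {o.subject_id for o in obs}
    if len(subject_ids) != 1:
        raise ValueError("pretreatment observations span multiple subjects")
    means = [average_triplicates(o, spec)[0] for o in obs]
    return SubjectBaseline(
        subject_id=obs[0].subject_id,
        baseline_qtc=float(np.mean(means)),
        n_ecgs_used=len(obs),
    )


def compute_all_baselines(
    ecgs: list[EcgObservation], spec: CorrectionSpec
) -> tuple[dict[str, SubjectBaseline], list[Exclusion]]:
    """Per-subject baselines; subjects with no pretreatment ECG are excluded."""
    by_subject: dict[str, list[EcgObservation]] = {}
    for obs in ecgs:
        by_subject.setdefault(obs.subject_id, []).append(obs)
    baselines: dict[str, SubjectBaseline] = {}
    exclusions: list[Exclusion] = []
    for subject_id, obs_list in by_subject.items():
        pre = [o for o in obs_list if o.phase == "pretreatment"]
        if not pre:
            exclusions.append(
                Exclusion(subject_id, obs_list[0].study_id, "", "", "no_pretreatment_ecg")
            )
            logger.warning("subject %s excluded: no pretreatment ECG", subject_id)
            continue
        baselines[subject_id] = compute_baseline(pre, spec)
    return baselines, exclusions


def build_analysis_records(
    ecgs: list[EcgObservation],
    concs: list[DrugConcentration],
    baselines: dict[str, SubjectBaseline],
    spec: CorrectionSpec,
    regimen_map: dict[str, set[str]],
) -> tuple[list[AnalysisRecord], list[Exclusion]]:
    """Assemble one analysis record per fully time-matched on-treatment ECG.

    ``regimen_map`` gives, per subject, the set of analytes whose
    concentration must be present for the ECG to be retained (explicit
    configuration, not inferred from the data).  ``delta_qtc`` is the
    triplicate-averaged QTc minus the subject's baseline.
    """
    conc_lookup: dict[tuple, float | None] = {}
    for c in concs:
        key = (c.subject_id, c.study_id, c.visit_id, c.time_postdose_label, c.analyte)
        conc_lookup[key] = c.concentration

    records: list[AnalysisRecord] = []
    exclusions: list[Exclusion] = []
    for obs in ecgs:
        if obs.phase != "on_treatment":
            continue
        if obs.subject_id not in baselines:
            exclusions.append(
                Exclusion(
                    obs.subject_id, obs.study_id, obs.visit_id,
                    obs.time_postdose_label, "no_baseline",
                )
            )
            continue
        regimen = regimen_map.get(obs.subject_id)
        if regimen is None:
            exclusions.append(
                Exclusion(
                    obs.subject_id, obs.study_id, obs.visit_id,
                    obs.time_postdose_label, "no_regimen_configured",
                )
            )
            continue
        unknown = set(regimen) - set(ANALYTES)
        if unknown:
            raise ValueError(f"regimen for {obs.subject_id} names unknown analytes {unknown}")

        concentrations = {a: 0.0 for a in ANALYTES}
        missing = []
        for analyte in sorted(regimen):
            key = (obs.subject_id, obs.study_id, obs.visit_id, obs.time_postdose_label, analyte)
            value = conc_lookup.get(key)
            if value is None:  # absent row or invalid sample
                missing.append(analyte)
            else:
                concentrations[analyte] = value
        if missing:
            exclusions.append(
                Exclusion(
                    obs.subject_id, obs.study_id, obs.visit_id,
                    obs.time_postdose_label,
                    "missing_concentration:" + ",".join(missing),
                )
            )
            continue

        qtc_mean, _ = average_triplicates(obs, spec)
        baseline = baselines[obs.subject_id]
        records.append(
            AnalysisRecord(
                subject_id=obs.subject_id,
                cell=obs.cell,
                week=obs.week,
                delta_qtc=qtc_mean - baseline.baseline_qtc,
                baseline_qtc=baseline.baseline_qtc,
                concentrations=concentrations,
                n_replicates=obs.n_replicates,
            )
        )
    logger.info(
        "built %d analysis records (%d exclusions)", len(records), len(exclusions)
    )
    return records, exclusions
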