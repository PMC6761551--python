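"""Synthetic ECG/PK data with the statistical structure the analysis assumes.

The generator runs the analysis model *forward*: subject baselines, a
heart-rate decline on treatment, per-cell secular-trend intercepts,
per-analyte lognormal concentrations, concentration slopes, a subject random
effect and residual noise are composed directly into per-replicate QT/HR
rows, and the corrected QTc is back-transformed to raw QT through the
subject's heart rate.  Re-running the full pipeline (exponent estimation ->
correction -> baselines -> mixed-model fit -> trend fit) on the output is
therefore a true end-to-end recovery test; the generator shares no model
object with the fitter.

Default parameter values are the study conditions the pipeline is meant to
emulate: correction exponent 0.42, pretomanid slope 1.61 and M2 slope 19.3
ms/(ug/ml), baseline coefficient -0.305, subject SD 9.58 ms, residual SD
10.2 ms, secular plateau 3.99 ms with rate 2.3/week, baseline heart-rate
median 88.5 bpm falling ~7.5 bpm on treatment, ~800 subjects across four
study designs with visits from week 2 to week 26.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_schema_io import ANALYTES, ECG_COLUMNS, CONC_COLUMNS

#: pretreatment visit labels by ECG count (screening, day -1, day-1 predose
#: and two extra screening-window visits for the five-sample pattern)
_PRETREATMENT_VISITS = {
    1: ["D1-predose"],
    2: ["D-1", "D1-predose"],
    3: ["SCR", "D-1", "D1-predose"],
    4: ["SCR2", "SCR", "D-1", "D1-predose"],
    5: ["SCR3", "SCR2", "SCR", "D-1", "D1-predose"],
}


@dataclass(frozen=True)
class StudyPlan:
    """One synthetic study: its regimen, visit weeks, timepoints and size."""

    study_id: str
    n_subjects: int
    regimen: tuple[str, ...]
    weeks: tuple[float, ...]
    timepoints: tuple[str, ...] = ("2h", "4h")
    replicates: int = 3

    def __post_init__(self) -> None:
        unknown = set(self.regimen) - set(ANALYTES)
        if unknown:
            raise ValueError(f"study {self.study_id}: unknown analytes {sorted(unknown)}")
        if self.n_subjects < 1 or not self.weeks:
            raise ValueError(f"study {self.study_id}: empty design")


def default_design() -> tuple[StudyPlan, ...]:
    """Four studies (~800 subjects) emulating a mono/combination program."""
    return (
        StudyPlan("EBA-A", 200, ("pretomanid",), (2.0, 4.0, 8.0, 16.0)),
        StudyPlan("EBA-B", 150, ("pretomanid",), (2.0, 8.0, 16.0, 26.0)),
        StudyPlan(
            "COMBO-PaMZ", 250,
            ("pretomanid", "moxifloxacin", "pyrazinamide"),
            (2.0, 4.0, 8.0),
        ),
        StudyPlan(
            "BPAL", 200,
            ("pretomanid", "bedaquiline", "M2", "linezolid"),
            (4.0, 16.0),
        ),
    )


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth parameters behind one synthetic dataset.

    All noise SDs may be set to 0 for exact-recovery tests.  ``seed`` is part
    of the truth: identical truths generate byte-identical tables.
    """

    r_true: float = 0.42
    slopes_true: dict[str, float] = field(
        default_factory=lambda: {
            "pretomanid": 1.61,
            "M2": 19.3,
            "moxifloxacin": 2.60,
            "bedaquiline": 0.0,
            "pyrazinamide": 0.0,
            "linezolid": 0.0,
        }
    )
    eoI_true: float = -0.305
    omega_true: float = 9.58  # subject random-effect SD, ms
    sigma_true: float = 10.2  # residual SD, ms
    pmax_true: float = 3.99  # secular plateau, ms
    lam_true: float = 2.3  # onset rate, 1/week
    delta_sd_true: float = 3.19  # trend residual SD, ms, unit-weight scale
    hr_baseline_median: float = 88.5  # bpm
    hr_decline: float = 7.5  # bpm drop on treatment (observed range 5-10)
    #: per-analyte (lognormal median ug/ml, geometric SD) of time-matched
    #: concentrations
    conc_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "pretomanid": (3.0, 1.5),
            "M2": (0.25, 1.5),
            "moxifloxacin": (2.5, 1.4),
            "bedaquiline": (1.2, 1.5),
            "pyrazinamide": (35.0, 1.3),
            "linezolid": (15.0, 1.4),
        }
    )
    design: tuple[StudyPlan, ...] = field(default_factory=default_design)
    seed: int = 20190445
    # nuisance/noise structure
    baseline_qtc_median: float = 405.0  # ms, subject-level QTc scale
    baseline_qtc_log_sd: float = 0.04  # ~16 ms between-subject spread
    qt_log_noise_sd: float = 0.02  # pretreatment multiplicative QT noise
    hr_between_log_sd: float = 0.11  # between-subject HR spread
    hr_within_log_sd: float = 0.04  # visit-to-visit HR wobble
    replicate_qt_jitter_sd: float = 1.0  # ms, within-triplicate
    replicate_hr_jitter_sd: float = 0.5  # bpm, within-triplicate
    missing_pk_fraction: float = 0.0  # fraction of PK samples invalidated

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["design"] = [dataclasses.asdict(s) for s in self.design]
        return json.dumps(d, indent=1)

    def zero_noise(self) -> "GeneratorTruth":
        """Copy with every stochastic model component silenced.

        Heart-rate variation is kept (it is physiology the correction needs,
        not noise), but QT noise, between-subject QTc spread, replicate
        jitter and all model-level random terms are zeroed, so the full
        pipeline recovers the truth exactly.  With homogeneous baselines the
        baseline covariate becomes unidentifiable; fit with
        ``include_baseline=False`` on such data.
        """
        return dataclasses.replace(
            self,
            omega_true=0.0,
            sigma_true=0.0,
            delta_sd_true=0.0,
            baseline_qtc_log_sd=0.0,
            qt_log_noise_sd=0.0,
            replicate_qt_jitter_sd=0.0,
            replicate_hr_jitter_sd=0.0,
        )


def regimen_map(truth: GeneratorTruth) -> dict[str, set[str]]:
    """subject_id -> analyte set, matching :func:`generate_study`'s subject ids."""
    mapping: dict[str, set[str]] = {}
    for plan in truth.design:
        for i in range(plan.n_subjects):
            mapping[f"{plan.study_id}-S{i:04d}"] = set(plan.regimen)
    return mapping


def _subject_physiology(truth: GeneratorTruth, rng, n: int):
    """Per-subject QTc scale A_i (ms) and baseline HR (bpm)."""
    a = truth.baseline_qtc_median * np.exp(rng.normal(0.0, truth.baseline_qtc_log_sd, n))
    hr = truth.hr_baseline_median * np.exp(rng.normal(0.0, truth.hr_between_log_sd, n))
    return a, hr


def _ecg_rows(rows, subject, study, visit, week, timepoint, phase, qtc_target, hr_center,
              truth, rng, replicates):
    """Emit replicate rows whose corrected-QT mean tracks ``qtc_target``.

    Returns the generator-side (mean QTc at r_true, mean HR) of the emitted
    replicates.
    """
    qtc_mean = 0.0
    hr_mean = 0.0
    for _ in range(replicates):
        qtc_rep = qtc_target + rng.normal(0.0, truth.replicate_qt_jitter_sd)
        hr_rep = hr_center + rng.normal(0.0, truth.replicate_hr_jitter_sd)
        qt_rep = qtc_rep * (hr_rep / 60.0) ** (-truth.r_true)
        rows.append((subject, study, visit, week, timepoint, phase, qt_rep, hr_rep))
        qtc_mean += qtc_rep / replicates
        hr_mean += hr_rep / replicates
    return qtc_mean, hr_mean


def generate_pretreatment(
    truth: GeneratorTruth,
    n_subjects: int,
    ecgs_per_subject: int | None = None,
    replicates: int = 1,
    study_id: str = "PRE",
    rng=None,
) -> pd.DataFrame:
    """Pretreatment ECG table for exponent-estimation studies.

    ``ecgs_per_subject`` of None uses the program's predominant baseline
    pattern deterministically: 76% of subjects contribute two pretreatment
    ECGs, 20% one, 4% five.  Each ECG draws its own heart rate, and QT
    follows QT = A_subject * RR^r_true * exp(noise).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if ecgs_per_subject is not None and not 1 <= ecgs_per_subject <= 5:
        raise ValueError("ecgs_per_subject must be in 1..5")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    a_subj, hr_subj = _subject_physiology(truth, rng, n_subjects)

    n_two = int(round(0.76 * n_subjects))
    n_one = int(round(0.20 * n_subjects))
    rows: list[tuple] = []
    for i in range(n_subjects):
        if ecgs_per_subject is not None:
            k = ecgs_per_subject
        else:
            k = 2 if i < n_two else (1 if i < n_two + n_one else 5)
        for visit in _PRETREATMENT_VISITS[k]:
            hr = hr_subj[i] * np.exp(rng.normal(0.0, truth.hr_within_log_sd))
            qtc = a_subj[i] * np.exp(rng.normal(0.0, truth.qt_log_noise_sd))
            _ecg_rows(
                rows, f"{study_id}-S{i:04d}", study_id, visit, 0.0, "predose",
                "pretreatment", qtc, hr, truth, rng, replicates,
            )
    return pd.DataFrame(rows, columns=ECG_COLUMNS)


def generate_study(truth: GeneratorTruth) -> tuple[pd.DataFrame, pd.DataFrame, GeneratorTruth]:
    """Full synthetic program: (ECG table, PK table, truth echo).

    Pretreatment ECGs define each subject's baseline; on-treatment cells get
    a secular-trend intercept plus cell noise, and each subject/visit/
    timepoint observation assembles

        dQTc = E_cell + eoI*(BQTc - median BQTc) + sum sl_a*C_a + eta + eps,

    which is back-transformed to raw QT at the subject's (declined) heart
    rate so the pipeline must redo correction, baselining and fitting to
    recover the truth.
    """
    rng = np.random.default_rng(truth.seed)
    ecg_rows: list[tuple] = []
    pk_rows: list[tuple] = []

    # ---- pretreatment & generator-side true baselines ---------------------
    subj_meta: list[tuple[str, StudyPlan, float, float]] = []  # id, plan, BQTc, HR
    for plan in truth.design:
        a_subj, hr_subj = _subject_physiology(truth, rng, plan.n_subjects)
        n_two = int(round(0.76 * plan.n_subjects))
        n_one = int(round(0.20 * plan.n_subjects))
        for i in range(plan.n_subjects):
            sid = f"{plan.study_id}-S{i:04d}"
            k = 2 if i < n_two else (1 if i < n_two + n_one else 5)
            qtc_means = []
            for visit in _PRETREATMENT_VISITS[k]:
                hr = hr_subj[i] * np.exp(rng.normal(0.0, truth.hr_within_log_sd))
                qtc = a_subj[i] * np.exp(rng.normal(0.0, truth.qt_log_noise_sd))
                qtc_mean, _ = _ecg_rows(
                    ecg_rows, sid, plan.study_id, visit, 0.0, "predose",
                    "pretreatment", qtc, hr, truth, rng, plan.replicates,
                )
                qtc_means.append(qtc_mean)
            subj_meta.append((sid, plan, float(np.mean(qtc_means)), hr_subj[i]))

    median_bqtc = float(np.median([m[2] for m in subj_meta]))

    # ---- per-cell secular intercepts --------------------------------------
    # delta_sd_true is on the unit-weight scale of the weighted second-stage
    # fit: a cell observed n times deviates from the trend with SD delta/sqrt(n)
    cell_intercept: dict[tuple[str, float, str], float] = {}
    for plan in truth.design:
        for week in plan.weeks:
            for tp in plan.timepoints:
                trend = truth.pmax_true * (1.0 - np.exp(-truth.lam_true * week))
                cell_intercept[(plan.study_id, week, tp)] = trend + rng.normal(
                    0.0, truth.delta_sd_true / np.sqrt(plan.n_subjects)
                )

    # ---- on-treatment observations ----------------------------------------
    eta = {sid: rng.normal(0.0, truth.omega_true) for sid, *_ in subj_meta}
    for sid, plan, bqtc, hr_base in subj_meta:
        for week in plan.weeks:
            visit = f"W{week:g}"
            for tp in plan.timepoints:
                concs = {}
                for analyte in plan.regimen:
                    med, gsd = truth.conc_distributions[analyte]
                    concs[analyte] = med * np.exp(rng.normal(0.0, np.log(gsd)))
                drug_effect = sum(
                    truth.slopes_true.get(a, 0.0) * c for a, c in concs.items()
                )
                eps = rng.normal(0.0, truth.sigma_true)
                dqtc = (
                    cell_intercept[(plan.study_id, week, tp)]
                    + truth.eoI_true * (bqtc - median_bqtc)
                    + drug_effect
                    + eta[sid]
                    + eps
                )
                hr = (hr_base - truth.hr_decline) * np.exp(
                    rng.normal(0.0, truth.hr_within_log_sd)
                )
                _ecg_rows(
                    ecg_rows, sid, plan.study_id, visit, week, tp,
                    "on_treatment", bqtc + dqtc, hr, truth, rng, plan.replicates,
                )
                for analyte in plan.regimen:
                    valid = rng.random() >= truth.missing_pk_fraction
                    pk_rows.append(
                        (
                            sid, plan.study_id, visit, tp, analyte,
                            concs[analyte] if valid else "",
                        )
                    )

    ecg = pd.DataFrame(ecg_rows, columns=ECG_COLUMNS)
    pk = pd.DataFrame(pk_rows, columns=CONC_COLUMNS)
    return ecg, pk, truth


def generate_analysis_records(
    truth: GeneratorTruth,
    n_subjects: int,
    weeks=(2.0, 4.0, 8.0, 16.0),
    timepoints=("2h", "4h"),
    analytes=("pretomanid",),
    study_id: str = "SIM",
    rng=None,
):
    """Modeling rows composed directly from the model equations (no ECG layer).

    Convenient for repeated parameter-recovery studies of the mixed-model
    fit: each subject gets a baseline QTc, a random effect, per-visit
    lognormal concentrations for the requested analytes, and

        dQTc = E_cell + eoI*(BQTc - median BQTc) + sum sl_a*C_a + eta + eps

    with E_cell the secular trend plus cell noise.  Returns a list of
    :class:`~qtconc.data_schema_io.AnalysisRecord`.
    """
    from .data_schema_io import AnalysisRecord, CellKey

    if rng is None:
        rng = np.random.default_rng(truth.seed)
    bqtc = truth.baseline_qtc_median * np.exp(
        rng.normal(0.0, truth.baseline_qtc_log_sd, n_subjects)
    )
    median_bqtc = float(np.median(bqtc))
    eta = rng.normal(0.0, truth.omega_true, n_subjects)
    cell_e = {
        (w, tp): truth.pmax_true * (1.0 - np.exp(-truth.lam_true * w))
        + rng.normal(0.0, truth.delta_sd_true / np.sqrt(n_subjects))
        for w in weeks
        for tp in timepoints
    }
    records = []
    for i in range(n_subjects):
        for w in weeks:
            for tp in timepoints:
                concs = {}
                for a in analytes:
                    med, gsd = truth.conc_distributions[a]
                    concs[a] = med * np.exp(rng.normal(0.0, np.log(gsd)))
                dqtc = (
                    cell_e[(w, tp)]
                    + truth.eoI_true * (bqtc[i] - median_bqtc)
                    + sum(truth.slopes_true.get(a, 0.0) * c for a, c in concs.items())
                    + eta[i]
                    + rng.normal(0.0, truth.sigma_true)
                )
                records.append(
                    AnalysisRecord(
                        subject_id=f"{study_id}-S{i:04d}",
                        cell=CellKey(study_id, f"W{w:g}", tp),
                        week=w,
                        delta_qtc=float(dqtc),
                        baseline_qtc=float(bqtc[i]),
                        concentrations=concs,
                    )
                )
    return records


def simulate_intercepts(
    pmax: float = 3.99,
    lam: float = 2.3,
    delta_sd: float = 3.19,
    n_cells: int = 40,
    seed: int = 0,
) -> list[tuple[float, float, int]]:
    """Cell-level (week, intercept, size) triples from the secular-trend model.

    Weeks span early onset (half-life log(2)/2.3 ~ 0.3 wk) through the
    26-week plateau; sizes mimic per-cell ECG counts (15-90).  ``delta_sd``
    is on the unit-weight scale of the weighted second-stage fit: a cell of
    size n deviates from the trend with SD delta_sd/sqrt(n), mirroring the
    intercept-estimation noise that motivates weighting by sample size.
    """
    rng = np.random.default_rng(seed)
    week_grid = np.array([0.29, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 26.0])
    weeks = week_grid[np.arange(n_cells) % len(week_grid)]
    sizes = rng.integers(15, 90, size=n_cells)
    eo = pmax * (1.0 - np.exp(-lam * weeks)) + rng.normal(
        0.0, delta_sd / np.sqrt(sizes), n_cells
    )
    return [(float(w), float(e), int(n)) for w, e, n in zip(weeks, eo, sizes)]
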