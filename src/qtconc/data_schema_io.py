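"""Tabular data model and delimited-text I/O for the concentration-QTc pipeline.

The pipeline consumes two flat tables:

* an ECG table with one row per individual ECG replicate
  (``subject_id, study_id, visit_id, week, time_postdose, phase, qt_ms, hr_bpm``);
* a drug-concentration table with one row per analyte measurement
  (``subject_id, study_id, visit_id, time_postdose, analyte, conc_ug_ml``).

Replicate ECG rows sharing the same (subject, study, visit, time-postdose,
phase) key are grouped into a single :class:`EcgObservation` at read time, so
triplicates travel together through correction and averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Analytes the pipeline knows about.  The bedaquiline metabolite M2 is a
#: distinct analyte from bedaquiline itself: M2, not the parent, is the
#: QT-active moiety and its plasma concentrations enter the model.
ANALYTES: tuple[str, ...] = (
    "pretomanid",
    "bedaquiline",
    "M2",
    "moxifloxacin",
    "pyrazinamide",
    "linezolid",
)

PHASES = ("pretreatment", "on_treatment")

ECG_COLUMNS = [
    "subject_id",
    "study_id",
    "visit_id",
    "week",
    "time_postdose",
    "phase",
    "qt_ms",
    "hr_bpm",
]
CONC_COLUMNS = [
    "subject_id",
    "study_id",
    "visit_id",
    "time_postdose",
    "analyte",
    "conc_ug_ml",
]

#: Spellings accepted as a missing value in optional numeric fields.
MISSING_TOKENS = ("", "NA")

QT_RANGE = (200.0, 700.0)  # ms, physiological plausibility bounds
HR_RANGE = (30.0, 200.0)  # bpm


class SchemaError(ValueError):
    """A table is structurally unusable (e.g. a required column is absent)."""


@dataclass(frozen=True)
class RowError:
    """One rejected input row, with its 1-based line number and the reason."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"line {self.line}: {self.message}"


@dataclass(frozen=True, order=True)
class CellKey:
    """Index of one study x visit x time-postdose grouping.

    The exposure-response model estimates a separate mean intercept for every
    such cell, so equality must be exact on all three components.
    """

    study_id: str
    visit_id: str
    time_postdose_label: str


@dataclass
class EcgObservation:
    """One ECG reading, possibly a triplicate, with scheduling metadata.

    ``qt_values`` and ``hr_values`` are parallel per-replicate lists (1-3
    entries).  ``week`` is the nominal protocol week of the visit; 0 is legal
    only for pretreatment/predose observations.
    """

    subject_id: str
    study_id: str
    visit_id: str
    week: float
    time_postdose_label: str
    qt_values: list[float]
    hr_values: list[float]
    phase: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if not (1 <= len(self.qt_values) <= 3):
            raise ValueError("1-3 QT replicates required")
        if len(self.qt_values) != len(self.hr_values):
            raise ValueError("qt_values and hr_values must have equal length")
        if self.week < 0 or not math.isfinite(self.week):
            raise ValueError("week must be a finite non-negative number")
        for qt in self.qt_values:
            if not QT_RANGE[0] < qt < QT_RANGE[1]:
                raise ValueError(f"QT {qt} ms outside plausible range {QT_RANGE}")
        for hr in self.hr_values:
            if not HR_RANGE[0] < hr < HR_RANGE[1]:
                raise ValueError(f"HR {hr} bpm outside plausible range {HR_RANGE}")

    @property
    def cell(self) -> CellKey:
        return CellKey(self.study_id, self.visit_id, self.time_postdose_label)

    @property
    def n_replicates(self) -> int:
        return len(self.qt_values)


@dataclass
class DrugConcentration:
    """One time-matched plasma concentration measurement (ug/ml).

    ``concentration`` is ``None`` when the sample was drawn but no valid
    value is available; such records never satisfy time-matching.
    """

    subject_id: str
    study_id: str
    visit_id: str
    time_postdose_label: str
    analyte: str
    concentration: float | None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.concentration is not None and (
            self.concentration < 0 or not math.isfinite(self.concentration)
        ):
            raise ValueError("concentration must be >= 0 when present")

    @property
    def cell(self) -> CellKey:
        return CellKey(self.study_id, self.visit_id, self.time_postdose_label)


@dataclass
class AnalysisRecord:
    """One modeling row: a baseline-subtracted QTc with matched concentrations.

    ``concentrations`` maps every known analyte to ug/ml, with 0 for analytes
    not administered to this subject.
    """

    subject_id: str
    cell: CellKey
    week: float
    delta_qtc: float
    baseline_qtc: float
    concentrations: dict[str, float] = field(default_factory=dict)
    #: replicates behind the averaged QTc (1 = singleton ECG, 3 = triplicate);
    #: used only by the optional residual-variance-by-replicate-class model.
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_qtc):
            raise ValueError("delta_qtc must be finite")
        for analyte, conc in self.concentrations.items():
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte {analyte!r}")
            if conc is None or not math.isfinite(conc) or conc < 0:
                raise ValueError(f"concentration for {analyte} must be finite >= 0")


# ---------------------------------------------------------------------------
# readers / writers


def _check_header(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _parse_float(token: str, what: str, line: int):
    token = (token or "").strip()
    if token in MISSING_TOKENS:
        raise ValueError(f"{what} is missing")
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"non-numeric {what} {token!r}") from None


def read_ecg_table(
    path,
    delimiter: str = ",",
    errors: list[RowError] | None = None,
) -> list[EcgObservation]:
    """Read an ECG replicate table and group replicates into observations.

    Rows failing validation are rejected individually: each rejection is
    logged with its line number, appended to ``errors`` when a list is
    supplied, and the remaining rows are still returned.  Replicate rows
    sharing (subject, study, visit, time-postdose, phase) become one
    :class:`EcgObservation`; replicate (qt, hr) pairs are stored in sorted
    order so the grouping is independent of input row order.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    _check_header(df, ECG_COLUMNS, path)
    if errors is None:
        errors = []

    groups: dict[tuple, dict] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            qt = _parse_float(row.qt_ms, "qt_ms", line)
            hr = _parse_float(row.hr_bpm, "hr_bpm", line)
            week = _parse_float(row.week, "week", line)
            phase = row.phase.strip()
            if phase not in PHASES:
                raise ValueError(f"unknown phase {phase!r}")
        except ValueError as exc:
            err = RowError(line, str(exc))
            errors.append(err)
            logger.warning("rejected ECG row: %s", err)
            continue
        key = (
            row.subject_id.strip(),
            row.study_id.strip(),
            row.visit_id.strip(),
            row.time_postdose.strip(),
            phase,
        )
        grp = groups.setdefault(key, {"week": week, "pairs": []})
        grp["pairs"].append((qt, hr))

    observations: list[EcgObservation] = []
    for (subject, study, visit, tp, phase), grp in groups.items():
        pairs = sorted(grp["pairs"])
        try:
            obs = EcgObservation(
                subject_id=subject,
                study_id=study,
                visit_id=visit,
                week=grp["week"],
                time_postdose_label=tp,
                qt_values=[p[0] for p in pairs],
                hr_values=[p[1] for p in pairs],
                phase=phase,
            )
        except ValueError as exc:
            err = RowError(-1, f"group {(subject, study, visit, tp)}: {exc}")
            errors.append(err)
            logger.warning("rejected ECG group: %s", err)
            continue
        observations.append(obs)
    observations.sort(key=lambda o: (o.subject_id, o.study_id, o.visit_id, o.time_postdose_label, o.phase))
    return observations


def read_concentration_table(
    path,
    delimiter: str = ",",
    errors: list[RowError] | None = None,
) -> list[DrugConcentration]:
    """Read a drug-concentration table (one row per analyte measurement).

    An empty or ``NA`` concentration is legal and yields ``concentration
    None`` (a drawn-but-invalid sample); negative or non-numeric values
    reject the row.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    _check_header(df, CONC_COLUMNS, path)
    if errors is None:
        errors = []

    records: list[DrugConcentration] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        token = row.conc_ug_ml.strip()
        try:
            conc = None if token in MISSING_TOKENS else _parse_float(token, "conc_ug_ml", line)
            rec = DrugConcentration(
                subject_id=row.subject_id.strip(),
                study_id=row.study_id.strip(),
                visit_id=row.visit_id.strip(),
                time_postdose_label=row.time_postdose.strip(),
                analyte=row.analyte.strip(),
                concentration=conc,
            )
        except ValueError as exc:
            err = RowError(line, str(exc))
            errors.append(err)
            logger.warning("rejected concentration row: %s", err)
            continue
        records.append(rec)
    return records


def ecg_to_frame(observations: list[EcgObservation]) -> pd.DataFrame:
    """Flatten observations back to one row per replicate."""
    rows = []
    for obs in observations:
        for qt, hr in zip(obs.qt_values, obs.hr_values):
            rows.append(
                {
                    "subject_id": obs.subject_id,
                    "study_id": obs.study_id,
                    "visit_id": obs.visit_id,
                    "week": obs.week,
                    "time_postdose": obs.time_postdose_label,
                    "phase": obs.phase,
                    "qt_ms": qt,
                    "hr_bpm": hr,
                }
            )
    return pd.DataFrame(rows, columns=ECG_COLUMNS)


def write_ecg_table(observations: list[EcgObservation], path, delimiter: str = ",") -> None:
    ecg_to_frame(observations).to_csv(path, sep=delimiter, index=False)


def conc_to_frame(records: list[DrugConcentration]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "study_id": r.study_id,
            "visit_id": r.visit_id,
            "time_postdose": r.time_postdose_label,
            "analyte": r.analyte,
            "conc_ug_ml": "" if r.concentration is None else r.concentration,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CONC_COLUMNS)


def write_concentration_table(records: list[DrugConcentration], path, delimiter: str = ",") -> None:
    conc_to_frame(records).to_csv(path, sep=delimiter, index=False)


def records_to_frame(records: list[AnalysisRecord]) -> pd.DataFrame:
    """Serialize analysis records to a flat table (one concentration column per analyte)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "study_id": r.cell.study_id,
            "visit_id": r.cell.visit_id,
            "time_postdose": r.cell.time_postdose_label,
            "week": r.week,
            "delta_qtc": r.delta_qtc,
            "baseline_qtc": r.baseline_qtc,
        }
        for analyte in ANALYTES:
            row[f"conc_{analyte}"] = r.concentrations.get(analyte, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[AnalysisRecord]:
    records = []
    for row in df.itertuples(index=False):
        concs = {a: float(getattr(row, f"conc_{a}")) for a in ANALYTES if hasattr(row, f"conc_{a}")}
        records.append(
            AnalysisRecord(
                subject_id=str(row.subject_id),
                cell=CellKey(str(row.study_id), str(row.visit_id), str(row.time_postdose)),
                week=float(row.week),
                delta_qtc=float(row.delta_qtc),
                baseline_qtc=float(row.baseline_qtc),
                concentrations=concs,
            )
        )
    return records
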