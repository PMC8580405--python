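"""Behavioral cohort table: loading, summaries, responder classification.

The patient table (24 hemianopic stroke patients, three stimulation
groups, three time points) carries high-resolution-perimetry stimulus
counts (black = blind, gray = partially damaged, white = intact),
detection reaction times for gray/white positions, and the perimetric
visual-field sensitivity FOV in dB.  Responders are patients whose FOV
percentage change from baseline is strictly positive, irrespective of
treatment group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

GROUP_NAMES = {0: "Sham", 1: "AC", 2: "ACDC"}
TIMEPOINTS = ("pre", "post", "fu")

_NUMERIC_COLUMNS = [
    "lesion_age_months",
    *[f"hrp_{c}_{t}" for t in TIMEPOINTS for c in ("black", "gray", "white")],
    *[f"rt_{c}_{t}" for t in TIMEPOINTS for c in ("gray", "white")],
    *[f"fov_{t}" for t in TIMEPOINTS],
    "age_years",
]


@dataclass
class PatientRecord:
    """One row of the behavioral table, fully typed."""

    id: int
    group: int                    # 0 Sham, 1 AC, 2 ACDC
    lesion_age_months: float
    hrp: dict                     # {(color, timepoint): count}
    rt: dict                      # {(color, timepoint): seconds}
    fov: dict                     # {timepoint: dB}
    gender: str
    age_years: float

    @property
    def group_name(self) -> str:
        return GROUP_NAMES[self.group]


@dataclass
class ResponderLabel:
    id: int
    responder: bool
    fov_pct_change: float

    @property
    def label(self) -> str:
        return "responder" if self.responder else "non-responder"


def packaged_patient_table() -> pd.DataFrame:
    """The packaged 24-patient behavioral table as a DataFrame."""
    with resources.files("hemianet.data").joinpath("table1_patients.csv").open() as f:
        return pd.read_csv(f)


def load_cohort(source: str | Path | pd.DataFrame | None = None) -> list[PatientRecord]:
    """Load and validate a behavioral table into typed patient records.

    ``source`` may be a CSV path, an already-loaded DataFrame, or None for
    the packaged patient table.  Every patient must have all three time
    points; group codes must be 0/1/2.
    """
    if source is None:
        df = packaged_patient_table()
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    records = []
    for _, row in df.iterrows():
        rid = int(row["id"])
        group = int(row["group"])
        if group not in GROUP_NAMES:
            raise ValueError(f"patient {rid}: invalid group code {group!r}")
        for col in _NUMERIC_COLUMNS:
            if col not in row or pd.isna(row[col]):
                raise ValueError(f"patient {rid}: missing value for {col!r}")
        hrp = {
            (c, t): float(row[f"hrp_{c}_{t}"])
            for t in TIMEPOINTS for c in ("black", "gray", "white")
        }
        if any(v < 0 for v in hrp.values()):
            raise ValueError(f"patient {rid}: negative HRP count")
        rt = {
            (c, t): float(row[f"rt_{c}_{t}"])
            for t in TIMEPOINTS for c in ("gray", "white")
        }
        if any(v <= 0 for v in rt.values()):
            raise ValueError(f"patient {rid}: non-positive reaction time")
        records.append(PatientRecord(
            id=rid, group=group,
            lesion_age_months=float(row["lesion_age_months"]),
            hrp=hrp, rt=rt,
            fov={t: float(row[f"fov_{t}"]) for t in TIMEPOINTS},
            gender=str(row["gender"]),
            age_years=float(row["age_years"]),
        ))
    return records


def _truncate2(x: float) -> float:
    """Truncate (not round) to two decimals, the table's display convention."""
    return math.floor(x * 100.0) / 100.0 if x >= 0 else -math.floor(-x * 100.0) / 100.0


def to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten records back to the canonical column schema."""
    rows = []
    for r in records:
        row = {"id": r.id, "group": r.group,
               "lesion_age_months": r.lesion_age_months}
        for t in TIMEPOINTS:
            for c in ("black", "gray", "white"):
                row[f"hrp_{c}_{t}"] = r.hrp[(c, t)]
        for t in TIMEPOINTS:
            for c in ("gray", "white"):
                row[f"rt_{c}_{t}"] = r.rt[(c, t)]
        for t in TIMEPOINTS:
            row[f"fov_{t}"] = r.fov[t]
        row["gender"] = r.gender
        row["age_years"] = r.age_years
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(records: list[PatientRecord], display: bool = True) -> pd.DataFrame:
    """Per-column mean and sample SD over the cohort.

    With ``display=True`` values are truncated to two decimals, matching
    the printed-table convention (25.4166... -> 25.41).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to summarize")
    df = to_frame(records)
    out = pd.DataFrame({
        "mean": df[_NUMERIC_COLUMNS].mean(),
        "sd": df[_NUMERIC_COLUMNS].std(ddof=1),
    })
    if display:
        out = out.map(_truncate2)
    return out


def percentage_change(
    records: list[PatientRecord],
    measure: str = "fov",
    later: str = "post",
    baseline: str = "pre",
) -> pd.Series:
    """Per-patient 100 * (later - baseline) / baseline for one measure.

    ``measure`` is ``"fov"`` or a prefixed HRP/RT column such as
    ``"hrp_white"`` / ``"rt_gray"``.  A zero baseline is an error naming
    the patient rather than a silently dropped row.
    """
    df = to_frame(records).set_index("id")
    def col(t): return measure if measure.count("_") == 2 else f"{measure}_{t}"
    base = df[col(baseline)]
    late = df[col(later)]
    zero = base == 0
    if zero.any():
        bad = list(df.index[zero])
        raise ZeroDivisionError(
            f"zero baseline {measure} at {baseline} for patient(s) {bad}"
        )
    return 100.0 * (late - base) / base


def classify_responders(
    records: list[PatientRecord], later: str = "post"
) -> list[ResponderLabel]:
    """Label each patient by the sign of FOV percentage change vs baseline.

    Responder iff the FOV percentage change (``later`` vs Pre) is > 0.
    The comparison time point defaults to Post and is a parameter.
    """
    pct = percentage_change(records, "fov", later=later, baseline="pre")
    return [
        ResponderLabel(id=r.id, responder=bool(pct[r.id] > 0),
                       fov_pct_change=float(pct[r.id]))
        for r in records
    ]


def responder_counts(labels: list[ResponderLabel]) -> tuple[int, int]:
    """(n_responders, n_non_responders)."""
    n_resp = sum(lab.responder for lab in labels)
    return n_resp, len(labels) - n_resp
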