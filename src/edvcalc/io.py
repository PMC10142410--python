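"""Delimited-text readers and writers for subject tables and results.

Canonical schema (header names matched case-insensitively):

    subject_id, sbp, dbp, pep_ms, et_ms, sv_ml, edv_ref_ml

Pressures in mmHg, timings in milliseconds, volumes in ml; dot decimal
separator regardless of locale.  ``edv_ref_ml`` is optional.  Rows with
unparseable or missing required numerics are flagged, never silently
coerced or dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .model import BeatObservation
from .pipeline import SubjectResult

__all__ = [
    "SubjectTable",
    "SchemaError",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_subjects",
    "write_subjects",
    "write_results",
    "write_cohort",
]

REQUIRED_COLUMNS = ("subject_id", "sbp", "dbp", "pep_ms", "et_ms", "sv_ml")
OPTIONAL_COLUMNS = ("edv_ref_ml",)


class SchemaError(ValueError):
    """The input file's header does not match the subject-table schema."""


@dataclass
class SubjectTable:
    """Ordered observations plus provenance and per-row parse flags."""

    observations: list[BeatObservation]
    source: str = ""
    flags: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)


def _to_float(value: object) -> Optional[float]:
    """Parse one cell; None for blank/NaN, raises ValueError if unparseable."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("nan", "na"):
        return None
    return float(s)


def read_subjects(
    path: str | Path,
    delimiter: str = ",",
    timings_seconds: bool = False,
) -> SubjectTable:
    """Read a subject table from delimited text.

    ``timings_seconds=True`` converts pep/et columns from seconds to
    milliseconds on read.  Missing optional ``edv_ref_ml`` is allowed;
    missing or unparseable required values flag the row ("missing data")
    so downstream exclusion filtering can report it.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"{path}: missing required column(s) {missing_cols}; "
            f"header found: {list(df.columns)}"
        )

    time_factor = 1000.0 if timings_seconds else 1.0
    observations: list[BeatObservation] = []
    flags: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, after the header line
        values: dict[str, Optional[float]] = {}
        bad: list[str] = []
        for col in ("sbp", "dbp", "pep_ms", "et_ms", "sv_ml", "edv_ref_ml"):
            raw = row.get(col)
            try:
                values[col] = _to_float(raw)
            except ValueError:
                values[col] = None
                bad.append(f"{col}={raw!r}")
        obs = BeatObservation(
            subject_id=str(row["subject_id"]).strip(),
            sbp=values["sbp"],
            dbp=values["dbp"],
            pep=None if values["pep_ms"] is None else values["pep_ms"] * time_factor,
            et=None if values["et_ms"] is None else values["et_ms"] * time_factor,
            sv=values["sv_ml"],
            edv_ref=values["edv_ref_ml"],
        )
        if bad:
            flags.append((rownum, f"unparseable: {', '.join(bad)}"))
        elif not obs.complete:
            flags.append((rownum, f"missing data: {', '.join(obs.missing_fields())}"))
        observations.append(obs)
    return SubjectTable(observations=observations, source=str(path), flags=flags)


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.6g}"


def write_subjects(table: Sequence[BeatObservation], path: str | Path) -> None:
    """Write observations in the canonical schema (6 significant digits)."""
    rows = [
        {
            "subject_id": o.subject_id,
            "sbp": _fmt(o.sbp),
            "dbp": _fmt(o.dbp),
            "pep_ms": _fmt(o.pep),
            "et_ms": _fmt(o.et),
            "sv_ml": _fmt(o.sv),
            "edv_ref_ml": _fmt(o.edv_ref),
        }
        for o in table
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results(results: Sequence[SubjectResult], path: str | Path) -> None:
    """Write per-subject estimates with all audit intermediates."""
    rows = []
    for r in results:
        o = r.observation
        c, e = r.coupling, r.estimate
        rows.append(
            {
                "subject_id": o.subject_id,
                "sbp": _fmt(o.sbp),
                "dbp": _fmt(o.dbp),
                "pep_ms": _fmt(o.pep),
                "et_ms": _fmt(o.et),
                "sv_ml": _fmt(o.sv),
                "edv_ref_ml": _fmt(o.edv_ref),
                "pes_mmhg": _fmt(c.pes if c else None),
                "pmax_mmhg": _fmt(c.pmax if c else None),
                "ees_over_ea": _fmt(c.ees_over_ea if c else None),
                "k": _fmt(c.k if c else None),
                "solver_iterations": c.iterations if c else "",
                "edv_calc_ml": _fmt(e.edv_calc if e else None),
                "esv_calc_ml": _fmt(e.esv_calc if e else None),
                "excluded": str(r.excluded).lower(),
                "exclusion_reason": r.exclusion_reason,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cohort(
    pairs: Sequence[tuple],
    obs_path: str | Path,
    truth_path: Optional[str | Path] = None,
) -> None:
    """Write a simulated cohort: observations, and optionally ground truth."""
    write_subjects([obs for _, obs in pairs], obs_path)
    if truth_path is not None:
        rows = [
            {
                "subject_id": obs.subject_id,
                "ees_mmhg_per_ml": f"{gt.ees:.6g}",
                "ea_mmhg_per_ml": f"{gt.ea:.6g}",
                "ees_over_ea": f"{gt.ratio:.6g}",
                "edv_ml": f"{gt.edv:.6g}",
                "sv_ml": f"{gt.sv:.6g}",
                "v0_ml": f"{gt.v0:.6g}",
                "pad_mmhg": f"{gt.pad:.6g}",
                "pep_ms": f"{gt.pep:.6g}",
            }
            for gt, obs in pairs
        ]
        pd.DataFrame(rows).to_csv(truth_path, index=False)
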