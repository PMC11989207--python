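"""Read, validate and write patient-level cohort tables.

Cohorts are comma-delimited UTF-8 text with a header row of canonical
column names; an empty cell is a missing value; times are months.
Invalid cells never crash a read and are never silently coerced: each
yields a structured :class:`Finding` naming the row and column, and the
corresponding record field is left missing.  Only a missing mandatory
column (``patient_id``, ``ct_stage``) or a duplicate patient id aborts
the read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .staging import PatientRecord, encode_n_stage, encode_t_stage

__all__ = ["COLUMNS", "Finding", "CohortReadError", "read_cohort",
           "records_to_frame", "write_cohort", "write_scored_cohort"]

COLUMNS = [
    "patient_id", "ct_stage", "cn_stage", "ypt_stage", "ypn_stage",
    "rt_post_stage", "rn_post_stage", "mrtrg", "ptrg",
    "cd3_ct", "cd3_im", "cd8_ct", "cd8_im", "grade",
    "dfs_months", "dfs_event", "os_months", "os_event",
]

SCORE_COLUMNS = [
    "is_mean_percentile", "is_class", "nar_path", "nar_path_cat",
    "nar_rad", "nar_rad_cat", "pcr", "near_pcr", "combined_stratum",
]

_MANDATORY = ("patient_id", "ct_stage")

_STAGE_FIELDS = {
    "ct_stage": ("ct", encode_t_stage),
    "cn_stage": ("cn", encode_n_stage),
    "ypt_stage": ("ypt", encode_t_stage),
    "ypn_stage": ("ypn", encode_n_stage),
    "rt_post_stage": ("rt_post", encode_t_stage),
    "rn_post_stage": ("rn_post", encode_n_stage),
}
_INT_FIELDS = {"mrtrg": "mrtrg", "ptrg": "ptrg", "grade": "grade",
               "dfs_event": "dfs_event", "os_event": "os_event"}
_FLOAT_FIELDS = {"cd3_ct": "cd3_ct", "cd3_im": "cd3_im", "cd8_ct": "cd8_ct",
                 "cd8_im": "cd8_im", "dfs_months": "dfs_months",
                 "os_months": "os_months"}


class CohortReadError(ValueError):
    """Structural problem that prevents reading a cohort file."""


@dataclass(frozen=True)
class Finding:
    """One row-level validation problem (the field is set missing)."""

    row: int          # 0-based data-row index
    column: str
    value: str
    message: str


def read_cohort(path: Union[str, Path]
                ) -> Tuple[List[PatientRecord], List[Finding]]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    Returns ``(records, findings)``.  Unknown columns are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise CohortReadError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False,
                     encoding="utf-8")
    for col in _MANDATORY:
        if col not in df.columns:
            raise CohortReadError(f"mandatory column missing: {col!r}")
    ids = df["patient_id"].tolist()
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise CohortReadError(f"duplicate patient_id values: {sorted(dupes)}")

    records: List[PatientRecord] = []
    findings: List[Finding] = []
    for i, row in df.iterrows():
        kwargs: Dict[str, object] = {"patient_id": row["patient_id"].strip()}

        def cell(col: str) -> Optional[str]:
            if col not in df.columns:
                return None
            v = str(row[col]).strip()
            return v if v != "" else None

        for col, (attr, encoder) in _STAGE_FIELDS.items():
            v = cell(col)
            if v is None:
                continue
            try:
                encoder(v)  # validate only; records keep the text label
                kwargs[attr] = v
            except ValueError as exc:
                findings.append(Finding(int(i), col, v, str(exc)))
        for col, attr in _INT_FIELDS.items():
            v = cell(col)
            if v is None:
                continue
            try:
                kwargs[attr] = int(v)
            except ValueError:
                findings.append(Finding(int(i), col, v, "not an integer"))
        for col, attr in _FLOAT_FIELDS.items():
            v = cell(col)
            if v is None:
                continue
            try:
                kwargs[attr] = float(v)
            except ValueError:
                findings.append(Finding(int(i), col, v, "not a number"))
        try:
            records.append(PatientRecord(**kwargs))
        except ValueError as exc:
            # range violation caught at record level: drop offending fields
            findings.append(Finding(int(i), "record", row["patient_id"],
                                    str(exc)))
            records.append(PatientRecord(patient_id=row["patient_id"].strip(),
                                         ct=kwargs.get("ct")))
    return records, findings


def _fmt(v, decimals: int = 3) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return f"{v:.{decimals}f}"
    return str(v)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Render records to a string DataFrame in the canonical column layout."""
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "ct_stage": _fmt(r.ct), "cn_stage": _fmt(r.cn),
            "ypt_stage": _fmt(r.ypt), "ypn_stage": _fmt(r.ypn),
            "rt_post_stage": _fmt(r.rt_post), "rn_post_stage": _fmt(r.rn_post),
            "mrtrg": _fmt(r.mrtrg), "ptrg": _fmt(r.ptrg),
            "cd3_ct": _fmt(r.cd3_ct), "cd3_im": _fmt(r.cd3_im),
            "cd8_ct": _fmt(r.cd8_ct), "cd8_im": _fmt(r.cd8_im),
            "grade": _fmt(r.grade),
            "dfs_months": _fmt(r.dfs_months), "dfs_event": _fmt(r.dfs_event),
            "os_months": _fmt(r.os_months), "os_event": _fmt(r.os_event),
        })
    return pd.DataFrame(rows, columns=COLUMNS, dtype=str)


def write_cohort(records: Sequence[PatientRecord],
                 path: Union[str, Path]) -> None:
    """Write records as a canonical cohort CSV (empty cell = missing)."""
    records_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def write_scored_cohort(records: Sequence[PatientRecord],
                        results: Sequence, path: Union[str, Path]) -> None:
    """Write a cohort CSV with per-patient score columns appended.

    ``results`` are :class:`larcscore.pipeline.ScoredRecord` objects
    aligned with ``records``; numeric score values use 3 decimal places.
    """
    if len(records) != len(results):
        raise ValueError("records and results must be aligned")
    df = records_to_frame(records)
    df["is_mean_percentile"] = [
        _fmt(s.immunoscore.mean_percentile if s.immunoscore else None)
        for s in results]
    df["is_class"] = [s.immunoscore.is_class if s.immunoscore else ""
                      for s in results]
    df["nar_path"] = [_fmt(s.nar_path.value if s.nar_path else None)
                      for s in results]
    df["nar_path_cat"] = [s.nar_path.category if s.nar_path else ""
                          for s in results]
    df["nar_rad"] = [_fmt(s.nar_rad.value if s.nar_rad else None)
                     for s in results]
    df["nar_rad_cat"] = [s.nar_rad.category if s.nar_rad else ""
                         for s in results]
    df["pcr"] = [_fmt(s.pcr) for s in results]
    df["near_pcr"] = [_fmt(s.near_pcr) for s in results]
    df["combined_stratum"] = [s.combined_stratum or "" for s in results]
    df.to_csv(path, index=False, encoding="utf-8")
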