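"""End-to-end orchestration: score a cohort and run the response analyses.

``score_cohort`` attaches per-patient results (immunoscore, pathologic
and radiologic NAR, endpoints, combined stratum) to validated records,
computing density percentiles cohort-wide per marker-region.
``analyze`` assembles the full report: prevalences, conditional pCR
rates, NAR x pCR contingency tables with exact-test p-values, and -- when
follow-up is present -- Kaplan-Meier summaries with log-rank tests by NAR
category and for the near-pCR comparison.  Every analysis uses its own
complete-case denominator, reported alongside the statistic.

``analyze_printed_tables`` runs the same contingency statistics on the
as-printed NAR and grade tables from the trial report, surfacing the
13-vs-15 pCR count discrepancy of the printed record as a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import scoring, stats, synthetic
from .staging import (PatientRecord, derive_near_pcr, derive_pcr,
                      encode_n_stage, encode_t_stage, is_radiologic_complete)

__all__ = ["ScoredRecord", "AnalysisReport", "score_cohort", "analyze",
           "analyze_printed_tables"]

logger = logging.getLogger("larcscore")

NAR_CATEGORIES = ("low", "intermediate", "high")


@dataclass(frozen=True)
class ScoredRecord:
    """A patient record with every derivable score and endpoint attached."""

    record: PatientRecord
    immunoscore: Optional[scoring.ImmunoscoreResult]
    nar_path: Optional[scoring.NarResult]
    nar_rad: Optional[scoring.NarResult]
    pcr: Optional[bool]
    near_pcr: Optional[bool]
    radiologic_complete: Optional[bool]
    combined_stratum: Optional[str]


def score_cohort(records: Sequence[PatientRecord]) -> List[ScoredRecord]:
    """Attach immunoscore, NAR scores, endpoints and strata to records.

    Density percentiles are computed across the cohort per marker-region
    over the patients with that marker present; the immunoscore needs all
    four.  Missing inputs yield missing outputs.
    """
    markers = ("cd3_ct", "cd3_im", "cd8_ct", "cd8_im")
    pct: Dict[str, Dict[str, float]] = {m: {} for m in markers}
    for m in markers:
        present = [(r.patient_id, getattr(r, m)) for r in records
                   if getattr(r, m) is not None]
        if present:
            values = [v for _, v in present]
            for (pid, _), p in zip(present, scoring.percentile_ranks(values)):
                pct[m][pid] = p
    if records and not any(r.has_densities() for r in records):
        logger.warning("no patient has a complete CD3/CD8 density set; "
                       "immunoscore skipped")

    out: List[ScoredRecord] = []
    for r in records:
        is_res = None
        if all(r.patient_id in pct[m] for m in markers):
            is_res = scoring.immunoscore(*(pct[m][r.patient_id]
                                           for m in markers))
        nar_p = None
        if None not in (r.ct, r.ypt, r.ypn):
            nar_p = scoring.nar_pathologic(encode_t_stage(r.ct),
                                           encode_t_stage(r.ypt),
                                           encode_n_stage(r.ypn))
        nar_r = None
        if None not in (r.ct, r.rt_post, r.rn_post):
            nar_r = scoring.nar_radiologic(encode_t_stage(r.ct),
                                           encode_t_stage(r.rt_post),
                                           encode_n_stage(r.rn_post))
        pcr = derive_pcr(r.ptrg, r.ypn)
        out.append(ScoredRecord(
            record=r,
            immunoscore=is_res,
            nar_path=nar_p,
            nar_rad=nar_r,
            pcr=pcr,
            near_pcr=derive_near_pcr(r.ptrg),
            radiologic_complete=is_radiologic_complete(r.mrtrg),
            combined_stratum=scoring.combined_stratum(
                is_res.is_class if is_res else None, r.mrtrg),
        ))
    return out


def _proportion(count: int, n: int) -> Dict[str, float]:
    return {"count": int(count), "n": int(n),
            "ratio": count / n if n else float("nan"),
            "pct": round(100.0 * count / n, 1) if n else float("nan")}


def _rate_block(flags: Sequence[Optional[bool]]) -> Optional[Dict[str, float]]:
    cc = [f for f in flags if f is not None]
    if not cc:
        return None
    return _proportion(sum(cc), len(cc))


@dataclass
class AnalysisReport:
    """Structured results mirroring the trial's Results section."""

    data: Dict[str, object]
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict[str, object]:
        return {"report": self.data, "warnings": list(self.warnings)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=_jsonable)

    def to_text(self) -> str:
        lines: List[str] = ["Response-scoring analysis report",
                            "=" * 40]
        _render(self.data, lines, indent=0)
        if self.warnings:
            lines.append("")
            lines.append("Warnings:")
            lines += [f"  - {w}" for w in self.warnings]
        return "\n".join(lines)

    def validate_percentages(self) -> None:
        """Every emitted percentage must equal its count ratio x100 within 0.05."""
        def walk(node):
            if isinstance(node, dict):
                if {"count", "n", "pct"} <= node.keys() and node["n"]:
                    raw = 100.0 * node["count"] / node["n"]
                    if abs(node["pct"] - raw) > 0.05:
                        raise AssertionError(
                            f"percentage {node['pct']} inconsistent with "
                            f"{node['count']}/{node['n']}")
                for v in node.values():
                    walk(v)
            elif isinstance(node, (list, tuple)):
                for v in node:
                    walk(v)
        walk(self.data)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def _render(node, lines: List[str], indent: int) -> None:
    pad = "  " * indent
    if isinstance(node, dict):
        if {"count", "n", "pct"} <= node.keys():
            lines[-1] += f" {node['count']}/{node['n']} ({node['pct']}%)"
            return
        for k, v in node.items():
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}{k}:")
                _render(v, lines, indent + 1)
            else:
                lines.append(f"{pad}{k}: {v}")
    elif isinstance(node, list):
        for v in node:
            lines.append(f"{pad}-")
            _render(v, lines, indent + 1)
    else:
        lines.append(f"{pad}{node}")


def _nar_table_block(scored: Sequence[ScoredRecord], variant: str,
                     warnings_out: List[str]) -> Dict[str, object]:
    """pCR x NAR-category crosstab with Freeman-Halton exact p."""
    cats, pcrs = [], []
    for s in scored:
        nar = s.nar_path if variant == "pathologic" else s.nar_rad
        cats.append(nar.category if nar else None)
        pcrs.append(None if s.pcr is None else ("pCR" if s.pcr else "non-pCR"))
    try:
        table = stats.crosstab(pcrs, cats, row_order=("non-pCR", "pCR"),
                               col_order=NAR_CATEGORIES)
    except ValueError:
        warnings_out.append(f"{variant} NAR x pCR table not computable "
                            "(empty complete-case denominator)")
        return {"computable": False}
    return _table_with_test(table)


def _table_with_test(table: stats.ContingencyTable) -> Dict[str, object]:
    arr = table.to_array()
    rows = {}
    for label, row in zip(table.row_labels, arr):
        n_row = int(row.sum())
        rows[label] = {col: _proportion(int(c), n_row)
                       for col, c in zip(table.col_labels, row)}
    res = stats.fisher_exact(table)
    return {"computable": True, "counts": [list(map(int, r)) for r in arr],
            "row_labels": list(table.row_labels),
            "col_labels": list(table.col_labels),
            "row_percentages": rows, "n": table.total,
            "exact_p": res.p_value,
            "n_tables_enumerated": res.n_tables_enumerated}


def _survival_block(scored: Sequence[ScoredRecord], variant: str,
                    endpoint: str) -> Dict[str, object]:
    """KM event-free proportions at end of follow-up + log-rank by NAR category."""
    time_attr = f"{endpoint}_months"
    event_attr = f"{endpoint}_event"
    groups: Dict[str, List] = {c: ([], []) for c in NAR_CATEGORIES}
    for s in scored:
        nar = s.nar_path if variant == "pathologic" else s.nar_rad
        t = getattr(s.record, time_attr)
        e = getattr(s.record, event_attr)
        if nar is None or t is None or e is None:
            continue
        groups[nar.category][0].append(t)
        groups[nar.category][1].append(e)
    nonempty = {c: g for c, g in groups.items() if g[0]}
    if not nonempty:
        return {"computable": False}
    all_t = [t for g in nonempty.values() for t in g[0]]
    horizon = max(all_t)
    block: Dict[str, object] = {"computable": True, "horizon_months": horizon,
                                "event_free": {}}
    for c, (t, e) in nonempty.items():
        block["event_free"][c] = {
            "n": len(t), "n_events": int(sum(e)),
            "proportion": stats.event_free_proportion(t, e, horizon)}
    if len(nonempty) >= 2:
        chi2, df, p = stats.logrank_test(list(nonempty.values()))
        block["logrank"] = {"chi2": chi2, "df": df, "p": p}
    return block


def _near_pcr_block(scored: Sequence[ScoredRecord]) -> Dict[str, object]:
    groups = {True: ([], []), False: ([], [])}
    for s in scored:
        t, e = s.record.dfs_months, s.record.dfs_event
        if s.near_pcr is None or t is None or e is None:
            continue
        groups[s.near_pcr][0].append(t)
        groups[s.near_pcr][1].append(e)
    if not (groups[True][0] and groups[False][0]):
        return {"computable": False}
    horizon = max(t for g in groups.values() for t in g[0])
    chi2, df, p = stats.logrank_test([groups[True], groups[False]])
    return {"computable": True, "horizon_months": horizon,
            "event_free": {
                "near_pcr": {"n": len(groups[True][0]),
                             "proportion": stats.event_free_proportion(
                                 *groups[True], horizon)},
                "not_near_pcr": {"n": len(groups[False][0]),
                                 "proportion": stats.event_free_proportion(
                                     *groups[False], horizon)}},
            "logrank": {"chi2": chi2, "df": df, "p": p}}


def analyze(scored: Sequence[ScoredRecord]) -> AnalysisReport:
    """Run every response analysis computable from the scored cohort."""
    warnings_out: List[str] = []
    data: Dict[str, object] = {}

    data["prevalence"] = {
        "pcr": _rate_block([s.pcr for s in scored]),
        "mrtrg1": _rate_block([s.radiologic_complete for s in scored]),
        "is_high": _rate_block([
            None if s.immunoscore is None else s.immunoscore.is_class == "high"
            for s in scored]),
        "near_pcr": _rate_block([s.near_pcr for s in scored]),
    }
    data["pcr_rate_by_group"] = {
        "mrtrg1": _rate_block([s.pcr for s in scored
                               if s.radiologic_complete]),
        "is_high": _rate_block([s.pcr for s in scored if s.immunoscore
                                and s.immunoscore.is_class == "high"]),
        "is_high_and_mrtrg1": _rate_block(
            [s.pcr for s in scored
             if s.combined_stratum == "is_high_and_trg1"]),
    }
    data["nar_tables"] = {
        "pathologic": _nar_table_block(scored, "pathologic", warnings_out),
        "radiologic": _nar_table_block(scored, "radiologic", warnings_out),
    }
    data["survival"] = {
        variant: {endpoint: _survival_block(scored, variant, endpoint)
                  for endpoint in ("dfs", "os")}
        for variant in ("pathologic", "radiologic")
    }
    data["near_pcr_dfs"] = _near_pcr_block(scored)

    grades = [s.record.grade for s in scored]
    if any(g is not None for g in grades):
        pcr_labels = [None if s.pcr is None else
                      ("pCR" if s.pcr else "non-pCR") for s in scored]
        try:
            table = stats.crosstab(pcr_labels, grades,
                                   row_order=("non-pCR", "pCR"))
            data["grade_by_pcr"] = _table_with_test(table)
        except ValueError:
            data["grade_by_pcr"] = {"computable": False}

    report = AnalysisReport(data=data, warnings=warnings_out)
    for w in warnings_out:
        logger.warning(w)
    report.validate_percentages()
    return report


def analyze_printed_tables(headline_pcr_count: int = 15) -> AnalysisReport:
    """Contingency statistics on the trial report's as-printed tables.

    The printed NAR and grade tables imply 13 pCR patients while the
    headline count is 15; the discrepancy is preserved and surfaced as a
    warning (it cannot be resolved from the printed record).
    """
    warnings_out: List[str] = []
    pathologic, radiologic = synthetic.paper_fixture_nar_tables()
    data: Dict[str, object] = {
        "nar_tables": {"pathologic": _table_with_test(pathologic),
                       "radiologic": _table_with_test(radiologic)},
    }
    grade = synthetic.paper_fixture_grade()
    n_pcr = sum(grade["pcr"].values())
    n_non = sum(grade["non_pcr"].values())
    data["grade_by_pcr"] = {
        "pcr": {f"grade{g}": _proportion(c, n_pcr)
                for g, c in sorted(grade["pcr"].items())},
        "non_pcr": {f"grade{g}": _proportion(c, n_non)
                    for g, c in sorted(grade["non_pcr"].items())},
    }
    table_pcr = int(pathologic.to_array()[1].sum())
    if table_pcr != headline_pcr_count or n_pcr != headline_pcr_count:
        warnings_out.append(
            f"printed NAR/grade tables imply {table_pcr} pCR patients but the "
            f"headline count is {headline_pcr_count}; the printed record is "
            "internally inconsistent and is reported as-is")
    report = AnalysisReport(data=data, warnings=warnings_out)
    for w in warnings_out:
        logger.warning(w)
    report.validate_percentages()
    return report
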