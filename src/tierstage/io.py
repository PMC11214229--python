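"""Reading and writing the delimited-text registry interchange tables.

Three input tables (UTF-8, header row, case-insensitive column names):

* pathology: ``case_id, diagnosis_date, site, tnm_string`` *or* separate
  ``t, n, m, prefix`` columns; any extra columns are carried as
  tumour-specific fields.
* admissions: ``case_id, admission_date, codes`` (semicolon-joined).
* clinical: ``case_id, record_date, tnm_string[, stage_group]``.

A JSON-lines alternative stores one whole bundle per line.  Output is one
row per staged case, as CSV and JSON lines.
"""

from __future__ import annotations

import json
from dataclasses import replace
from datetime import date
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from tierstage.model import (
    AdmissionRecord,
    CaseBundle,
    ClinicalRecord,
    PathologyRecord,
    StagedCase,
    TNMAssertion,
    bundle_from_dict,
    bundle_to_dict,
)
from tierstage.tnm import AXES, format_assertion, normalize_category, parse_tnm_string


class SchemaError(ValueError):
    """An input table violates the documented schema."""


def _read_table(path, required: tuple[str, ...], optional: tuple[str, ...] = ()
                ) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_date(text: str, path, column: str) -> Optional[date]:
    text = (text or "").strip()
    if not text:
        return None
    try:
        return date.fromisoformat(text)
    except ValueError as exc:
        raise SchemaError(f"{path}: bad ISO date {text!r} in column {column}") from exc


def _pathology_assertion(row: pd.Series, record_date, path) -> TNMAssertion:
    if "tnm_string" in row.index and str(row["tnm_string"]).strip():
        return parse_tnm_string(str(row["tnm_string"]), source="pathology",
                                record_date=record_date)
    components = []
    prefix = str(row.get("prefix", "") or "").strip().lower() or "p"
    for axis in AXES:
        raw = str(row.get(axis.lower(), "") or "").strip()
        if raw:
            components.append(replace(normalize_category(axis, raw), prefix=prefix))
    return TNMAssertion(components=tuple(components), source="pathology",
                        record_date=record_date,
                        post_therapy="y" in prefix)


_RESERVED_PATHOLOGY = {"case_id", "diagnosis_date", "site", "record_date",
                       "tnm_string", "t", "n", "m", "prefix"}


def read_bundles(pathology_path, admissions_path=None, clinical_path=None
                 ) -> list[CaseBundle]:
    """Assemble case bundles from the three delimited tables.

    Admissions and clinical rows are matched to cases by ``case_id`` only;
    rows for unknown case ids are ignored.  Order follows the pathology
    table's first occurrence of each case id.
    """
    pdf = _read_table(pathology_path, ("case_id", "diagnosis_date", "site"))
    cases: dict[str, dict] = {}
    order: list[str] = []
    for _, row in pdf.iterrows():
        cid = str(row["case_id"]).strip()
        if cid not in cases:
            cases[cid] = {
                "site": str(row["site"]).strip().lower() or None,
                "diagnosis_date": _parse_date(row["diagnosis_date"],
                                              pathology_path, "diagnosis_date"),
                "pathology": [], "admissions": [], "clinical": [],
            }
            order.append(cid)
        rec_date = (_parse_date(row["record_date"], pathology_path, "record_date")
                    if "record_date" in row.index else None) \
            or cases[cid]["diagnosis_date"]
        fields = {c: str(row[c]) for c in pdf.columns
                  if c not in _RESERVED_PATHOLOGY and str(row[c]).strip()}
        cases[cid]["pathology"].append(PathologyRecord(
            _pathology_assertion(row, rec_date, pathology_path), fields))

    if admissions_path is not None:
        adf = _read_table(admissions_path, ("case_id", "admission_date", "codes"))
        for _, row in adf.iterrows():
            cid = str(row["case_id"]).strip()
            if cid not in cases:
                continue
            codes = tuple(c.strip() for c in str(row["codes"]).split(";")
                          if c.strip())
            cases[cid]["admissions"].append(AdmissionRecord(
                _parse_date(row["admission_date"], admissions_path,
                            "admission_date"), codes))

    if clinical_path is not None:
        cdf = _read_table(clinical_path, ("case_id", "record_date", "tnm_string"))
        for _, row in cdf.iterrows():
            cid = str(row["case_id"]).strip()
            if cid not in cases:
                continue
            rec_date = _parse_date(row["record_date"], clinical_path, "record_date")
            stage = str(row.get("stage_group", "") or "").strip() or None
            cases[cid]["clinical"].append(ClinicalRecord(
                parse_tnm_string(str(row["tnm_string"]), source="clinical",
                                 record_date=rec_date), stage))

    return [
        CaseBundle(
            case_id=cid, site=c["site"], diagnosis_date=c["diagnosis_date"],
            pathology_records=tuple(c["pathology"]),
            admission_records=tuple(c["admissions"]),
            clinical_records=tuple(c["clinical"]),
        )
        for cid, c in ((cid, cases[cid]) for cid in order)
    ]


def write_bundle_tables(bundles: Iterable[CaseBundle], out_dir) -> dict[str, Path]:
    """Write bundles back out as the three interchange tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prows, arows, crows = [], [], []
    for b in bundles:
        for rec in b.pathology_records:
            prows.append({
                "case_id": b.case_id,
                "diagnosis_date": b.diagnosis_date.isoformat() if b.diagnosis_date else "",
                "site": b.site or "",
                "record_date": (rec.assertion.record_date.isoformat()
                                if rec.assertion.record_date else ""),
                "tnm_string": format_assertion(rec.assertion.components),
                **dict(rec.fields),
            })
        for rec in b.admission_records:
            arows.append({
                "case_id": b.case_id,
                "admission_date": rec.admission_date.isoformat(),
                "codes": ";".join(rec.codes),
            })
        for rec in b.clinical_records:
            crows.append({
                "case_id": b.case_id,
                "record_date": (rec.assertion.record_date.isoformat()
                                if rec.assertion.record_date else ""),
                "tnm_string": format_assertion(rec.assertion.components),
                "stage_group": rec.reported_stage or "",
            })
    paths = {}
    for name, rows, cols in (
        ("pathology", prows, ["case_id", "diagnosis_date", "site",
                              "record_date", "tnm_string"]),
        ("admissions", arows, ["case_id", "admission_date", "codes"]),
        ("clinical", crows, ["case_id", "record_date", "tnm_string",
                             "stage_group"]),
    ):
        path = out_dir / f"{name}.csv"
        df = pd.DataFrame(rows)
        if df.empty:
            df = pd.DataFrame(columns=cols)
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def read_bundles_jsonl(path) -> list[CaseBundle]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(bundle_from_dict(json.loads(line)))
    return out


def write_bundles_jsonl(bundles: Iterable[CaseBundle], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for b in bundles:
            fh.write(json.dumps(bundle_to_dict(b), sort_keys=True) + "\n")


def staged_to_frame(cases: Iterable[StagedCase]) -> pd.DataFrame:
    rows = []
    for c in cases:
        row = {
            "case_id": c.case_id,
            "site": c.site or "",
            "stage_group": c.stage_group or "",
            "umbrella_only": c.umbrella_only,
            "tier": c.tier,
            "assumptions": ";".join(c.assumptions_applied),
            "post_therapy": c.post_therapy,
            "reason": c.reason or "",
        }
        for axis in AXES:
            comp = c.final.get(axis)
            row[axis.lower()] = str(comp) if comp is not None else ""
            prov = c.provenance.get(axis)
            row[f"{axis.lower()}_source"] = prov.source if prov else ""
        rows.append(row)
    cols = ["case_id", "site", "t", "n", "m", "stage_group", "umbrella_only",
            "tier", "assumptions", "t_source", "n_source", "m_source",
            "post_therapy", "reason"]
    return pd.DataFrame(rows, columns=cols)


def write_staged(cases: list[StagedCase], out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = staged_to_frame(cases)
    csv_path = out_dir / "staged.csv"
    frame.to_csv(csv_path, index=False, lineterminator="\n")
    jsonl_path = out_dir / "staged.jsonl"
    with open(jsonl_path, "w", encoding="utf-8") as fh:
        for rec in frame.to_dict(orient="records"):
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return {"csv": csv_path, "jsonl": jsonl_path}
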