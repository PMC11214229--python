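"""Domain types shared across the staging engine.

A :class:`CaseBundle` collects everything the registry holds for one case:
structured pathology TNM, coded hospital-admission records, and optional
clinical/MDT records.  The tier engine turns a bundle into a
:class:`StagedCase` carrying the derived TNM, stage group, completeness tier
and per-axis provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Optional, Sequence

from tierstage.ajcc import SITES
from tierstage.tnm import TNMComponent

SOURCES = ("pathology", "admission", "clinical")

TIERS = ("1", "2", "3", "unstageable")


@dataclass(frozen=True)
class TNMAssertion:
    """Up to three prefixed T/N/M components from one source record."""

    components: tuple[TNMComponent, ...]
    source: str
    record_date: Optional[date] = None
    post_therapy: bool = False

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        axes = [c.axis for c in self.components]
        if len(axes) != len(set(axes)):
            raise ValueError("at most one component per axis")
        if self.source == "admission":
            if any(c.subcategory is not None for c in self.components):
                raise ValueError(
                    "admission-sourced components carry no subcategory (binary origin)"
                )
        if any(c.post_therapy for c in self.components) and not self.post_therapy:
            raise ValueError("y-prefixed component requires post_therapy=True")

    def get(self, axis: str) -> Optional[TNMComponent]:
        for c in self.components:
            if c.axis == axis:
                return c
        return None


@dataclass(frozen=True)
class PathologyRecord:
    assertion: TNMAssertion
    # Tumour-specific fields (Breslow depth, hormone receptors, ...) are
    # carried opaquely and checked only for presence, never interpreted.
    fields: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class AdmissionRecord:
    admission_date: date
    codes: tuple[str, ...]


@dataclass(frozen=True)
class ClinicalRecord:
    assertion: TNMAssertion
    reported_stage: Optional[str] = None


@dataclass(frozen=True)
class CaseBundle:
    case_id: str
    site: Optional[str]
    diagnosis_date: Optional[date]
    pathology_records: tuple[PathologyRecord, ...] = ()
    admission_records: tuple[AdmissionRecord, ...] = ()
    clinical_records: tuple[ClinicalRecord, ...] = ()


@dataclass(frozen=True)
class Provenance:
    source: str  # a SOURCES member, or "assumption"
    record_date: Optional[date] = None
    prefix: Optional[str] = None


@dataclass(frozen=True)
class StagedCase:
    case_id: str
    site: Optional[str]
    final: Mapping[str, Optional[TNMComponent]]  # axis -> component or None
    stage_group: Optional[str]
    umbrella_only: bool
    tier: str  # "1", "2", "3" or "unstageable"
    provenance: Mapping[str, Provenance]
    assumptions_applied: tuple[str, ...] = ()
    post_therapy: bool = False
    reason: Optional[str] = None  # why unstageable, when it is

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}")
        if (self.tier == "unstageable") != (self.stage_group is None):
            raise ValueError("tier is 'unstageable' iff stage_group is absent")
        for axis, comp in self.final.items():
            if comp is not None and axis not in self.provenance:
                raise ValueError(f"final {axis} present without provenance")

    @property
    def tier_rank(self) -> int:
        """Numeric tier, unstageable ranking worst (4)."""
        return 4 if self.tier == "unstageable" else int(self.tier)


@dataclass(frozen=True)
class Finding:
    level: str  # "fatal", "warning" or "info"
    code: str
    message: str

    @property
    def fatal(self) -> bool:
        return self.level == "fatal"


def validate_bundle(bundle: CaseBundle,
                    required_fields: Sequence[str] = ()) -> list[Finding]:
    """Check a bundle against the minimum dataset requirements.

    Returns findings rather than raising: fatal findings make the bundle
    unusable for staging (the engine emits the case as unstageable), warnings
    and info findings are advisory.  Pure: equal bundles yield equal findings.
    """
    findings: list[Finding] = []
    if bundle.diagnosis_date is None:
        findings.append(Finding("fatal", "missing_diagnosis_date",
                                "missing diagnosis_date"))
    if bundle.site not in SITES:
        findings.append(Finding("fatal", "unknown_site",
                                f"unknown site {bundle.site!r}; supported: {SITES}"))
    if bundle.diagnosis_date is not None:
        for rec in bundle.admission_records:
            if rec.admission_date < bundle.diagnosis_date:
                findings.append(Finding(
                    "warning", "pre_diagnosis_admission",
                    f"pre-diagnosis admission ignored ({rec.admission_date})"))
        for rec in bundle.pathology_records:
            d = rec.assertion.record_date
            if d is not None and d < bundle.diagnosis_date:
                findings.append(Finding(
                    "warning", "pre_diagnosis_record",
                    f"pre-diagnosis pathology record ignored ({d})"))
    for rec in bundle.admission_records:
        for code in rec.codes:
            if not code or not code[0].isalpha() or not any(ch.isdigit() for ch in code):
                findings.append(Finding("warning", "malformed_code",
                                        f"malformed diagnosis code {code!r}"))
    if required_fields:
        present = set()
        for rec in bundle.pathology_records:
            present.update(k for k, v in rec.fields.items() if str(v).strip())
        for name in required_fields:
            if name not in present:
                findings.append(Finding("info", "missing_tumour_field",
                                        f"tumour-specific field {name!r} missing"))
    return findings


# ---------------------------------------------------------------------------
# Serialisation (JSON-lines bundle interchange; round-trip safe)

def _component_to_dict(c: TNMComponent) -> dict:
    d = {"axis": c.axis, "category": c.category}
    if c.subcategory is not None:
        d["subcategory"] = c.subcategory
    if c.prefix is not None:
        d["prefix"] = c.prefix
    if c.binary:
        d["binary"] = True
    return d


def _component_from_dict(d: Mapping) -> TNMComponent:
    return TNMComponent(axis=d["axis"], category=d["category"],
                        subcategory=d.get("subcategory"),
                        prefix=d.get("prefix"), binary=d.get("binary", False))


def _assertion_to_dict(a: TNMAssertion) -> dict:
    return {
        "components": [_component_to_dict(c) for c in a.components],
        "source": a.source,
        "record_date": a.record_date.isoformat() if a.record_date else None,
        "post_therapy": a.post_therapy,
    }


def _assertion_from_dict(d: Mapping) -> TNMAssertion:
    return TNMAssertion(
        components=tuple(_component_from_dict(c) for c in d["components"]),
        source=d["source"],
        record_date=date.fromisoformat(d["record_date"]) if d.get("record_date") else None,
        post_therapy=d.get("post_therapy", False),
    )


def bundle_to_dict(bundle: CaseBundle) -> dict:
    return {
        "case_id": bundle.case_id,
        "site": bundle.site,
        "diagnosis_date": (bundle.diagnosis_date.isoformat()
                           if bundle.diagnosis_date else None),
        "pathology_records": [
            {"assertion": _assertion_to_dict(r.assertion),
             "fields": dict(r.fields)}
            for r in bundle.pathology_records
        ],
        "admission_records": [
            {"admission_date": r.admission_date.isoformat(),
             "codes": list(r.codes)}
            for r in bundle.admission_records
        ],
        "clinical_records": [
            {"assertion": _assertion_to_dict(r.assertion),
             "reported_stage": r.reported_stage}
            for r in bundle.clinical_records
        ],
    }


def bundle_from_dict(d: Mapping) -> CaseBundle:
    return CaseBundle(
        case_id=d["case_id"],
        site=d.get("site"),
        diagnosis_date=(date.fromisoformat(d["diagnosis_date"])
                        if d.get("diagnosis_date") else None),
        pathology_records=tuple(
            PathologyRecord(_assertion_from_dict(r["assertion"]),
                            dict(r.get("fields", {})))
            for r in d.get("pathology_records", [])
        ),
        admission_records=tuple(
            AdmissionRecord(date.fromisoformat(r["admission_date"]),
                            tuple(r.get("codes", [])))
            for r in d.get("admission_records", [])
        ),
        clinical_records=tuple(
            ClinicalRecord(_assertion_from_dict(r["assertion"]),
                           r.get("reported_stage"))
            for r in d.get("clinical_records", [])
        ),
    )
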