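"""Tiered derivation of stage at diagnosis for one case or a cohort.

For each case the engine (i) filters every source record to the staging
window, (ii) resolves per-axis conflicts by decision-tree logic — favouring
more advanced TNM values, with stated values always beating unassessable X —
(iii) applies the registry-derived-stage absence assumptions (NX=N0, MX=M0;
T is never assumed), (iv) maps the final TNM to an AJCC 8e stage group, and
(v) assigns a completeness tier:

* **Tier 1 — complete AJCC TNM**: stage derived at sub-stage level, every
  axis either explicitly stated or a *corroborated* absence (the in-window
  admission stream was reviewed and silent), with at least one
  clinical-grade signal (clinical record, clinical-prefixed value carried in
  a pathology report, or in-window admission data) and any required
  tumour-specific fields present.
* **Tier 2 — registry-derived stage**: stage derivable only with admission
  supplementation and/or uncorroborated absence assumptions, or only at the
  umbrella (main stage category) level.
* **Tier 3 — pathology stage**: stage from pathology pTNM alone, with no
  clinical-grade or admission data in the window.
* **unstageable**: no stage group derivable after supplementation and
  assumptions.

Post-therapy (y-prefixed) assertions are excluded from stage-at-diagnosis
derivation by default: neoadjuvant therapy makes post-resection pTNM
unrepresentative of stage at diagnosis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

from tierstage import ajcc
from tierstage.admissions import CodeMap, StagingWindow, derive_binary_nm, in_window
from tierstage.model import (
    CaseBundle,
    Finding,
    Provenance,
    StagedCase,
    TNMAssertion,
    validate_bundle,
)
from tierstage.tnm import AXES, TNMComponent, advancement_rank

_PRECEDENCE = {"clinical": 2, "pathology": 1, "admission": 0}


@dataclass(frozen=True)
class TierRules:
    """Configurable aspects of tier assignment.

    ``required_fields`` maps site -> tumour-specific field names that must be
    present in a pathology record for Tier 1 (e.g. Breslow depth for
    melanoma); the default demands none.
    """

    required_fields: Mapping[str, Sequence[str]] = field(default_factory=dict)
    #: treat a clinical-prefixed value inside a pathology report (the
    #: pathologist transferring clinical staging into the report) as a
    #: clinical-grade signal — the only way a pathology file yields Tier 1
    #: without other sources.
    clinical_prefix_counts: bool = True


@dataclass(frozen=True)
class EngineConfig:
    window: StagingWindow = StagingWindow()
    #: cross-source conflict rule for stated-vs-stated values:
    #: "advancement" (default: the more advanced value wins, any source) or
    #: "precedence" (clinical > pathology > admission wins regardless).
    cross_source: str = "advancement"
    #: include y-prefixed (post-therapy) assertions in derivation.
    include_post_therapy: bool = False
    rules: TierRules = TierRules()

    def __post_init__(self) -> None:
        if self.cross_source not in ("advancement", "precedence"):
            raise ValueError("cross_source must be 'advancement' or 'precedence'")


@dataclass(frozen=True)
class AxisCandidate:
    component: TNMComponent
    source: str
    record_date: Optional[date] = None


def _sort_key(c: AxisCandidate) -> tuple:
    # more advanced > more specific > higher precedence > earlier record
    day = -(c.record_date.toordinal() if c.record_date else date.max.toordinal())
    return (advancement_rank(c.component),
            0 if c.component.subcategory is None else 1,
            _PRECEDENCE[c.source],
            day)


def resolve_axis(candidates: Sequence[AxisCandidate],
                 cross_source: str = "advancement") -> Optional[AxisCandidate]:
    """Resolve one axis from all in-window assertions.

    Conflicts resolve by advancement (X always loses to a stated value);
    exact ties break to the more specific value, then the higher-precedence
    source (clinical > pathology > admission), then the earliest record.
    Under ``cross_source="precedence"`` a stated value from a
    higher-precedence source wins outright over any lower-precedence value.
    """
    if not candidates:
        return None
    stated = [c for c in candidates if not c.component.is_x]
    if not stated:
        return max(candidates, key=_sort_key)
    if cross_source == "precedence":
        top = max(_PRECEDENCE[c.source] for c in stated)
        stated = [c for c in stated if _PRECEDENCE[c.source] == top]
    return max(stated, key=_sort_key)


def apply_absence_assumptions(
    resolved: Mapping[str, Optional[AxisCandidate]],
) -> tuple[dict[str, Optional[TNMComponent]], dict[str, Provenance], list[str]]:
    """Turn missing/X N and M into N0/M0, recording each assumption.

    T is never assumed.  Returns (final components, provenance, assumptions).
    """
    final: dict[str, Optional[TNMComponent]] = {}
    provenance: dict[str, Provenance] = {}
    assumptions: list[str] = []
    for axis in AXES:
        cand = resolved.get(axis)
        if cand is not None and not cand.component.is_x:
            final[axis] = cand.component
            provenance[axis] = Provenance(cand.source, cand.record_date,
                                          cand.component.prefix)
        elif axis in ("N", "M"):
            final[axis] = TNMComponent(axis, "0")
            provenance[axis] = Provenance("assumption")
            assumptions.append(f"{axis}X->{axis}0")
        else:  # T stays absent; an unassessable TX carries no information
            final[axis] = None
    return final, provenance, assumptions


def _melanoma_context(resolved: Mapping[str, Optional[AxisCandidate]]) -> Optional[str]:
    """Clinical vs pathological grouping context from the winning T/N values.

    Any clinical or admission contribution to T or N selects the clinical
    table; otherwise pathological values select the pathological table; with
    no T/N information both contexts are tried (umbrella fallback).
    """
    flavours = set()
    for axis in ("T", "N"):
        cand = resolved.get(axis)
        if cand is None or cand.component.is_x:
            continue
        prefix = cand.component.prefix or ""
        if cand.source in ("clinical", "admission") or "c" in prefix:
            flavours.add("c")
        elif cand.source == "pathology" or "p" in prefix:
            flavours.add("p")
    if "c" in flavours:
        return "c"
    if "p" in flavours:
        return "p"
    return None


def _unstageable(bundle: CaseBundle, reason: str,
                 post_therapy: bool = False) -> StagedCase:
    return StagedCase(
        case_id=bundle.case_id, site=bundle.site,
        final={a: None for a in AXES}, stage_group=None, umbrella_only=False,
        tier="unstageable", provenance={}, assumptions_applied=(),
        post_therapy=post_therapy, reason=reason,
    )


def stage_case(bundle: CaseBundle,
               tables: Mapping[str, ajcc.AjccStageTable],
               code_map: Optional[CodeMap] = None,
               config: EngineConfig = EngineConfig()) -> StagedCase:
    """Derive the final TNM, stage group and tier for one case."""
    code_map = code_map or CodeMap.default()
    required = tuple(config.rules.required_fields.get(bundle.site, ()))
    findings = validate_bundle(bundle, required_fields=required)
    fatal = [f for f in findings if f.fatal]
    if fatal:
        return _unstageable(bundle, "; ".join(f.message for f in fatal))
    dx = bundle.diagnosis_date
    window = config.window

    def usable(assertion: TNMAssertion) -> bool:
        if assertion.post_therapy and not config.include_post_therapy:
            return False
        if assertion.record_date is not None and not in_window(dx, assertion.record_date, window):
            return False
        return True

    post_therapy_seen = any(
        r.assertion.post_therapy
        for r in (*bundle.pathology_records, *bundle.clinical_records)
    )
    assertions = [r.assertion for r in bundle.pathology_records if usable(r.assertion)]
    clinical_inwindow = [r.assertion for r in bundle.clinical_records
                         if usable(r.assertion)]
    assertions.extend(clinical_inwindow)

    admissions_inwindow = tuple(
        rec for rec in bundle.admission_records
        if in_window(dx, rec.admission_date, window)
    )
    adm_assertion = derive_binary_nm(admissions_inwindow, code_map, bundle.site)
    if adm_assertion is not None:
        assertions.append(adm_assertion)

    candidates: dict[str, list[AxisCandidate]] = {a: [] for a in AXES}
    for assertion in assertions:
        for comp in assertion.components:
            candidates[comp.axis].append(
                AxisCandidate(comp, assertion.source, assertion.record_date))
    resolved = {axis: resolve_axis(cands, config.cross_source)
                for axis, cands in candidates.items()}

    final, provenance, assumptions = apply_absence_assumptions(resolved)

    table = tables[bundle.site]
    context = _melanoma_context(resolved) if table.contexts_differ() else "p"
    result = ajcc.stage_group(table, final["T"], final["N"], final["M"],
                              context=context)

    umbrella_only = result.umbrella_only
    stage = result.stage
    admission_sourced = any(
        provenance[a].source == "admission" for a in AXES if final[a] is not None
    )
    if stage is not None and admission_sourced:
        stage = ajcc.umbrella_of(stage)
        umbrella_only = True

    if stage is None:
        if not assertions and post_therapy_seen:
            reason = "post-therapy (yTNM) records only; excluded from stage at diagnosis"
        elif not assertions:
            reason = "no staging information in any in-window source"
        else:
            reason = "no stage group derivable after supplementation and assumptions"
        return _unstageable(bundle, reason, post_therapy=post_therapy_seen)

    # --- tier assignment -------------------------------------------------
    has_admission = bool(admissions_inwindow)
    clinical_grade = bool(clinical_inwindow)
    if config.rules.clinical_prefix_counts:
        clinical_grade = clinical_grade or any(
            cand is not None and not cand.component.is_x
            and "c" in (cand.component.prefix or "")
            for cand in resolved.values()
        )

    def axis_complete(axis: str) -> bool:
        if provenance.get(axis) is None or final[axis] is None:
            return False
        if provenance[axis].source == "assumption":
            # absence assumptions count as complete only when the admission
            # stream was available in-window to corroborate the absence
            return has_admission
        return True

    fields_missing = any(f.code == "missing_tumour_field" for f in findings)

    if not clinical_grade and not has_admission:
        tier = "3"
    elif (not umbrella_only and all(axis_complete(a) for a in AXES)
          and not fields_missing):
        tier = "1"
    else:
        tier = "2"

    return StagedCase(
        case_id=bundle.case_id, site=bundle.site, final=final,
        stage_group=stage, umbrella_only=umbrella_only, tier=tier,
        provenance={a: p for a, p in provenance.items() if final[a] is not None},
        assumptions_applied=tuple(assumptions),
        post_therapy=post_therapy_seen, reason=None,
    )


@dataclass
class RunLog:
    n_cases: int = 0
    tier_counts: Counter = field(default_factory=Counter)
    case_findings: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def summary(self) -> str:
        tiers = ", ".join(f"tier {t}: {self.tier_counts.get(t, 0)}"
                          for t in ("1", "2", "3", "unstageable"))
        return (f"{self.n_cases} cases staged ({tiers}); "
                f"{len(self.errors)} case-level errors")


def stage_cohort(bundles: Iterable[CaseBundle],
                 tables: Mapping[str, ajcc.AjccStageTable],
                 code_map: Optional[CodeMap] = None,
                 config: EngineConfig = EngineConfig()) -> tuple[list[StagedCase], RunLog]:
    """Stage every bundle, order-preserving and deterministic.

    Per-case isolation: a failing case is emitted as unstageable with the
    error recorded in the run log; it never aborts the run.
    """
    code_map = code_map or CodeMap.default()
    log = RunLog()
    out: list[StagedCase] = []
    for bundle in bundles:
        try:
            case = stage_case(bundle, tables, code_map, config)
        except Exception as exc:  # per-case isolation
            case = _unstageable(bundle, f"error: {exc}")
            log.errors[bundle.case_id] = str(exc)
        findings = validate_bundle(bundle)
        if findings:
            log.case_findings[bundle.case_id] = findings
        out.append(case)
        log.n_cases += 1
        log.tier_counts[case.tier] += 1
    return out, log
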