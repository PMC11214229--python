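"""Synthetic linked registry streams with known ground truth.

The generator emulates the statistical structure of a population-based
cancer registry's three staging sources: every case gets a true sub-stage
level TNM drawn consistently with a configured umbrella-stage distribution;
records are then emitted per-source with configurable availability —
pathology pTNM with per-axis completeness (missing axes reported as X), an
optional full-cTNM clinical/MDT record, and coded admission records for
node-positive / metastatic cases whose dates may fall outside the 120-day
staging window.  Neoadjuvant-treated cases emit y-prefixed pathology, which
the engine excludes from stage-at-diagnosis derivation.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from tierstage import ajcc
from tierstage.model import (
    AdmissionRecord,
    CaseBundle,
    ClinicalRecord,
    PathologyRecord,
    StagedCase,
    TNMAssertion,
)
from tierstage.tnm import TNMComponent, normalize_category

_TRUTH_CONTEXT = "c"  # truth stages are clinical-correlated stage at diagnosis


class SpecError(ValueError):
    """Invalid cohort specification."""


@dataclass(frozen=True)
class SourceAvailability:
    """Per-source emission probabilities (independent Bernoulli draws)."""

    pathology_t: float = 0.95  # P(T axis stated in the pathology report)
    pathology_n: float = 0.90
    pathology_m: float = 0.10  # explicit pM is rare; usually pMX
    clinical: float = 0.20     # P(clinical/MDT record with full cTNM)
    admission: float = 0.80    # P(admission coded | N+ or M+ truth)


@dataclass(frozen=True)
class CohortSpec:
    n: int = 1000
    site_mix: Mapping[str, float] = field(
        default_factory=lambda: {"colorectal": 0.4, "breast": 0.35, "melanoma": 0.25})
    # per-site umbrella-stage distribution of the simulated truth
    stage_dist: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        "colorectal": {"I": 0.18, "II": 0.27, "III": 0.32, "IV": 0.23},
        "breast": {"0": 0.08, "I": 0.40, "II": 0.32, "III": 0.14, "IV": 0.06},
        "melanoma": {"0": 0.10, "I": 0.55, "II": 0.18, "III": 0.12, "IV": 0.05},
    })
    availability: SourceAvailability = SourceAvailability()
    nat_fraction: float = 0.05         # P(neoadjuvant therapy -> yTNM pathology)
    coding_error_rate: float = 0.0     # P(spurious metastasis admission code)
    seed: int = 0
    year: int = 2019                   # diagnosis dates uniform over this year
    # admission-date offset from diagnosis: geometric-like, truncated, so a
    # fraction of records falls outside the default 120-day window
    admission_offset_p: float = 0.03
    admission_max_offset_days: int = 180

    def validate(self) -> None:
        if self.n <= 0:
            raise SpecError("n must be > 0")
        for name, dist in [("site_mix", self.site_mix), *(
                (f"stage_dist[{s}]", d) for s, d in self.stage_dist.items())]:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise SpecError(f"{name} proportions sum to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise SpecError(f"{name} has negative proportions")
        for site in self.site_mix:
            if site not in ajcc.SITES:
                raise SpecError(f"unknown site {site!r} in site_mix")
            if self.site_mix[site] > 0 and site not in self.stage_dist:
                raise SpecError(f"no stage_dist for site {site!r}")
        probs = {
            "pathology_t": self.availability.pathology_t,
            "pathology_n": self.availability.pathology_n,
            "pathology_m": self.availability.pathology_m,
            "clinical": self.availability.clinical,
            "admission": self.availability.admission,
            "nat_fraction": self.nat_fraction,
            "coding_error_rate": self.coding_error_rate,
            "admission_offset_p": self.admission_offset_p,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"{name}={p} outside [0, 1]")
        if self.admission_max_offset_days <= 0:
            raise SpecError("admission_max_offset_days must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    case_id: str
    site: str
    t: str  # leaf tokens
    n: str
    m: str
    stage: str          # true sub-stage label (clinical context)
    umbrella: str
    emitted: Mapping[str, bool]  # which streams produced records
    post_therapy: bool


def _component(axis: str, token: str, prefix: str) -> TNMComponent:
    return replace(normalize_category(axis, token), prefix=prefix)


def _truth_indices(tables) -> dict[str, dict[str, list]]:
    return {site: ajcc.inverse_index(tables[site], _TRUTH_CONTEXT)
            for site in ajcc.SITES}


def generate_cohort(spec: CohortSpec,
                    tables: Optional[Mapping[str, ajcc.AjccStageTable]] = None,
                    ) -> tuple[list[CaseBundle], list[GroundTruth]]:
    """Generate ``spec.n`` linked cases with ground truth.

    Deterministic given ``spec.seed``; every true TNM is groupable to a
    sub-stage in the site's stage table by construction (drawn uniformly
    among the leaf triples consistent with the drawn umbrella stage).
    """
    spec.validate()
    tables = tables or ajcc.load_stage_tables()
    rng = np.random.default_rng(spec.seed)
    inverse = _truth_indices(tables)
    av = spec.availability

    sites = sorted(spec.site_mix)
    site_p = np.array([spec.site_mix[s] for s in sites], dtype=float)
    site_p = site_p / site_p.sum()

    bundles: list[CaseBundle] = []
    truths: list[GroundTruth] = []
    year_start = date(spec.year, 1, 1)
    year_days = (date(spec.year + 1, 1, 1) - year_start).days

    for i in range(spec.n):
        case_id = f"S{i + 1:06d}"
        site = sites[rng.choice(len(sites), p=site_p)]
        dist = spec.stage_dist[site]
        umbrellas = sorted(dist)
        probs = np.array([dist[u] for u in umbrellas], dtype=float)
        umbrella = umbrellas[rng.choice(len(umbrellas), p=probs / probs.sum())]
        choices = inverse[site][umbrella]
        t_tok, n_tok, m_tok, stage = choices[rng.integers(len(choices))]
        dx = year_start + timedelta(days=int(rng.integers(year_days)))
        nat = bool(rng.random() < spec.nat_fraction)

        pathology: list[PathologyRecord] = []
        clinical: list[ClinicalRecord] = []
        admissions: list[AdmissionRecord] = []
        emitted = {"pathology": False, "clinical": False, "admission": False}

        # pathology report (resection / biopsy), axes masked to X when the
        # report is incomplete; y-prefixed after neoadjuvant therapy
        prefix = "yp" if nat else "p"
        pt = t_tok if rng.random() < av.pathology_t else "X"
        pn = n_tok if rng.random() < av.pathology_n else "X"
        pm = m_tok if rng.random() < av.pathology_m else "X"
        path_date = dx + timedelta(days=int(rng.integers(7, 45)))
        pathology.append(PathologyRecord(TNMAssertion(
            components=(
                _component("T", pt, prefix),
                _component("N", pn, prefix),
                _component("M", pm, prefix),
            ),
            source="pathology", record_date=path_date, post_therapy=nat,
        )))
        emitted["pathology"] = True

        if rng.random() < av.clinical:
            clin_date = dx + timedelta(days=int(rng.integers(0, 60)))
            clinical.append(ClinicalRecord(TNMAssertion(
                components=(
                    _component("T", t_tok, "c"),
                    _component("N", n_tok, "c"),
                    _component("M", m_tok, "c"),
                ),
                source="clinical", record_date=clin_date,
            ), reported_stage=stage))
            emitted["clinical"] = True

        # N1mi (micrometastases) is a microscopy finding: it does not
        # generate a coded nodal-involvement admission
        node_positive = n_tok not in ("0", "1mi")
        met_positive = m_tok != "0"
        if (node_positive or met_positive) and rng.random() < av.admission:
            offset = min(int(rng.geometric(spec.admission_offset_p)),
                         spec.admission_max_offset_days)
            codes = []
            if node_positive:
                codes.append("C77.9")
            if met_positive:
                codes.append("C78.0")
            admissions.append(AdmissionRecord(dx + timedelta(days=offset),
                                              tuple(codes)))
            emitted["admission"] = True
        if spec.coding_error_rate and rng.random() < spec.coding_error_rate:
            admissions.append(AdmissionRecord(
                dx + timedelta(days=int(rng.integers(0, 100))), ("C79.9",)))
            emitted["admission"] = True

        bundles.append(CaseBundle(
            case_id=case_id, site=site, diagnosis_date=dx,
            pathology_records=tuple(pathology),
            admission_records=tuple(admissions),
            clinical_records=tuple(clinical),
        ))
        truths.append(GroundTruth(
            case_id=case_id, site=site, t=t_tok, n=n_tok, m=m_tok,
            stage=stage, umbrella=umbrella, emitted=emitted,
            post_therapy=nat,
        ))
    return bundles, truths


def tier_profile(staged: list[StagedCase]) -> pd.DataFrame:
    """Counts per tier (rows, fixed order) per site (columns).

    Columns are the sites present in the cohort (sorted) plus ``"all"``;
    counts in each column sum to that column's cohort size.
    """
    tiers = ("1", "2", "3", "unstageable")
    sites = sorted({c.site for c in staged if c.site is not None})
    counts = pd.DataFrame(0, index=list(tiers), columns=sites + ["all"], dtype=int)
    for case in staged:
        if case.site in sites:
            counts.loc[case.tier, case.site] += 1
        counts.loc[case.tier, "all"] += 1
    counts.index.name = "tier"
    return counts


# ---------------------------------------------------------------------------
# Named presets encoding the qualitative per-site mechanisms: melanoma is
# usually resected immediately with complete early-stage pathology; breast
# and colorectal rely more on clinical/MDT sources, with more neoadjuvant
# therapy and more unstageable cases.  Presets are illustrative parameter
# choices, not calibrated to any registry's published distribution.

_PRESETS = {
    "melanoma-like": dict(
        site_mix={"melanoma": 1.0},
        availability=SourceAvailability(pathology_t=0.98, pathology_n=0.92,
                                        pathology_m=0.05, clinical=0.02,
                                        admission=0.75),
        nat_fraction=0.01,
    ),
    "colorectal-like": dict(
        site_mix={"colorectal": 1.0},
        availability=SourceAvailability(pathology_t=0.85, pathology_n=0.82,
                                        pathology_m=0.08, clinical=0.18,
                                        admission=0.85),
        nat_fraction=0.12,
    ),
    "breast-like": dict(
        site_mix={"breast": 1.0},
        availability=SourceAvailability(pathology_t=0.88, pathology_n=0.82,
                                        pathology_m=0.05, clinical=0.08,
                                        admission=0.80),
        nat_fraction=0.18,
    ),
}


def preset_spec(name: str, n: int = 1000, seed: int = 0) -> CohortSpec:
    """A named per-site preset spec ("melanoma-like", "colorectal-like",
    "breast-like")."""
    if name not in _PRESETS:
        raise SpecError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    return CohortSpec(n=n, seed=seed, **_PRESETS[name])


def preset_names() -> tuple[str, ...]:
    return tuple(sorted(_PRESETS))
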