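"""Shared fixtures: stage tables and the published worked-example bundles."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from tierstage import load_stage_tables, parse_tnm_string
from tierstage.model import (
    AdmissionRecord,
    CaseBundle,
    ClinicalRecord,
    PathologyRecord,
)

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DX = date(2019, 3, 1)


@pytest.fixture(scope="session")
def tables():
    return load_stage_tables()


def pathology_bundle(case_id: str, site: str, tnm: str, *,
                     admissions=(), clinical=(), dx: date = DX) -> CaseBundle:
    """A one-pathology-report bundle, optionally with admission/clinical
    records, all dated inside the staging window."""
    return CaseBundle(
        case_id=case_id, site=site, diagnosis_date=dx,
        pathology_records=(PathologyRecord(
            parse_tnm_string(tnm, record_date=dx.replace(day=20))),),
        admission_records=tuple(admissions),
        clinical_records=tuple(clinical),
    )


NODAL_ADMISSION = AdmissionRecord(date(2019, 4, 1), ("C77.9",))
METASTASIS_ADMISSION = AdmissionRecord(date(2019, 4, 1), ("C78.0",))


@pytest.fixture
def complete_ajcc_bundle():
    """Pathology report carrying clinical M: pT1 pN2 cM1a colorectal."""
    return pathology_bundle("wk1", "colorectal", "pT1N2 cM1a")


@pytest.fixture
def rd_stage_bundle():
    """pT1 pNX pMX with a nodal admission code: registry-derived stage."""
    return pathology_bundle("wk2", "colorectal", "pT1 pNX pMX",
                            admissions=[NODAL_ADMISSION])


@pytest.fixture
def comparison_bundles():
    """The two-view comparison: same case with and without pN2a detail."""
    with_subcat = pathology_bundle("wk3a", "colorectal", "pT1 pN2a pMX",
                                   admissions=[NODAL_ADMISSION])
    without_subcat = pathology_bundle("wk3b", "colorectal", "pT1 pNX pMX",
                                      admissions=[NODAL_ADMISSION])
    return with_subcat, without_subcat


@pytest.fixture
def pathology_only_bundle():
    """pT1 pN2a pMX, no admissions, no clinical: pathology stage only."""
    return pathology_bundle("wk4", "colorectal", "pT1 pN2a pMX")
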