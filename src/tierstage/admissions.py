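"""Supplementing N and M from coded hospital-admission records.

Coded admission data (ICD-10 style diagnosis codes) carries only binary
yes/no evidence of nodal involvement or distant metastasis, never counts or
subcategories.  Records are considered only inside the staging window —
120 days from diagnosis by default, inclusive at both ends — so the derived
values reflect extent of disease at diagnosis rather than progression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from typing import Iterable, Optional, Sequence

import yaml

from tierstage.model import AdmissionRecord, TNMAssertion
from tierstage.tnm import TNMComponent


@dataclass(frozen=True)
class StagingWindow:
    """Staging data-collection window anchored at the diagnosis date."""

    window_days: int = 120

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be > 0")


def in_window(diagnosis_date: date, record_date: date,
              window: StagingWindow = StagingWindow()) -> bool:
    """True iff 0 <= (record_date - diagnosis_date) <= window_days.

    Inclusive at day 0 and at the final day; pre-diagnosis records are
    always out of window.
    """
    delta = (record_date - diagnosis_date).days
    return 0 <= delta <= window.window_days


class CodeMapError(ValueError):
    """Invalid code-map configuration."""


@dataclass(frozen=True)
class CodeMap:
    """Diagnosis-code prefixes signalling nodal or distant secondary disease.

    Matching is by prefix on the normalised code (uppercased, dots removed),
    so ``"C77"`` matches ``C77.9``/``C779``.  ``exclusions`` are ignored
    entirely and take priority; ``site_overrides`` may replace any of the
    three lists per site.
    """

    nodal: tuple[str, ...] = ("C77",)
    metastasis: tuple[str, ...] = ("C78", "C79")
    exclusions: tuple[str, ...] = ()
    site_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site in self.site_overrides:
            self._check(self.for_site(site))
        self._check(self)

    @staticmethod
    def _check(cm: "CodeMap") -> None:
        nodal = {CodeMap._norm(p) for p in cm.nodal}
        mets = {CodeMap._norm(p) for p in cm.metastasis}
        for a in nodal:
            for b in mets:
                if a.startswith(b) or b.startswith(a):
                    raise CodeMapError(
                        f"nodal and metastasis prefix sets overlap: {a!r} vs {b!r}"
                    )

    @staticmethod
    def _norm(code: str) -> str:
        return code.strip().upper().replace(".", "")

    def for_site(self, site: Optional[str]) -> "CodeMap":
        ov = self.site_overrides.get(site)
        if not ov:
            return self
        return CodeMap(
            nodal=tuple(ov.get("nodal", self.nodal)),
            metastasis=tuple(ov.get("metastasis", self.metastasis)),
            exclusions=tuple(ov.get("exclusions", self.exclusions)),
        )

    def _match(self, code: str, prefixes: Sequence[str]) -> bool:
        c = self._norm(code)
        if any(c.startswith(self._norm(x)) for x in self.exclusions):
            return False
        return any(c.startswith(self._norm(p)) for p in prefixes)

    def is_nodal(self, code: str) -> bool:
        return self._match(code, self.nodal)

    def is_metastasis(self, code: str) -> bool:
        return self._match(code, self.metastasis)

    @classmethod
    def from_yaml(cls, path) -> "CodeMap":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "CodeMap":
        try:
            return cls(
                nodal=tuple(raw.get("nodal", ())),
                metastasis=tuple(raw.get("metastasis", ())),
                exclusions=tuple(raw.get("exclusions", ()) or ()),
                site_overrides=dict(raw.get("site_overrides", {}) or {}),
            )
        except TypeError as exc:
            raise CodeMapError(f"malformed code map: {exc}") from exc

    @classmethod
    def default(cls) -> "CodeMap":
        text = resources.files("tierstage.data").joinpath("icd10_codes.yaml") \
            .read_text(encoding="utf-8")
        return cls._from_mapping(yaml.safe_load(text))


def derive_binary_nm(admissions: Iterable[AdmissionRecord],
                     code_map: CodeMap,
                     site: Optional[str] = None) -> Optional[TNMAssertion]:
    """Convert in-window admission records into a binary N/M assertion.

    N = 1 (no subcategory) iff any nodal code is present; M = 1 iff any
    metastasis code is present.  Axes without a triggering code are *absent*
    from the assertion — the M0/N0 reading of silence is an absence
    assumption applied later by the tier engine, not an admission value.
    The assertion is dated to the earliest triggering admission.  Returns
    None when no code triggers (including for an empty record list).

    Monotone: adding an admission record can only add positive indicators.
    """
    cm = code_map.for_site(site)
    nodal_date: Optional[date] = None
    met_date: Optional[date] = None
    for rec in admissions:
        for code in rec.codes:
            if cm.is_nodal(code):
                if nodal_date is None or rec.admission_date < nodal_date:
                    nodal_date = rec.admission_date
            elif cm.is_metastasis(code):
                if met_date is None or rec.admission_date < met_date:
                    met_date = rec.admission_date
    components = []
    if nodal_date is not None:
        components.append(TNMComponent("N", "1", binary=True))
    if met_date is not None:
        components.append(TNMComponent("M", "1", binary=True))
    if not components:
        return None
    dates = [d for d in (nodal_date, met_date) if d is not None]
    return TNMAssertion(components=tuple(components), source="admission",
                        record_date=min(dates))
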