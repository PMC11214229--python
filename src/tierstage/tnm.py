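"""Parsing, normalisation and advancement ordering of prefixed TNM tokens.

The TNM classification records the extent of the primary tumour (T), regional
lymph-node involvement (N) and distant metastasis (M).  Values carry a prefix
describing their context: ``p`` pathological, ``c`` clinical, ``y``/``yp``
post-therapy.  Registry sources report these as compact token strings such as
``"pT1N2 cM1a"``; a leading prefix distributes to the axes that follow it
until a new prefix appears.

This module is pure: no file I/O, no site-specific knowledge.  Site-specific
stage grouping lives in :mod:`tierstage.ajcc`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable, Optional

AXES = ("T", "N", "M")

#: Recognised prefixes in canonical form.  ``y`` marks post-therapy values.
PREFIXES = ("p", "c", "y", "yp")

# Numeral order per axis, least to most advanced.  "X" (unassessable) is
# handled separately: it ranks below every stated value so that conflict
# resolution always favours stated information.
_NUMERAL_ORDER = {
    "T": ("0", "is", "1", "2", "3", "4"),
    "N": ("0", "1", "2", "3"),
    "M": ("0", "1"),
}

# Subcategory order within a numeral.  A bare category ranks below its own
# lettered subcategories (N2 < N2a < N2b): at equal numeral the lettered
# value carries strictly more adverse specificity.  "mi" (micrometastasis,
# N1mi) instead ranks *below* the bare category: micrometastatic involvement
# is milder than unqualified N1, which by convention means macrometastases.
_SUB_ORDER = ("mi", None, "a", "b", "c", "d")

_VALID_SUBS = {
    "T": {"a", "b", "c", "d"},
    "N": {"a", "b", "c", "mi"},
    "M": {"a", "b", "c", "d"},
}


class TNMParseError(ValueError):
    """Raised when a TNM token string cannot be parsed."""


@dataclass(frozen=True)
class TNMComponent:
    """One normalised T, N or M value.

    ``binary`` marks values derived from coded admission data, which assert
    only presence/absence (yes/no) and therefore stand for *any* positive
    category of the axis rather than the specific bare category.
    """

    axis: str
    category: str
    subcategory: Optional[str] = None
    prefix: Optional[str] = None
    binary: bool = False

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.category != "X" and self.category not in _NUMERAL_ORDER[self.axis]:
            raise ValueError(
                f"invalid {self.axis} category {self.category!r}"
            )
        if self.subcategory is not None:
            if self.category == "X":
                raise ValueError("category X never carries a subcategory")
            if self.subcategory not in _VALID_SUBS[self.axis]:
                raise ValueError(
                    f"invalid {self.axis} subcategory {self.subcategory!r}"
                )
            if self.subcategory == "mi" and (self.axis, self.category) != ("N", "1"):
                raise ValueError("'mi' subcategory is only defined for N1")
        if self.prefix is not None and self.prefix not in PREFIXES:
            raise ValueError(f"unknown prefix {self.prefix!r}")
        if self.binary and self.subcategory is not None:
            raise ValueError("binary (admission-sourced) components carry no subcategory")

    @property
    def is_x(self) -> bool:
        return self.category == "X"

    @property
    def post_therapy(self) -> bool:
        return self.prefix is not None and "y" in self.prefix

    @property
    def token(self) -> str:
        """Category token without axis letter or prefix, e.g. ``"2a"``."""
        return self.category + (self.subcategory or "")

    def __str__(self) -> str:  # e.g. "pN2a", "M1", "cMX"
        return f"{self.prefix or ''}{self.axis}{self.token}"


def advancement_rank(component: TNMComponent) -> tuple[int, int]:
    """Sort key ordering components from least to most advanced.

    ``X`` ranks below every stated value; within a numeral a bare category
    ranks below its subcategories.
    """
    if component.is_x:
        return (-1, 0)
    numeral = _NUMERAL_ORDER[component.axis].index(component.category)
    if component.binary:
        # a binary (admission-derived) positive is the minimal assumption at
        # its numeral: any stated value of the same numeral outranks it
        return (numeral, -1)
    sub = _SUB_ORDER.index(component.subcategory)
    return (numeral, sub)


def ordered_categories(axis: str) -> list[str]:
    """All valid category tokens for an axis, least to most advanced (X first)."""
    out = ["X"]
    for numeral in _NUMERAL_ORDER[axis]:
        for sub in _SUB_ORDER:
            if sub is None:
                out.append(numeral)
                continue
            if sub not in _VALID_SUBS[axis] or numeral in ("0", "is"):
                continue
            if sub == "mi" and (axis, numeral) != ("N", "1"):
                continue
            out.append(numeral + sub)
    return out


def more_advanced(a: TNMComponent, b: TNMComponent) -> TNMComponent:
    """Return the more advanced of two same-axis components.

    Conflicting reports are resolved by favouring the more advanced value;
    an unassessable ``X`` loses to any stated value.  Exact ties return the
    first argument.
    """
    if a.axis != b.axis:
        raise ValueError(f"axis mismatch: {a.axis} vs {b.axis}")
    return b if advancement_rank(b) > advancement_rank(a) else a


_CATEGORY_RE = re.compile(r"^(is|IS|Is|[Xx]|[0-9](?:mi|MI|[a-dA-D])?)$")


def normalize_category(axis: str, raw: str) -> TNMComponent:
    """Normalise a raw category token (``"t1"``, ``"N2a"``, ``"M1A"``) to a
    canonical :class:`TNMComponent` with no prefix.

    An optional leading axis letter matching ``axis`` is tolerated; case and
    surrounding whitespace are ignored.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    token = raw.strip()
    if token[:1].upper() == axis:
        token = token[1:]
    m = _CATEGORY_RE.match(token)
    if not m:
        raise TNMParseError(f"invalid {axis} category token {raw!r}")
    token = token.lower()
    try:
        if token == "x":
            return TNMComponent(axis, "X")
        if token == "is":
            return TNMComponent(axis, "is")
        category, sub = token[0], token[1:] or None
        return TNMComponent(axis, category, sub)
    except ValueError as exc:
        raise TNMParseError(f"invalid {axis} category token {raw!r}: {exc}") from exc


# One prefixed axis-value group inside a combined TNM string.
_TOKEN_RE = re.compile(
    r"\s*(?:(yp|yc|y|p|c|YP|YC|Y|P|C)\s*)?"
    r"([TNMtnm])\s*"
    r"(is|IS|Is|[Xx]|[0-9](?:mi|MI|[a-dA-D])?)"
)


def parse_tnm_string(text: str, source: str = "pathology",
                     record_date: Optional[date] = None) -> "TNMAssertion":
    """Parse a combined prefixed TNM string into a :class:`TNMAssertion`.

    A prefix distributes to all subsequent axes until a new prefix appears,
    so ``"pT1N2 cM1a"`` yields pT1, pN2, cM1a.  Any ``y`` prefix sets the
    post-therapy flag on the assertion.
    """
    from tierstage.model import TNMAssertion  # circular-at-import, not at call

    if not text or not text.strip():
        raise TNMParseError("empty TNM string")
    components: dict[str, TNMComponent] = {}
    current_prefix: Optional[str] = None
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise TNMParseError(
                f"unparseable TNM fragment {text[pos:pos + 12]!r} in {text!r}"
            )
        prefix_raw, axis_raw, cat_raw = m.groups()
        if prefix_raw is not None:
            current_prefix = prefix_raw.lower()
            if current_prefix == "yc":  # post-therapy clinical: record as y
                current_prefix = "y"
        axis = axis_raw.upper()
        if axis in components:
            raise TNMParseError(f"duplicate {axis} value in {text!r}")
        comp = normalize_category(axis, cat_raw)
        components[axis] = replace(comp, prefix=current_prefix)
        pos = m.end()
    post_therapy = any(c.post_therapy for c in components.values())
    return TNMAssertion(
        components=tuple(components[a] for a in AXES if a in components),
        source=source,
        record_date=record_date,
        post_therapy=post_therapy,
    )


def format_assertion(components: Iterable[TNMComponent]) -> str:
    """Canonical string form; the inverse of :func:`parse_tnm_string` on
    canonical strings (prefix printed whenever it differs from the running
    prefix)."""
    out: list[str] = []
    running: object = object()  # sentinel: first group always states its prefix
    for comp in components:
        if comp.prefix != running:
            if out:
                out.append(" ")
            out.append(f"{comp.prefix or ''}{comp.axis}{comp.token}")
            running = comp.prefix
        else:
            out.append(f"{comp.axis}{comp.token}")
    return "".join(out)
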