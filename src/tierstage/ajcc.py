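"""AJCC 8th-edition stage grouping from (site, T, N, M).

The stage tables are shipped as human-reviewable text assets (one per site)
rather than code, so the medical content stays auditable and versioned.  At
load time every table is verified to be exhaustive and mutually exclusive:
each valid leaf-level (T, N, M) combination matches exactly one row per
staging context.

Grouping handles three levels of input specificity:

* leaf-level components (``N2a``) map directly to their row;
* bare categories (``N2``) expand to their subcategory leaves — if all
  matching rows agree the sub-stage is returned, otherwise the shared
  umbrella (main stage category) with ``umbrella_only=True``;
* binary admission-derived values carry the registry assumption that a
  positive code equals category 1, and expand like the bare category;
* absent or X components expand to the whole axis.

If matching rows do not even share an umbrella, the triple is not groupable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product
from typing import Mapping, Optional, Sequence

from tierstage.tnm import TNMComponent

SITES = ("colorectal", "breast", "melanoma")
CONTEXTS = ("c", "p")

_UMBRELLAS = ("0", "I", "II", "III", "IV")
_LETTERS = ("", "A", "B", "C", "D")


class TableIntegrityError(ValueError):
    """A stage-table asset is missing, overlapping, or schema-invalid."""


def umbrella_of(stage: str) -> str:
    """Strip the sub-stage letter: IIIA -> III; umbrella labels map to
    themselves (idempotent)."""
    if stage in _UMBRELLAS:
        return stage
    if stage[:-1] in _UMBRELLAS and stage[-1] in _LETTERS:
        return stage[:-1]
    raise ValueError(f"unknown stage label {stage!r}")


def stage_order_key(stage: str) -> tuple[int, int]:
    """Ordering key over stage labels: 0 < I < IA < IB < II < ... < IVC."""
    umb = umbrella_of(stage)
    letter = stage[len(umb):]
    return (_UMBRELLAS.index(umb), _LETTERS.index(letter))


@dataclass(frozen=True)
class StageRow:
    t: Optional[frozenset[str]]  # None = wildcard (any leaf)
    n: Optional[frozenset[str]]
    m: Optional[frozenset[str]]
    stage: str
    context: str  # "c", "p" or "*"

    def matches(self, t: str, n: str, m: str, context: str) -> bool:
        if self.context not in ("*", context):
            return False
        return all(
            pat is None or tok in pat
            for pat, tok in ((self.t, t), (self.n, n), (self.m, m))
        )


@dataclass(frozen=True)
class AjccStageTable:
    """Site-specific mapping from leaf (T, N, M) triples to stage groups."""

    site: str
    edition: str
    rows: tuple[StageRow, ...]
    leaves: Mapping[str, tuple[str, ...]]  # axis -> ordered leaf tokens
    # (t, n, m, context) -> stage, precomputed over all valid leaf triples
    _lookup: Mapping[tuple[str, str, str, str], str]

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return tuple(sorted({r.stage for r in self.rows}, key=stage_order_key))

    def contexts_differ(self) -> bool:
        return any(r.context != "*" for r in self.rows)


def _valid_leaf_triple(site: str, t: str, n: str, m: str) -> bool:
    """Domain of the exhaustiveness check: anatomically meaningful leaf
    combinations.  In-situ disease (Tis) is only staged with N0, and a
    breast T0 N0 M0 (no tumour, no nodes, no metastasis) is not a stage."""
    if t == "is" and n != "0":
        return False
    if site == "breast" and (t, n, m) == ("0", "0", "0"):
        return False
    return True


def _parse_pattern(cell: str, leaves: Sequence[str], axis: str,
                   site: str) -> Optional[frozenset[str]]:
    if cell == "*":
        return None
    toks = tuple(tok.strip() for tok in cell.split(","))
    bad = [tok for tok in toks if tok not in leaves]
    if bad:
        raise TableIntegrityError(
            f"{site}: pattern token(s) {bad} not in declared {axis} leaves"
        )
    return frozenset(toks)


def _load_site_table(text: str, site: str) -> AjccStageTable:
    leaves: dict[str, tuple[str, ...]] = {}
    rows: list[StageRow] = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#leaves"):
            _, axis, toks = line.split("\t")
            leaves[axis.upper()] = tuple(tok.strip() for tok in toks.split(","))
            continue
        if line.startswith("#"):
            continue
        cells = line.split("\t")
        if not header_seen:
            if [c.lower() for c in cells] != ["t", "n", "m", "stage", "context"]:
                raise TableIntegrityError(
                    f"{site}: unexpected header {cells} at line {lineno}"
                )
            header_seen = True
            continue
        if len(cells) != 5:
            raise TableIntegrityError(f"{site}: malformed row at line {lineno}")
        t_pat, n_pat, m_pat, stage, context = (c.strip() for c in cells)
        if context not in ("*",) + CONTEXTS:
            raise TableIntegrityError(f"{site}: bad context {context!r} line {lineno}")
        umbrella_of(stage)  # label must be grammatical
        rows.append(StageRow(
            t=_parse_pattern(t_pat, leaves.get("T", ()), "T", site),
            n=_parse_pattern(n_pat, leaves.get("N", ()), "N", site),
            m=_parse_pattern(m_pat, leaves.get("M", ()), "M", site),
            stage=stage,
            context=context,
        ))
    if set(leaves) != {"T", "N", "M"}:
        raise TableIntegrityError(f"{site}: missing #leaves declarations")

    lookup: dict[tuple[str, str, str, str], str] = {}
    for ctx in CONTEXTS:
        for t, n, m in product(leaves["T"], leaves["N"], leaves["M"]):
            if not _valid_leaf_triple(site, t, n, m):
                continue
            matched = [r for r in rows if r.matches(t, n, m, ctx)]
            if len(matched) != 1:
                kind = "no row" if not matched else f"{len(matched)} rows"
                raise TableIntegrityError(
                    f"{site} ({ctx}): {kind} matching T{t} N{n} M{m}"
                )
            lookup[(t, n, m, ctx)] = matched[0].stage
    return AjccStageTable(
        site=site, edition="AJCC 8", rows=tuple(rows), leaves=dict(leaves),
        _lookup=lookup,
    )


def _load_umbrella_asset(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("stage\t"):
            continue
        stage, umb = (c.strip() for c in line.split("\t"))
        out[stage] = umb
    return out


def load_stage_tables(asset_dir=None) -> dict[str, AjccStageTable]:
    """Load and integrity-check the per-site stage tables.

    ``asset_dir`` may be a path-like directory holding ``ajcc8_<site>.tsv``
    and ``umbrella.tsv``; by default the packaged assets are used.  Missing,
    overlapping, or non-exhaustive tables abort with
    :class:`TableIntegrityError`.
    """
    import pathlib

    def read(name: str) -> str:
        if asset_dir is not None:
            path = pathlib.Path(asset_dir) / name
            if not path.exists():
                raise TableIntegrityError(f"missing stage-table asset {path}")
            return path.read_text(encoding="utf-8")
        ref = resources.files("tierstage.data").joinpath(name)
        if not ref.is_file():
            raise TableIntegrityError(f"missing packaged asset {name}")
        return ref.read_text(encoding="utf-8")

    tables = {site: _load_site_table(read(f"ajcc8_{site}.tsv"), site)
              for site in SITES}
    umb = _load_umbrella_asset(read("umbrella.tsv"))
    for stage, expected in umb.items():
        if umbrella_of(stage) != expected:
            raise TableIntegrityError(
                f"umbrella asset disagrees with label grammar for {stage!r}"
            )
    for table in tables.values():
        missing = [s for s in table.stage_labels if s not in umb]
        if missing:
            raise TableIntegrityError(
                f"{table.site}: stages {missing} absent from umbrella map"
            )
    return tables


@dataclass(frozen=True)
class GroupResult:
    stage: Optional[str]  # None = not groupable
    umbrella_only: bool = False

    @property
    def groupable(self) -> bool:
        return self.stage is not None


NOT_GROUPABLE = GroupResult(None)


def _leaf_expansion(table: AjccStageTable, axis: str,
                    comp: Optional[TNMComponent]) -> tuple[str, ...]:
    leaves = table.leaves[axis]
    if comp is None or comp.is_x:
        return leaves
    # A binary admission-derived positive is recorded as the bare category 1
    # (the registry assumption: a positive nodal/metastatic code equals
    # N1/M1), so it expands exactly like an explicit bare category below.
    token = comp.token
    if token in leaves:
        return (token,)
    if comp.subcategory is not None and comp.category in leaves:
        # table does not subdivide this category (e.g. breast T1c -> T1)
        return (comp.category,)
    if comp.subcategory is None:
        # bare category where the table holds subcategory leaves; "mi" is
        # excluded from bare expansion (micrometastases are only reported
        # when specifically measured)
        subs = tuple(l for l in leaves
                     if l.startswith(comp.category) and l != comp.category
                     and not l.endswith("mi"))
        if subs:
            return subs
    return ()


def _stage_in_context(table: AjccStageTable, expansions, context: str) -> GroupResult:
    stages = set()
    for t, n, m in product(*expansions):
        stage = table._lookup.get((t, n, m, context))
        if stage is not None:
            stages.add(stage)
    if not stages:
        return NOT_GROUPABLE
    if len(stages) == 1:
        return GroupResult(stages.pop())
    umbrellas = {umbrella_of(s) for s in stages}
    if len(umbrellas) == 1:
        return GroupResult(umbrellas.pop(), umbrella_only=True)
    return NOT_GROUPABLE


def stage_group(table: AjccStageTable,
                t: Optional[TNMComponent],
                n: Optional[TNMComponent],
                m: Optional[TNMComponent],
                context: Optional[str] = None) -> GroupResult:
    """Map (T, N, M) components (any may be absent) to a stage group.

    ``context`` selects clinical (``"c"``) or pathological (``"p"``) grouping
    where the site distinguishes them (melanoma).  With ``context=None`` both
    are evaluated; if they disagree the shared umbrella is returned with
    ``umbrella_only=True``, and if the umbrellas conflict the triple is not
    groupable.
    """
    for axis, comp in (("T", t), ("N", n), ("M", m)):
        if comp is not None and comp.axis != axis:
            raise ValueError(f"component {comp} passed as axis {axis}")
    expansions = tuple(
        _leaf_expansion(table, axis, comp)
        for axis, comp in (("T", t), ("N", n), ("M", m))
    )
    if any(len(e) == 0 for e in expansions):
        return NOT_GROUPABLE
    if context is not None:
        if context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")
        return _stage_in_context(table, expansions, context)
    results = {_stage_in_context(table, expansions, ctx) for ctx in CONTEXTS}
    if len(results) == 1:
        return results.pop()
    stages = {r.stage for r in results}
    if None in stages:
        return NOT_GROUPABLE
    umbrellas = {umbrella_of(s) for s in stages}
    if len(umbrellas) == 1:
        return GroupResult(umbrellas.pop(), umbrella_only=True)
    return NOT_GROUPABLE


def inverse_index(table: AjccStageTable, context: str) -> dict[str, list[tuple[str, str, str, str]]]:
    """umbrella -> list of (t, n, m, sub-stage) leaf triples grouping to it.

    Used by the synthetic generator to draw a true TNM consistent with a
    drawn umbrella stage.
    """
    out: dict[str, list[tuple[str, str, str, str]]] = {}
    for (t, n, m, ctx), stage in table._lookup.items():
        if ctx != context:
            continue
        out.setdefault(umbrella_of(stage), []).append((t, n, m, stage))
    for v in out.values():
        v.sort()
    return out
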