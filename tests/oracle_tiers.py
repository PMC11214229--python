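"""Analytic tier-distribution oracle for the synthetic generator.

Under the generator, each case's tier is a deterministic function of its
true TNM and a handful of independent Bernoulli source-availability draws.
This module enumerates those joint outcomes with exact probabilities and
re-derives the expected tier from its own decision table — written directly
from the tiering rules, independently of the engine's code path.  Stage
grouping itself is delegated to the table lookup, which is verified against
an independent second transcription elsewhere in the suite.
"""

from __future__ import annotations

from collections import defaultdict

from tierstage import ajcc
from tierstage.synth import CohortSpec
from tierstage.tnm import TNMComponent, normalize_category


def _binary(axis: str) -> TNMComponent:
    return TNMComponent(axis, "1", binary=True)


def _oracle_tier(table, t_tok: str, n_tok: str, m_tok: str, *,
                 clinical: bool, nat: bool, t_stated: bool, n_stated: bool,
                 m_stated: bool, adm_in: bool) -> str:
    """Expected tier for one availability outcome (independent decision
    table; mirrors the framework rules, not the engine implementation)."""
    # micrometastatic nodal involvement (N1mi) is a pathology finding and
    # never generates a coded nodal admission
    npos, mpos = n_tok not in ("0", "1mi"), m_tok != "0"
    if clinical:
        # full cTNM at sub-stage level always outranks everything else
        return "1"
    if nat:
        # y-prefixed pathology is excluded; admissions plus the absence
        # assumptions (missing N/M read as 0) are all that remain
        if not adm_in:
            return "unstageable"
        n = _binary("N") if npos else normalize_category("N", "0")
        m = _binary("M") if mpos else normalize_category("M", "0")
        ctx = "c" if npos else None
        res = ajcc.stage_group(table, None, n, m, context=ctx)
        return "2" if res.groupable else "unstageable"

    t = normalize_category("T", t_tok) if t_stated else None
    n_coarse = m_coarse = False
    if n_stated:
        n = normalize_category("N", n_tok)
    elif npos and adm_in:
        n, n_coarse = _binary("N"), True
    else:
        n = normalize_category("N", "0")
    if m_stated:
        m = normalize_category("M", m_tok)
    elif mpos and adm_in:
        m, m_coarse = _binary("M"), True
    else:
        m = normalize_category("M", "0")

    if n_coarse:
        ctx = "c"
    elif t_stated or n_stated:
        ctx = "p"
    else:
        ctx = None
    res = ajcc.stage_group(table, t, n, m, context=ctx)
    if not res.groupable:
        return "unstageable"
    if not adm_in:
        return "3"  # pathology-only: nothing corroborates the derivation
    if n_coarse or m_coarse or res.umbrella_only or not t_stated:
        return "2"
    return "1"


def expected_tier_probs(spec: CohortSpec, tables) -> dict[str, float]:
    """Exact tier probabilities implied by the spec's Bernoulli structure."""
    av = spec.availability
    # P(admission record falls inside the 120-day window | emitted):
    # geometric offsets, support {1, 2, ...}, truncation above 120 days only
    w = 1.0 - (1.0 - spec.admission_offset_p) ** 120
    p_adm_in = av.admission * w
    probs: dict[str, float] = defaultdict(float)
    for site, site_p in spec.site_mix.items():
        if site_p == 0:
            continue
        table = tables[site]
        inv = ajcc.inverse_index(table, "c")
        for umbrella, u_p in spec.stage_dist[site].items():
            triples = inv[umbrella]
            for t_tok, n_tok, m_tok, _stage in triples:
                base = site_p * u_p / len(triples)
                emits_adm = (n_tok not in ("0", "1mi")) or (m_tok != "0")
                adm_states = ([(True, p_adm_in), (False, 1 - p_adm_in)]
                              if emits_adm else [(False, 1.0)])
                probs["1"] += base * av.clinical
                rest = base * (1 - av.clinical)
                for nat, p_y in ((True, spec.nat_fraction),
                                 (False, 1 - spec.nat_fraction)):
                    for adm_in, p_a in adm_states:
                        if nat:
                            tier = _oracle_tier(
                                table, t_tok, n_tok, m_tok, clinical=False,
                                nat=True, t_stated=False, n_stated=False,
                                m_stated=False, adm_in=adm_in)
                            probs[tier] += rest * p_y * p_a
                            continue
                        for ts, p_t in ((True, av.pathology_t),
                                        (False, 1 - av.pathology_t)):
                            for ns, p_n in ((True, av.pathology_n),
                                            (False, 1 - av.pathology_n)):
                                for ms, p_m in ((True, av.pathology_m),
                                                (False, 1 - av.pathology_m)):
                                    tier = _oracle_tier(
                                        table, t_tok, n_tok, m_tok,
                                        clinical=False, nat=False,
                                        t_stated=ts, n_stated=ns,
                                        m_stated=ms, adm_in=adm_in)
                                    probs[tier] += (rest * p_y * p_a
                                                    * p_t * p_n * p_m)
    return dict(probs)
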