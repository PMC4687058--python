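"""Duplicate-pair detection by the reciprocal second-best-hit rule.

In an all-vs-all protein search every gene's best hit is itself, so its
"second best" hit is its best non-self hit.  Two genes A and B form a
candidate duplicate pair when each is the other's best non-self hit and both
supporting e-values are below the threshold (default 1e-10).  Self hits are
removed by identifier equality (not by rank), so a search tool that
suppresses self hits cannot shift the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import HitRecord


@dataclass
class CandidatePair:
    id_a: str  # lexicographically smaller
    id_b: str
    evalue_ab: float
    evalue_ba: float
    bitscore_ab: float
    bitscore_ba: float


def rank_hits(hits: list[HitRecord]) -> dict[str, list[HitRecord]]:
    """Per-query hit lists, self hits removed, multiple rows per query-subject
    collapsed to the lowest e-value (tie: highest bitscore), sorted by
    ascending e-value with ties broken by descending bitscore then subject id.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[key] = h
    ranked: dict[str, list[HitRecord]] = {}
    for (q, _s), h in best.items():
        ranked.setdefault(q, []).append(h)
    for q in ranked:
        ranked[q].sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return ranked


def reciprocal_second_best(ranked: dict[str, list[HitRecord]],
                           evalue_max: float = 1e-10) -> list[CandidatePair]:
    """Emit each unordered pair (A, B) once when B is A's top non-self hit, A
    is B's top non-self hit, and both e-values are strictly below
    ``evalue_max``."""
    pairs: list[CandidatePair] = []
    seen: set[frozenset[str]] = set()
    for q, hlist in ranked.items():
        if not hlist:
            continue
        top = hlist[0]
        s = top.subject_id
        key = frozenset((q, s))
        if key in seen:
            continue
        back = ranked.get(s)
        if not back or back[0].subject_id != q:
            continue
        if top.evalue >= evalue_max or back[0].evalue >= evalue_max:
            continue
        seen.add(key)
        a, b = sorted((q, s))
        ab = top if q == a else back[0]
        ba = back[0] if q == a else top
        pairs.append(CandidatePair(
            id_a=a, id_b=b,
            evalue_ab=ab.evalue, evalue_ba=ba.evalue,
            bitscore_ab=ab.bitscore, bitscore_ba=ba.bitscore,
        ))
    pairs.sort(key=lambda p: (p.id_a, p.id_b))
    return pairs


def detect_pairs(hits: list[HitRecord], evalue_max: float = 1e-10
                 ) -> list[CandidatePair]:
    """Convenience: rank then apply the reciprocal rule."""
    return reciprocal_second_best(rank_hits(hits), evalue_max=evalue_max)
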