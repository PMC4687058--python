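"""Divergence statistics for duplicate pairs: 4DTV and NG86 Ka/Ks.

4DTV is the proportion of fourfold-degenerate sites at which the two
sequences differ by a transversion.  Because transversions are rarer than
transitions, back mutations at these positions are unlikely, making 4DTV a
robust clock for dating duplication events.  The raw proportion is corrected
for multiple substitutions with Kimura's pure-transversion distance

    B = -1/2 * ln(1 - 2Q),

the two-state (purine/pyrimidine) analogue of Jukes-Cantor; it is monotone,
reduces to Q for small Q, and diverges at the two-state saturation point
Q = 1/2.  The correction is swappable via the ``correction`` argument.

Ka/Ks uses the Nei-Gojobori (1986) counting method: per-codon synonymous and
nonsynonymous site fractions are obtained by enumerating the nine
single-nucleotide neighbours of each codon (mutations to stop codons are
excluded from both the numerator and the site denominators), observed
differences are partitioned by averaging over all minimal substitution
pathways that avoid stop codons, and the proportions are corrected with
Jukes-Cantor, d = -3/4 * ln(1 - 4p/3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Callable

from .genetics import CODON_TABLE, STOP_CODONS, is_transversion
from .align import CodonAlignment, find_4d_sites


@dataclass
class FourDTV:
    n_sites: int
    n_transversions: int
    raw: float | None  # None when no 4D sites
    corrected: float | None = None
    saturated: bool = False


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    omega: float | None
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0
    flags: list[str] = field(default_factory=list)


def raw_4dtv(sites: list[tuple[str, str]] | list[tuple[int, str, str]]) -> FourDTV:
    """Count transversion differences over 4D sites.

    Accepts (base_a, base_b) tuples or the (column, base_a, base_b) output of
    :func:`wgdpairs.align.find_4d_sites`.  With zero sites the statistic is
    undefined (``raw`` is ``None``), not zero."""
    n = 0
    tv = 0
    for site in sites:
        a, b = site[-2], site[-1]
        n += 1
        if is_transversion(a, b):
            tv += 1
    if n == 0:
        return FourDTV(n_sites=0, n_transversions=0, raw=None)
    return FourDTV(n_sites=n, n_transversions=tv, raw=tv / n)


def kimura_transversion_correction(q: float) -> float:
    """-1/2 * ln(1 - 2q); defined for 0 <= q < 0.5."""
    return -0.5 * math.log1p(-2.0 * q)


def correct_4dtv(q: float,
                 correction: Callable[[float], float] = kimura_transversion_correction
                 ) -> float:
    """Multiple-hit-corrected 4DTV.  Raises ``ValueError`` at q >= 0.5 (the
    pair is saturated; flag it rather than reporting a number)."""
    if q < 0.0:
        raise ValueError("raw 4DTV must be >= 0")
    if q >= 0.5:
        raise ValueError("raw 4DTV >= 0.5: transversion distance saturated")
    return correction(q)


def fourdtv_of_alignment(aln: CodonAlignment) -> FourDTV:
    """Raw and corrected 4DTV of a codon alignment; saturated pairs are
    flagged and left uncorrected."""
    res = raw_4dtv(find_4d_sites(aln))
    if res.raw is None:
        return res
    if res.raw >= 0.5:
        res.saturated = True
        return res
    res.corrected = correct_4dtv(res.raw)
    return res


# ---------------------------------------------------------------------------
# NG86


_BASES = "ACGT"


@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon: each position
    contributes one site split by the fraction of its non-stop single-base
    neighbours that are synonymous."""
    syn = 0.0
    aa = CODON_TABLE[codon]
    for pos in range(3):
        s = n = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            cand = codon[:pos] + base + codon[pos + 1:]
            if cand in STOP_CODONS:
                continue
            if CODON_TABLE[cand] == aa:
                s += 1
            else:
                n += 1
        if s + n:
            syn += s / (s + n)
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal substitution pathways that avoid stop codons."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = codon_a
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            total_s += s
            total_n += n
            n_paths += 1
    if n_paths == 0:
        # Every pathway passes through a stop; classify each differing
        # position by the effect of that single change on codon_a.
        warnings.warn(
            f"all substitution pathways between {codon_a} and {codon_b} pass "
            "through stop codons; using single-site classification"
        )
        s = n = 0
        for pos in diff_pos:
            cand = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1:]
            if cand not in STOP_CODONS and CODON_TABLE[cand] == CODON_TABLE[codon_a]:
                s += 1
            else:
                n += 1
        return float(s), float(n)
    return total_s / n_paths, total_n / n_paths


def jukes_cantor(p: float) -> float:
    """d = -3/4 * ln(1 - 4p/3); defined for p < 3/4."""
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_ka_ks(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka, Ks and omega = Ka/Ks from the ungapped codon columns.

    Site counts are averaged over the two sequences.  ``omega`` is ``None``
    when Ks = 0; saturation (p >= 3/4) or an empty alignment sets a flag and
    leaves the affected statistic undefined."""
    columns = [
        (ca, cb) for ca, cb in aln.ungapped_columns()
        if "N" not in ca and "N" not in cb
    ]
    if not columns:
        return KaKsResult(ka=None, ks=None, omega=None, flags=["undefined"])
    S = N = Sd = Nd = 0.0
    for ca, cb in columns:
        sa, na = _codon_site_fractions(ca)
        sb, nb = _codon_site_fractions(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        s, n = _pathway_differences(ca, cb)
        Sd += s
        Nd += n
    res = KaKsResult(ka=None, ks=None, omega=None, syn_sites=S, nonsyn_sites=N,
                     syn_diffs=Sd, nonsyn_diffs=Nd)
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    if ps >= 0.75:
        res.flags.append("ks_saturated")
    else:
        res.ks = jukes_cantor(ps)
    if pn >= 0.75:
        res.flags.append("ka_saturated")
    else:
        res.ka = jukes_cantor(pn)
    if "ks_saturated" in res.flags or "ka_saturated" in res.flags:
        res.flags.append("saturated")
    if res.ka is not None and res.ks is not None and res.ks > 0:
        res.omega = res.ka / res.ks
    return res


@dataclass
class DivergenceEstimates:
    """All divergence statistics for one pair."""

    pair_id: str
    id_a: str
    id_b: str
    n_4d_sites: int
    n_transversions: int
    four_dtv_raw: float | None
    four_dtv_corr: float | None
    ka: float | None
    ks: float | None
    omega: float | None
    flags: list[str] = field(default_factory=list)


def pair_divergence(aln: CodonAlignment, pair_id: str | None = None
                    ) -> DivergenceEstimates:
    """4DTV (raw + corrected) and NG86 Ka/Ks for one codon alignment."""
    dtv = fourdtv_of_alignment(aln)
    kaks = estimate_ka_ks(aln)
    flags = list(kaks.flags)
    if dtv.raw is None:
        flags.append("no_4d_sites")
    elif dtv.saturated:
        flags.append("4dtv_saturated")
    return DivergenceEstimates(
        pair_id=pair_id or f"{aln.id_a}|{aln.id_b}",
        id_a=aln.id_a, id_b=aln.id_b,
        n_4d_sites=dtv.n_sites, n_transversions=dtv.n_transversions,
        four_dtv_raw=dtv.raw, four_dtv_corr=dtv.corrected,
        ka=kaks.ka, ks=kaks.ks, omega=kaks.omega, flags=flags,
    )
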