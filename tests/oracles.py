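"""Independent brute-force oracles used by the test suite.

These reimplement, by different mechanisms, the quantities the package
computes: a plain recursion over the affine-gap alignment space, NG86 site
and pathway counting via depth-first search, exact integer hypergeometric
summation, and exact binomial tail sums.  They are deliberately slow and
simple; they never share code with the implementation they check.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

DNA = "ACGT"

GENETIC_CODE = {}
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_i = 0
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            GENETIC_CODE[_b1 + _b2 + _b3] = _AMINO[_i]
            _i += 1


def alignment_score_oracle(a: str, b: str, gap_open: float = 10.0,
                           gap_extend: float = 1.0) -> float:
    """Maximum global alignment score, affine gaps costing
    gap_open + gap_extend * L, by exhaustive recursion over the alignment
    space (memoised on position + gap state)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 none, 1 gap consuming b, 2 gap consuming a
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(_BLOSUM62[a[i], b[j]] + best(i + 1, j + 1, 0))
        if j < len(b):
            cost = gap_extend + (gap_open if state != 1 else 0.0)
            options.append(-cost + best(i, j + 1, 1))
        if i < len(a):
            cost = gap_extend + (gap_open if state != 2 else 0.0)
            options.append(-cost + best(i + 1, j, 2))
        return max(options)

    return best(0, 0, 0)


def ng86_oracle(codons_a: list[str], codons_b: list[str]
                ) -> tuple[float | None, float | None]:
    """(ka, ks) by independent NG86 counting: per-position synonymous site
    fractions over non-stop neighbours, pathway averaging by depth-first
    search, Jukes-Cantor correction.  Returns (None, None) when saturated."""

    def site_fractions(codon: str) -> float:
        syn = 0.0
        for pos in range(3):
            same = other = 0
            for base in DNA:
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1:]
                if GENETIC_CODE[mut] == "*":
                    continue
                if GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                    same += 1
                else:
                    other += 1
            if same + other:
                syn += same / (same + other)
        return syn

    def paths(cur: str, target: str):
        """Yield (syn_steps, nonsyn_steps) for every stop-free pathway."""
        diffs = [k for k in range(3) if cur[k] != target[k]]
        if not diffs:
            yield (0, 0)
            return
        for k in diffs:
            nxt = cur[:k] + target[k] + cur[k + 1:]
            if GENETIC_CODE[nxt] == "*":
                continue
            step_syn = 1 if GENETIC_CODE[nxt] == GENETIC_CODE[cur] else 0
            for s, n in paths(nxt, target):
                yield (s + step_syn, n + (1 - step_syn))

    S = Sd = Nd = 0.0
    L = len(codons_a)
    for ca, cb in zip(codons_a, codons_b):
        S += (site_fractions(ca) + site_fractions(cb)) / 2.0
        results = list(paths(ca, cb))
        if results:
            Sd += sum(s for s, _ in results) / len(results)
            Nd += sum(n for _, n in results) / len(results)
        else:
            for k in range(3):
                if ca[k] == cb[k]:
                    continue
                mut = ca[:k] + cb[k] + ca[k + 1:]
                if GENETIC_CODE[mut] != "*" and GENETIC_CODE[mut] == GENETIC_CODE[ca]:
                    Sd += 1
                else:
                    Nd += 1
    N = 3.0 * L - S
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return None, None
    ks = -0.75 * math.log(1 - 4 * ps / 3)
    ka = -0.75 * math.log(1 - 4 * pn / 3)
    return ka, ks


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided (overrepresentation) Fisher p for the table [[a, b], [c, d]]
    by exact integer hypergeometric summation."""
    N = a + b + c + d
    K = a + c  # successes in the population
    n = a + b  # draws
    denom = math.comb(N, n)
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
    return float(total)


def binomial_two_sided(ya: int, t: int) -> float:
    """Two-sided exact binomial(t, 1/2) p-value: sum of outcome probabilities
    not exceeding the observed one (exact rational arithmetic)."""
    pmf = [Fraction(math.comb(t, k), 2 ** t) for k in range(t + 1)]
    obs = pmf[ya]
    return float(sum(p for p in pmf if p <= obs))


def spearman_rho_oracle(x, y) -> float:
    """Spearman rho by explicit average-ranking and the Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
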