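"""Expression-vs-sequence-divergence association, annotation transfer and
GO-term enrichment.

Associations use Spearman rank correlation (average ranks for ties; exact
permutation p-value at small n, large-sample approximation otherwise).
Annotation transfer assigns each query the GO set of its single best hit
passing e-value < 1e-10 and bitscore > 40.  Enrichment uses one-sided
Fisher's exact tests per term on the 2x2 table (in test set vs not, has term
vs not), with the test genes removed from the reference margin so the two
margins are disjoint, and BH adjustment across terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_fdr
from .io import HitRecord


def spearman_assoc(x, y, exact_n_max: int = 10) -> tuple[float, float]:
    """Spearman rho and p-value for paired observations.

    Ties take average ranks.  For n <= ``exact_n_max`` the p-value is from
    exact enumeration of all pairings; otherwise the large-sample t
    approximation is used.  A constant input leaves rho undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    if n <= exact_n_max:
        def statistic(perm_x):
            return stats.spearmanr(perm_x, y).statistic

        res = stats.permutation_test(
            (x,), statistic, permutation_type="pairings",
            alternative="two-sided", n_resamples=math.factorial(n) + 1,
        )
        rho = stats.spearmanr(x, y).statistic
        return float(rho), float(res.pvalue)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def transfer_annotations(hits: list[HitRecord],
                         reference_go: dict[str, set[str]],
                         evalue_max: float = 1e-10,
                         bitscore_min: float = 40.0) -> dict[str, set[str]]:
    """Annotate each query with the GO set of its single best reference hit.

    A hit qualifies when e-value < ``evalue_max`` (strict) and bitscore >
    ``bitscore_min`` (strict).  Best = lowest e-value, ties broken by higher
    bitscore then subject id.  Queries without a qualifying hit, or whose best
    hit has no reference terms, are simply absent."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue >= evalue_max or h.bitscore <= bitscore_min:
            continue
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
                cur.evalue, -cur.bitscore, cur.subject_id):
            best[h.query_id] = h
    out: dict[str, set[str]] = {}
    for q, h in best.items():
        terms = reference_go.get(h.subject_id)
        if terms:
            out[q] = set(terms)
    return out


@dataclass
class EnrichmentResult:
    term: str
    test_with: int
    test_without: int
    ref_with: int
    ref_without: int
    odds_ratio: float
    p_value: float
    adjusted_p: float = float("nan")
    overrepresented: bool = False


def fisher_enrichment(test_set: set[str], reference_set: set[str],
                      annotations: dict[str, set[str]],
                      alpha: float = 0.05, mode: str = "disjoint",
                      alternative: str = "greater") -> list[EnrichmentResult]:
    """Per-term Fisher's exact tests of the test set against the reference.

    ``mode="disjoint"`` (default) removes the test genes from the reference
    margin; ``"inclusive"`` keeps them.  ``alternative="greater"`` tests
    overrepresentation.  BH adjustment across terms; a term is called
    overrepresented when its adjusted p <= ``alpha``."""
    test_set = set(test_set)
    reference_set = set(reference_set)
    if not test_set <= reference_set:
        raise ValueError("test set must be a subset of the reference set")
    if not test_set:
        return []
    comparison = reference_set - test_set if mode == "disjoint" else reference_set
    terms = sorted({t for g in test_set | comparison
                    for t in annotations.get(g, ())})
    results = []
    for term in terms:
        a = sum(1 for g in test_set if term in annotations.get(g, ()))
        b = len(test_set) - a
        c = sum(1 for g in comparison if term in annotations.get(g, ()))
        d = len(comparison) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        results.append(EnrichmentResult(
            term=term, test_with=a, test_without=b, ref_with=c, ref_without=d,
            odds_ratio=float(odds), p_value=float(p),
        ))
    if results:
        adj = bh_fdr([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
            r.overrepresented = q <= alpha
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def correlation_table(de: pd.DataFrame, divergence: pd.DataFrame,
                      measures: tuple[str, ...] = ("omega", "ka", "ks",
                                                   "four_dtv_corr"),
                      de_metric: str = "abs_log2_fc") -> pd.DataFrame:
    """Condition x divergence-measure Spearman correlations.

    ``de``: the per-pair per-condition DE table; ``divergence``: per-pair
    divergence statistics indexed by pair id.  The DE quantity correlated is
    |log2 FC| by default (``de_metric="abs_log2_fc"``; ``"fdr"`` and
    ``"log2_fc"`` are also accepted)."""
    rows = []
    for cond, sub in de.groupby("condition"):
        sub = sub.set_index("pair")
        if de_metric == "abs_log2_fc":
            metric = sub["log2_fc"].abs()
        elif de_metric in sub.columns:
            metric = sub[de_metric]
        else:
            raise ValueError(f"unknown DE metric {de_metric!r}")
        for measure in measures:
            joined = pd.concat([metric.rename("de"),
                                divergence[measure].rename("div")],
                               axis=1, join="inner").dropna()
            if len(joined) < 3:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearman_assoc(joined["de"].to_numpy(),
                                        joined["div"].to_numpy())
            rows.append((cond, measure, rho, p, len(joined)))
    return pd.DataFrame(rows, columns=["condition", "measure", "rho", "p_value", "n"])
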