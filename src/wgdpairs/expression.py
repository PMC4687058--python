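"""Expression quantification and copy-vs-copy differential expression.

Counts and effective lengths are inputs (quantification internals such as
RSEM's EM are out of scope; for assembled transcripts the effective length is
taken as the CDS/contig length).  TPM for gene *g* in one sample is

    TPM_g = (count_g / len_g) / sum_h (count_h / len_h) * 1e6

Differential expression between the two copies of a duplicate pair is tested
within one condition (tissue x genotype) by an exact negative-binomial
conditional test: per-sample counts are library-size normalised to
pseudo-counts, summed per copy, and the conditional distribution of the split
of the total between the two copies (negative hypergeometric for a common
dispersion phi; binomial in the Poisson limit phi -> 0) yields a two-sided
exact p-value, as in the classical exact NB test family.  p-values are
adjusted per condition with Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

FC_BIN_EDGES = (0.4, 2.0, 8.0)


@dataclass
class ExpressionTable:
    """Per-gene, per-sample counts with effective lengths and sample metadata.

    ``counts``: genes x samples; ``lengths``: bp per gene; ``samples``: indexed
    by sample id with columns ``tissue``, ``genotype``, ``replicate``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if not self.counts.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]

    @property
    def condition_keys(self) -> pd.Series:
        return self.samples["tissue"] + "_" + self.samples["genotype"].astype(str)

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.condition_keys))

    def samples_for(self, condition: str) -> list[str]:
        keys = self.condition_keys
        return list(keys.index[keys == condition])

    def tpm(self) -> pd.DataFrame:
        return compute_tpm(self.counts, self.lengths)

    def fpkm(self) -> pd.DataFrame:
        return compute_fpkm(self.counts, self.lengths)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million; per-sample columns sum to 1e6.  Samples with a
    zero total are flagged by all-NaN columns."""
    if (lengths.loc[counts.index] <= 0).any():
        raise ValueError("non-positive effective length")
    rate = counts.div(lengths.loc[counts.index], axis=0)
    totals = rate.sum(axis=0)
    tpm = rate.div(totals.where(totals > 0), axis=1) * 1e6
    return tpm


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series,
                 total_fragments: pd.Series | None = None) -> pd.DataFrame:
    """FPKM = count * 1e9 / (length_bp * total mapped fragments in sample)."""
    if total_fragments is None:
        total_fragments = counts.sum(axis=0)
    fpkm = counts.div(lengths.loc[counts.index], axis=0).div(
        total_fragments.where(total_fragments > 0), axis=1
    ) * 1e9
    return fpkm


def call_expressed(tpm: pd.DataFrame, samples: pd.DataFrame,
                   threshold: float = 1.0) -> pd.DataFrame:
    """Gene x condition boolean: expressed iff the arithmetic mean TPM over the
    condition's replicates is strictly above ``threshold``."""
    keys = samples["tissue"] + "_" + samples["genotype"].astype(str)
    out = {}
    for cond in dict.fromkeys(keys):
        cols = keys.index[keys == cond]
        out[cond] = tpm[cols].mean(axis=1) > threshold
    return pd.DataFrame(out, index=tpm.index)


def classify_partitioning(tissues_a: set[str], tissues_b: set[str],
                          tissue_names: tuple[str, str] = ("leaf", "root")) -> str:
    """Classify a pair from the per-tissue expressed calls of its two copies.

    ``tissues_a``/``tissues_b``: the set of tissues in which each copy is
    expressed (in at least one genotype).  Classes:

    - ``both_silent``: neither copy expressed anywhere
    - ``one_silent``: exactly one copy expressed
    - ``single_tissue_<t>``: both copies expressed only in tissue *t*
    - ``partitioned``: the copies are expressed in disjoint single tissues
    - ``both_both``: otherwise (the copies share at least one tissue and at
      least one copy is expressed more broadly than a single common tissue,
      or both are expressed in both tissues)
    """
    t1, t2 = tissue_names
    a = set(tissues_a) & {t1, t2}
    b = set(tissues_b) & {t1, t2}
    if not a and not b:
        return "both_silent"
    if not a or not b:
        return "one_silent"
    if a == b == {t1}:
        return f"single_tissue_{t1}"
    if a == b == {t2}:
        return f"single_tissue_{t2}"
    if not (a & b):
        return "partitioned"
    return "both_both"


# ---------------------------------------------------------------------------
# Exact negative-binomial copy-vs-copy test


def _normalised_pseudocounts(counts: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Scale each sample's counts to the geometric-mean library size and round
    to integers (equal-library pseudo-counts)."""
    libs = counts[sample_ids].sum(axis=0).astype(float)
    if (libs <= 0).all():
        return counts[sample_ids].copy()
    ref = float(np.exp(np.log(libs.where(libs > 0)).mean()))
    factors = ref / libs.where(libs > 0, ref)
    pseudo = counts[sample_ids].mul(factors, axis=1)
    return pseudo.round().astype(np.int64)


def _conditional_logpmf(t: int, r: float | None) -> np.ndarray:
    """log P(Y_a = k | Y_a + Y_b = t) for k = 0..t, for two iid group sums.

    ``r`` is the NB size of each group sum (n_replicates / dispersion); ``None``
    selects the Poisson limit (binomial with p = 1/2)."""
    k = np.arange(t + 1)
    if r is None:
        lp = stats.binom.logpmf(k, t, 0.5)
    else:
        lp = (special.gammaln(k + r) - special.gammaln(k + 1)
              + special.gammaln(t - k + r) - special.gammaln(t - k + 1))
        lp = lp - special.logsumexp(lp)
    return lp


def nb_exact_test(counts_a: np.ndarray, counts_b: np.ndarray,
                  dispersion: float = 0.1) -> tuple[float, float]:
    """Exact conditional test of equal abundance of two copies.

    ``counts_a``/``counts_b``: normalised pseudo-counts of the two copies over
    the same replicates.  Returns ``(log2_fc, p_value)``; the fold change is
    log2((mean_b + 0.5) / (mean_a + 0.5)).  Two-sided p-value as the sum of all
    conditional outcome probabilities not exceeding the observed one.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.shape != counts_b.shape or counts_a.ndim != 1:
        raise ValueError("copy count vectors must be 1-D and equal length")
    n = counts_a.size
    if n < 2:
        raise ValueError("need at least 2 replicates per condition")
    ya = int(round(counts_a.sum()))
    yb = int(round(counts_b.sum()))
    log2_fc = math.log2((counts_b.mean() + 0.5) / (counts_a.mean() + 0.5))
    t = ya + yb
    if t == 0:
        return 0.0, 1.0
    r = None if dispersion <= 0 else n / dispersion
    lp = _conditional_logpmf(t, r)
    obs = lp[ya]
    p = float(np.exp(special.logsumexp(lp[lp <= obs + 1e-9])))
    return log2_fc, min(p, 1.0)


def estimate_common_dispersion(counts: pd.DataFrame, sample_ids: list[str],
                               bounds: tuple[float, float] = (1e-4, 5.0)) -> float:
    """Plug-in profile-likelihood common NB dispersion across genes.

    Maximises sum_g sum_i log NB(y_gi; mean = mean_g, dispersion = phi) over a
    single phi with the per-gene mean profiled out at the sample mean.  A
    simplification of edgeR-style common-dispersion estimation; adequate for
    the equal-replicate designs handled here.
    """
    y = counts[sample_ids].to_numpy(dtype=float)
    mu = y.mean(axis=1, keepdims=True)
    keep = mu[:, 0] > 0
    y, mu = y[keep], mu[keep]

    def neg_ll(log_phi: float) -> float:
        phi = math.exp(log_phi)
        r = 1.0 / phi
        ll = (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
              + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
        return -float(ll.sum())

    res = optimize.minimize_scalar(
        neg_ll, bounds=(math.log(bounds[0]), math.log(bounds[1])), method="bounded"
    )
    return float(math.exp(res.x))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving by the
    original index; monotonicity enforced."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def fc_bin(log2_fc: float) -> str:
    """Fold-change bin on |log2 FC|: low < 0.4 <= mid <= 2 < high <= 8 < extreme."""
    a = abs(log2_fc)
    if a < FC_BIN_EDGES[0]:
        return "low"
    if a <= FC_BIN_EDGES[1]:
        return "mid"
    if a <= FC_BIN_EDGES[2]:
        return "high"
    return "extreme"


def de_test_pairs(table: ExpressionTable, pairs: list[tuple[str, str, str]],
                  dispersion: float = 0.1, fdr_max: float = 0.05) -> pd.DataFrame:
    """Copy-vs-copy DE tests for every pair in every condition.

    ``pairs``: (pair_id, id_a, id_b).  Returns one row per pair per condition
    with log2_fc, p_value, BH-adjusted fdr (family = all pairs within the
    condition), the significance call (fdr <= ``fdr_max``) and the fc bin.
    """
    rows = []
    for cond in table.conditions():
        sample_ids = table.samples_for(cond)
        if len(sample_ids) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        pseudo = _normalised_pseudocounts(table.counts, sample_ids)
        stats_rows = []
        for pair_id, id_a, id_b in pairs:
            fc, p = nb_exact_test(
                pseudo.loc[id_a].to_numpy(), pseudo.loc[id_b].to_numpy(),
                dispersion=dispersion,
            )
            stats_rows.append((pair_id, cond, fc, p))
        if not stats_rows:
            continue
        df = pd.DataFrame(stats_rows, columns=["pair", "condition", "log2_fc", "p_value"])
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        df["significant"] = df["fdr"] <= fdr_max
        df["fc_bin"] = df["log2_fc"].map(fc_bin)
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["pair", "condition", "log2_fc", "p_value", "fdr",
                     "significant", "fc_bin"]
        )
    return pd.concat(rows, ignore_index=True)
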