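"""TPM, expressed calls, partitioning, the exact NB test and BH-FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import binomial_two_sided
from wgdpairs.expression import (
    bh_fdr, call_expressed, classify_partitioning, compute_fpkm, compute_tpm,
    estimate_common_dispersion, fc_bin, nb_exact_test,
)


def _samples(n, tissue="leaf", genotype="520"):
    return pd.DataFrame(
        {"tissue": tissue, "genotype": genotype,
         "replicate": range(1, n + 1)},
        index=[f"{tissue}_{genotype}_r{i}" for i in range(1, n + 1)],
    )


# ---------------------------------------------------------------------------
# TPM / FPKM

def test_tpm_equal_genes_split_the_million():
    counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 100, "g2": 100})
    tpm = compute_tpm(counts, lengths)
    assert tpm["s1"].tolist() == [500_000.0, 500_000.0]


def test_tpm_single_expressed_gene_and_length_weighting():
    counts = pd.DataFrame({"s1": [7, 0]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 100, "g2": 100})
    assert compute_tpm(counts, lengths)["s1"].tolist() == [1_000_000.0, 0.0]
    counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 100, "g2": 200})
    tpm = compute_tpm(counts, lengths)["s1"]
    assert tpm.tolist() == pytest.approx([666_666.666667, 333_333.333333])


def test_tpm_columns_sum_to_one_million(small_dataset):
    tpm = small_dataset.expression.tpm()
    sums = tpm.sum(axis=0)
    assert np.allclose(sums, 1e6, rtol=1e-9)


def test_tpm_all_zero_sample_is_flagged_nan():
    counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 1]}, index=["g1", "g2"])
    lengths = pd.Series({"g1": 100, "g2": 100})
    tpm = compute_tpm(counts, lengths)
    assert tpm["s1"].isna().all()
    assert tpm["s2"].sum() == pytest.approx(1e6)


def test_fpkm_definition():
    counts = pd.DataFrame({"s1": [100]}, index=["g1"])
    lengths = pd.Series({"g1": 1000})
    total = pd.Series({"s1": 1_000_000})
    fpkm = compute_fpkm(counts, lengths, total)
    assert fpkm.loc["g1", "s1"] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# Expressed calls and partitioning

def test_call_expressed_mean_rule_is_strict():
    samples = _samples(2)
    tpm = pd.DataFrame(
        {"leaf_520_r1": [0.5, 1.0, 0.0], "leaf_520_r2": [1.6, 1.0, 0.0]},
        index=["g1", "g2", "g3"],
    )
    calls = call_expressed(tpm, samples)
    assert calls["leaf_520"].tolist() == [True, False, False]  # mean 1.05 / 1.0 / 0


@pytest.mark.parametrize("a,b,expected", [
    ({"leaf", "root"}, {"leaf", "root"}, "both_both"),
    ({"leaf"}, {"root"}, "partitioned"),
    ({"root"}, {"leaf"}, "partitioned"),
    ({"leaf"}, {"leaf"}, "single_tissue_leaf"),
    ({"root"}, {"root"}, "single_tissue_root"),
    ({"leaf"}, {"leaf", "root"}, "both_both"),
    (set(), {"leaf"}, "one_silent"),
    (set(), set(), "both_silent"),
])
def test_partitioning_classes_exhaustive(a, b, expected):
    assert classify_partitioning(a, b) == expected


# ---------------------------------------------------------------------------
# Exact NB test

def test_identical_copies_give_null_result():
    counts = np.array([10, 20, 30, 40])
    fc, p = nb_exact_test(counts, counts.copy(), dispersion=0.1)
    assert fc == 0.0
    assert p == pytest.approx(1.0)


def test_zero_total_gives_p_one_fc_zero():
    z = np.zeros(3)
    fc, p = nb_exact_test(z, z, dispersion=0.1)
    assert (fc, p) == (0.0, 1.0)


def test_replicate_count_guard():
    with pytest.raises(ValueError, match="replicates"):
        nb_exact_test(np.array([5.0]), np.array([7.0]))


def test_poisson_limit_matches_exact_binomial_oracle():
    """dispersion -> 0 reduces the conditional split test to binomial(t, 1/2)."""
    cases = [
        (np.array([3, 2]), np.array([8, 7])),
        (np.array([0, 1]), np.array([10, 12])),
        (np.array([12, 13]), np.array([12, 13])),
        (np.array([25, 0]), np.array([0, 25])),
        (np.array([4, 4, 4]), np.array([9, 9, 9])),
    ]
    for ca, cb in cases:
        _, p = nb_exact_test(ca, cb, dispersion=0.0)
        ya, t = int(ca.sum()), int(ca.sum() + cb.sum())
        assert p == pytest.approx(binomial_two_sided(ya, t), abs=1e-9)


def test_dispersion_widens_the_null():
    ca = np.array([100, 110, 90, 105])
    cb = np.array([140, 150, 135, 150])
    _, p_poisson = nb_exact_test(ca, cb, dispersion=0.0)
    _, p_nb = nb_exact_test(ca, cb, dispersion=0.2)
    assert p_nb > p_poisson


def test_common_dispersion_estimate_in_range(rng):
    true_phi = 0.15
    r = 1 / true_phi
    mu = 200.0
    y = rng.negative_binomial(r, r / (r + mu), size=(400, 5))
    counts = pd.DataFrame(y, columns=[f"s{i}" for i in range(5)])
    est = estimate_common_dispersion(counts, list(counts.columns))
    assert 0.10 < est < 0.22


# ---------------------------------------------------------------------------
# BH and fold-change bins

def test_bh_step_up_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases_and_validation():
    assert bh_fdr([0.2]).tolist() == [0.2]
    assert bh_fdr([1.0, 1.0]).tolist() == [1.0, 1.0]
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=40))
def test_bh_matches_statsmodels(pvals):
    from statsmodels.stats.multitest import multipletests

    ours = bh_fdr(pvals)
    theirs = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(ours, theirs, atol=1e-12)


@pytest.mark.parametrize("fc,expected", [
    (0.0, "low"), (0.39, "low"), (0.4, "mid"), (-1.0, "mid"), (2.0, "mid"),
    (2.01, "high"), (8.0, "high"), (-8.5, "extreme"),
])
def test_fc_bins_partition_at_documented_edges(fc, expected):
    assert fc_bin(fc) == expected
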