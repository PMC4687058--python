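"""Spearman associations, annotation transfer and Fisher enrichment."""

import numpy as np
import pytest

from oracles import hypergeom_upper_tail, spearman_rho_oracle
from wgdpairs.enrichment import (
    fisher_enrichment, spearman_assoc, transfer_annotations,
)
from wgdpairs.io import HitRecord


def hit(q, s, evalue, bitscore):
    return HitRecord(query_id=q, subject_id=s, evalue=evalue, bitscore=bitscore)


# ---------------------------------------------------------------------------
# Spearman

def test_spearman_perfect_monotone():
    rho, p = spearman_assoc([1, 2, 3], [3, 2, 1])
    assert rho == pytest.approx(-1.0)
    x = np.arange(100.0)
    rho, _ = spearman_assoc(x, x)
    assert rho == pytest.approx(1.0)


def test_spearman_ties_match_hand_ranked_formula():
    x = [1, 1, 2, 3]
    y = [2, 1, 4, 8]
    rho, _ = spearman_assoc(x, y)
    assert rho == pytest.approx(spearman_rho_oracle(x, y), abs=1e-12)


def test_spearman_invariant_under_monotone_transforms(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    rho1, p1 = spearman_assoc(x, y)
    rho2, p2 = spearman_assoc(np.exp(x), 3 * y + 7)
    assert rho1 == pytest.approx(rho2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_spearman_constant_input_undefined():
    rho, p = spearman_assoc([1.0, 1.0, 1.0], [1, 2, 3])
    assert np.isnan(rho) and np.isnan(p)
    with pytest.raises(ValueError):
        spearman_assoc([1, 2], [1, 2])


def test_spearman_small_n_exact_permutation_p():
    # n=4, rho=1: 1 of 4! pairings reaches |rho| = 1 in each direction
    rho, p = spearman_assoc([1, 2, 3, 4], [10, 20, 30, 40])
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(2 / 24, abs=1e-12)


# ---------------------------------------------------------------------------
# Annotation transfer

def test_transfer_best_hit_rules():
    ref_go = {"At1": {"GO:0003677"}, "At2": {"GO:0000001"}}
    hits = [
        hit("q1", "At1", 1e-20, 80.0),      # qualifies
        hit("q2", "At1", 1e-20, 35.0),      # bitscore too low
        hit("q3", "At1", 1e-8, 90.0),       # e-value too high
        hit("q4", "At1", 1e-30, 90.0),      # equal e-value ties ...
        hit("q4", "At2", 1e-30, 50.0),      # ... broken by bitscore
    ]
    ann = transfer_annotations(hits, ref_go)
    assert ann == {"q1": {"GO:0003677"}, "q4": {"GO:0003677"}}


def test_transfer_boundary_thresholds_are_strict():
    ref_go = {"At1": {"GO:0000001"}}
    assert transfer_annotations([hit("q", "At1", 1e-10, 80.0)], ref_go) == {}
    assert transfer_annotations([hit("q", "At1", 1e-20, 40.0)], ref_go) == {}


# ---------------------------------------------------------------------------
# Fisher enrichment

def test_fisher_p_equals_hypergeometric_sum():
    annotations = {}
    # a=5 test-with, b=5 test-without, c=5 ref-with, d=85 ref-without
    test = {f"t{i}" for i in range(10)}
    ref_extra = {f"r{i}" for i in range(90)}
    for i in range(5):
        annotations[f"t{i}"] = {"GO:X"}
        annotations[f"r{i}"] = {"GO:X"}
    res = fisher_enrichment(test, test | ref_extra, annotations)
    r = next(x for x in res if x.term == "GO:X")
    assert (r.test_with, r.test_without, r.ref_with, r.ref_without) == (5, 5, 5, 85)
    assert r.p_value == pytest.approx(hypergeom_upper_tail(5, 5, 5, 85),
                                      abs=1e-12)


def test_fisher_ubiquitous_term_is_not_enriched():
    genes = {f"g{i}" for i in range(40)}
    annotations = {g: {"GO:ALL"} for g in genes}
    res = fisher_enrichment(set(list(genes)[:10]), genes, annotations)
    assert res[0].p_value == pytest.approx(1.0)


def test_fisher_test_only_term_is_strongly_enriched():
    annotations = {f"t{i}": {"GO:Y"} for i in range(10)}
    test = set(annotations)
    ref = test | {f"r{i}" for i in range(90)}
    res = fisher_enrichment(test, ref, annotations)
    r = res[0]
    assert r.p_value < 1e-6
    assert r.p_value == pytest.approx(hypergeom_upper_tail(10, 0, 0, 90),
                                      rel=1e-9)
    assert r.overrepresented


def test_fisher_validates_and_handles_empty_test():
    with pytest.raises(ValueError):
        fisher_enrichment({"a"}, {"b"}, {})
    assert fisher_enrichment(set(), {"b"}, {}) == []


def test_enrichment_null_false_positive_rate(rng):
    """Annotations independent of set membership: few terms reach adjusted
    significance."""
    genes = [f"g{i}" for i in range(400)]
    terms = [f"GO:{i:07d}" for i in range(40)]
    annotations = {
        g: {terms[j] for j in rng.choice(40, size=3, replace=False)}
        for g in genes
    }
    test = set(rng.choice(genes, size=100, replace=False))
    res = fisher_enrichment(test, set(genes), annotations)
    frac = np.mean([r.overrepresented for r in res])
    assert frac <= 0.05 + 0.05


def test_pair_copies_annotated_identically_on_synthetic(small_dataset):
    go = small_dataset.go_map
    for t in small_dataset.truth.pairs.values():
        assert go[t.id_a] == go[t.id_b]
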