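"""4DTV statistics and the NG86 Ka/Ks estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import ng86_oracle
from conftest import mutated_copy, random_sense_codons
from wgdpairs.align import CodonAlignment, codon_alignment_for_pair, find_4d_sites
from wgdpairs.divergence import (
    correct_4dtv, estimate_ka_ks, fourdtv_of_alignment, pair_divergence,
    raw_4dtv,
)
from wgdpairs.simulate import SimulationConfig, simulate_genes


def test_raw_4dtv_counting():
    res = raw_4dtv([("A", "T"), ("A", "G"), ("C", "C")])
    assert (res.n_sites, res.n_transversions) == (3, 1)
    assert res.raw == pytest.approx(1 / 3)
    assert raw_4dtv([("A", "A"), ("G", "G")]).raw == 0.0


def test_raw_4dtv_zero_sites_is_undefined_not_zero():
    res = raw_4dtv([])
    assert res.raw is None


def test_raw_4dtv_saturated_boundary():
    res = raw_4dtv([("A", "C")])
    assert res.raw == 1.0
    with pytest.raises(ValueError, match="saturated"):
        correct_4dtv(res.raw)


@pytest.mark.parametrize("q,expected", [
    (0.0, 0.0),
    (0.1, 0.111572),
    (0.49, 1.956012),
])
def test_correction_values(q, expected):
    assert correct_4dtv(q) == pytest.approx(expected, abs=1e-6)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.499))
def test_correction_monotone_and_at_least_identity(q):
    assert correct_4dtv(q) >= q
    eps = 1e-6
    if q + eps < 0.5:
        assert correct_4dtv(q + eps) > correct_4dtv(q)


def test_ka_ks_identical_sequences():
    codons = ["ATG", "GCT", "GGA", "AAA"]
    aln = CodonAlignment("a", "b", codons, codons)
    res = estimate_ka_ks(aln)
    assert res.ka == 0.0
    assert res.ks == 0.0
    assert res.omega is None


def test_ka_ks_single_synonymous_codon():
    # TTT and TTC both encode Phe: one synonymous difference, no nonsynonymous.
    # On a single codon the synonymous proportion Sd/S = 1/(1/3) saturates the
    # Jukes-Cantor correction, so Ks is flagged rather than reported.
    aln = CodonAlignment("a", "b", ["TTT"], ["TTC"])
    res = estimate_ka_ks(aln)
    assert res.syn_diffs == pytest.approx(1.0)
    assert res.nonsyn_diffs == pytest.approx(0.0)
    assert res.ka == 0.0
    assert res.ks is None and "ks_saturated" in res.flags
    # over a background of identical codons the same difference yields
    # ka = 0 and ks > 0
    aln = CodonAlignment("a", "b", ["TTT"] + ["GGA"] * 9, ["TTC"] + ["GGA"] * 9)
    res = estimate_ka_ks(aln)
    assert res.ka == 0.0
    assert res.ks > 0.0
    assert res.omega == 0.0


def test_ka_ks_empty_alignment_flagged():
    aln = CodonAlignment("a", "b", ["---"], ["GGA"])
    res = estimate_ka_ks(aln)
    assert res.ka is None and "undefined" in res.flags


def test_ka_ks_matches_pathway_enumeration_oracle(rng):
    """NG86 against an independent DFS pathway/site-count oracle."""
    for _ in range(60):
        a = random_sense_codons(rng, 50)
        b = mutated_copy(rng, a, p_sub=0.08)
        aln = CodonAlignment("a", "b", a, b)
        res = estimate_ka_ks(aln)
        ka_o, ks_o = ng86_oracle(a, b)
        if ka_o is None:
            assert "saturated" in res.flags
            continue
        assert res.ka == pytest.approx(ka_o, abs=1e-9)
        assert res.ks == pytest.approx(ks_o, abs=1e-9)


def _simulated_omegas(nonsyn_scale, seed, n_pairs=120):
    cfg = SimulationConfig(seed=seed, n_wgd_pairs=n_pairs, n_tandem_pairs=0,
                           n_singletons=0, n_codons_range=(190, 210),
                           nonsyn_rate_scale=nonsyn_scale,
                           branch_transversion_rate=0.12)
    records, truth = simulate_genes(cfg)
    by_id = {r.id: r for r in records}
    out = []
    for t in truth.pairs.values():
        aln = codon_alignment_for_pair(by_id[t.id_a].cds, by_id[t.id_b].cds)
        est = pair_divergence(aln, t.pair_id)
        out.append(est)
    return out


def test_neutral_evolution_recovers_omega_near_one():
    omegas = [e.omega for e in _simulated_omegas(1.0, seed=21)
              if e.omega is not None]
    assert 0.85 < np.median(omegas) < 1.15


def test_purifying_selection_recovers_low_omega():
    omegas = [e.omega for e in _simulated_omegas(0.25, seed=22)
              if e.omega is not None]
    assert np.median(omegas) < 0.5


def test_ks_and_corrected_4dtv_positively_correlated():
    """Both statistics index synonymous divergence, so pooling pairs across a
    range of divergences they must rise together."""
    ks, dtv = [], []
    for i, rate in enumerate((0.05, 0.08, 0.12, 0.16, 0.19)):
        cfg = SimulationConfig(seed=30 + i, n_wgd_pairs=20, n_tandem_pairs=0,
                               n_singletons=0, n_codons_range=(190, 210),
                               branch_transversion_rate=rate)
        records, truth = simulate_genes(cfg)
        by_id = {r.id: r for r in records}
        for t in truth.pairs.values():
            aln = codon_alignment_for_pair(by_id[t.id_a].cds, by_id[t.id_b].cds)
            est = pair_divergence(aln, t.pair_id)
            if est.ks is not None and est.four_dtv_corr is not None:
                ks.append(est.ks)
                dtv.append(est.four_dtv_corr)
    assert np.corrcoef(ks, dtv)[0, 1] > 0.5


def test_fourdtv_of_alignment_saturation_flag():
    aln = CodonAlignment("a", "b", ["GGA", "GGA"], ["GGT", "GGC"])
    res = fourdtv_of_alignment(aln)
    assert res.raw == 1.0
    assert res.saturated and res.corrected is None
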