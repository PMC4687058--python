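"""Generator contracts: determinism, planted divergence, placement, counts."""

import math

import numpy as np
import pytest

from wgdpairs.genetics import STOP_CODONS, codons_of
from wgdpairs.simulate import (
    SimulationConfig, simulate_counts, simulate_dataset, simulate_genes,
    simulate_hits, write_dataset,
)
from wgdpairs.align import codon_alignment_for_pair, find_4d_sites
from wgdpairs.divergence import raw_4dtv
from wgdpairs.pairs import detect_pairs


def test_config_validation():
    with pytest.raises(ValueError, match="branch_transversion_rate"):
        SimulationConfig(branch_transversion_rate=0.5)
    with pytest.raises(ValueError, match="tandem_distance_bp"):
        SimulationConfig(tandem_distance_bp=100_000)
    with pytest.raises(ValueError):
        SimulationConfig(n_singletons=-1)


def test_singletons_only_gives_empty_truth():
    cfg = SimulationConfig(seed=3, n_wgd_pairs=0, n_tandem_pairs=0,
                           n_singletons=5)
    records, truth = simulate_genes(cfg)
    assert len(records) == 5
    assert truth.pairs == {}
    assert len(truth.singletons) == 5


def test_fixed_seed_is_byte_identical(tmp_path):
    cfg = SimulationConfig(seed=1, n_wgd_pairs=4, n_tandem_pairs=2,
                           n_singletons=5, n_codons_range=(170, 200))
    for sub in ("a", "b"):
        write_dataset(simulate_dataset(cfg), tmp_path / sub)
    for name in ("cds.fasta", "pep.fasta", "genes.bed", "hits.tsv",
                 "counts.tsv", "samples.tsv", "go_map.tsv", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == \
               (tmp_path / "b" / name).read_bytes(), name


def test_no_internal_stops_and_valid_cds_structure(small_dataset):
    for rec in small_dataset.records:
        codons = codons_of(rec.cds)
        assert codons[0] == "ATG"
        assert codons[-1] in STOP_CODONS
        assert not any(c in STOP_CODONS for c in codons[:-1])


def test_placement_obeys_pair_class(small_dataset):
    by_id = {r.id: r for r in small_dataset.records}
    cfg = small_dataset.config
    for t in small_dataset.truth.pairs.values():
        a, b = by_id[t.id_a], by_id[t.id_b]
        if t.kind == "wgd":
            assert a.chromosome != b.chromosome
        else:
            assert a.chromosome == b.chromosome
            gap = max(a.start, b.start) - min(a.end, b.end)
            assert gap == cfg.tandem_distance_bp


def test_planted_raw_4dtv_matches_target():
    """Mean realised raw 4DTV over pairs within 3 binomial SE of the target;
    the per-pair value as measured from the sequences equals the recorded
    ground truth exactly."""
    cfg = SimulationConfig(seed=5, n_wgd_pairs=60, n_tandem_pairs=0,
                           n_singletons=0, n_codons_range=(290, 310),
                           branch_transversion_rate=0.10)
    records, truth = simulate_genes(cfg)
    by_id = {r.id: r for r in records}
    raws = []
    n_sites_total = 0
    for t in truth.pairs.values():
        aln = codon_alignment_for_pair(by_id[t.id_a].cds, by_id[t.id_b].cds)
        res = raw_4dtv(find_4d_sites(aln))
        # rare parallel prefix substitutions can add a 4D column that was not
        # in the planting set, shifting the measured raw value by ~1/n_sites
        assert res.raw == pytest.approx(t.realised_raw_4dtv, abs=2.5 / res.n_sites)
        raws.append(res.raw)
        n_sites_total += res.n_sites
    se = math.sqrt(0.1 * 0.9 / n_sites_total)
    assert abs(np.mean(raws) - 0.10) <= 3 * se


def test_counts_null_pairs_have_equal_means(rng):
    cfg = SimulationConfig(seed=9, n_wgd_pairs=40, n_tandem_pairs=0,
                           n_singletons=0, n_codons_range=(320, 340),
                           fraction_de_pairs=0.0, nb_dispersion=0.0,
                           mean_expression=500.0,
                           conditions=(("leaf", "520", 6),))
    records, truth = simulate_genes(cfg)
    table = simulate_counts(records, truth, cfg)
    assert all(all(v == 0.0 for v in t.fc_log2.values())
               for t in truth.pairs.values())
    by_id = {r.id: r for r in records}
    for t in truth.pairs.values():
        ca = table.counts.loc[t.id_a].mean()
        cb = table.counts.loc[t.id_b].mean()
        mu = 500.0 * len(by_id[t.id_a].cds) / 1000.0
        # Poisson limit: copy means agree within sampling error
        assert abs(ca - cb) < 6 * math.sqrt(2 * mu / 6)


def test_counts_recover_planted_fold_change():
    cfg = SimulationConfig(seed=13, n_wgd_pairs=100, n_tandem_pairs=0,
                           n_singletons=0, n_codons_range=(330, 336),
                           fraction_de_pairs=1.0, fc_log2_effects=(4.0, 0.0),
                           mean_expression=500.0,
                           conditions=(("leaf", "520", 5),))
    records, truth = simulate_genes(cfg)
    table = simulate_counts(records, truth, cfg)
    ratios = []
    for t in truth.pairs.values():
        fc = t.fc_log2["leaf_520"]
        assert abs(fc) == pytest.approx(4.0)
        ca = table.counts.loc[t.id_a].mean()
        cb = table.counts.loc[t.id_b].mean()
        ratios.append(math.copysign(1, fc) * math.log2(cb / ca))
    assert abs(np.mean(ratios) - 4.0) < 0.2


def test_counts_rejects_unknown_truth_ids(small_dataset):
    cfg = small_dataset.config
    records, truth = simulate_genes(cfg)
    truth.singletons.append("ghost0001")
    with pytest.raises(ValueError, match="ghost0001"):
        simulate_counts(records, truth, cfg)


def test_hits_construction_single_pair_and_singleton():
    cfg = SimulationConfig(seed=2, n_wgd_pairs=1, n_tandem_pairs=0,
                           n_singletons=1, n_codons_range=(170, 180))
    records, truth = simulate_genes(cfg)
    hits = simulate_hits(records, truth)
    rows = {(h.query_id, h.subject_id) for h in hits}
    assert rows == {
        ("wgd0001a", "wgd0001a"), ("wgd0001a", "wgd0001b"),
        ("wgd0001b", "wgd0001b"), ("wgd0001b", "wgd0001a"),
        ("sgl0001", "sgl0001"),
    }
    for h in hits:
        if h.query_id != h.subject_id:
            assert h.evalue < 1e-10
            self_score = next(x.bitscore for x in hits
                              if x.query_id == h.query_id
                              and x.subject_id == h.query_id)
            assert h.bitscore < self_score


def test_decoy_hits_do_not_create_pairs():
    cfg = SimulationConfig(seed=4, n_wgd_pairs=5, n_tandem_pairs=0,
                           n_singletons=10, n_codons_range=(170, 200))
    ds_plain = simulate_dataset(cfg, n_decoys=0)
    ds_decoy = simulate_dataset(cfg, n_decoys=30)
    pairs_plain = {(p.id_a, p.id_b) for p in detect_pairs(ds_plain.hits)}
    pairs_decoy = {(p.id_a, p.id_b) for p in detect_pairs(ds_decoy.hits)}
    assert pairs_plain == pairs_decoy
    assert pairs_plain == {(t.id_a, t.id_b)
                           for t in ds_plain.truth.pairs.values()}


def test_go_terms_identical_within_pairs(small_dataset):
    go = small_dataset.go_map
    for t in small_dataset.truth.pairs.values():
        assert go[t.id_a] == go[t.id_b]
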