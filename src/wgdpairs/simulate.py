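"""Synthetic genome + transcriptome with planted duplicate pairs.

The generator plants three gene classes with full ground truth:

* WGD pairs — an ancestral random CDS evolved into two copies placed on
  different chromosomes, with a controlled transversion divergence at
  fourfold-degenerate (4D) sites;
* tandem pairs — same divergence process, both copies on one chromosome at a
  controlled genomic separation (< 100 kb), so the proximity filter has true
  positives;
* singletons — unpaired genes.

Divergence model.  Non-4D positions (codon positions 1 and 2, and third
positions outside the eight 4D codon families) evolve on each branch by
single-nucleotide proposals whose transition:transversion mix follows kappa
(K80 rates); proposals creating a stop codon are rejected, and nonsynonymous
proposals are accepted with probability ``nonsyn_rate_scale``, which tunes the
true Ka/Ks of the planted pairs.  At the surviving 4D sites of each pair an
exact quota ``round(branch_transversion_rate * n_4D)`` of transversion
differences is planted at randomly chosen sites, and transitions are added at
the remaining 4D sites with the K80 transition-difference probability matched
to the same divergence.  Planting a quota rather than per-site coin flips
pins each pair's realised raw 4DTV to its target within rounding
(<= 1/(2 n_4D)), so window-recovery checks are exact while the expected raw
4DTV still equals ``branch_transversion_rate``.

Read counts are negative binomial with a per-gene mean proportional to CDS
length (``mean_expression`` is the expected count of a 1-kb transcript), with
the planted copy-vs-copy log2 fold change split symmetrically between the two
copies (x 2^(+-fc/2)).  Effective length equals CDS length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import (
    FOURFOLD_PREFIXES, SENSE_CODONS, STOP_CODONS, TRANSITION, TRANSVERSIONS,
    CODON_TABLE, translate,
)
from .io import (
    HitRecord, SequenceRecord, write_bed, write_counts_tsv, write_fasta,
    write_go_map, write_hits_tabular, write_sample_sheet,
)
from .expression import ExpressionTable

#: The study design the generator emulates: two tissues x two genotypes with
#: 5/5/4/4 sequenced biological replicates.
DEFAULT_CONDITIONS = (
    ("leaf", "520", 5),
    ("leaf", "592", 5),
    ("root", "520", 4),
    ("root", "592", 4),
)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_wgd_pairs: int = 100
    n_tandem_pairs: int = 20
    n_singletons: int = 200
    n_codons_range: tuple[int, int] = (170, 450)
    branch_transversion_rate: float = 0.10  # target raw 4DTV per pair
    ts_tv_ratio: float = 2.0  # kappa
    nonsyn_rate_scale: float = 0.25  # acceptance prob of nonsynonymous changes
    n_chromosomes: int = 19
    tandem_distance_bp: int = 20_000
    conditions: tuple[tuple[str, str, int], ...] = DEFAULT_CONDITIONS
    nb_dispersion: float = 0.1
    mean_expression: float = 200.0  # expected count for a 1-kb transcript
    fc_log2_effects: tuple[float, float] = (1.2, 0.8)  # |effect| ~ N(mu, sd)
    fraction_de_pairs: float = 0.76
    go_n_terms: int = 50
    go_terms_per_gene: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.branch_transversion_rate < 0.5:
            raise ValueError(
                "branch_transversion_rate must lie in (0, 0.5): the "
                "multiple-hit correction -0.5*ln(1-2q) is undefined at >= 0.5"
            )
        if self.tandem_distance_bp >= 100_000:
            raise ValueError("tandem_distance_bp must be < 100000")
        for name in ("n_wgd_pairs", "n_tandem_pairs", "n_singletons",
                     "n_chromosomes", "go_n_terms", "go_terms_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_codons_range[0] < 5 or self.n_codons_range[0] > self.n_codons_range[1]:
            raise ValueError("invalid n_codons_range")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0.0 <= self.fraction_de_pairs <= 1.0:
            raise ValueError("fraction_de_pairs must lie in [0, 1]")


@dataclass
class PairTruth:
    pair_id: str
    kind: str  # "wgd" | "tandem"
    id_a: str
    id_b: str
    target_raw_4dtv: float
    realised_raw_4dtv: float
    fc_log2: dict[str, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    pairs: dict[str, PairTruth] = field(default_factory=dict)
    singletons: list[str] = field(default_factory=list)

    def pair_ids_of_kind(self, kind: str) -> list[str]:
        return [p for p, t in self.pairs.items() if t.kind == kind]

    def member_pairs(self, kind: str | None = None) -> set[frozenset[str]]:
        return {
            frozenset((t.id_a, t.id_b))
            for t in self.pairs.values()
            if kind is None or t.kind == kind
        }

    def to_json(self, path: str | Path) -> None:
        data = {
            "pairs": {k: asdict(v) for k, v in sorted(self.pairs.items())},
            "singletons": list(self.singletons),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            pairs={k: PairTruth(**v) for k, v in data["pairs"].items()},
            singletons=data["singletons"],
        )


# ---------------------------------------------------------------------------
# Sequence evolution


def _k80_difference_probs(q_tv: float, kappa: float, scale: float = 1.0
                          ) -> tuple[float, float]:
    """(P_transition_diff, P_transversion_diff) between two sequences whose
    total path has a K80 transversion-difference probability ``q_tv``; ``scale``
    rescales the underlying branch length (0.5 = one of two equal branches)."""
    bT = -math.log(1.0 - 2.0 * q_tv) / 4.0 * scale
    aT = kappa * bT
    e4 = math.exp(-4.0 * bT)
    e2 = math.exp(-2.0 * (aT + bT))
    p_tv = 0.5 * (1.0 - e4)
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    return p_ts, p_tv


def _random_cds_codons(n_codons: int, rng: np.random.Generator) -> list[str]:
    """ATG + random internal sense codons + one stop codon."""
    internal = [SENSE_CODONS[i] for i in
                rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)]
    stop = sorted(STOP_CODONS)[rng.integers(0, 3)]
    return ["ATG"] + internal + [stop]


def _mutate_position(codons: list[str], ci: int, pj: int, p_ts: float,
                     p_tv: float, nonsyn_scale: float,
                     rng: np.random.Generator) -> None:
    """Propose a K80-weighted substitution at one codon position; reject stops
    and (with prob 1 - nonsyn_scale) nonsynonymous changes."""
    u = rng.random()
    codon = codons[ci]
    base = codon[pj]
    if u < p_ts:
        new = TRANSITION[base]
    elif u < p_ts + p_tv:
        new = TRANSVERSIONS[base][rng.integers(0, 2)]
    else:
        return
    cand = codon[:pj] + new + codon[pj + 1:]
    if cand in STOP_CODONS:
        return
    if CODON_TABLE[cand] != CODON_TABLE[codon] and rng.random() >= nonsyn_scale:
        return
    codons[ci] = cand


def _evolve_pair(anc: list[str], cfg: SimulationConfig,
                 rng: np.random.Generator) -> tuple[list[str], list[str], float]:
    """Evolve an ancestral codon list into two diverged copies.

    Returns (codons_a, codons_b, realised_raw_4dtv)."""
    q = cfg.branch_transversion_rate
    kappa = cfg.ts_tv_ratio
    p_ts_b, p_tv_b = _k80_difference_probs(q, kappa, scale=0.5)  # per branch
    p_ts_t, _ = _k80_difference_probs(q, kappa, scale=1.0)  # leaf-to-leaf

    a = list(anc)
    b = list(anc)
    n = len(anc)
    fourfold_anc = [i for i in range(1, n - 1) if anc[i][:2] in FOURFOLD_PREFIXES]

    # Branch evolution of non-4D positions (4D third positions are reserved
    # for the quota planting below).
    for copy in (a, b):
        for ci in range(1, n - 1):
            for pj in (0, 1):
                _mutate_position(copy, ci, pj, p_ts_b, p_tv_b,
                                 cfg.nonsyn_rate_scale, rng)
            if anc[ci][:2] not in FOURFOLD_PREFIXES:
                _mutate_position(copy, ci, 2, p_ts_b, p_tv_b,
                                 cfg.nonsyn_rate_scale, rng)

    # 4D sites that survived prefix evolution in both copies.
    fourd = [i for i in fourfold_anc
             if a[i][:2] == b[i][:2] and a[i][:2] in FOURFOLD_PREFIXES]
    n4d = len(fourd)
    n_tv = int(round(q * n4d))
    tv_sites = set(rng.choice(fourd, size=n_tv, replace=False)) if n_tv else set()
    for i in fourd:
        target = a if rng.random() < 0.5 else b
        base = target[i][2]
        if i in tv_sites:
            new = TRANSVERSIONS[base][rng.integers(0, 2)]
        elif rng.random() < p_ts_t:
            new = TRANSITION[base]
        else:
            continue
        target[i] = target[i][:2] + new

    # Third positions of ancestral 4D codons whose prefixes diverged are no
    # longer counted as 4D sites; give them ordinary leaf-to-leaf evolution.
    p_ts_leaf, p_tv_leaf = _k80_difference_probs(q, kappa, scale=1.0)
    for i in fourfold_anc:
        if i not in fourd:
            _mutate_position(b, i, 2, p_ts_leaf, p_tv_leaf,
                             cfg.nonsyn_rate_scale, rng)

    raw = n_tv / n4d if n4d else float("nan")
    return a, b, raw


# ---------------------------------------------------------------------------
# Genome layout


class _Layout:
    """Sequential gene placement per chromosome with large intergenic gaps so
    that only deliberately planted tandems fall within 100 kb of each other."""

    MIN_GAP = 150_000
    MAX_GAP = 400_000

    def __init__(self, n_chromosomes: int, rng: np.random.Generator) -> None:
        self.rng = rng
        self.chroms = [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
        self.cursor = {c: 0 for c in self.chroms}

    def place(self, chrom: str, length: int, gap: int | None = None
              ) -> tuple[int, int]:
        if gap is None:
            gap = int(self.rng.integers(self.MIN_GAP, self.MAX_GAP))
        start = self.cursor[chrom] + gap
        end = start + length
        self.cursor[chrom] = end
        return start, end

    def random_chrom(self) -> str:
        return self.chroms[self.rng.integers(0, len(self.chroms))]

    def two_distinct(self) -> tuple[str, str]:
        i, j = self.rng.choice(len(self.chroms), size=2, replace=False)
        return self.chroms[i], self.chroms[j]


# ---------------------------------------------------------------------------
# Public operations


def simulate_genes(config: SimulationConfig
                   ) -> tuple[list[SequenceRecord], GroundTruth]:
    """Generate the gene set and its ground truth (deterministic per seed)."""
    rng = np.random.default_rng([config.seed, 0])
    if config.n_chromosomes < 2 and config.n_wgd_pairs > 0:
        raise ValueError("WGD pairs need at least 2 chromosomes")
    layout = _Layout(config.n_chromosomes, rng)
    records: list[SequenceRecord] = []
    truth = GroundTruth()
    lo, hi = config.n_codons_range

    def make_record(gid: str, codons: list[str], chrom: str,
                    gap: int | None = None) -> SequenceRecord:
        cds = "".join(codons)
        start, end = layout.place(chrom, len(cds), gap=gap)
        return SequenceRecord(
            id=gid, cds=cds, peptide=translate(cds), chromosome=chrom,
            start=start, end=end, strand="+",
        )

    for kind, n_pairs in (("wgd", config.n_wgd_pairs),
                          ("tnd", config.n_tandem_pairs)):
        for k in range(n_pairs):
            n_codons = int(rng.integers(lo, hi + 1))
            anc = _random_cds_codons(n_codons, rng)
            cod_a, cod_b, raw = _evolve_pair(anc, config, rng)
            pair_id = f"{kind}{k + 1:04d}"
            if kind == "wgd":
                chrom_a, chrom_b = layout.two_distinct()
                rec_a = make_record(pair_id + "a", cod_a, chrom_a)
                rec_b = make_record(pair_id + "b", cod_b, chrom_b)
            else:
                chrom = layout.random_chrom()
                rec_a = make_record(pair_id + "a", cod_a, chrom)
                rec_b = make_record(pair_id + "b", cod_b, chrom,
                                    gap=config.tandem_distance_bp)
            records.extend([rec_a, rec_b])
            truth.pairs[pair_id] = PairTruth(
                pair_id=pair_id, kind="wgd" if kind == "wgd" else "tandem",
                id_a=rec_a.id, id_b=rec_b.id,
                target_raw_4dtv=config.branch_transversion_rate,
                realised_raw_4dtv=raw,
            )

    for k in range(config.n_singletons):
        n_codons = int(rng.integers(lo, hi + 1))
        codons = _random_cds_codons(n_codons, rng)
        gid = f"sgl{k + 1:04d}"
        records.append(make_record(gid, codons, layout.random_chrom()))
        truth.singletons.append(gid)

    return records, truth


def simulate_counts(records: list[SequenceRecord], truth: GroundTruth,
                    config: SimulationConfig) -> ExpressionTable:
    """NB read counts per gene per replicate; fills ``truth.*.fc_log2``.

    Copy means are ``mean_expression * len_kb * 2^(+-fc/2)``; a fraction
    ``fraction_de_pairs`` of pairs receives a nonzero planted effect per
    condition, drawn as sign * N(mu, sd) from ``fc_log2_effects``.
    """
    rng = np.random.default_rng([config.seed, 1])
    by_id = {r.id: r for r in records}
    for t in truth.pairs.values():
        if t.id_a not in by_id or t.id_b not in by_id:
            raise ValueError(f"truth names unknown gene ids for pair {t.pair_id}")
    for gid in truth.singletons:
        if gid not in by_id:
            raise ValueError(f"truth names unknown singleton id {gid}")

    sample_rows = []
    for tissue, genotype, n_rep in config.conditions:
        for i in range(1, n_rep + 1):
            sample_rows.append((f"{tissue}_{genotype}_r{i}", tissue, genotype, i))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "tissue", "genotype", "replicate"]
    ).set_index("sample")
    cond_of = {s: f"{row.tissue}_{row.genotype}" for s, row in samples.iterrows()}
    conditions = list(dict.fromkeys(cond_of.values()))

    gene_ids = [r.id for r in records]
    lengths = pd.Series({r.id: len(r.cds) for r in records}, name="length")

    # Planted per-condition effects.
    mu_fc, sd_fc = config.fc_log2_effects
    for pid in sorted(truth.pairs):
        t = truth.pairs[pid]
        is_de = rng.random() < config.fraction_de_pairs
        for cond in conditions:
            if is_de:
                eff = rng.normal(mu_fc, sd_fc)
                if rng.random() < 0.5:
                    eff = -eff
            else:
                eff = 0.0
            t.fc_log2[cond] = float(eff)

    mean = pd.DataFrame(index=gene_ids, columns=samples.index, dtype=float)
    base = config.mean_expression * lengths / 1000.0
    for s in samples.index:
        mean[s] = base
    for t in truth.pairs.values():
        for s in samples.index:
            fc = t.fc_log2[cond_of[s]]
            mean.loc[t.id_a, s] = base[t.id_a] * 2.0 ** (-fc / 2.0)
            mean.loc[t.id_b, s] = base[t.id_b] * 2.0 ** (+fc / 2.0)

    mu = mean.to_numpy()
    if config.nb_dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples.index)
    return ExpressionTable(counts=counts_df, lengths=lengths, samples=samples)


def simulate_hits(records: list[SequenceRecord], truth: GroundTruth,
                  rng: np.random.Generator | None = None, n_decoys: int = 0,
                  decoy_evalue: float = 1e-5) -> list[HitRecord]:
    """All-vs-all similarity table: a self hit per gene (best bitscore), mutual
    hits for pair members below the pairing e-value threshold, and optional
    decoy hits above it."""
    if rng is None:
        rng = np.random.default_rng(0)

    def row(q: str, s: str, evalue: float, bitscore: float, pct: float,
            alen: int) -> HitRecord:
        return HitRecord(
            query_id=q, subject_id=s, pct_identity=pct, align_len=alen,
            mismatches=int(round(alen * (100.0 - pct) / 100.0)), gap_opens=0,
            q_start=1, q_end=alen, s_start=1, s_end=alen,
            evalue=evalue, bitscore=round(bitscore, 1),
        )

    hits: list[HitRecord] = []
    pep_len = {r.id: len(r.peptide) for r in records}
    for r in records:
        hits.append(row(r.id, r.id, 0.0, 2.0 * pep_len[r.id], 100.0, pep_len[r.id]))
    for t in truth.pairs.values():
        alen = min(pep_len[t.id_a], pep_len[t.id_b])
        for q, s in ((t.id_a, t.id_b), (t.id_b, t.id_a)):
            hits.append(row(q, s, 1e-120, 1.8 * alen, 95.0, alen))
    ids = [r.id for r in records]
    partners = {fs for fs in truth.member_pairs()}
    made = 0
    while made < n_decoys and len(ids) >= 2:
        i, j = rng.choice(len(ids), size=2, replace=False)
        if frozenset((ids[i], ids[j])) in partners:
            continue
        alen = min(pep_len[ids[i]], pep_len[ids[j]]) // 3
        hits.append(row(ids[i], ids[j], decoy_evalue, 30.0, 35.0, alen))
        made += 1
    return hits


def simulate_go(records: list[SequenceRecord], truth: GroundTruth,
                config: SimulationConfig) -> dict[str, set[str]]:
    """GO labels: both copies of a pair receive the identical term set
    (annotation is by sequence similarity, and planted pairs are similar);
    terms are assigned independently of DE status."""
    rng = np.random.default_rng([config.seed, 2])
    vocab = [f"GO:{i + 1:07d}" for i in range(config.go_n_terms)]
    k = min(config.go_terms_per_gene, len(vocab))
    go: dict[str, set[str]] = {}

    def draw() -> set[str]:
        return {vocab[i] for i in rng.choice(len(vocab), size=k, replace=False)}

    for pid in sorted(truth.pairs):
        t = truth.pairs[pid]
        terms = draw()
        go[t.id_a] = set(terms)
        go[t.id_b] = set(terms)
    for gid in truth.singletons:
        go[gid] = draw()
    return go


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    records: list[SequenceRecord]
    truth: GroundTruth
    hits: list[HitRecord]
    expression: ExpressionTable
    go_map: dict[str, set[str]]


def simulate_dataset(config: SimulationConfig, n_decoys: int = 0
                     ) -> SyntheticDataset:
    """Run all generator stages with sub-streams derived from ``config.seed``."""
    records, truth = simulate_genes(config)
    expression = simulate_counts(records, truth, config)
    hits = simulate_hits(records, truth,
                         rng=np.random.default_rng([config.seed, 3]),
                         n_decoys=n_decoys)
    go_map = simulate_go(records, truth, config)
    return SyntheticDataset(config, records, truth, hits, expression, go_map)


def read_dataset(indir: str | Path) -> SyntheticDataset:
    """Load a dataset previously written by :func:`write_dataset` (the file
    contract every pipeline stage also consumes individually)."""
    from .io import (
        read_counts_tsv, read_fasta, read_go_map, read_hits_tabular,
        read_positions, read_sample_sheet, attach_positions,
    )

    d = Path(indir)
    records = read_fasta(d / "cds.fasta", alphabet="dna")
    peps = {r.id: r.peptide for r in read_fasta(d / "pep.fasta", alphabet="peptide")}
    for r in records:
        r.peptide = peps.get(r.id, "")
    attach_positions(records, read_positions(d / "genes.bed", "bed"))
    counts = read_counts_tsv(d / "counts.tsv")
    lengths = read_counts_tsv(d / "lengths.tsv")["length"]
    samples = read_sample_sheet(d / "samples.tsv")
    truth_path = d / "truth.json"
    truth = GroundTruth.from_json(truth_path) if truth_path.exists() else GroundTruth()
    return SyntheticDataset(
        config=SimulationConfig(),
        records=records,
        truth=truth,
        hits=read_hits_tabular(d / "hits.tsv"),
        expression=ExpressionTable(counts=counts, lengths=lengths, samples=samples),
        go_map=read_go_map(d / "go_map.tsv"),
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every external-format view of the dataset (FASTA, BED, TSV,
    tabular hits, GO map, JSON truth)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.records, out / "cds.fasta", what="cds")
    write_fasta(ds.records, out / "pep.fasta", what="peptide")
    write_bed(ds.records, out / "genes.bed")
    write_hits_tabular(ds.hits, out / "hits.tsv")
    write_counts_tsv(ds.expression.counts, out / "counts.tsv")
    lengths = ds.expression.lengths.to_frame()
    lengths.to_csv(out / "lengths.tsv", sep="\t", index_label="gene")
    write_sample_sheet(ds.expression.samples, out / "samples.tsv")
    write_go_map(ds.go_map, out / "go_map.tsv")
    ds.truth.to_json(out / "truth.json")
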