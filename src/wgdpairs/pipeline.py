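"""End-to-end orchestration of the duplicate-retention analysis.

Stages (each also exposed as a CLI subcommand): contig filtering ->
reciprocal-hit pairing -> codon alignment + divergence statistics -> WGD
classification (4DTV window + tandem filter) -> expression divergence (TPM,
expressed calls, partitioning, copy-vs-copy DE) -> association + GO
enrichment.  One log line per stage records input/output record counts,
mirroring the filtering-cascade style of transcriptome studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as _classify
from .align import codon_alignment_for_pair
from .divergence import DivergenceEstimates, pair_divergence
from .enrichment import correlation_table, enrichment_to_frame, fisher_enrichment
from .expression import (
    ExpressionTable, call_expressed, classify_partitioning, compute_fpkm,
    de_test_pairs,
)
from .filtering import FilterReport, apply_filters
from .io import Position, SequenceRecord
from .pairs import CandidatePair, detect_pairs
from .simulate import SyntheticDataset

logger = logging.getLogger("wgdpairs")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the study's values."""

    min_len: int = 500
    min_fpkm: float = 1.0
    fpkm_rule: str = "any"
    min_orf_codons: int = 100
    evalue_max: float = 1e-10
    dtv_low: float = 0.04
    dtv_high: float = 0.2
    window_metric: str = "raw"
    tandem_max_bp: int = 100_000
    tpm_expressed: float = 1.0
    fdr_max: float = 0.05
    bitscore_min: float = 40.0
    dispersion: float = 0.1
    enrichment_alpha: float = 0.05

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class PipelineResult:
    filter_report: FilterReport
    retained: list[SequenceRecord]
    candidates: list[CandidatePair]
    estimates: list[DivergenceEstimates]
    classified: list[_classify.ClassifiedPair]
    cascade: dict[str, int]
    chrom_matrix: pd.DataFrame
    frac_diff_chromosome: float | None
    expressed: pd.DataFrame = field(default_factory=pd.DataFrame)
    partitioning: pd.DataFrame = field(default_factory=pd.DataFrame)
    de: pd.DataFrame = field(default_factory=pd.DataFrame)
    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def wgd_pairs(self) -> list[_classify.ClassifiedPair]:
        return [c for c in self.classified if c.wgd_retained]


def estimates_to_frame(estimates: list[DivergenceEstimates]) -> pd.DataFrame:
    df = pd.DataFrame([e.__dict__ for e in estimates])
    if not df.empty:
        df["flags"] = df["flags"].map(";".join)
        df = df.set_index("pair_id", drop=False)
    return df


def positions_of(records: list[SequenceRecord]) -> dict[str, Position]:
    return {
        r.id: Position(r.chromosome, r.start, r.end, r.strand)
        for r in records if r.placed
    }


def divergence_for_pairs(records: list[SequenceRecord],
                         candidates: list[CandidatePair]
                         ) -> list[DivergenceEstimates]:
    by_id = {r.id: r for r in records}
    out = []
    for cand in candidates:
        a, b = by_id[cand.id_a], by_id[cand.id_b]
        aln = codon_alignment_for_pair(a.cds, b.cds, id_a=a.id, id_b=b.id)
        out.append(pair_divergence(aln, pair_id=f"{a.id}|{b.id}"))
    return out


def partitioning_table(expressed: pd.DataFrame, samples: pd.DataFrame,
                       pairs: list[tuple[str, str, str]]) -> pd.DataFrame:
    """Per-pair expression-partitioning classes across the two tissues.

    A copy counts as expressed in a tissue when it is expressed in that
    tissue in at least one genotype."""
    cond_tissue = {}
    keys = samples["tissue"] + "_" + samples["genotype"].astype(str)
    for sample, cond in keys.items():
        cond_tissue[cond] = samples.loc[sample, "tissue"]
    tissues = tuple(dict.fromkeys(samples["tissue"]))
    if len(tissues) != 2:
        raise ValueError("partitioning classification needs exactly 2 tissues")

    def tissue_set(gene: str) -> set[str]:
        return {
            cond_tissue[cond]
            for cond in expressed.columns
            if expressed.loc[gene, cond]
        }

    rows = []
    for pair_id, id_a, id_b in pairs:
        cls = classify_partitioning(tissue_set(id_a), tissue_set(id_b),
                                    tissue_names=tissues)
        rows.append((pair_id, id_a, id_b, cls))
    return pd.DataFrame(rows, columns=["pair", "id_a", "id_b", "class"])


def run_pipeline(ds: SyntheticDataset, cfg: PipelineConfig | None = None,
                 run_expression: bool = True, run_enrichment: bool = True
                 ) -> PipelineResult:
    """Run every stage on an in-memory dataset."""
    cfg = cfg or PipelineConfig()
    table = ds.expression

    fpkm = compute_fpkm(table.counts, table.lengths)
    retained, report = apply_filters(
        ds.records, fpkm, min_len=cfg.min_len, min_fpkm=cfg.min_fpkm,
        fpkm_rule=cfg.fpkm_rule, min_orf_codons=cfg.min_orf_codons,
    )
    logger.info("filter: %d contigs in, %d after length, %d after expression, "
                "%d after ORF", report.n_input, report.n_after_length,
                report.n_after_expression, report.n_after_orf)

    retained_ids = {r.id for r in retained}
    hits = [h for h in ds.hits
            if h.query_id in retained_ids and h.subject_id in retained_ids]
    candidates = detect_pairs(hits, evalue_max=cfg.evalue_max)
    logger.info("pairs: %d hits -> %d candidate pairs", len(hits), len(candidates))

    estimates = divergence_for_pairs(retained, candidates)
    logger.info("divergence: %d pairs aligned and scored", len(estimates))

    positions = positions_of(retained)
    classified = _classify.classify_pairs(
        estimates, positions, dtv_low=cfg.dtv_low, dtv_high=cfg.dtv_high,
        tandem_max_bp=cfg.tandem_max_bp, window_metric=cfg.window_metric,
    )
    cascade = _classify.cascade_counts(classified)
    chrom_matrix, frac_diff = _classify.chromosome_pairing_summary(classified)
    logger.info("classify: %(n_candidates)d candidates, %(n_in_window)d in "
                "window, %(n_tandem_in_window)d tandem, %(n_wgd_retained)d "
                "WGD-retained", cascade)

    result = PipelineResult(
        filter_report=report, retained=retained, candidates=candidates,
        estimates=estimates, classified=classified, cascade=cascade,
        chrom_matrix=chrom_matrix, frac_diff_chromosome=frac_diff,
    )

    wgd = result.wgd_pairs
    pair_tuples = [(c.pair_id, c.id_a, c.id_b) for c in wgd]
    if run_expression and pair_tuples:
        tpm = table.tpm()
        expressed = call_expressed(tpm, table.samples, threshold=cfg.tpm_expressed)
        result.expressed = expressed
        result.partitioning = partitioning_table(expressed, table.samples,
                                                 pair_tuples)
        result.de = de_test_pairs(table, pair_tuples,
                                  dispersion=cfg.dispersion,
                                  fdr_max=cfg.fdr_max)
        n_sig = int(result.de["significant"].sum()) if len(result.de) else 0
        logger.info("expression: %d pairs x %d conditions tested, %d "
                    "significant calls", len(pair_tuples),
                    result.de["condition"].nunique() if len(result.de) else 0,
                    n_sig)

        div_df = estimates_to_frame(estimates)
        div_df = div_df.rename(columns={"four_dtv_corr": "four_dtv_corr"})
        result.correlations = correlation_table(result.de, div_df)

        if run_enrichment and ds.go_map:
            annotated = {g for g in retained_ids if ds.go_map.get(g)}
            dup_genes = {g for c in wgd for g in (c.id_a, c.id_b)} & annotated
            de_pairs = set(result.de.loc[result.de["significant"], "pair"])
            de_genes = {g for c in wgd if c.pair_id in de_pairs
                        for g in (c.id_a, c.id_b)} & annotated
            nonde_genes = dup_genes - de_genes
            sets = {
                "all_duplicates": dup_genes,
                "de_duplicates": de_genes,
                "non_de_duplicates": nonde_genes,
            }
            for name, test in sets.items():
                res = fisher_enrichment(test, annotated, ds.go_map,
                                        alpha=cfg.enrichment_alpha)
                result.enrichment[name] = enrichment_to_frame(res)
            logger.info("enrichment: %d annotated genes, test sets %s",
                        len(annotated),
                        {k: len(v) for k, v in sets.items()})
    return result


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage's tabular output under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.filter_report.to_frame().to_csv(out / "filter_report.tsv", sep="\t",
                                           index=False)
    pd.DataFrame([c.__dict__ for c in result.candidates]).to_csv(
        out / "pairs.tsv", sep="\t", index=False)
    estimates_to_frame(result.estimates).to_csv(out / "divergence.tsv",
                                                sep="\t", index=False)
    _classify.classified_to_frame(result.classified).to_csv(
        out / "classified.tsv", sep="\t", index=False)
    _classify.dtv_histogram(result.estimates).to_csv(out / "dtv_hist.tsv",
                                                     sep="\t", index=False)
    result.chrom_matrix.to_csv(out / "chrom_matrix.tsv", sep="\t")
    if len(result.de):
        result.de.to_csv(out / "de.tsv", sep="\t", index=False)
    if len(result.partitioning):
        result.partitioning.to_csv(out / "partitioning.tsv", sep="\t", index=False)
    if len(result.correlations):
        result.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    for name, df in result.enrichment.items():
        df.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
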