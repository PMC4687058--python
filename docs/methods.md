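# Methods

This note documents the models, statistics and design choices behind
`wgdpairs`, in the order the pipeline applies them, followed by what the
synthetic-data generator does and does not emulate.

## Coordinates and formats

All genomic intervals are 0-based half-open internally. BED input is taken
as-is; GFF3 (1-based, closed) is converted on read. Keeping one convention
removes off-by-one ambiguity in the 100 kb tandem rule. Similarity tables
are the 12-column tab-separated BLAST dialect; readers are total on the
package's own writers (round-trip property tests).

## Contig filtering

Three pure predicates, applied length → expression → ORF:

- **Length** ≥ 500 bp, inclusive.
- **Expression**: FPKM = count · 10⁹ / (length · total mapped fragments).
  A contig passes when FPKM ≥ 1 in *at least one* sample. Whether the
  threshold should hold in one sample, all samples, or pooled is genuinely
  open; the permissive any-sample reading is the default and the rule is
  configurable (`any|all|mean`).
- **ORF**: longest ATG-to-stop reading frame over all six frames, at least
  100 codons (the conventional default of ORF-calling tools), and it must
  terminate at a stop codon. Coding-potential scoring (Markov models of
  hexamer usage) is deliberately out of scope; the minimal ORF finder is
  sufficient for the synthetic data and for length/frame bookkeeping.

## Reciprocal second-best-hit pairing

In an all-vs-all search each gene's best hit is itself, so its duplicate is
expected to be the *second* best hit. Self hits are removed by identifier
equality rather than by rank, so a tool that suppresses self hits cannot
shift the rule. Multiple HSP rows per query–subject keep the lowest
e-value. Ranking ties (equal e-value) break by descending bitscore, then
subject id, making output deterministic. A pair (A, B) is emitted once when
each is the other's top non-self hit and both e-values are strictly below
10⁻¹⁰. Reciprocity forces a matching: no gene appears in two pairs.

## Codon alignment and 4D sites

ClustalW on two sequences reduces to pairwise global alignment, so peptides
are aligned with Needleman–Wunsch/Gotoh affine-gap dynamic programming
(BLOSUM62; a gap of length L costs 10 + 1·L), via Biopython's
`PairwiseAligner`. Scores are verified against an exhaustive recursion over
the alignment space for short peptides. Among co-optimal alignments the
aligner's first reported traceback is taken; scores, and hence every
downstream count on ungapped columns, are unaffected by the choice.
Terminal stop codons are stripped before back-translation; each CDS must
translate exactly to its ungapped peptide, and internal stops are errors.

A column yields a 4D site only when (i) both codons are ungapped and free
of ambiguity codes, (ii) the two-base prefixes are identical across the
pair, and (iii) the prefix is one of the eight families (CTN, GTN, TCN,
CCN, ACN, GCN, CGN, GGN) whose four codons encode one amino acid. Without
prefix identity the degeneracy class of the third position is ambiguous
between the two sequences and "transversions per 4D site" is not well
defined. Only the column itself must be clean; neighbouring gaps are not
masked.

## 4DTV and its correction

Raw 4DTV is the proportion Q of 4D sites differing by a transversion
(purine ↔ pyrimidine). With zero 4D sites the statistic is undefined and
flagged — never reported as 0. The multiple-hit correction is Kimura's
pure-transversion distance

    B = −1/2 · ln(1 − 2Q),

the unique two-state analogue of Jukes–Cantor: at a 4D site only the
purine/pyrimidine class matters, transversion events flip the class at
total rate 2β, and inverting the two-state Markov chain gives B = 2βT. It
is monotone, ≥ Q, → Q as Q → 0, and saturates at Q = ½ (such pairs are
flagged, not corrected). The exact correction formula used by the
transcriptome studies this package follows is not always printed; this
choice is therefore explicit and swappable behind
`correct_4dtv(..., correction=...)` — any alternative monotone correction
can be dropped in without touching callers.

## Ka/Ks (NG86)

Maximum-likelihood codon models are out of scope; the counting estimator is
fully specifiable and oracle-checkable:

- **Sites**: each codon position contributes one site, split into
  synonymous/nonsynonymous by the fraction of its non-stop single-base
  neighbours that preserve the amino acid (mutations to stops are excluded
  from numerator and denominator alike). Site totals are averaged over the
  two sequences.
- **Differences**: codons differing at k positions are resolved by
  enumerating all k! substitution orders, discarding orders that pass
  through a stop codon, and averaging synonymous/nonsynonymous step counts
  over the surviving orders. If every order is blocked (possible for some
  2–3-difference pairs), each differing position is classified by its
  single-site effect, with a warning.
- **Correction**: proportions pS = Sd/S, pN = Nd/N are Jukes–Cantor
  corrected, d = −¾ ln(1 − 4p/3). Saturation (p ≥ ¾) flags the affected
  statistic individually (`ks_saturated` / `ka_saturated`): on a one-codon
  alignment with a synonymous difference, Ka = 0 is still reported while Ks
  is undefined. ω = Ka/Ks is null when Ks = 0.

The estimator agrees with an independent pathway-enumeration oracle to
< 10⁻⁹ on random 50-codon pairs, and recovers the generator's selection
regime: median ω ≈ 1 under neutral evolution, median ω < 0.5 at
acceptance probability 0.25.

## WGD classification

- **Window**: a pair is in the WGD peak when its 4DTV lies in
  [0.04, 0.2], endpoints inclusive. Peak detection is not automated — the
  window is a configuration parameter with literature defaults, and a
  histogram export lets users inspect their own 4DTV distribution. The
  window is applied to the **raw** transversion proportion by default, with
  the corrected value always reported alongside; because the correction is
  strictly monotone the two conventions are equivalent up to transforming
  the endpoints (−½ ln(1 − 2·0.2) ≈ 0.223), and the metric is a single
  configuration switch (`window_metric`).
- **Tandem rule**: copies on one chromosome whose interval gap (end of the
  upstream gene to start of the downstream gene; overlap counts as 0) is
  strictly less than 100 kb are tandem duplicates, not WGD survivors.
  Interval gap is the conservative reading of "within 100 kb of each
  other"; midpoint or start-to-start distances would be larger. Pairs with
  unplaced copies are never tandem and are annotated as such; they are also
  excluded from the denominator of the different-chromosome fraction.
- **Conservation**: by construction
  n_candidates = n_out_of_window + n_in_window and
  n_in_window = n_tandem_in_window + n_wgd_retained.

## Expression divergence

TPM_g = (count_g/len_g) / Σ_h (count_h/len_h) × 10⁶ per sample; columns sum
to 10⁶ exactly, all-zero samples are flagged NaN. Effective length is the
CDS length (no fragment-length modelling; the TPM arithmetic is
unaffected). A copy is expressed in a condition when its mean TPM across
replicates is strictly above 1.

Pair-level partitioning across two tissues (a copy counts as expressed in a
tissue when expressed there in at least one genotype) uses a fixed
exhaustive table: `both_silent`, `one_silent`, `single_tissue_<t>` (both
copies only in tissue t), `partitioned` (disjoint single tissues — the
reciprocal-silencing signature of subfunctionalization), `both_both`
(otherwise).

Copy-vs-copy differential expression treats the two copies as the two
groups within one tissue × genotype; this is the only reading under which a
separate DE count per condition makes sense. The test is an exact
negative-binomial conditional test: per-sample counts are scaled to the
geometric-mean library size and rounded (equal-library pseudo-counts, a
simplification of quantile adjustment), summed per copy, and the split of
the total t between the copies is compared with its conditional null — a
negative hypergeometric with group-sum size r = n/φ, reducing to
binomial(t, ½) in the Poisson limit φ → 0 (verified against an exact
binomial oracle). Two-sided p-values sum all outcomes no more probable than
the observed one. The common dispersion φ is a prominent configuration
value (default 0.1, a conventional bulk-RNA-seq magnitude); a plug-in
profile-likelihood estimator across genes is provided as an option, but the
fixed-dispersion default keeps results exactly reproducible. Under planted
null data the p < 0.05 rate is ≈ 0.05 (measured 0.046–0.050 at 2,000
pairs); at planted |log₂ FC| = 4, mean 500 and 5 replicates all pairs are
detected.

BH-FDR is the step-up procedure with monotonicity enforcement, applied per
condition across pairs; "FDR" without a named procedure means BH here.
log₂ FC uses a 0.5 pseudo-count on normalised means. |log₂ FC| bins:
low < 0.4 ≤ mid ≤ 2 < high ≤ 8 < extreme (bins are on the absolute value;
the sign only records direction).

## Association and enrichment

Spearman correlations (average ranks for ties) relate |log₂ FC| — the
default DE metric, configurable — to ω, Ka, Ks and corrected 4DTV per
condition. For n ≤ 10 the p-value is an exact permutation enumeration;
otherwise the large-sample approximation. Annotation transfer gives each
query the GO set of its single best hit with e-value < 10⁻¹⁰ and bitscore
> 40 (both strict), ties broken by bitscore then subject id. Enrichment is
a one-sided Fisher's exact test per term on the 2×2 table test-set ×
has-term, with test genes removed from the reference margin so the margins
are disjoint (an inclusive-reference mode is available), BH-adjusted across
terms, overrepresented at adjusted p ≤ 0.05. GO-graph ancestor propagation
is not performed. Genes (copies), not pairs, are the annotation unit.

## The synthetic-data generator

Defaults emulate the study design the package targets: 19 chromosomes, two
tissues × two genotypes (leaf/root × genotypes "520"/"592") with 5/5/4/4
replicates, a planted transversion divergence of 0.10 (the centre of the
0.04–0.2 WGD window), transition:transversion ratio κ = 2, nonsynonymous
acceptance 0.25 (yielding median Ka/Ks ≈ 0.22–0.23), DE in 76% of pairs
with |log₂ FC| ~ N(1.2, 0.8), NB dispersion 0.1 and a baseline mean of 200
counts per kb of transcript. Dispersion and baseline are conventional
choices — the emulated study published no count-level estimates.

Each pair descends from a random ancestral CDS (ATG + random sense codons
+ stop). Codon positions outside the 4D third positions evolve on each of
the two branches by single-nucleotide proposals with K80 (κ-weighted)
substitution probabilities; proposals creating stops are rejected and
nonsynonymous proposals are accepted with probability `nonsyn_rate_scale` —
a rejection emulation of purifying selection that tunes the true Ka/Ks
without a full codon model. At the 4D sites that survive prefix evolution
in both copies, the generator plants an exact quota round(q · n_4D) of
transversion differences at randomly chosen sites and adds transitions at
the K80 rate matched to the same divergence. Planting a quota rather than
flipping per-site coins pins each pair's realised raw 4DTV to its target
within rounding (≤ 1/(2 n_4D)) while keeping the expectation equal to q;
per-site sampling would spread per-pair values with sd ≈ √(q(1−q)/n_4D) ≈
0.018 at 300 codons, which would scatter pairs planted near a window edge
across it. Transversions at 4D sites are always synonymous, so selection
never distorts the planted divergence. One caveat: rare parallel prefix
substitutions on both branches can create a 4D column outside the planting
set, shifting the measured raw value by ~1/n_4D for a handful of pairs.

WGD copies are placed on two distinct chromosomes; tandem copies on one
chromosome at exactly `tandem_distance_bp` interval gap (default 20 kb);
all other intergenic gaps are ≥ 150 kb so only planted tandems can trip the
100 kb rule. Counts are NB with mean `mean_expression` · len/1000 ·
2^(±fc/2) (the planted effect split symmetrically between copies; φ = 0
falls back to Poisson). The hits table contains a self hit per gene (best
bitscore), mutual sub-threshold hits for pair members, and optional decoy
hits above the e-value threshold. Both copies of a pair receive identical
GO term sets, assigned independently of DE status.

What the generator does **not** emulate: raw reads, assembly and mapping
error, isoforms and allele-specific expression, indels (planted pairs are
colinear, so alignments are gapless), gene families larger than two,
synteny blocks, and GO-term correlation structure. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated generative model, not robustness to assembly artefacts or family
structure in real transcriptomes.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 100–200 planted pairs for
recovery checks, 2,000 pairs for null calibration, 500 random codon pairs
and 200 random peptide pairs for oracle equivalence — sizes chosen so the
whole suite completes in a few minutes while keeping Monte-Carlo margins
small relative to the asserted tolerances. Numerical details: log1p-based
forms of both distance corrections (accurate for small proportions);
p-value ties in the exact tests compared with a 10⁻⁹ log-space slack;
seeds fixed everywhere, with generator sub-streams derived from the single
configuration seed so each stage is independently reproducible.
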