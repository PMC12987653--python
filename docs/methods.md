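# Methods

This note documents the statistical procedures, the synthetic-data models,
the numerical conventions, and the design choices behind `clonomosaic`.

## Clonotype definition and counting

A clonotype is identified by the tuple (V gene, J gene, CDR3 nucleotide
sequence) of each chain. The default scheme is **paired** TRA+TRB: a cell
with both productive chains is keyed by both; a cell missing one chain
falls back to the present chain's key. A **beta-only** scheme is available
by configuration. Paired-nucleotide keys are the strictest common
convention; nucleotide (rather than amino-acid) identity avoids collapsing
convergent rearrangements. Cells with two contigs of the same chain keep
the higher-UMI contig, ties broken lexicographically by CDR3nt — a
deterministic stand-in for the "most supported chain" heuristic. Only
productive contigs are used by default (configurable). Counts are **cells,
not UMIs**: a clone's abundance is the number of cells carrying it.

## Diversity under equal-depth downsampling

The inverse Simpson index `D = 1 / Σ p_c²` is the effective number of
equally abundant clones; it is maximized (D = number of clones) exactly on
uniform repertoires and any perturbation strictly decreases it. Because D
is depth-dependent in finite samples, repertoires are compared at a common
depth — the minimum sample size across compared repertoires, the only
depth valid for all. Each of `n_boot` (default 1000) iterations draws
`depth` cells **without replacement** from the repertoire's cell multiset
(multivariate hypergeometric over clone counts) and recomputes the index;
the point estimate is the resample mean, the CI the empirical
`(1±ci)/2` quantiles (default 95%). At `depth = N` every draw is the full
repertoire, so the estimate degenerates to the plug-in index with zero CI
width. Resampling with replacement (a true bootstrap at depth) is
available by flag. Every estimate records its seed.

The bootstrap CI describes subsampling variability of the observed
repertoire around that repertoire's own expected depth-d index; in
simulations it covers that expectation (estimated by an independent
label-permutation subsampler) in well over 90% of replicates.

## Occupancy and clone classes

Occupancy bins are right-closed intervals `(lo, hi]` over clone
proportions, default edges (0, 1e-4, 1e-3, 0.01, 0.1, 1]; each bin holds
the summed proportion of its clones, so values sum to 1. Singlet means
n = 1; expanded n > 1. A clone is **dominant** when its proportion strictly
exceeds 1% **and** its count strictly exceeds 50 cells — a conjunction of
a relative and an absolute threshold so that neither tiny samples (where
1% is a few cells) nor huge ones (where 50 cells is a trace) produce
spurious dominants.

## Sharing and concordance

Repertoires built under the same scheme are outer-joined on clonotype key.
Upset counts use **exact presence patterns** (the standard upset-plot
convention): each clone is counted once, in the cell of precisely the
sample subset it occupies, so pattern counts partition the union.

Concordance between two samples is Pearson's r on
`log10(p_c)` with a pseudocount `q = 0.5 / N_s` substituted for clones
absent from sample s (scope "union"; scope "shared" restricts to clones
present in both). The pseudocount (half a cell) keeps exclusive clones on
the plot at a value below any observed clone, and 0.5 is the conventional
continuity correction; it is configurable. A global least-squares line is
fitted through the same points. Results with fewer than 3 points are
flagged rather than computed. The persistence report combines the
time-point and blood–gut concordances with the fraction of
time-point-1-expanded clonotypes re-detected later and in the gut.

## Per-cell mutation detection

Reads must be primary, mapped, non-duplicate alignments carrying cell
barcode and UMI tags (defaults CB/UB, configurable; uncorrected tags are
not substituted). The allele at the 1-based locus position is resolved by
an explicit CIGAR walk: M/=/X report the aligned base, a deletion spanning
the position reports "del", a reference skip (splice) means the read does
not cover the position. Evidence is counted at **UMI level**: reads
grouped by (cell, UMI) contribute one consensus allele by majority vote,
exact ties collapsing to "ambiguous". A cell is **mutant** with
≥ `alt_min` (default 1) alternate UMIs — mirroring a presence/absence
definition of detectable mutant transcripts — **wildtype-covered** with
reference UMIs and zero alternate UMIs, **uncovered** with no spanning
UMI, and **ambiguous** otherwise (including alternate evidence below
`alt_min` when a stricter threshold is configured). Mutant fractions are
reported among covered cells only. Under a uniform substitution model with
per-base error ε, a wildtype cell with k UMIs is falsely called mutant
with probability `1 − (1 − ε/3)^k`; this is logged per mutant call and
used as the closed-form check in tests.

## Differential expression and enrichment

Expression is library-size normalized: `x = ln(1 + 10⁴ · c / total)`;
zero-total cells are excluded. DGE between two disjoint, tissue-matched
cell groups uses the two-sided Wilcoxon rank-sum test (normal
approximation with tie correction — the dominant convention for
single-cell contrasts), testing genes expressed in ≥ 10% of either group,
with Benjamini–Hochberg correction within the contrast (never pooled
across contrasts). Fold-changes are `log2((mean_A + pc)/(mean_B + pc))` on
de-logged normalized values.

Preranked GSEA ranks genes by `sign(lfc) · (−log10 p)` (configurable) and
computes the classic weighted Kolmogorov–Smirnov running sum: hits
increment by `|score|^w / Σ_hits |score|^w` (w = 1), misses decrement by
`1/(n_genes − n_hits)`; the ES is the extreme deviation. The null is
gene-label permutation (equivalent, per set size, to uniform random sets),
`NES = ES / mean(|same-sign null ES|)`, nominal p the add-one-smoothed
fraction of same-sign null ES at least as extreme, and FDR q the standard
permutation tail-ratio on pooled normalized NES, clipped to [0, 1].
Sample-label permutation is not an option with a single index patient. A
set covering every ranked gene is degenerate (no misses) and scores 0,
flagged. **Tie convention:** when the maximal positive and negative
deviations tie in magnitude (structural for clustered hit blocks), the
extreme reached first in the walk is reported; ES negation under ranking
reversal is exact away from these measure-zero ties and is tested as such.

Cell-type abundances are compared as
`Δ = asin(√p_a) − asin(√p_b)` — the variance-stabilizing transform for
proportions, whose sampling variance `≈ 1/(4n)` is composition-free —
with analytic normal CIs from `var(Δ) = 1/(4n_a) + 1/(4n_b)`; multiple
sample pairs are averaged with combined variance. The contrast builder
emits three families per tissue: patient expanded-clone cells vs control
cells, mutant vs intra-patient wildtype-covered cells (the "no detectable
mutant reads" comparator), and mutant vs control cells; a cell may appear
in several families, but groups within one contrast are always disjoint.

## Synthetic-data models

All generators are deterministic given their seed and emit truth tables
sufficient to score every downstream result without re-simulation; their
outputs are consumed only through the package's format readers.

**Repertoires.** Background clone sizes follow a log-series law
(canonical one-parameter heavy-tailed model for clone-size distributions;
θ = 0.96 gives a realistic mix of singletons and mid-size clones at a few
thousand cells). Planted clones are set to exact target proportions
(defaults 15%/8%/3% — an oligoclonal profile with unambiguous dominants);
the remainder is filled by log-series draws truncated to the cell budget.
Cells get distinct synthetic CDR3 sequences per clone, both chains.

**Paired repertoires.** A clone universe (default 600) is split into
shared (fraction s, default 0.8) and sample-exclusive clones. Shared
clones receive bivariate-lognormal latent abundances with correlation ρ on
the log scale (σ = 1.0); counts are multinomial realizations of the
normalized abundances. The truth table stores the latent values, and the
generator reports the **empirical** latent correlation, which is the
recovery target. The default depth is 30,000 cells: the multinomial
realization adds ~`1/count` variance per clone on the log scale, so at
d cells and m clones the attainable Pearson r is attenuated by
`≈ 1/(1 + (m/d)·e^{σ²}/σ²)` (minimized at σ = 1); ~60 cells per clone
keeps the attenuation under ~5%, while at ~20 cells per clone no choice
of σ brings it under ~12%. Shallower pairs are still valid inputs — only
the recovery guarantee weakens.

**Reads.** Each cell is mutant with probability m (default 0.3); locus
UMI coverage is Poisson(λ = 2); reads per UMI are 1 + Poisson(r); every
read spans the locus with a pure-match CIGAR (indel fixtures for the
CIGAR walker are built in tests). The true allele is corrupted per base
with probability ε, uniform over the three alternatives. The truth table
stores each cell's genotype and the post-error UMI-consensus allele
counts, computed by the generator's own bookkeeping independent of the
SAM parser.

**Expression.** Counts are negative binomial (dispersion 0.5) with
lognormal base means; DE genes (default 50 at log2 fold-change 2, up in
the first group) are drawn among genes with mean ≥ 0.5 so the planted
effect is testable. A constant high-expression "housekeeping" background
(200 genes at mean 500) carries ~50× the test-gene mass, standing in for
the untested bulk of a real transcriptome: per-cell totals are then
dominated by group-independent mass, so planting DE shifts composition by
only ~0.2% — well below per-cell library-size noise. Without this, the
planted mass inflates one group's totals and, after normalization,
coherently breaks count ties in the Wilcoxon ranks of every null gene,
destroying FDR control — a real compositional artifact that the generator
would otherwise exaggerate far beyond realistic proportions. Enriched
gene sets are drawn from the planted DE genes, null sets from the rest;
cell-type labels follow a per-sample Dirichlet-multinomial.

What the generators do **not** emulate: V(D)J recombination statistics,
doublets, ambient RNA, batch effects between experiments, UMI collisions,
and transcript-position coverage bias. Passing tests therefore validate
the statistical machinery and its error control under the stated models,
not robustness to those artifacts.

## Pipeline and reproducibility

Stages couple only through TSV files in the run directory; the manifest
records the package version, config hash, seeds, per-stage row counts and
sha256 checksums of every output, so re-running a config reproduces the
run bit for bit (verified in tests, including across process boundaries).
Plots are derived artifacts only — every number in the report exists in a
TSV first. Config validation reports all schema violations at once.

## Problem sizes

The test-suite and acceptance-script simulations use: diversity
calibration at counts {500, 300, 200} (depth 50, 1000 bootstrap
iterations, 2×10⁴–10⁵ brute-force draws, 200 coverage replicates);
concordance recovery at 625 clones / 500 shared / 30,000 cells; variant
calling at 1,000–5,000 cells; DGE at 2,000 test genes × 200 cells per
group; GSEA null uniformity over 500 random sets at 1,000–2,000
permutations; pipeline determinism on a three-stage demo config. These
sizes give stable statistics for every check while keeping a full run in
the tens of seconds on a laptop.

## Known limitations

- Clonotype keys are exact-match; no CDR3 similarity clustering or
  specificity inference.
- The DGE test is per-cell Wilcoxon; pseudobulk/mixed-model approaches and
  cross-experiment batch correction are out of scope (contrasts are
  tissue-matched instead).
- The variant caller handles one SNV locus per run, on the alignment
  reference's coordinates; no liftover, phasing, or variant discovery.
- Analytic proportion CIs treat cells as independent within a sample;
  they understate uncertainty under clonal correlation of cell types.
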