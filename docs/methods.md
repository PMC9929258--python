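# Methods

This note documents the models, the numerical choices, and the design
decisions behind `dmhseq`, and what the synthetic benchmark does and
does not establish about real data.

## The synthetic DMH experiment

The generator (`dmhseq.synth`) emulates a pooled single-cell dissection
of the dorsomedial hypothalamus from two genotypes, plus a matched bulk
design.  Its defaults define the study conditions used throughout the
tests and the acceptance script.

**Cell population.** Cells are drawn i.i.d. from eight classes
(neurons 60%, astrocytes 12%, oligodendrocytes 8%, OPC 5%, microglia
5%, endothelial 4%, pericytes 3%, vascular smooth muscle 3%); neurons
are subdivided GABAergic : glutamatergic at 55 : 45.  Each of the nine
resulting subclasses over-expresses its canonical markers (one hallmark
gene per non-neuronal class; Snap25/Syp/Tubb3/Elavl2 for all neurons;
Slc32a1/Gad1/Gad2 vs Slc17a6 for the two neuron subtypes) plus 15
additional program genes, all by a multiplicative `marker_fold`
(default 20).  Real cell types differ in hundreds of genes; the extra
program genes stand in for that breadth so that the embedding is not
driven by single genes.

**Counts.** Gene base means are lognormal(0, 1.3) (median 1, heavy
tail).  Canonical markers and designated effect genes get a base-mean
floor of 2.0 — marker and pathway genes that the analysis relies on are
well expressed in real tissue, and a marker at mean 0.01 would be
biologically meaningless.  A cell's expected count is
`base_mean x class fold x condition multiplier x library factor`, with
library factors lognormal(0, 0.35).  Counts are negative binomial with
`variance = mu + phi mu^2`, dispersion 0.15 (0.05 for bulk replicates,
which average over cells).  Ten genes named with the conventional
`mt-` prefix are scaled so that their expected share of each cell's
total equals the configured mitochondrial fraction (default 5% for
every class).

**Genotype effects** (applied to the second condition, "KO"): *Prkar2b*
fully ablated (log₂FC = −∞, the knocked-out subunit); *Prkar1a*
up-shifted by log₂(1.5) (the compensatory ~50% increase); a PKA-activity
set of 8 genes shifted by −log₂(1.5) and a GABA-transport set of 10
genes by +log₂(1.5).  Per-gene effects override set-level effects.

**Coupled pathway activity.** Each subclass draws one lognormal(0, 0.4)
activity factor that multiplies *both* the PKA-activity and
GABA-transport sets.  This encodes the biological coupling the analysis
is meant to detect — classes with high PKA signalling also transport
more GABA — and makes the positive cluster-level score correlation a
structural property of the data rather than an accident of sampling.

**What the generator does not model** (deliberately): doublets, ambient
RNA, batch effects beyond genotype, read-level noise, zero inflation
beyond NB sampling, per-sample biological variability within a
genotype.  Passing the recovery tests therefore shows that the pipeline
is correct and well calibrated for data that satisfy its own
assumptions; it does not show robustness to the artefacts above.

## QC and normalization

Cells are filtered before genes (the order changes gene retention and
is fixed).  Boundaries follow the filtering rules literally: `< 500`
UMIs and `> 40%` mitochondrial reads are strict, so a 500-UMI cell and
a 40.0%-mito cell are retained; the gene rule `>= 2 counts in >= 5
cells` is inclusive and reads "at least 2 counts in each of at least 5
cells".  Filters are applied to the pooled matrix, not per sample.

Normalization scales every cell to the median total and log₂-transforms
with pseudocount 1 (zero maps to zero; the inverse transform recovers
counts exactly).  HVG statistics are computed on the linearized
normalized values — dispersion = variance/mean is only meaningful for
count-scale data.  Binning is equal-frequency on (mean, gene id); the
within-bin standardization is a robust z (median centre, MAD scale),
chosen because the procedure scales "with respect to the median" and
the scale denominator is otherwise unspecified.  A zero-MAD bin
contributes scaled dispersion 0.  All ties break lexicographically by
gene id, which makes selection invariant to gene order.

## Embedding, clustering, annotation

t-SNE (Barnes–Hut, perplexity 30, fixed seed, PCA initialisation) runs
on the standardized selected genes directly — no PCA pre-reduction by
default, since none is part of the procedure being reproduced; one can
be enabled upstream if desired.  The published procedure resolved
clusters by manually tuned "ellipse thresholds" in t-SNE space, which
is not reproducible; the closest automatable analogue used here is a
deterministic density method: points with ≥ `min_samples` (10)
neighbours within `eps` are core points, core points within `eps` of
each other are merged by connected components, and every non-core point
joins the nearest cluster centroid so that all cells are labelled.
When `eps` is not given it adapts to the map as the 0.90 quantile of
the `min_samples`-th nearest-neighbour distances.  The procedure is
invariant to cell order (labels renumbered by descending cluster size)
and reproducible bit-for-bit under a fixed seed.

Neuron/non-neuron classification fits a two-component 1-D Gaussian
mixture (EM, k-means initialisation, 5 restarts, variance floor 1e-6,
fixed seed) to the per-cluster aggregated neuron score.  "Aggregated"
is implemented as the mean of the four marker medians — symmetric,
scale-stable, and configurable; the mixture is fitted on cluster-level
aggregates (one point per cluster), the literal reading of the
procedure; a per-cell variant can be built from the same parts.  A
cluster is neuronal when its posterior for the higher-mean component
exceeds 0.5 (the parameter-free maximum-posterior rule).  The
GABAergic/glutamatergic dichotomy compares the Slc32a1 and Slc17a6
medians strictly; an exact tie is reported as unclassified rather than
assigned arbitrarily.  Non-neuronal clusters take the argmax over the
canonical type markers, with the top-minus-runner-up margin reported
and a zero margin labelled ambiguous.

## Differential expression

One NB engine serves both unit conventions: bulk samples
(median-of-ratios size factors, linear-scale median to match the
textbook definition) and cells within an annotated class (size factors
= totals / median total).  Cells are treated as independent units, as
in the original per-cluster analysis; a pseudobulk route can be
composed from `CountMatrix.concat` but is not the default.

Dispersion is estimated by moments on size-factor-normalized counts
using the exact moment equation `Var(y_j/s_j) = mu/s_j + phi mu^2`
(ignoring the 1/s correction, as naive estimators do, inflates phi by
`(E[1/s]-1)/mu` and makes low-expression tests conservative).  Raw
estimates are left unclipped below zero, a parametric trend
`phi(mu) = a/mu + b` is fitted by least squares to per-bin winsorized
means (cap at the within-bin 0.9 quantile, ≤ 20 equal-count bins), and
the final dispersion is the even weighted average of raw and trend,
clipped to [1e-8, 50].  The winsorized mean is the compromise that
keeps genes with genuine biological structure (markers across a class
mixture) from dragging the trend up while staying nearly unbiased for
the null bulk — a plain bin median under-shoots because the raw
estimator's null distribution is right-skewed, and that alone moves the
null rejection rate by a percentage point.

The test is a per-gene two-group NB GLM with log link, fitted by Newton
steps on the per-group log-mean (vectorized across genes; the per-gene
fit agrees with an independent GLM implementation to ~1e-6).  Inference
is a Wald test on the group log-ratio by default; genes with one
all-zero group fall back to the likelihood-ratio test, which remains
defined there (an all-zero gene in both groups is untestable: p = NaN,
excluded from the multiplicity correction).  Genes with total count
below `min_total_count` (10) are likewise flagged untestable.
Benjamini–Hochberg adjustment passes NaN through.  The DEG rule is
`|log2FC| >= log2(1.5)` (inclusive, both directions — both up- and
down-regulation are of interest) and adjusted `p <= 0.05`; the
inclusive `<=` was chosen where the source material uses both `<=` and
`<`, and both thresholds are configurable.

**Calibration.** Under the within-class null (one cell class, no
effects, 200 cells/condition, 2000 genes) the Wald test rejects at
4.8–5.5% at nominal 5% across seeds, and BH calls no false DEGs.  The
within-class setting is the relevant null because the per-cluster test
is always run inside one annotated class; pooling classes adds
compositional variance that the dispersion estimator correctly charges
to phi but the balanced contrast never sees, making pooled-null
rejection conservative (~3–4%) — a property, not a defect.

**A boundary caveat.** The emulated *Prkar1a* shift equals log₂(1.5),
which is also the calling threshold.  An unbiased fold estimator lands
above its own true value about half the time, so at 300 GABAergic
cells/condition the gene is *significant* in every run (adjusted
p ≤ 0.05, positive estimate) but passes the fold rule in only ~55–60%
of runs.  Any effect strictly above the threshold, or the ablated gene,
is detected essentially always; the empirical FDR with 10% planted
effects stays ≤ 0.03.

## Pathway scores and enrichment

A set score is the unweighted mean of normalized expression over the
set's genes (no control-gene background — the simplest auditable
choice); cluster scores average the member cells.  Correlation is
Pearson by default ("positive correlation" unqualified), Spearman
behind a flag.  Over-representation is the upper-tail hypergeometric
probability with BH across sets.  The identities of the real
PKA-activity (8) and GABAergic-function (39) DEG sets are not published
in the main text; the built-in stand-ins are synthetic and any true
lists can be supplied as two-column TSV (`set_name`, `gene_id`).

## Problem sizes

Defaults were chosen desk-scale while preserving cluster separability:
2000 genes and 3000 cells for pipeline runs, 200–550 cells/condition
for the DGE studies, 10–20 seeded replicates where a rate is measured.
The acceptance script averages two full pipeline runs and reports every
other quantity from fresh simulations seeded off `--seed`.

## Known limitations

* Density clustering can split an elongated t-SNE blob at low `eps`;
  the adaptive quantile works on desk-scale maps but very large maps
  may need `eps` set explicitly.
* The dispersion trend is parametric (`a/mu + b`); strongly non-NB
  noise would call for a nonparametric trend.
* The GMM neuron classifier needs at least two clusters with distinct
  scores; a dataset of only neurons (or only glia) is rejected as
  degenerate rather than guessed at.
* Single-cell DGE treats cells as exchangeable within genotype;
  mouse-level correlation is not modelled (nor simulated).
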