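# Methods

## Scope and assumptions

The pipeline begins at a validated gene × cell count matrix; alignment,
counting and any read-level processing are upstream and out of scope. All
matrices are oriented genes × cells. Gene identity is the `gene_id` key;
symbols are display-only, because symbol spellings are unstable across
annotation releases (Nkx2-1 vs Nkx2–1 and the like).

Counts are assumed to be non-negative integers. The negative binomial is
the working noise model throughout: it motivates the variance-stabilizing
transform, and the synthetic-data generator draws from it.

## QC gating

Three per-cell gates, applied jointly: total uniquely mapped reads
≥ 2,000,000 (inclusive), mitochondrial read fraction < 0.05 (strict), and
fraction of annotated genes detected ≥ 0.10 (inclusive). The boundary
directions are taken literally from how the thresholds are conventionally
printed (≥ / < / ≥); the inclusive/strict distinction only matters for
cells exactly at a boundary, which the test suite pins down explicitly.
The "about 3,700 genes" gloss sometimes attached to the detection gate is
10% of a ~37,000-gene annotation, not an independent threshold; only the
fraction is implemented. The mitochondrial fraction is computed over matrix
counts rather than raw reads, since the artifact's input begins at the
count matrix; with mitochondrial transcripts dominating their loci the two
are close in practice. The read gate uses the cell table's
`total_mapped_reads` metadata, which is the sequencing-level quantity the
matrix cannot supply.

## Normalizations

* **nRPKM** — `count · 1e9 / (length_bp · total)`. The per-cell
  denominator defaults to the total counts assigned to annotated genes
  (column sum); a `denominator="mapped"` option uses total mapped reads
  instead. The assigned-counts default keeps the transform self-contained
  and is monotone-equivalent for within-cell comparisons; the choice is
  recorded in the matrix metadata. A zero-total cell yields zeros rather
  than an error.
* **norm_mRNA_mol** — molecule counts divided by `s(c) = total(c) /
  mean(total)`; the scaling factors average to one, so the normalization
  preserves the grand mean.
* **log₂(x+1)** — applied after either; monotone, zero-preserving.

## Variance stabilization and PCA

PCA uses the top 500 most variable genes of variance-stabilized counts.
Two stabilizers are provided. The default closed form,
`y = (2/√α)·asinh(√(α·x))`, is the exact variance-stabilizing transform of
a negative binomial with dispersion α applied to size-factor-scaled counts;
α is fitted by method of moments (`var = μ + αμ²` per gene, aggregated as
the median over genes) and a non-positive estimate falls back to
`log₂(x+1)` on scaled counts with a warning. In the Poisson limit the form
reduces to `2√x`. Size factors are median-of-ratios over genes expressed in
every cell, falling back to column-sum ratios when no such gene exists.

PCA is an exact SVD of the gene-centered matrix restricted to the selected
genes. Genes are centered but not scaled to unit variance — scaling would
undo the stabilization — with scaling available as an option since either
convention is defensible. Sign indeterminacy is resolved by making each
loading vector's largest-magnitude entry non-negative; variance explained
is each singular value's squared share of the total. Variable-gene ties at
the selection cutoff break lexicographically by gene id so the selection is
deterministic.

## PC-associated genes

Genes are prefiltered to nRPKM ≥ 0.5 in at least 25% of cells (both bounds
inclusive), then each gene's log₂(nRPKM+1) profile is regressed on one PC's
scores. The t statistic is moderated: residual variances are shrunk toward
a prior via `s²_post = (d₀s₀² + d·s²)/(d₀+d)`, with (d₀, s₀²) fitted by
matching the mean and variance of the log residual variances to a scaled F
distribution (trigamma inversion by Newton iteration); the moderated t has
d₀+d degrees of freedom, reverting to the normal reference when the prior
degrees of freedom are infinite. Moderation is togglable, and with it off
the statistic reduces to the textbook OLS slope test (verified against a
first-principles implementation). Precision weights on observations are
deliberately not used: the inputs here are log-stabilized nRPKM values,
not raw counts with mean-variance trends of the kind such weights model.
The P ≤ 10⁻⁴ cutoff is applied per component, for any of the first four
components, without cross-component multiplicity correction — the union
rule is part of the recipe. Zero-variance genes get p = 1; zero-variance
scores are an error.

## Hierarchical clustering

Agglomerative clustering with 1 − Pearson correlation distance and average
linkage by default (both configurable); flat sub-population counts (4
progenitor, 3 neuron) are supplied by the caller as k, since the recipe
fixes the counts rather than inferring them. A constant item has undefined
correlation; its distances are set to the maximum (1.0) with a warning.
Removal of contaminating cells before reduction (e.g. progenitors later
identified as microglia) is expressed as a caller-supplied exclusion list,
not automated.

## Differential expression

Prefilter: ≥ 10 counts in ≥ 3 cells pooled across both groups ("samples of
either condition" read as the pooled cells). The test is the two-sided
Mann-Whitney on nRPKM values, exact when the combined sample size is ≤ 20
with no ties (enumeration is cheap below that), otherwise the normal
approximation with midrank tie and continuity corrections. The fold change
floors per-cell log₂(nRPKM) at −8 — mapping zeros from −∞ to −8 — and takes
the difference of group medians of the floored values. Flooring before the
median is the only reading under which the floor can affect the result;
the alternative (medians of raw nRPKM, floored afterwards) is exposed via
`mode="raw"`. Adjustment defaults to Holm — the default of the adjustment
routine this recipe names — with Benjamini-Hochberg available, and the
method is recorded in the result metadata; in scRNA-seq practice BH is the
more common choice, so the default is a fidelity decision, not a
recommendation. Genes failing the prefilter are reported with p = 1 and
LFC = 0 but excluded from the correction. Top-gene ranking is by ascending
adjusted p, then descending |LFC|, then gene id.

## Cell-type markers and classification

A gene is a marker for type T when its expression is at or above the
threshold (norm ≥ 1) in at least the required prevalence of T's cells
(75% for a labelled reference, 50% within-dataset) and is detected
(strictly > 0) in fewer than 25% of the cells of **each** other type — the
per-other-type scope follows the singular phrasing of the rule, with a
pooled-other-cells option retained. All prevalence bounds are inclusive:
detection in exactly 25% of another type disqualifies.

Classification counts, per cell and type, the markers expressed above the
call threshold (default 0, i.e. any expression; the hit rule states no
level). A unique type reaching ≥ 4 markers is assigned; two or more types
reaching it is a conflict exclusion. Ad-hoc biological exclusions are
expressed as configurable (type_x, type_y, action) rules — e.g.
oligodendrocyte+interneuron → exclude, pyramidal+* → implausible,
interneuron+* → suppress — rather than hardcoded special cases. Reference
class relabelling (merging pyramidal classes, splitting choroid/ependymal
from astrocytes, pericytes/smooth-muscle from endothelium) is an input
label mapping, not code.

Two-signature supervised classification scores each cell by its mean
per-gene z over the up- and down-signature and assigns the larger side; the
margin for calling a cell ambiguous defaults to 0 (hard argmax) since the
recipe shows no ambiguity band, with the margin exposed for examining
transitional cells. The age trend of class proportions is tested one-sided
against the earliest age, by Fisher's exact test (default) or a
two-proportion z-test; the original analysis does not name its test, so
neither variant claims to reproduce its printed p-values.

## qPCR

Missing Ct values are set to 40 (the run length — no amplification
observed), ΔCt is computed per cell against Actb (assay-wide per-cell
offsets cancel exactly), and each gene is z-scored across cells. The z
uses the population (n-denominator) standard deviation, matching the
heatmap z convention used elsewhere in the package; the choice is recorded
in metadata. Zero-variance rows z-score to zero with a warning rather than
erroring, since all-missing genes are routine.

## Reporting

Heatmap values are per-gene z-scores of log₂(nRPKM) floored at −6 (zeros
included via the floor). Cross-system concordance joins two DE tables on
shared genes and flags genes significant in both systems at raw p < 0.05
with agreeing fold-change sign; raw rather than adjusted p follows the
stated convention of the comparison, with an adjusted-p switch. Volcano
tables use the strict p < 0.05 inequality. Plot rendering is a thin
optional layer; the tested surface is the tables.

## Synthetic data: what it emulates, and what it does not

The generator plants the structure the analysis is designed to find, with
defaults fixed at the study's cohort scale:

* Conditions E11.5/E13.5/E15.5/E17.5 with 96/48/63/18 cells; the
  progenitor:neuron mix per age follows the observed two-population
  composition (39/54/24/7% progenitors), so the immature-neuron share
  rises steeply at the later ages.
* 120 population-program genes and 25 exclusive genes per sub-population
  (4 progenitor, 3 neuron sub-populations) at log₂ effect 2.5 — a strong
  but realistic program-level separation for developmental states.
* Three rare non-neuronal types (microglia 4 cells, astrocyte 4,
  endothelial 1) each carrying 5 exclusive markers at mean 50, plus one
  dual-signature cell co-expressing two types' markers to exercise the
  conflict path. The same classes at 20 cells each form the labelled
  molecule-count reference for marker transfer.
* Negative-binomial counts (shared dispersion 0.5; 0.3 for the reference)
  with lognormal library factors (σ = 0.25), drawn as a gamma-Poisson
  mixture. 2,000 genes keep every stage fast at desk scale.
* Eight planted low-quality cells with 8× mitochondrial expression and
  600k–1.8M mapped reads; clean cells carry 2.2–4M reads, so the QC
  thresholds straddle the planted values and gate fidelity is measurable
  as exact sensitivity/specificity.
* Background gene means are bimodal by design — ~70% "expressed" (lognormal
  around 8) and ~30% near-silent (0.02) — so that no background gene can
  satisfy the marker rule by chance and planted-marker recovery is exact,
  not approximate. Real data have a continuum of intermediate expression;
  this is the generator's most deliberate idealization.
* qPCR: 16 genes (Actb plus two alternating population programs ~5 cycles
  apart), per-cell assay offsets, and reaction dropout concentrated in
  weak (high-Ct) wells at a controlled overall rate — so the fill-at-40
  convention behaves as it does on a real chip, where failures are
  censoring of weak reactions rather than random deletions.

Not emulated: realistic gene-length distributions, batch and chip effects,
doublets, gene-gene correlation beyond the planted programs, ambient
contamination, and intermediate marker expression. Passing tests therefore
demonstrate that the implementation executes the recipe correctly and
recovers planted structure under the stated noise model — not that the
recipe is robust to everything real data can do.

## Numerical choices and degenerate inputs

Seeded `numpy` Generators everywhere; identical seeds reproduce matrices
bit-for-bit. Deterministic tie-breaks: lexicographic gene ids in
variable-gene selection and top-DE ranking; PCA sign fixed by the
largest-magnitude loading. Integer cell allocation to populations uses
largest-remainder rounding so planted proportions are exact. All-zero
cells produce zero metrics rather than errors; all-zero matrices error in
normalizations that would divide by zero. Exact/approximate rank-test
switch at combined n = 20. Adjusted p-values are clipped to 1 and
monotone-enforced. Trigamma inversion iterates Newton to 1e-10 relative.

## Problem sizes

Defaults were chosen so the full suite and the reproduction script each
run in well under a minute of compute: 2,000 genes × 235 cells for the
cohort, 60 reference cells, 1,000 genes × 60 cells for the null DE
calibration, 500 genes × 80 cells for planted-effect recovery, and
enumeration oracles at combined n ≤ 10 (≤ 252 assignments per instance).

## Known limitations

* The exact nRPKM denominator (assigned counts vs total mapped reads) is
  ambiguous in the source recipe; both are offered and the choice is
  recorded, but results differ slightly between them.
* The moderated-t here is unweighted; analyses that used precision weights
  on raw counts will not be numerically identical.
* Which variance-stabilizing variant produced the original "stabilized
  expression values" is not knowable from the recipe; the NB closed form
  with a single moment-matched dispersion is a faithful, simpler stand-in,
  and the log2 fallback is always available.
* Marker thresholds are absolute (norm ≥ 1), so marker derivation is not
  invariant to rescaling the matrix; thresholds must be rescaled with it.
* The proportion-trend test is a choice among plausible tests, not a
  reproduction of the original (unnamed) one.
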