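# Methods

## The inference

The unit of analysis is the per-cell-type, per-gene summed UMI count
G[g, t]: raw counts of gene g summed over all cells labelled cell type t,
after the standard detection filters (genes detected — count ≥ 1 — in at
least 3 cells; cells expressing strictly more than 200 genes; gene filter
first, one pass each). UMIs are a proxy for relative RNA content, not
absolute molecule numbers.

**Dosage-compensation test.** For each cell type, the log2(G+1) values of
X-linked genes are compared with those of autosomal genes (2L, 2R, 3L, 3R
and 4; Y and unplaced contigs never enter the autosomal side; chromosome 4
can be dropped with a flag since it is heterochromatic and atypical) by a
two-sided Wilcoxon rank-sum test. P-values are Holm-adjusted across the
family of cell types in one run (9 in the default design). Because the
rank-sum test is invariant under strictly monotone transforms, testing
log2(G+1) is mathematically identical to testing raw counts; the log
transform matters only for plotting and for the Pearson correlation below.
Classification at level α (default 0.05):

| condition | call |
|---|---|
| adjusted p ≥ α | DC (dosage compensated) |
| adjusted p < α, X median > autosomal median | Excess DC |
| adjusted p < α, X median < autosomal median | No DC |

The X:A ratio reported beside the call is the ratio of per-gene medians of
raw summed counts. Genes with zero counts in the focal cell type are
retained as long as they passed the global detection filter (the
`nonzero_only` flag restricts to per-type nonzero genes for sensitivity
analysis; this is a deliberate default, since the detection filter is the
only stated inclusion rule). The total-count ratio (sum over X / sum over
autosomes) is logged alongside for transparency but never drives the call.

**CES proximity.** Each X gene's distance to the dosage-compensation
machinery's chromatin entry sites is the absolute difference between the
gene start and the nearest CES start (start-to-start; the gene start is
the minimum genomic coordinate of the span, ignoring strand — a
strand-aware mode uses the transcription start instead; ties go to the
lower-coordinate site). Genes split into close (distance < 10 000 bp,
strict) and distant sets. Per cell type: a two-sided rank-sum of
log2(G+1) close vs distant, Holm across cell types, `Active DCC` iff
adjusted p < α; the close/distant ratio of raw-count medians; and the
Pearson correlation (with a t-distribution p, df = n−2, Holm across cell
types) between distance in bp and log2(G+1) — negative where the complex
is active. BED input is converted at the boundary to the internal 1-based
inclusive convention (start = bed_start + 1).

**Directional scaled test.** Per-gene scaling across cell types comes in
two modes: minmax (linear map of each gene's profile onto [0, 1]) and
center (z-score across cell types, sample sd; constant genes map to zero
in both — the only well-defined choice at 0/0). A one-sided rank-sum then
asks, per cell type, whether scaled X (or Y) genes exceed scaled autosomal
genes, Holm-corrected. The center mode is the default for this test
because the question is about each gene's position relative to its own
trajectory mean; both modes are exposed and the report logs which was
used.

**Robustness reruns.** The full dosage test is repeated on the gene
universe minus a flagged class (testis-specific, testis-biased, or the
X-restricted versions of either; flags are caller-supplied annotation
columns). The delta report lists cell types whose interpretation changed.

**Marker enrichment.** One-vs-rest two-sided rank-sum per (gene, cell
type) on log-normalized values (ln(1 + 10⁴·count/cell_total)), Bonferroni
with m = genes tested per sweep — the per-sweep family is the documented
convention of the standard one-vs-rest marker tools; no fold-change or
detection-percentage pre-filter is applied by default so the statistic is
self-contained. Cluster annotation applies ordered rules (required and
excluded marker sets); a cluster gets the first rule whose required
markers are all significantly enriched (adjusted p < α and in-type mean
above out-of-type mean) and whose excluded markers are not. Rule order
resolves marker overlap (hub's Fas3 rule precedes epithelial's
MtnA-without-Fas3 rule).

## Statistical primitives

The rank-sum test, Holm and Bonferroni corrections and Pearson correlation
are implemented in-package (`scdosage.stats`), since their exact
conventions — midranks, tie-corrected variance, continuity correction 0.5,
the step-down running maximum — are what downstream numbers depend on.
Small tie-free samples (max(n1, n2) ≤ 8) use full enumeration of the
rank-sum distribution via a dynamic program; everything else uses the
normal approximation. The exact path is the internal oracle: exhaustively
over all tie-free equal splits, approximation and enumeration agree within
0.02 from n1 = n2 = 5 upward (the gap at n = 4 is 0.031 for any
continuity-corrected normal approximation — an irreducible property of the
approximation at that size, not of this implementation). Fully degenerate
input (every pooled value identical) returns p = 1 by convention. Report
tables round to 3 significant figures, half away from zero, scientific
notation for p < 0.01.

## The synthetic generator

`simulate.generate` draws, for a cell of type t and gene g,

    count ~ NegativeBinomial(mean = depth_t · w_g · f_{g,t} / Z_t,
                             dispersion θ)

with w_g a log-normal baseline (log2 sd σ), f_{g,t} the product of the
X dosage factor d_t (X genes), the CES boost (below), marker boosts (one
canonical marker gene per cell type, ×20 in its home type) and optional
gene-class boosts, and Z_t = Σ_g w_g f_{g,t} so the expected per-cell depth
is exactly depth_t. Everything is deterministic given the seed.

**CES boost.** X genes in DCC-active cell types receive
1 + β·exp(−distance/λ), geometric-mean-centred across X genes. The
centring makes the boost a pure redistribution of X output toward
CES-proximal genes: without it, an active cell type with d_t = 1 would
carry a chromosome-wide upward shift of the X distribution (the boost's
mean log effect) and be miscalled Excess DC, contradicting the
construction that d_t is the net chromosome-wide effect. The exponential
form is a modelling assumption — the real decay is only known to be
smooth and monotone.

**Default configuration** (`default_study_config`) is a stylized,
scaled-down emulation of a two-strain adult-testis study design, not a fit
to any real library: 9 cell types, ~1200 cells, per-type depth 2 000–15 000
expected UMIs peaking in late spermatogonia/early spermatocytes; 500 genes
on the X and on each major autosomal arm (100 on chromosome 4, 30 on Y);
dosage factors {1.0, 1.0, 1.0, 1.8, 0.85, 0.66, 0.63, 0.70, 0.77} along
the trajectory — parity in somatic types (the DC interpretation is the
generative truth; observed ratios in any single study scatter around 1),
excess compensation in GSC/early spermatogonia, graded loss through
meiosis; CES boost active in the five compensated types, with 60 evenly
spaced sites, β = 6, λ = 4 000 bp; σ = 1.0 (log2), θ = 2.

The free parameters (σ, θ, β, λ, site count, gene counts) were fixed once
by a design power analysis of this scaled-down size: σ = 1.0 places the
rank-test effect of the smallest "No DC" factor (0.77) at ≈ 6 null
standard deviations (reliably detected) while keeping parity types at the
null; 60 sites give an expected close group of ~26 genes, where β = 6 at
λ = 4 kb yields close-vs-far power ≳ 0.99 without perturbing the
chromosome-wide test; 500 genes/arm keep the median-ratio sampling error
of the X:A estimate near 0.03, well inside the ±0.1 recovery band. Runtime
is ~0.5 s per dataset, so 20-replicate recovery experiments run in
seconds.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: strain/batch effects, ambient RNA, doublets,
gene-length and GC biases, correlated gene programs (counts are
independent across genes given the mean), realistic gene-density variation
along chromosomes, continuous differentiation (cell types are discrete),
and any mechanistic model of the MSL complex. Recovery results certify the
statistical pipeline, not the biology.

**Borderline factors.** The 0.85 factor (late spermatogonia) sits at the
boundary the published design itself flags as doubly interpretable: with
a rank statistic of unit null variance no test can reliably call 0.85
non-significant while calling 0.77 significant. The recovery experiments
therefore accept either DC or No DC for that one cell type and require
exact concordance everywhere else.

## Numerical conventions and degenerate inputs

- Coordinates are 1-based inclusive internally; BED converts at the
  boundary (bijectively).
- Holm ties break by input position (stable sort); adjusted values are
  capped at 1.
- Pearson r on constant input is NaN with a warning, never an exception,
  so per-cell-type sweeps survive degenerate strata.
- Proximity groups smaller than 3 genes skip the cell type with a
  warning; an entirely untestable dataset yields an empty table (the
  function wrapper raises).
- Zero autosomal or far-group medians flag the ratio as NaN with a
  warning.
- Matrix orientation: genes × cells on disk (10x triplet convention),
  cells × genes in memory.

## Known limitations

- The normal-approximation path is the production regime for gene-scale
  inputs; exact enumeration is only feasible (and only used) for tiny
  samples.
- The dosage interpretation is purely statistical; in particular the
  pipeline deliberately never calls meiotic sex chromosome inactivation
  (that would require X:A < 0.5 with retained-transcript modelling).
- Marker enrichment reports no fold-change-based pre-filtering by
  default, so its p-values are comparable across runs but not numerically
  identical to tools that pre-filter.
- Cell-type labels are taken as given; clustering and embedding are out
  of scope.
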