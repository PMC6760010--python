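# Methods

This note records the models and procedures `pitsc` implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Normalization

Counts are normalized per cell to a common library size: E_{ij} =
c_{ij}/T_j · median(T), with log expression log10(E+1).  The median total
is computed over all cells present when `normalize` is first called and
can be carried (frozen) onto later subsets, so thresholds and DE
statistics computed on cleaned subsets remain on the same scale; a
recompute is a one-flag choice.  Cells with zero total UMI are a hard
error — they must be removed upstream, and the error names the offending
barcode.

## Otsu expression thresholds

Each gene's log-expression sample is histogrammed into 256 equal-width
bins over its own [min, max] range (whether the original convention used
per-gene or global bin edges is not documented anywhere we could verify;
per-gene ranges adapt resolution to each gene's dynamic range and are what
we test against).  Candidate thresholds are the 256 left bin edges
including the minimum; class 0 holds values strictly below the candidate
and class 1 values at or above it, matching the ≥ call convention; the
between-class variance σ²_B = ω₀ω₁(μ₀−μ₁)² is computed by the cumulative
scheme, exactly (bin sums of the actual values, not bin midpoints), so the
result equals a brute-force argmax with direct class means.  Ties resolve
to the smallest candidate: deterministic, and biased toward calling more
cells expressing, consistent with ≥.

Degenerate genes (fewer than two distinct values) get no threshold; no
cell is called when the common value is 0, every cell otherwise — the only
sensible limits.  For unimodal zero-inflated genes the threshold lands
inside the body of the distribution and *under-calls* the nonzero
fraction; this is a property, not a bug (the same convention is applied
everywhere for comparability), and the test suite asserts it.

The cell-cycle score variant uses one bin per observed integer score
instead of 256 bins, since scores are small integers; candidates are the
distinct observed values.

Thresholds are computed per analysis context: per sex on pre-QC cells for
classification, then once more on the final cleaned cell set with sexes
pooled for every reported statistic.

## Marker-rule classification

Rules are "expression above threshold in at least k of this gene set".
Exclusion classes run first (pericyte ≥2 of Col1a1/Col1a3/Dcn/Lum;
melanotroph ≥2 of Pomc/Pcsk2/Pax7; posterior ≥2 of
Lhx2/Nkx2-1/Gfap/S100b/Avp/Oxt) and take precedence over typing, which
resolves the Pomc overlap between melanotrophs and corticotrophs
deterministically.  Tier 1 (E, Le, EC, FSC: ≥2 of 4; HPC: ≥2 of
Resp18/Uchl1/Chgb/Scg2) and tier 2 within HPC (C ≥2 of
Pomc/Crhr1/Avpr1b; G ≥2 of Cga/Lhb/Gnrhr/Fshb; T ≥2 of Cga/Tshb/Trhr;
S ≥1 of Gh1/Ghrhr; L ≥1 of Prl/Agtr1b) use exactly-one logic per tier:
more than one satisfied rule makes the cell ambiguous, none leaves it
unclassified.  Ambiguity is evaluated per tier, so sharing a single gene
(Cga) does not create ambiguity unless two full criteria are met.  Rule
sets are plain data and fully overridable for other tissues.

Markers missing from the matrix are dropped from a rule with a warning
and k capped at the remaining size.  This is the documented contract for
user-supplied matrices; with one caveat — a rule reduced to a single gene
becomes aggressive — which is why the synthetic gene universe always
contains the exclusion-rule genes.

Unclassified cells are imputed from the 30 nearest same-sex neighbors by
Euclidean distance in significant-PC space (the distance metric is our
choice; nothing else is defensible in a PC embedding).  The most frequent
neighbor label wins; ties, ambiguous/unclassified winners, and exclusion
classes leave the cell unclassified.  Ambiguous cells are never imputed,
and rule-derived labels are never changed.

## QC

f_MT is the fraction of a cell's UMIs on mitochondrial genes (chromosome
tag "MT" or an Mt- symbol prefix).  Because f_MT distributions differ
between cell types, the cut is per type: f_MT > mean + 2·sd (upper tail
only — the rule can never remove a cell at or below its type mean).
Genes-per-cell and UMI-per-cell are trimmed at their extreme 1.5% tails,
per distribution independently with the union excluded once as
"count_outlier" (whether the original tails were joint or marginal is
unstated; marginal-and-union is the conservative reading).  Quantiles use
midpoint interpolation and cells exactly at a cutoff are kept.  Types
with fewer than 10 cells are skipped — their statistics are meaningless.
QC runs on classified cells, before imputation and doublet removal.

## HVG selection, PCA, significant components

Dispersion is φ = (s²−m)/m² on normalized counts (zero for Poisson-like
genes).  Eligible genes (expressed in ≥ 30 cells) are ranked within 20
equal-frequency mean bins by (φ − bin median)/bin MAD; quantile bins avoid
the empty bins that equal-width binning produces on skewed mean
distributions, and a zero-MAD bin contributes normalized dispersion 0
(nothing can be ranked inside a degenerate bin).  The top 1,000 genes are
selected by default.

Selected genes' log expression is standardized per gene and clamped to
[−10, 10] before SVD, limiting the leverage of genes expressed only in a
tiny subpopulation.  Zero-variance selected genes are dropped with a
warning.

Significance of components: each gene's counts are permuted among cells
(marginals preserved exactly, cell-wise correlation destroyed), the data
re-normalized and the identical transform re-applied with standardization
recomputed, and the top singular value recorded; the number of significant
PCs is the count of observed singular values above the maximum over all
repetitions (100 by default).  The HVG set is frozen across repetitions —
the null is "this transform applied to structureless data", not "the full
selection pipeline re-run".  Note one subtlety: variable sequencing depth
itself creates a weak but real correlated direction through the concavity
of log(E+1), which the permutation null (whose totals homogenize) does not
contain; on data with depth variation the test will count that direction
as significant.  Calibration tests therefore use constant-depth Poisson
noise, which is the structureless case the test is meant to reject.

The 2-D embedding is a visualization-only contract delegated to a
pluggable backend (scikit-learn t-SNE by default, perplexity 40, 2,000
iterations); nothing downstream consumes it.

## Doublet detection

Each repetition boosts the matrix with 30% synthetic doublets: parent
pairs drawn uniformly with replacement (distinct parents), counts summed
and downsampled *without replacement* (multivariate hypergeometric) to
the larger parent's total, preserving count integrality.  HVG selection
and PCA are re-run on the boosted matrix each repetition — repetitions
are only informative if their randomness differs.  For each true cell the
k = 30 nearest neighbors (self excluded) are counted for synthetic
members s, and P(X ≥ s) is computed from Hypergeometric(population =
n_true − 1 + n_synth, successes = n_synth, draws = k), BH-adjusted across
true cells, flagged at adjusted p < 0.01, and unioned over 10 repetitions.

Neighborhoods must be measured in the informative subspace: at desk-scale
sizes the noise singular values are close enough to the structure that
Euclidean distances over many noise PCs swamp the cluster separations.
When the caller does not fix the number of PCs, the detector calibrates
it with the permutation test on the unboosted matrix (minimum 2); the
pipeline passes its per-sex significant-PC count.  Homotypic doublets are
essentially invisible to this detector by construction — a documented
property that the suite asserts rather than hides.

## Differential expression and dominance

Expression track: Kruskal–Wallis omnibus across types on log expression,
then all-pairs rank-sum contrasts (normal approximation with tie
correction, no continuity correction), Bonferroni-corrected within gene
over the number of pairs.  Proportion track: Pearson χ² on the
type × expressing table, then pairwise pooled two-proportion Z tests
(exactly the statsmodels pooled statistic; degenerate pooled proportions
imply equal proportions and give p = 1).  All omnibus and contrast
p-values are then BH-adjusted across genes.  A gene is upregulated in t
when *either* track passes in full: adjusted omnibus p < 0.001 and every
relevant adjusted contrast p < 0.001, with the mean (or proportion)
higher in t than in every other type.  Tracks are never mixed within one
passing condition.

Dominant in t: upregulated, ≥ 20% of t's cells expressing, and against
every other type u either mean_t ≥ 3 · mean_u or pct_t ≥ pct_u + 30
percentage points.  The "30% higher proportion" is read as an absolute
30-point gap, not a 1.3× ratio — its companion criterion is already a
ratio, and sex-dimorphism patterns are near-binary presence/absence.  A
zero-mean comparator always satisfies the fold criterion.  Specific:
dominant and < 5% expressing in every other type.  Group targets (HPC =
C,G,T,S,L; PIT = FSC + HPC) require the conditions for every in-group ×
out-group pair, with specificity against out-group types only.

Sex dimorphism runs within each type with the Wilcoxon rank-sum test
between sexes (BH across genes) plus the proportion track, then the same
dominance constants with the two sexes as the two types; the constants
are not restated anywhere for the sex analysis, so reusing them is an
explicit choice.

## Cell-cycle iteration

Score each cell by the number of current markers called expressing;
Otsu-threshold the integer score distribution; candidates are cells with
score strictly above the threshold.  The new marker list is the set of
genes with rank-sum BH-adjusted p < 0.001 for upregulation in candidates,
expressed in ≥ 50% of candidates and < 5% of remaining cells, intersected
with the mitotic cell cycle GO term.  Iterate until both the marker list
and the candidate set are unchanged (exact set equality); an emptied
marker list or empty candidate set terminates with zero proliferating
cells.  The packaged seed list is ten canonical mitotic genes (Mki67,
Top2a, cyclins, CDK1, Aurora/Polo kinases, Bub1); the GO fixture is a
synthetic desk-scale stand-in assembled from canonical mammalian mitotic
genes.  Both are plain text files and user-replaceable.

## 3′ annotation extension

3′-end sequencing places reads at the distal 3′UTR, often outside
conservative annotations.  Each gene's 3′ boundary (end on +, start on −)
moves outward by min(4000, ⌊gap/2⌋) bases, where the gap is the count of
intervening bases to the nearest other gene boundary in the 3′ direction
on either strand; two genes facing across a gap g each take ⌊g/2⌋, which
cannot collide, so the no-overlap guarantee holds constructively and a
global sweep asserts it.  Genes overlapping in the input are flagged and
left unextended.  Gene, transcript and terminal-exon records move
together so exonic counting benefits; inner exons are untouched.  The
operation is deliberately not idempotent (a second pass would eat further
into the shrunken gaps), so written GTFs carry a run-marker header and
re-extension is refused.  Mitochondrial annotations from a secondary
reference are appended contig-filtered, source-tagged, with colliding
gene ids suffixed.

## Pipeline

Stage order is fixed: read/merge → normalize → per sex (thresholds →
exclusion + tiered classification → per-type QC → HVG/PCA + significant
PCs → kNN imputation → doublet detection/removal) → pooled (final
thresholds → percent expressing → type DE + dominance incl. groups → sex
DE → cell-cycle iteration → optional embedding).  Imputed cells are not
re-QC'd (they were typed after QC ran; re-running QC on rescued cells
would change type statistics mid-pipeline).  A master seed derives
per-stage seeds by hashing stage names, so partial reruns are
reproducible stage-locally; the manifest records parameters, seeds, stage
cell counts and SHA-256 checksums of every output table, and identical
configurations produce checksum-identical outputs.

## The synthetic generator, and what the tests show

`generate_dataset` samples gene-wise negative-binomial counts
(gamma–Poisson; inverse-dispersion 10 by default — enough overdispersion
for φ to be informative, Poisson in the limit) with mean = baseline ×
type fold × library scale.  Ambient leakage thins each cell binomially
and replaces the removed mass with multinomial draws from the pooled mean
profile, reproducing marker leakage into foreign types.  Mitochondrial
counts are re-drawn so each cell's f_MT matches a truncated-normal draw
(±0.02 after integer rounding).  Doublets sum two distinct-type,
same-sex parents and are downsampled to the larger parent's total — the
same generative form the detector synthesizes.  One RNG stream per
logical step (baseline, assignment, sampling, ambient, mito, doublets)
derived from the master seed keeps stages independently reproducible.

The default pituitary scenario: nine cell types carrying the classifier's
own marker genes (fold 30, marker baseline mean 1.0), ~500 genes, ~400
median UMI per cell, 5% ambient fraction, per-type f_MT means 5–7%, 2%
doublets, 2% cycling cells carrying a 40-gene mitotic program (fold 60
over a 0.04 baseline), female-dominant genes in lactotrophs and
male-dominant (Y-linked-style) genes in gonadotrophs at trace baseline
0.01.  Exclusion-rule genes are always present in the gene universe, at
trace abundance when their cell types are not simulated — transcripts of
a dissected-away lobe.  Validation scenarios scale these conditions:
classification recovery uses fold-20 markers, 300 cells/type and a small
hormone-dim somatotroph subpopulation (secretory program present, Gh1/
Ghrhr near ambient) to exercise the imputation stage; dominance recovery
plants 50 fold-5 dominant genes per type against 2,000 null genes;
doublet recovery uses two well-separated types at 500 cells each; the
permutation-test calibration uses constant-depth Poisson noise and three
disjoint planted programs.  These sizes are the package's validation
conditions; they keep the full suite in the minutes range.

What passing does **not** show: the generator has no batch effects beyond
replicate labels, no gene–gene correlation within a type beyond the
planted programs, no read-level artifacts (UMI collapsing, barcode
errors), clean log-normal depth, and marker programs far cleaner than
biology.  Accuracy numbers on it are upper bounds, not forecasts for real
tissue; what the tests establish is that each algorithm recovers exactly
the structure it claims to target, at effect sizes where that structure
is identifiable, and rejects data where it is absent.

## Known limitations

- The marker-rule scheme inherits its markers; applying the default rules
  outside rat pituitary requires new rule sets (supported, plain data).
- The doublet detector is blind to homotypic doublets and loses power
  when types are not separated in PC space.
- The permutation PC test counts any correlated direction, including
  depth artifacts, as structure.
- `rename_symbols` implements id- and exact-location matching only; fuzzy
  coordinate matching is out of scope.
- Dense in-memory expression matrices cap practical size at roughly 10⁴
  genes × 10⁵ cells on a 64 GB machine; the pipeline targets
  droplet-experiment scale (10³–10⁴ cells), not atlas scale.
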