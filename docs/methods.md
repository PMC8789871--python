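# Methods

This note documents the statistical model behind `alveonet`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Preprocessing

**QC.** A cell is removed if it has fewer than `min_transcripts` total
transcripts, more than `max_mito_fraction` of its transcriptome of
mitochondrial origin, or fewer than `min_unspliced_fraction` of transcripts
from unspliced mRNA. Removal criteria are strict inequalities, matching the
originating tissue protocols; the boundary cell (exactly 1000 transcripts,
exactly 20 % mitochondrial) is retained. Two presets are provided: human
tissue (1000, 0.20, 0.12) and mouse (1000, 0.05, 0.075). QC is idempotent
and reports removal counts per criterion (a cell can fail several).

**Normalization.** CP10K/log1p:
`normalized[c,g] = ln(1 + 10⁴ · counts[c,g] / total[c])`. This conserves
`Σ_g expm1(normalized) = 10⁴` per cell exactly (up to float rounding), a
property the test suite asserts at 1e−6 relative tolerance.

**Scaling.** Per gene: optionally replace values by OLS residuals on a
per-cell covariate (default: the mitochondrial fraction, with intercept),
then standardize with the sample standard deviation (n−1) and clip to
±`clip` (default 10). Genes whose variance is zero — including genes that
become constant only after regression, up to float noise (sd ≤ 1e−12) —
map to all-zero columns rather than amplified rounding error.

**Differential expression.** Two-sided rank-sum test on the normalized
layer. For group sizes ≤ 8 per group the p-value is an exact enumeration of
the permutation null of the rank-sum statistic over pooled average ranks
(this handles ties exactly, unlike the classical no-tie tables); larger
groups use the tie-corrected normal approximation without continuity
correction. The linear fold change is `(mean_lin_a + 1)/(mean_lin_b + 1)`
with `mean_lin = mean(expm1(normalized))`, so the reported log2 fold change
exponentiates back to the printed linear value. Multiplicity: Bonferroni
over the genes passing the pre-filters (expressed in ≥ `min_pct` of either
group, |log2 fc| ≥ `min_fc`; both default to 0 and are config-exposed,
since no universally correct values exist). Compositional tests use
Benjamini–Hochberg instead, as is conventional for cell-type proportion
panels; both procedures are options on either operation.

**Markers.** Per (cell type, gene) the diagnostic odds ratio on per-cell
detection (count > 0), with a 0.5 continuity correction on all four cells
of the 2×2 table: `DOR = (TP+0.5)(TN+0.5) / ((FP+0.5)(FN+0.5))`. The
correction makes DOR finite and positive always, equal to 1 for a gene
detected nowhere with equal group sizes, and exactly reciprocal under
swapping in-group and out-group.

**Composition.** Per-subject cell-type proportions within a compartment
denominator (epithelial fractions among epithelial cells, etc.; a
whole-dataset denominator is a config option), rank-sum across subjects,
BH across cell types. Fold changes default to mean per-subject
proportions; the median is a config option. Subjects with zero cells in
the compartment are excluded with a logged warning.

## Connectome

An edge source → target exists for pair (ligand, receptor) iff strictly
more than `gate` (default 5 %) of source cells express the ligand and of
target cells the receptor — the gate is evaluated per the edge's own two
cell types, with strict inequality. Edge weights are products of cluster
means: `weight_norm` on the normalized layer, `weight_scaled` on the
z-scored layer. Scaled weights can be negative (product of z-means); they
are retained in edge tables but clipped to 0 when building the adjacency
for centrality, which requires non-negative weights. Pairs whose genes are
absent from the profiles are skipped with a logged warning and a count on
the result, so public ligand–receptor lists work against reduced panels.
Autocrine (self) edges are retained; `Connectome.drop_self_edges()`
removes them.

HITS centrality runs on the node-level summed adjacency with 2-norm
normalization per half-step, tolerance 1e−10, at most 1000 iterations, and
max-1 rescaling of both score vectors (so node sizes are comparable across
conditions). The power iteration is verified in the tests against a dense
eigendecomposition of W·Wᵀ and Wᵀ·W at 1e−8 and against the networkx
implementation; HITS is scale-invariant, so multiplying all normalized
means by a constant leaves the scores unchanged.

## Pathway statistics

Mode-level summaries use **unscaled** weights (`weight_norm`): cumulative
outgoing weight of a node is the sum over its mode edges as source,
incoming as target; outgoing, incoming and total mode weight are conserved
identically. For cross-condition comparability the 2 × n_nodes cumulative
weights are pooled across conditions within each mode × direction and
standardized (sample sd); pooling rather than within-condition scaling is
the default because within-condition scaling would erase exactly the
condition shift the Durbin test is meant to detect (within-condition
scaling is a config option). Zero-variance pools map to zero.

The **Durbin test** ranks within blocks (average ranks for ties) and uses
the complete-design reduction
`T = 12/(k·t·(t+1)) · Σⱼ (Rⱼ − k(t+1)/2)²`, algebraically equal to the
Friedman statistic, referred to χ²(t−1). The statistic is omnibus, hence
inherently two-sided. Blocks default to cell type × direction (k = 12 for
six cell types), using both signaling directions of a mode in one test; a
cell-type-only blocking is available. A permutation option enumerates all
within-block label permutations when there are ≤ `n_permutations` of them
(t!^k) and Monte-Carlo samples otherwise, reporting the upper-tail p.

A caveat the test suite makes explicit: for t = 2 the statistic reduces to
a sign-test form with a very coarse discrete null, `T = (wins − losses)²/k`
under no ties. At k = 8 the χ²(1) tail can differ from the exact
permutation tail by ~0.1 in absolute p — far beyond Monte-Carlo error —
so the asymptotic p should be trusted only for moderate k; at the
pipeline's default blocking (k = 12) the empirical type-I error at nominal
0.05 is ≈ 0.039 (discreteness makes the test slightly conservative there;
k = 8 would instead give 0.070). The permutation method is the exact
alternative.

Per-node **fold changes** of cumulative mode weight are disease/control on
unscaled weights (scaled ones can be negative): control 0 with disease > 0
is flagged infinite, both 0 undefined; both are excluded from ranked
tables. Mode-change flagging restricts to the union over the two
conditions of the top-k (default 3) nodes by the matching Kleinberg score
(hub for outgoing, authority for incoming) and flags
|log2 fc| > 0.3 — the threshold is interpreted on the log2 scale since
cumulative-weight ratios near 1 are the null.

## Differential connectome

For every edge present in either condition's gated connectome:
`lfc = log2((m_dis + δ)/(m_ctrl + δ))` on cluster means of the normalized
layer, with stabilizer δ = 1e−9 guarding zero means; the perturbation
score is `|lfc_ligand · lfc_receptor|`. Base 2 and the stabilizer are
config-exposed and recorded on the result object. Because the fold change
is taken on log1p-normalized means, count-scale folds are compressed
(a 4-fold count increase lands near lfc ≈ 0.8 at typical expression
levels); the perturbation threshold of 0.10 in the chord-diagram filter
should be read on that scale. The filter keeps edges with both lfcs > 0,
ligand and receptor expressed in ≥ 5 % of their cell types in the disease
condition (the condition in which edges are "increased"; requiring both
conditions is an option), and perturbation ≥ 0.10; all three flags are
recorded per edge, the filter is idempotent, and edges gated out of both
conditions are never silently scored as zero.

## Synthetic data

The generator emulates the study design the pipeline assumes: two
conditions × 8 subjects × 6 cell types, ~40 cells per subject per type,
200 genes. Counts are gamma–Poisson (negative binomial with mean m and
size θ: `Var = m + m²/θ`), with log-normal subject (σ = 0.15) and
library-size (σ = 0.25) factors; θ = 10 throughout. These values give
per-cell totals around 2,500 and per-gene overdispersion typical of UMI
data at cluster level; the rank-based tests downstream assume nothing
beyond exchangeability, so the precise overdispersion is not critical.
Mitochondrial and unspliced fractions are independent Beta draws — good
cells from Beta(4, 60) and Beta(20, 50), a configurable contaminated
fraction from Beta(30, 45) (high-mito) or Beta(3, 60) (low-unspliced)
components that essentially always violate the human QC preset. The QC
fields are deliberately not mechanistically linked to the counts; they
exist to exercise the QC contract, and QC recovery is asserted at ±2
percentage points.

One global seed drives a stream-splitting scheme: every
condition × subject × cell-type block draws from its own child stream
(`SeedSequence([seed, tag, condition, subject, cell_type])`), so adding
cell types or subjects does not perturb existing draws, and identical
seeds give bit-identical datasets.

The default scenario plants a 4-fold CXCL12 increase in the gCap-like
capillary type and 2-fold CXCR4 increases in the two immune types. CXCL
ligands are capillary-restricted (zero elsewhere), so all outgoing CXCL
blocks other than gCap's are exact zero ties in the Durbin table; with
the seven shifted blocks (gCap outgoing + six incoming) the planted-mode
Durbin p is 0.043 essentially deterministically, while the null modes have
at most six non-tie blocks and cannot reach significance at k = 12. This
makes the end-to-end recovery assertions sharp rather than flaky. What
passing these tests shows is that the pipeline's plumbing and statistics
recover a known planted signal; it does not validate biological realism —
the generator has no gene–gene correlation, no doublets, no batch effects,
and its QC fields are independent of expression.

## Numerical choices and degenerate inputs

- HITS: all-zero adjacency is an error ("no positive signaling weight");
  ties in scores are preserved (symmetric targets get equal authority).
- Exact rank-sum enumeration switches to the normal approximation above 8
  per group; the enumeration tolerates float ties via a 1e−12 guard.
- Fold changes: 0/0 is undefined (flagged), x/0 infinite (flagged);
  ranked tables exclude both.
- Circos export sorts by perturbation descending with a stable
  lexicographic (source, target, ligand) tie-break, so outputs are
  byte-reproducible.
- Empty datasets read and validate fine; every downstream stage rejects
  them with a named error rather than propagating empties.

## Problem sizes used by the test suite

The default suite and the acceptance script run entirely on simulated
data: ~3,800 cells × 200 genes per scenario draw, 20 scenario seeds for
recovery rates, 50 random digraphs for the HITS oracle, 100 tables for the
Durbin/Friedman identity, and 2,000 null tables for test calibration.
These sizes were chosen so each claim is measured with comfortable margin
(recovery rates near 1, Monte-Carlo error well inside the asserted bands)
while the whole suite stays interactive.
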