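# Methods

`dopanet` implements the computational stages of an integrative analysis
that links a curated disease gene catalog (multiple-sclerosis genetics) to
the dopaminergic synapse pathway: pathway over-representation, set-pair
interactome enrichment against randomized-network nulls, rotation
gene-set testing of expression data, tercile-discretization gene-set
association, and quantification of myelin reporter images. This note
records the models, the defaults, and the design decisions behind each
stage, and what the synthetic-data experiments do and do not demonstrate.

## Gene identity and input formats

Gene symbols are matched case-insensitively and stored upper-case; no
alias or identifier mapping is attempted, so inputs must already share a
symbol namespace. Gene sets are read from standard GMT (name, description,
genes; the description doubles as a category label). Interactions are read
from SIF-dialect TSV (`source<TAB>type<TAB>target`); a type whitelist
reproduces the convention of keeping only four regulatory Pathway-Commons
interaction types (controls-state-change-of, controls-expression-of,
controls-transport-of, controls-phosphorylation-of) when building the
directed graph. Undirected edges are canonicalized to lexicographic
endpoint order and duplicate (source, target, type, directedness) tuples
collapse, so repeated rows are harmless. Self-loops are kept in the graph
and reported in the summary but never enter cross-set statistics.

## Pathway over-representation

For a query set of n genes in a universe of N genes, a pathway with m
genes and overlap k is scored by the hypergeometric upper tail
P(X ≥ k). The universe defaults to the union of the collection's genes
(the pathway-annotated genome) and is configurable. Pathways with fewer
than `min_overlap` query genes (default 10, following the "≥10 target
genes" convention; a flag switches the filter to pathway size) are
dropped *before* Benjamini–Hochberg correction, so the FDR is controlled
over exactly the reported rows. Output rows sort by p, ties by name, for
deterministic reports. Category aggregation counts pathways with
q < α per category.

The tail probability is floored at the smallest positive float: it is
mathematically positive whenever k ≤ min(m, n), and downstream code may
take logs.

## Set-pair interactome enrichment

Two disjoint gene sets A and B (in the motivating analysis: the
dopaminergic-synapse members of the catalog versus the remaining curated
genes) are compared on a graph through two statistics:

* `ppi_count` — interactions spanning A and B. On an undirected
  interactome this counts undirected edges with one endpoint in each set;
  on a directed regulatory graph it counts edges with A upstream
  (source ∈ A, target ∈ B) or A downstream. The two graph flavors are
  never mixed in one test, and multiple interaction types between the
  same pair count once (a flag on the reader keeps types separate).
* `lcc_size` — the node count of the largest connected component of the
  subgraph induced by A ∪ B, treating all edges as undirected. Only
  set members participate; one-step bridging through outside genes is
  deliberately out of scope because the statistic measures the density of
  the combined disease module itself.

Each observed value is referred to an ensemble of `n_random` randomized
networks. Two null models are available: `degree_preserving_rewire`
(double-edge swaps, separately for the undirected and directed edge sets;
degrees and in/out-degrees are preserved exactly, no self-loops or
duplicates are introduced, and type labels are reassigned by shuffling
the original multiset) and `node_label_shuffle` (topology fixed, labels
permuted uniformly — equivalent to redrawing the gene sets at random).
Rewiring is the default because it preserves hub structure, the stricter
null for interactome work. The empirical p-value uses the add-one
estimator p = (1 + #{null ≥ obs}) / (1 + n_random), which can never be
zero; z = (obs − mean)/sd is reported alongside and set to NaN when the
null ensemble has no spread.

Calibration of the label-shuffle null was checked by simulation: with
random disjoint 40-gene sets on a 500-node preferential-attachment graph
(attachment 3, ≈1500 edges) the rejection rate at 0.05 sits within the
binomial confidence band over 500 replicates for both statistics. Set
sizes of 40 were chosen for this experiment because the cross-count null
must take enough distinct integer values for the discrete empirical p to
approach its uniform grid; with very sparse expected cross counts the
add-one p is conservative (ties inflate it), which is a property of any
integer-valued permutation statistic, not an error.

## Expression preprocessing and the rotation gene-set test

Two filter entry points mirror the two common microarray pipelines:
`filter_by_detection` keeps probes with a detection p-value below 0.01 in
at least one sample (beadarray-style data), and `filter_by_signal` keeps
probes whose log2 signal reaches 6.0 (inclusive) in at least one sample.
Quantile normalization forces every sample onto the mean-of-sorted-values
reference distribution; tied observations receive the mean of the
reference values for the tied ranks, so a constant sample maps to the
reference mean. Proprietary platform-specific error models are not
implemented; the signal-floor path expects already-normalized input.

Per-gene inference uses a moderated two-sample t: the pooled residual
variance s²_g is shrunk toward a prior, s̃² = (d₀s₀² + d s²_g)/(d₀ + d),
with (d₀, s₀²) estimated by moment matching on the log variances
(digamma/trigamma inversion). When the observed spread of log variances
does not exceed the χ² sampling component, d₀ = ∞ and the prior variance
is the arithmetic mean of the gene variances, so equal-variance data
reduces exactly to the ordinary pooled t.

The set-level test is a rotation test. The two-group design is reduced by
orthogonal projection to one effect coordinate (the normalized group
contrast) plus a (n−2)-dimensional residual space; each gene becomes a
vector z_g in this (d+1)-space with ‖z_g‖² = effect² + d·s². A rotation
draws one uniform unit vector r (shared by all genes, preserving
inter-gene correlation) and recomputes effect = z_g·r and
s²(r) = (‖z_g‖² − (z_g·r)²)/d. The default set statistic is the mean of
squared moderated t over the set — the direction-agnostic "mixed"
alternative, which detects sets whose members move in both directions;
mean-absolute and signed-mean (two-sided) summaries are available. The
p-value is (b+1)/(R+1) over R rotations (default 9999).

One numerical subtlety matters for exactness: the variance prior is fit
on the rotation-invariant per-gene energies ‖z_g‖²/(d+1) rather than on
the residual variances, making every rotated statistic the same function
of z_g·r as the observed one. The observed statistic is then exactly
exchangeable with the rotation draws under the Gaussian null, and the
p-value is exactly uniform on its grid — verified empirically at 20 000
replicates. Degenerate inputs (constant matrix, a group with fewer than
two samples, a set disjoint from the matrix) raise informative errors.

## Tercile set association

Expression values are discretized by absolute magnitude into terciles:
the top third of entries become +1, the bottom third −1, the middle 0.
Ranking is global by default (the discretization is a property of the
whole matrix); per-sample ranking is available. Ties break by stable
(gene, sample) order, so exactly ⌊T/3⌋ entries land in each extreme band
regardless of ties, and the output depends only on the ranks of the
magnitudes.

Two genes are *concordant* when their discretized profiles agree in at
least `min_agree` of samples (default 2/3), either directly (positive) or
after negation (negative); positive takes precedence on an exact tie, so
all-zero profile pairs count positive. The association between set A and
set B is the hypergeometric upper tail of the concordant pair count:
population = all (a, b) pairs with a ∈ A, b ∈ background∖A; draws = the
pairs with b ∈ B (shared genes are removed from B); successes =
concordant pairs. The reported sign is the dominant concordance direction
among the drawn pairs. The per-pair concordance primitive and its 2/3
default are this package's concrete realization of set–set "correlation
by hypergeometric distribution"; the construction is deliberately simple
and symmetric (planting anti-correlated profiles mirrors the sign at
identical p).

Known limitation: the hypergeometric treats pairs as exchangeable, but
set B is drawn gene-wise, so gene-level heterogeneity that makes some
background genes concordant with *many* A-genes (for example, strong
between-gene baseline differences under global discretization) clusters
the successes and makes the pair-level test anticonservative. The
calibration experiments therefore use an exchangeable-gene null (no
between-gene baseline spread), which is the regime in which the
construct's p-value is honest; on real data with broad expression
baselines the p-values should be read as enrichment scores rather than
exact tail probabilities.

## Myelin image quantification

A stack is max-projected across slices, binarized with a dual threshold
(lower ≤ pixel ≤ upper; the same thresholds must be applied to every
image being compared — they are user inputs, as in the underlying imaging
protocol), and summarized by:

* coverage — a column is myelin-positive when it contains at least
  `min_pixels_per_column` (default 1) true pixels; maximal runs of
  positive columns shorter than `min_segment_px` (default 1) are
  discarded as speckle; coverage = 100 × kept-run length / width;
* thickness — the height of the tight bounding box around *all* true
  pixels (for multi-band masks the box spans the bands, matching the
  single-box protocol).

Groups of embryos are compared with Welch's unpaired t-test on coverage
(Student's variant available). Zero-variance pathologies are handled
explicitly: identical constant groups return (t=0, p=1); constant groups
with different means raise.

## Synthetic data

All generators draw from substreams of a single spec-level seed
(seed ⊕ a stable per-generator tag), so each stage is independently and
bit-exactly reproducible. Defaults describe the study conditions used
throughout the tests:

* interactome — preferential attachment, 500 nodes, 3 edges per new node
  (≈1500 edges, heavy-tailed degrees); type labels drawn from the four
  regulatory types plus two decoys; optional random edge orientation;
  `plant_cross_edges` adds exactly k new cross-set edges (default signal:
  30 between 20-gene sets).
* expression — two groups of 10 samples; per-gene baseline
  N(8, 1) on the log2 scale; unit within-gene noise; planted sets receive
  a case-group shift of δ = 1.5 standardized units with alternating sign
  along the set (so a directional set statistic averages to zero and only
  a direction-agnostic test sees the signal) and an optional shared
  latent factor with loading √ρ; detection p-values decrease
  monotonically with intensity (p = 10^−(y−5)). The generator emulates
  two-group microarray structure only — no probe-level redundancy,
  platform effects, batch structure, or missing values — so passing tests
  demonstrate the statistics' behavior under their model, not robustness
  to real microarray artifacts.
* catalog — uniform draws from the collection universe with `excess`
  forced draws from one set; study counts are geometric (success 0.65),
  reproducing the many-singleton evidence distribution of literature
  curation (roughly a third of genes supported by more than one study).
* images — a horizontal band of known thickness covering a known fraction
  of columns (one interior gap when geometry allows), 10 slices with
  multiplicative intensity jitter (sd 0.03), Gaussian blur (σ = 1 px) and
  additive Gaussian noise (sd 0.03) on a 0.1 background / 0.8 signal
  scale. The noise default is deliberately modest: thickness is defined
  as a bounding box over all true pixels, so a single super-threshold
  noise pixel in the blurred shoulder row would extend the box; at
  sd 0.03 the shoulder margin is ≈4.5σ and ground truth is recovered
  within ±2 coverage points and ±1 px thickness. For noisier real data
  the `min_pixels_per_column` and `min_segment_px` guards are the
  appropriate defense. Real confocal stacks additionally contain uneven
  illumination, depth attenuation and anatomical curvature that the
  generator does not emulate.

## Determinism

Every randomized operation takes an explicit seed, and results serialize
to byte-identical JSON across runs with the same seed. The test suite
asserts this end-to-end (generators, network test with rewiring, rotation
test, association, catalog).
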