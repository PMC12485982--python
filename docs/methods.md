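# Methods

This note documents the statistical procedures implemented in
`procap_atlas`, the conventions and defaults they use, the model behind
the synthetic-data generator, and the known limits of what the bundled
benchmarks demonstrate.

## Coordinates and signal model

All coordinates are 0-based, half-open (`[start, end)`), the native
convention of BED/bedGraph; 1-based formats would be converted at the
boundary. Signal is stored sparsely as non-negative integer counts of
read ends per base, keyed by `(chromosome, strand)`, separately for 5'
(initiation) and 3' (polymerase position) ends. Minus-strand bedGraphs
that encode counts as negative values are accepted and stored as
magnitudes, with the dialect logged. bedGraph is the canonical on-disk
format; all writes merge adjacent equal-count runs so a write/read cycle
is lossless.

## Element classification

Peaks (normally from an external caller; a naive sliding-window caller is
included only to turn synthetic tracks into fixtures) are paired across
strands when their summits lie within 300 bp. Pairing is greedy
nearest-first: among all feasible cross-strand pairs, repeatedly take the
closest, breaking exact-distance ties to the leftmost plus then leftmost
minus summit. This is deterministic and independent of input order, and
each peak joins at most one element. Summit-to-summit distance is used
because summits are the stable anchor for variable-width peaks. Greedy
matching is not guaranteed to maximize the number of pairs: a chain
configuration can cost one pair relative to the optimal matching even
without ties. The tests verify greedy against an independent exhaustive
implementation of the same rule and bound it by the true maximum
matching; on realistic (caller-disjoint) peak sets the difference is
rare and one pair at most per chain.

Proximity uses the element-span midpoint: proximal iff the unsigned
distance to the nearest annotated TSS is ≤ 500 bp (boundary inclusive).
The midpoint is a documented choice — edge- or summit-anchored distances
differ by at most half the span width. Context is intragenic iff the
span overlaps any gene interval by ≥ 1 bp.

## Gene-body ratio QC

Highly expressed genes are the top 10% (ceiling) ranked by sense-strand
5' signal in the promoter window [TSS − 1 kb, TSS + 100 bp],
strand-oriented. Per gene, the TSS region is the first 500 bp downstream
of the TSS and the body runs from TSS + 500 to TTS − 500; genes shorter
than 1 kb have no body and are skipped. With densities d = count/length,
the per-gene ratio is d_body / (d_body + d_tss), zero when both vanish.
The sample statistic is the mean of per-gene ratios (robust to one
dominant gene); a `pooled` mode that sums densities across genes first
is provided and tested. Only sense-strand reads are counted throughout,
since gene-body contamination is sense run-on signal. The pass threshold
is 0.025 (fail at ≥ 0.025). The ratio is invariant to global scaling of
the library and monotone under moving reads from TSS windows into
bodies.

## Quantification and normalization

Counts are 5' ends within the element span, both strands; overlapping
elements each count shared reads. Size factors are median-of-ratios:
per-element references are geometric means across samples, computed over
elements with strictly positive counts in every sample (the method's
defining filter), each sample's factor is its median count/reference
ratio, and factors are rescaled to geometric mean 1 for identifiability.
Variance stabilization is `log2(count/s + 1)` rather than a fitted
mean-dispersion transform: the log matrix feeds correlation, PCA,
clustering and linear models, for which log1p preserves the intended
behaviour without fitting a dispersion trend (differential testing,
which would need the full transform, is out of scope). Both the
nonnegative `count/s` matrix and the log matrix are exposed, because
downstream stages need different properties (see below).

## Tissue specificity

Per element, q_t is the mean *scaled* (count/s) expression over samples
of tissue t — probabilities require nonnegative inputs, so the log
matrix is deliberately not used here. With p_t = q_t / Σ q_t and
H = −Σ p_t log2 p_t (0·log 0 := 0), the score is S = 1 − H / log2 N for
N tissue types. Elements with zero total expression have undefined
probabilities; they are flagged and excluded from selection.

Tissue-specific sets use a per-tissue ±1-coded OLS: regress each
element's log-normalized expression on an intercept and membership
(+1/−1), in tissues with ≥ 3 samples, and take the membership
t-statistic (n − 2 residual df; zero residual variance yields a signed
infinity sentinel). For balanced designs this equals the classical
equal-variance two-sample t, which the tests verify. Each tissue's
specific set is the top ⌈5% × |union set|⌉ elements by t, ties broken
by element id. The non-specific background set is {distal with S < 0.1}
∪ {proximal with S < 0.02} minus every tissue-specific set.

## Initiation shape

Within a divergent element, per strand, SI = 2 + Σ p_i log2 p_i over
the positions carrying ≥ 1 read inside the span (reads outside the span
are ignored). SI = 2 − (positional entropy in bits): 2 for a point
mass, 2 − log2 L for a uniform spread over L positions, hence the P/B
boundary SI > −1.5 separates spreads of effectively ≤ 11 from ≥ 12
uniform positions. An SI of exactly −1.5 is broad (strict inequality
for peaked). Strands with fewer than 50 reads are filtered, not scored.
Signal is pooled across samples of a tissue as raw counts; SI is
scale-invariant per element, so only the relative weighting of samples
(not any global scaling) depends on this choice.

## Pause distances

Each read pair contributes distance = 3' − 5' on the plus strand and
5' − 3' on the minus strand; negative distances are malformed and
tallied, as are reads whose 5' end falls in no element. Reads are
assigned by 5'-end containment because initiation defines element
membership. Element summaries use the lower median (no interpolation on
even counts, keeping medians on the base-pair grid). Classes are
data-driven tertiles of element medians (≥ 20 reads required): below
the 1/3 quantile is early, above the 2/3 quantile late, the remainder —
including exact boundary values, and therefore every element when the
medians are degenerate — intermediate. Fixed user cutoffs are available
because no universal class boundaries exist; when medians cluster into
fewer, larger groups than three, a quantile boundary can land inside a
cluster and leave a class empty, which is inherent to quantile cuts. A
seeded bootstrap difference-of-medians summary supports two-condition
comparisons (e.g. factor-depletion experiments).

## Tissue-of-origin analyses

Sample clustering is agglomerative with distance 1 − Pearson r and
average linkage — the standard dendrogram construction for expression
profiles; linkage and metric are arguments. PC-space similarity fits
PCA jointly on tumors and normals (columns as observations,
mean-centered), keeps the smallest number of components whose cumulative
explained variance reaches 90%, and computes Pearson r between sample
score vectors; normals are grouped per tumor as primary-site,
metastatic-site or other. If a single component already reaches the
target, correlation over a length-1 vector is undefined and the sign of
the score product is reported instead.

The origin classifier's features are the union of per-tissue specific
sets minus elements claimed by more than one tissue (an error names any
tissue left featureless). The model is a one-vs-rest linear SVC with
C = 1 and squared-hinge loss on the log-normalized training matrix;
"default hyperparameters" is pinned to these values for determinism.
Queries are ranked by decision score with ties broken by tissue name;
features absent from a query are imputed as 0 with a warning count. The
model serializes to JSON (features, classes, weights, intercepts).

## Synthetic-data generator

The generator emulates the data *structure* the analyses consume, not
sequence biology: there is no FASTA, no motifs, no base-resolution
sequence-to-profile model.

- **Geometry.** Genes are placed on a regular grid per chromosome
  (default 30 genes of 10 kb over 2 × 1 Mb); proximal elements are
  centered at gene TSSs ± 100 bp (at most one per gene), distal
  elements in intergenic slots ≥ 3 kb from genes. Divergent elements
  (default 70%) place minus and plus summits a uniform 80–300 bp apart
  with 100 bp peak half-widths; unidirectional elements use one strand.
- **Counts.** Element count per sample ~ NB(mean = activity × size
  factor, size = `nb_dispersion`, default 50, i.e. dispersion α = 0.02
  — typical replicate-level variability once tissue effects are modeled
  explicitly in the activity matrix). Divergent strands draw
  independently at half the mean. Sample size factors are log-uniform
  in [0.5, 2] so normalization has planted structure to recover.
- **Activity.** A default 30% of elements are tissue-specific: ON at
  `baseline_mean × fold_change` (100 × 8) in one tissue and at
  `baseline_mean × off_level` (default 0.2, i.e. a 40:1 ON/OFF
  contrast) elsewhere; tissue-specific enhancers are near-silent
  outside their tissue, and an entropy score cannot exceed 0.5 over 8
  tissues from a mere 8:1 contrast against a ubiquitous baseline.
  Non-specific elements sit at baseline everywhere.
- **Positions.** Peaked strands draw 5' offsets from a two-sided
  geometric decay around the summit (success probability 0.5, ≈ ±2 bp
  spread); broad strands are uniform over the span. These are the two
  extremes the SI statistic contrasts, without asserting any particular
  in-vivo shape distribution.
- **Pausing.** Each read's 3' end is its 5' end plus a strand-oriented
  offset ~ round(Normal(μ, 5)) clamped at 0, with per-element μ drawn
  from three regimes (25/50/90 bp) emulating early/intermediate/late
  classes; the clamp's atom at zero is negligible for μ ≥ 20 (4 σ).
- **Background.** Uniform genome-wide reads at 0.1 reads/kb/strand per
  sample; every read, background included, appears in the per-sample
  read-pair table, so track totals and pair rows agree exactly.
- **Degradation fixture.** `degrade_library` moves a chosen fraction of
  reads (sampled without replacement from the read multiset) to
  uniform positions on the sense strand of gene bodies, emulating
  failed cap enrichment; library size is conserved.

A count-level companion (`simulate_count_matrix`,
`simulate_origin_study`) skips per-base geometry for studies that only
need element counts: the origin study mirrors the 15-tissue / 93-normal
/ 23-query design, with queries mixing primary and metastatic-site
signatures 0.7 : 0.3 before NB sampling.

**What passing tests show — and do not.** Recovery benchmarks
demonstrate internal consistency: the implementations invert the
generator's known model at realistic depths and effect sizes. They do
not demonstrate robustness to features of real PRO-cap data the
generator omits — mappability gaps, copy-number variation, overlapping
or nested elements, non-NB overdispersion from batch structure,
correlated tissue signatures, or peak-caller idiosyncrasies. Headline
accuracies on synthetic origin studies (≈100% at default noise) are
properties of the generator's disjoint, strong signatures, not forecasts
for real atlases.

## Problem sizes and numerical choices

The default study conditions are 2 chromosomes × 1 Mb, 30 genes, 60
elements, 4 tissues × 3 samples, baseline mean 100; recovery benchmarks
use 200 elements × 10 samples (size factors), 1,000 strand profiles
(shape), 300 elements × 500 reads (pausing), 800 elements × 8 tissues ×
3 samples (specificity), and 20 replicates of the 15-tissue origin
design. These sizes give stable statistics at interactive runtimes.
Noise robustness for origin prediction is probed at NB sizes 50/5/1;
below that, median-of-ratios normalization itself becomes undefined (no
element row stays positive in all 116 samples), so harsher levels are
outside the method's operating range rather than a harder test of it.

Determinism: every stochastic step takes a `numpy.random.Generator` or
seed; the pipeline writes a resolved config and SHA-256 checksums of
every output, and identical config + seed reproduce identical bytes.
Tie-breaks are fixed everywhere (leftmost summits in pairing, gene/
element ids in rankings, tissue names in prediction ties). Entropy terms
use 0·log 0 := 0; probabilities are validated to sum to 1 within 1e−9.
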