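# Methods

## The model in brief

Samples are venom-gland individuals from a handful of closely related
lineages. Their traits — normalized expression, CRE accessibility, footprint
occupancy, genotype dosage — are not independent observations: relatives
covary. We model each trait as Brownian motion (BM) on a rooted weighted tree
whose tips are the individual samples; individuals attach beneath their
lineage's node by short ε-branches (default ε = 0.01 × tree height), so
within-lineage resemblance is part of the same covariance model rather than a
nuisance. Felsenstein's independent contrasts then transform n tip values
into n − 1 independent, unit-variance increments.

The contrast transform is linear, so the recursion is run once on unit
vectors to produce an explicit operator `T` (rows in post-order over internal
nodes). Correctness is characterized exactly by `T C Tᵀ = I`, where `C` is
the BM tip covariance of the (binarized, ε-adjusted) tree, together with the
identity Σ contrast² = (x − μ̂)ᵀ C⁻¹ (x − μ̂) at the GLS root estimate μ̂; the
tests verify both to < 1e-8 on random trees and additionally compare contrast
values against `ape::pic` in R. Polytomies are resolved to binary nodes with
zero-length edges raised to 1e-6 × tree height.

### The per-gene regression

For each venom gene the response is log2(normalized count + 1) — a variance-
stabilizing proxy chosen because the downstream uses are ranking and
regression, not differential-expression testing; raw normalized counts are
available via `transform="none"`. Six predictor classes are assembled per
gene: accessibility at its promoters/enhancers, accessibility at CTCF sites
and at the top-3 most variable unannotated peaks within ±1 kb of the gene
array, binarized footprints at its CREs, expression of the venom-regulating
TF panel, and 0/1/2-coded genotypes at CRE variants (missing calls imputed
to the per-variant mode; variants > 50% missing dropped). Response and
predictors are transformed to contrasts; any class with more than one
variable is reduced to the first principal axis of its contrast block so the
output has exactly one coefficient per class (PCA is uncentered because
contrasts have expectation zero under BM; a literal
variables-exceed-samples trigger and centering are available as flags). The
regression includes an intercept, mirroring the default of standard linear-
model fitting, with a through-origin option; collinear classes are dropped
deterministically in the fixed class order (later first). Raw per-class
t-test p-values are reported; a BH-adjusted view across the matrix is
optional because the matrix display convention marks significance at raw
p < 0.05.

### Other components

- **Size factors** re-implement median-of-ratios normalization as a defined
  formula over genes with all-positive counts, with an explicit
  pseudo-reference fallback for sparse matrices.
- **CLR coupling** pools all gene × individual points into one OLS after
  per-sample CLR; zeros are offset by half the smallest positive entry of
  each matrix (the source analyses do not state a zero policy). Per-
  individual fits are available; pooling matches a single scatter of all
  points.
- **π** treats each individual's single projected consensus sequence as one
  haplotype, which biases π downward relative to diploid estimators — a
  deliberate match to consensus-based workflows, documented here as a caveat.
  Heterozygotes project the alternate allele by default (maximizing
  sensitivity of TFBS-change detection); both policies are exposed and the
  per-CRE table reports π under each. Unequal-length consensus sets are
  aligned by a reference-anchored merge of pairwise global alignments,
  adequate for the ≥ 95%-identity sequences this pipeline sees; gap and N
  columns are excluded pairwise.
- **Motif scanning** scores PFM log-odds with per-cell pseudo-count 0.8 and a
  uniform background, both strands; a hit requires relative score
  ≥ 1 − 0.15 = 0.85 of the achievable range, interpreting a "similarity
  threshold of 0.15" as a max-normalized deficit. Windows containing N are
  skipped; motifs whose best and worst scores coincide are skipped with a
  warning.
- **Footprint binarization** uses supplied thresholds when available and
  otherwise a deterministic 1-D two-means split per sample (initialized at
  the 10th/90th percentiles); ties at the threshold count as bound.
  Per-element occupancy counts TFBS rows, not distinct binding events, when
  motifs overlap.
- **Deletion calling** is an explicit operationalization of read-density
  inspection: per-sample depth ratios against a background median excluding
  the query region, then runs of ≥ 3 consecutive windows below 0.25 (hom) or
  0.75 (het), 500-bp windows by default. All thresholds are configurable.

## The synthetic-data generator

`regnet.simulate` emulates the study design: 4 lineages × 3 samples on a
pure-birth lineage tree, ~50 venom genes with promoters and ~40 enhancers,
a 40-TF panel, negative-binomial counts (dispersion 0.1) with left/right
gland replicates (one individual has a single gland), lognormal
accessibility, bimodal footprint scores (N(1,1) unbound vs N(8,1) bound)
coupled to genotype, variants inside CREs including motif-breaking ones
(verified at generation time to destroy their hit), a ~4-kb enhancer
deletion visible in Poisson(50) windowed depth, and protein abundances
proportional to normalized mRNA with lognormal noise (sd 0.5).

Parameters that define the study conditions, with rationale:

- **bm_rate = 1.0** (log scale): venom genes swing across orders of magnitude
  between lineages; e^±2 over the tree height reproduces that.
- **Planted driver effect = 4.0** (grid 1, 2, 4, 6): the driver latent is the
  planted enhancer's log accessibility, itself BM with rate 0.5; effect 4
  gives the response a driver component comparable to the strong single-locus
  effects the real system exhibits.
- **400 stable background genes**: median-of-ratios size factors need a core
  of stable genes, as in a real transcriptome; with too few, the size factors
  absorb venom-gene covariation and leak a shared per-sample artifact into
  every response.
- **Accessibility = BM(0.1) + iid noise (sd 0.02 on logs)**: chromatin state
  is heritable across the tree; the small iid term represents technical
  noise.

What the generator does **not** emulate: read-level data, linkage
disequilibrium, gene-family sequence homology, copy-number variation beyond
the single planted deletion, cell-type mixtures, and any mismatch between
the guide tree and the true genealogy. Passing tests therefore demonstrate
the pipeline's internal correctness and statistical behavior under its own
model — not robustness to the full messiness of real sequencing data.

## Validation studies and what they show

The studies in `regnet.studies` (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use these problem sizes, chosen to make each check
statistically meaningful while keeping the full run to minutes on one CPU:
200 random trees (≤ 12 tips) for operator exactness; 1,000 BM replicates for
contrast-variance calibration; 1,000 null genes (10 bundles × 100 genes) for
type-I error; 200 replicates per effect size for recovery; 100 random
alignments / sequence-motif pairs for the π and scanner oracles.

Two design points deserve emphasis:

- **Null calibration is tested under the model's own assumptions.** The
  ε-branch construction makes contrast standardization divide within-lineage
  differences by √(2ε) ≈ 0.17, so any iid measurement noise is amplified
  ~9-fold in those contrasts. With NB dispersion 0.1 this noise violates the
  BM error model and the per-class type-I error of the OLS t-tests drifts in
  predictor-structure-dependent directions (measured roughly 0.02–0.08 at
  nominal 0.05: anti-conservative for classes whose predictors carry iid
  noise, conservative for lineage-constant binary predictors). This is a
  property of contrast regression with measurement error, not an
  implementation defect. The calibration study therefore disables counting
  noise (dispersion → 0, where counts reduce to rounded means), under which
  the end-to-end per-class false-positive rate is exact to binomial
  precision. Users applying the model to real data should know that
  measurement noise makes the reported p-values approximate.
- **Effect recovery keeps full default noise.** With dispersion 0.1 and all
  layers noisy, the planted class is top-ranked in ~70% of replicates at the
  default effect size, rising monotonically with effect size (common random
  numbers pair the replicates across the grid). The ceiling reflects the
  honest difficulty of the design: 11 contrasts supporting 6 predictors plus
  an intercept leaves 4 residual degrees of freedom.

## Numerical choices

Deterministic tie-breaks: de novo peak selection orders by (−variance,
genomic start); collinearity drops later classes first in the fixed order
(cre_accessibility, ctcf_accessibility, denovo_accessibility, tf_footprints,
tf_expression, cre_genotype); PC1 sign makes the largest-magnitude loading
positive. Degenerate inputs (constant score columns, all-zero classes,
degenerate motifs, pairs with no comparable alignment columns) are dropped
with warnings rather than propagated as NaN. All randomness flows from
numpy `default_rng` seeds; bundle files are written with fixed float
formatting so identical seeds give byte-identical output.

## Known limitations

Coefficients of different classes are not on a common scale (predictors are
not standardized), so Fig.-4-style displays should compare significance, not
raw magnitude, across classes. The TF-venom correlation network is not
phylogenetically corrected — by design, matching the analysis it mirrors —
and on tree-structured data its significant-pair count is inflated by shared
ancestry. The per-gene model assumes one trait value per sample tip; the
alternative of collapsing individuals to lineage means is statistically
cleaner but cannot support six predictor classes with only four lineages.
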