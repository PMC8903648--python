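# Methods

This note records the statistical procedures phenolink implements, the
choices made where a convention had to be fixed, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Data model

The central object is a samples × features grid of log2 abundances
(`ExpressionMatrix`), as produced by TMT or label-free quantitation after
ratio/intensity transformation. Missing entries are first-class: most
operations act on present values only, and the operations that cannot
tolerate missingness (PCA, clustering) refuse it explicitly rather than
imputing silently. Phenotypes (`PhenotypeTable`) are per-sample clinical
variables declared categorical or numerical by a suffix tag in the column
label; the tag is the user's declaration of type and is never guessed.

Intact glycopeptides are identified by the underscore convention
`Gene_PeptideStart_Peptide_GlycositeNumber_GlycositePosition_Glycan`.
Because gene symbols may themselves contain underscores while peptide
sequences and glycan compositions cannot, the parser splits the five
trailing fields from the right; the glycosite position must fall inside
the peptide span, and the glycan must tokenize as repeated
letter-code + positive-count pairs (no fixed monosaccharide alphabet is
enforced — codes vary across search engines). Formatting then parsing is
the identity, property-tested over generated identifiers. When a peptide
carries more than one glycosite the identifier still encodes a single
position token; the parser accepts it and leaves multi-site encodings to
the user's review.

## Preprocessing and QC

- **Median normalization** shifts each sample additively so its median
  over present features equals the target (default 0). The even-count
  median is the mean of the two central order statistics; this matters
  because the idempotence contract (post-normalization medians equal the
  target to 1e-9) depends on it.
- **Noise filtration** keeps a feature iff its observed fraction is ≥ the
  threshold (default 0.5). The boundary is inclusive: removal is for
  features observed in *less than* the threshold fraction, so a feature at
  exactly 50% survives.
- **Imputation** fills with a scaled minimum: over the whole matrix
  (GlobalMin), per sample row (SampleMin), or per feature column
  (FeatureMin). The scale defaults to 1.0 and is exposed as configuration.
  FeatureMin is column-wise — the minimum of that feature across samples —
  which is the reading under which it differs from SampleMin at all.
  Present values are never altered; all-missing rows/columns must be
  filtered before row/column-wise imputation.
- **QC metrics**: Pearson correlation (Spearman selectable) between each
  pair of designated QC replicate samples over their co-present features
  (pairs sharing < 3 features are reported undefined and excluded from the
  mean), and a per-feature coefficient of variation across the QC samples.
  CV is computed on the linear scale (2^value) with the n−1 standard
  deviation, because a CV on median-centered log2 values divides by a
  near-zero mean and is meaningless; a log2-scale switch exists for data
  that arrive unnormalized.

## Phenotype profiling and correlation

Categorical levels are encoded 0, 1, 2, … in lexicographic order (the map
is reported in the output for auditability; binary phenotypes are
invariant to relabeling up to sign, multi-level encodings are
order-dependent and users needing a specific ordinal order should encode
it in the level names). Pairwise phenotype correlation defaults to
Spearman — the encodings are ordinal at best — with p-values from the
usual t-approximation; pairs sharing fewer than 3 samples or containing a
constant vector are reported undefined rather than fabricated.

## Differential expression

For a two-group contrast, each feature with ≥ 2 observations per group is
tested (features failing this are reported untested, never dropped); the
default test is the unequal-variance Welch t, chosen for robustness over
the pooled form, which remains selectable. The Wilcoxon rank-sum test uses
exact enumeration when both groups have ≤ 10 observations and the pooled
values are tie-free, otherwise the normal approximation with continuity
and tie correction. Paired variants (paired t, signed-rank) require a
pairing phenotype and fail loudly on orphaned pairs.

Fold change is median-based: log2FC = median(group 1) − median(group 2) on
the log2 scale, exponentiated to a fold change (mean-based selectable).
p-values are adjusted by the Benjamini–Hochberg step-up within one
comparison run (one family per run), and a feature is called
up-/down-regulated when adjusted p < 0.01 and |log2FC| > log2(1.5), both
thresholds configurable.

## PCA contribution score

After mean-centering each feature across samples (z-score scaling is
optional — log2 abundances are already on a common scale), the matrix is
decomposed by SVD. Each retained component distributes its explained
variance ratio VRᵢ over the features in proportion to their absolute
loadings:

    S_j = Σᵢ VRᵢ · |Vᵢⱼ| / Σⱼ' |Vᵢⱼ'|

so Σⱼ Sⱼ = Σᵢ VRᵢ exactly — the conservation identity is asserted to 1e-9
in the tests and acceptance script. The number of retained components n is
user-set (default 10, clipped with a warning to min(n_samples − 1,
n_features)); features are ranked by Sⱼ with the top 100 selected by
default, and the 10 largest-|loading| features are reported per component.

## Clustering

Feature profiles are z-scored across samples (sample sd; constant features
are rejected by name), then clustered agglomeratively with Euclidean
distance and Ward linkage — none of these conventions is forced by the
problem, they are simply the standard choices — and the tree is cut to the
user-defined k. Cluster ids are renumbered by first appearance in feature
order so output is deterministic and order-invariant up to label
permutation.

## Per-feature association

For a binary phenotype the screen computes the Pearson correlation between
each feature and the 0/1 encoding (the point-biserial correlation;
Spearman selectable) and flags the feature associated when p < alpha
(default 0.05). Multi-level categorical phenotypes are handled one-vs-rest
with each contrast reported separately.

The logistic model P(y=1|x) = expit(a + bx) is fit by plain IRLS, no
regularization, max 100 iterations, convergence when the log-likelihood
changes by < 1e-8. Complete separation (non-overlapping class ranges in x,
where the MLE diverges) is detected and flagged; the capped iterate is
still monotone in x, so the in-sample ROC/AUC computed from it is valid.
AUC is rank-based (Mann–Whitney with midranks for ties), equal to the
probability a random positive outscores a random negative; the AUC is
in-sample, from the single fit on all samples, and is not a
cross-validated estimate. By default the association stage screens the
union of DE-significant features and the PCA top-k (all features by flag).

## Over-representation analysis

Gene sets come from local GMT files. Query features collapse to gene
symbols (glycoforms via their gene field); the background defaults to the
genes measured in the matrix — the universe the selection actually came
from — and is overridable. Each set is restricted to the background and
kept when its restricted size lies in [5, 2000] (defaults; bounds applied
after restriction) and is smaller than the background. Enrichment is
one-sided, p = P(X ≥ k) for hypergeometric X, BH-adjusted across tested
sets; depletion is not reported.

## Synthetic cohorts

`fixtures.generate_cohort` emulates the input structure the pipeline
assumes: per-feature baselines Uniform(18, 30) on the log2 scale
(cosmetic, mimicking reporter-intensity magnitudes), an additive group
shift of ±effect on a planted fraction of features (half up, half down),
i.i.d. Gaussian residuals, a binary tumor/non-tumor phenotype plus a
correlated ordinal grade, QC replicates that are noisy copies of one base
sample, and MCAR missingness (a left-censored intensity-dependent mode
exists to exercise minimum-based imputation meaningfully). Defaults — 20
vs 20 samples, 1000 features, 10% planted effects at |log2FC| = 1,
residual sd 0.25, 3 QC replicates — are the study conditions used
throughout the tests and the acceptance script; at these conditions the
per-feature effect size is large (d = 4), so near-complete recovery at the
default gate is the analytically expected outcome, not a tuned one.

What the generator does *not* emulate: correlated features, batch
structure, isobaric interference/ratio compression, heavy-tailed noise, or
informative missingness beyond the simple censoring mode. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not performance on real cohort data.

## Numerical and engineering choices

- Delimiter inferred from extension (.csv comma, otherwise tab),
  overridable; empty cells and "NA"/"NaN" (case-insensitive, configurable)
  are missing; matrices are written at repr precision so round trips are
  exact.
- Strict sample alignment between matrix and phenotype table by default; a
  deliberate `allow_subset` flag runs on the intersection, because silent
  subsetting hides joins gone wrong.
- All pipeline stages are deterministic given inputs; the seed recorded in
  the manifest governs only synthetic-data generation. Two runs with the
  same config produce byte-identical CSVs.
- Problem sizes in tests and the acceptance script (cohorts up to 43 × 1000,
  exhaustive enumerations up to N = 12 for ORA and group sizes 10 for the
  rank-sum) were chosen so every check completes in seconds while the
  enumeration oracles remain fully exhaustive.
- The interactive-dashboard style of exploration is out of scope;
  visualization is limited to optional static volcano/PCA images behind a
  `plots` flag, and all computation is exposed through the library, the
  CSV outputs and the CLI.

## Limitations

No moderated-variance (shrinkage) tests, no covariate adjustment or
multivariable models, no cross-validated AUC, no batch correction beyond
median alignment, no model-based imputation, no preranked GSEA, and no
spreadsheet ingestion (export to CSV/TSV first). Multi-level phenotype
correlation depends on the lexicographic encoding; treat those r values as
ordinal approximations.
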