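# Methods

`crossmark` implements a cross-cohort meta-analysis workflow for discovering
and validating gut-microbiome diagnostic markers of colorectal cancer (CRC)
against healthy controls (HC) and colorectal adenoma (CA).  This note
documents the models, the statistical procedures, the defaults and the
numerical choices, and what the bundled synthetic data generator does and
does not emulate.

## Data model

Each cohort is a `CohortProfile`: a samples × taxa matrix of relative
abundances (fractions, rows summing to 1 after `renormalize`) plus per-sample
metadata (`group` ∈ {HC, CA, CRC, other labels}, `age` in years, `sex`,
`bmi` in kg/m², optional tumor `stage`).  Taxon columns may be bare genus
names or full MetaPhlAn-style pipe-delimited lineages
(`k__Bacteria|p__...|g__Gemella`); `aggregate_to_rank` sums species-level
columns into genera and, by default, drops mass that is unclassified at the
target rank (a flag retains it as a pseudo-taxon).  Harmonization between
taxonomies is exact string match on the genus name after prefix stripping; a
user-supplied synonym map can extend it.  "Detected" means abundance above a
detection threshold (default 0) in at least one sample; `common_taxa`
intersects detected taxa across cohorts.

## Community ecology

Alpha diversity: Shannon index H = −Σ pᵢ ln pᵢ in nats (natural log is the
convention of the standard ecology toolkits) and richness (count of features
above a threshold).  Group differences in alpha diversity use the
tie-corrected Kruskal–Wallis test; all-identical data returns p = 1 by
convention.

Beta diversity is Bray–Curtis, d(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ).
Ordination is classical PCoA: Gower-center −½D², eigendecompose, scale
eigenvectors by √λ.  Negative eigenvalues (Bray–Curtis is non-Euclidean) are
reported, not corrected — no Cailliez adjustment — and are excluded from the
proportion-explained denominator.

PERMANOVA uses the pseudo-F
(SS_between/(g−1)) / (SS_within/(n−g)) computed from squared distances via
group sums, with labels permuted freely (no strata) and the "+1" p-value
convention p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), so the minimum
attainable p with the conventional 999 permutations is 1.00e−03 and p is
never zero.  The dispersion-homogeneity test (betadisper, Anderson's method)
embeds samples in full PCoA space, computes each sample's distance to its
own group centroid with imaginary-axis contributions subtracted in squared
form (clipped at zero before the square root), takes a one-way ANOVA F on
those distances, and permutes the fixed distance vector across groups for
the p-value.  Groups of size 1 are excluded with a warning.

## Confounder analysis

For each taxon the fraction of abundance variance explained by a categorical
factor is the one-way ANOVA R² = SS_between/SS_total.  Disease status and
each confounder are fit univariately on the same non-missing sample subset,
mirroring the one-vs-one comparison plots used in multi-cohort microbiome
studies; no joint model is fit.  Abundances enter untransformed by default
(log10(x + 1e−6) is available but off).  BMI is binned at the conventional
cutoffs thin < 20, normal 20–25, overweight 25–30, obese > 30, taken
left-closed at the boundaries (25.0 is overweight, 30.0 obese); age is
binned into decades (<50, 50–60, 60–70, ≥70) so it can enter the factor
ANOVA.

## Differential abundance and consensus voting

Per cohort, every taxon is tested with a two-sided Wilcoxon rank-sum test:
exact enumeration of the null when the pooled size is ≤ 12 with no ties,
otherwise the tie-corrected normal approximation with continuity correction.
Direction (up/down in CRC) is called from the difference of group means.
Defaults follow the workflow this package reproduces: α = 0.05 for taxa,
α = 0.01 for KO gene families, no multiple-testing correction (a
Benjamini–Hochberg option exists but is off by default for fidelity to the
uncorrected screening design).

A taxon is a *universal marker* when it is significant in at least
`min_cohorts` cohorts (default 3 for CRC-vs-HC with six cohorts, 2 for
CRC-vs-CA with three) and every significant cohort agrees on direction.
Votes are idempotent per cohort and invariant to cohort order.

The pooled ("mixed data") analysis centers each taxon's log10(x + 1e−6)
abundances per cohort before pooling and testing.  This is a deliberate,
simple location-shift batch stand-in — *not* the published mixed-effects
batch-correction model some studies use — and is documented as such; its job
is to remove cohort-mean offsets that would otherwise masquerade as group
effects when group composition is unbalanced across cohorts.

The phylum-composition check builds a groups × top-k (default 8) table of
group-mean percentages, rescales each group row to 100, and applies a
chi-square test of homogeneity; expected cells below 1 warn rather than
fail.  The construction of this table (mean percentages rather than counts)
is a documented choice — the screening design it reproduces does not pin the
input table down.

## Random-forest signatures

`SignatureClassifier` is a scikit-learn-compatible estimator: a random
forest over a fixed, ordered genus list, parameterized by `mtry` (features
per split) and `ntree` (trees), the randomForest naming this literature
uses.  Features are raw fraction abundances (forests are monotone-transform
invariant, so no scaling).  Tuning minimizes out-of-bag error over a grid
(defaults mtry ∈ {1..|genera|}, ntree ∈ {100..1000 step 100}); ties break
toward smaller ntree, then smaller mtry.

Evaluation: AUC is the rank statistic (ties count ½) of predicted CRC
probability, with a DeLong 95% CI (midrank structural components, normal
interval, clipped to [0, 1]).  Accuracy, sensitivity, specificity and
F-score = 2·Precision·Recall/(Precision + Recall) are computed at
probability threshold 0.5 with CRC positive.  `confusion_metrics`
reconstructs the full confusion table from reported (sensitivity,
specificity, n_pos, n_neg) by rounding TP = sens·n_pos and TN = spec·n_neg
to counts — this is what makes published accuracy/F quadruples
desk-checkable.

Cross-cohort generalization: study-to-study transfer (train on one cohort,
test on each other; the matrix diagonal is within-cohort stratified 5-fold
CV on pooled out-of-fold scores — the within-study scheme is otherwise
unspecified, so CV is our choice and resubstitution/OOB are also available)
and leave-one-dataset-out (train on the union of the other cohorts).
Cohorts missing a contrast class are marked missing with a warning.  The
disease-specificity screen applies a fitted CRC signature to other-disease
cohorts (groups {control, disease}); AUC near 0.5 means the signature does
not react to that disease, i.e. it is CRC-specific.  Genera absent from a
disease table are imputed as zero with a warning.

## Functional analysis

KO gene-family tables go through the same per-cohort Wilcoxon + direction
vote at α = 0.01.  Marker–KO association uses tie-corrected Spearman
correlation with the t-approximation p (n−2 df); edges with p < 0.05 form
the marker–KO network (exported as TSV edge list or GraphML).  Correlations
on pooled samples are computed after per-cohort mean-centering by default
(maximizes n while damping batch offsets; a per-cohort mode exists).  The
pathway screen keeps, per cohort, pathways whose group-mean fold change
(with a 1e−9 pseudocount) exceeds 5 or falls below 0.2 AND whose Wilcoxon
p < 0.1, then applies the same direction-consistent vote at 2 cohorts.

## Synthetic data generator

`generate_cohorts` draws log-abundances
log x = b_genus + o_cohort,genus + δ_group,genus + ε, exponentiates and
closes each sample to sum 1.  The default preset is the study condition the
package is tested under: 6 cohorts × 30 samples per group (HC, CA, CRC),
130 genera of which 117 form a core detected everywhere (cohort-private
genera are zeroed outside their own cohort), baseline spread
b ~ N(0, 2), per-genus per-cohort batch offsets o ~ N(0, 1.0), sample noise
ε ~ N(0, 1.0), and 12 planted markers with 1.5-log-unit CRC shifts: three
"sharp" markers at low baseline (−3) that are near-zero in HC, intermediate
in CA (+0.5) and high in CRC (+1.5) — the pattern reported for the genera
shared by both published signatures — plus three CRC-enriched and six
CRC-depleted markers.  Marker genera sit at the median baseline (0) rather
than drawing from the baseline spread: CRC marker taxa are low-to-moderate
abundance organisms, and a marker that happened to draw a dominant baseline
would, purely through compositional closure, drag every other genus the
opposite way and manufacture spurious "universal" markers that no real
dataset of this design exhibits.  Because batch offsets are drawn per genus
per cohort while disease shifts touch only 12 genera, study identity
dominates between-sample dissimilarity — pooled PERMANOVA by study is
significant and study explains more per-genus variance than disease for the
vast majority of non-marker genera — which is the qualitative multi-study
structure the workflow is designed to survive.

Confounders (age, sex, BMI) are distributionally shifted by group (older in
CRC) but causally inert: they never enter the abundance model, so the
variance-decomposition stage has a known null.  Randomness is hierarchical:
one global seed, with each cohort on an independent stream keyed by
(seed, cohort index), so adding a cohort never perturbs earlier ones and
identical seeds reproduce bitwise-identical tables.

KO tables couple each linked KO to its marker genus through the genus's
standardized within-cohort log abundance with signed strength s (default
0.8, four KOs per marker): log KO = μ + s·z_genus + √(1−s²)·noise.  The
coupling is monotone, so strength 1 gives Spearman ρ exactly 1.  KO tables
are not re-closed to sum 1, so planted links survive exactly.

What the generator does **not** emulate: sequencing counts and their
sampling noise (a log-normal relative-abundance model, not
Dirichlet-multinomial), read-level artifacts, taxonomic misclassification,
16S copy-number or primer bias, phylogenetic correlation between genera,
confounders that actually drive abundances, and zero-inflation beyond what
closure and cohort-private genera induce.  Passing recovery tests on this
generator therefore shows the pipeline is correct and well-calibrated under
its own assumptions, not that the published effect sizes would be recovered
from raw sequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script run the default preset (540 samples, 130
genera, 200 KOs) with 999 permutations for the headline PERMANOVA/
betadisper numbers and 99 permutations inside calibration sweeps; recovery
sweeps use 5–10 seeds.  Permutation p-values can never be 0 by
construction; Wilcoxon on identical pooled values returns 1; constant
abundance gives variance-explained 0 by convention; PCoA eigenvalues within
1e−10 of 0 (relative) are treated as null axes; the betadisper squared
distance is clipped at 0 before the square root.  Randomness derives from
explicit integer seeds everywhere (numpy `default_rng`, sklearn
`random_state`), and pipeline reruns with the same config and seed
reproduce identical content hashes.

## Known limitations

The batch stand-in is a location shift on log abundances, weaker than
published batch-harmonization models.  The transfer-matrix diagonal depends
on the chosen CV scheme.  DeLong intervals are asymptotic and degenerate at
AUC = 1 (zero width).  The pathway screen's fold-change gate on group means
is sensitive to single large samples at small n.  Genus-name harmonization
across taxonomies is exact-match only unless a synonym map is supplied.
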