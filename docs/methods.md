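# Methods

## Association model

For one K-locus the response is its binary indicator over the isolates of
the analysis set (only isolates with a confident K-locus call — classes
`Good`, `Very Good`, `Perfect` — should enter; `repertoire.confident_isolates`
subsets them). The model is a penalized logistic regression

    (1/n)·NLL(β₀, γ, β)  +  λ·( α‖β‖₁ + (1−α)/2·‖β‖₂² )

in which the intercept β₀ and the lineage covariates γ are unpenalized and
only the protein-cluster coefficients β carry the elastic-net penalty.
Keeping the covariates unpenalized is deliberate: population-structure
adjustment must not compete with candidate predictors for penalty budget.
Lineage enters as one indicator column per sequence cluster (SC) minus a
reference level (the largest SC; ties break to the lexicographically
smallest label), so the covariate block is full rank. The underlying
assumption, inherited from the study design, is that prophage carriage is
shaped by recent horizontal acquisition rather than deep shared ancestry,
so discrete lineage labels (not a phylogeny or kinship matrix) suffice as
the structure adjustment.

Two mixing modes are fitted per locus: α = 0.8 (lasso-dominated; the
biological prior is that one enzyme family recognizes one capsule type)
and α = 0.069 (ridge-dominated; tolerant of mosaic RBP families split
over several correlated clusters). Predictors retained by either mode are
pooled (union); an intersection rule is available via
`GwasConfig.mode_combination`.

### Solver

The solver is proximal Newton (IRLS) with coordinate descent on the
penalized block, written as a numba kernel:

* at each outer iteration the binomial log-likelihood is replaced by its
  weighted quadratic approximation at the current coefficients
  (probabilities clipped to [1e-5, 1−1e-5] for weight stability);
* the unpenalized block is updated by an exact weighted least-squares
  solve; penalized coordinates by soft-thresholding, iterating over the
  active set with vectorized KKT checks over all coordinates to admit
  violators;
* the accepted step is halved until the true penalized objective is
  non-increasing, which makes the per-λ objective trace monotone (this is
  asserted by tests);
* the λ path (default 100 grid points, geometric from λ_max down to
  λ_max/1000) is fitted with warm starts. λ_max is computed from the null
  model (intercept + covariates only) as max_j |x_jᵀ(y − p₀)| / (n·max(α,
  0.01)); at λ ≥ λ_max all penalized coefficients are exactly zero. The
  α-clamp at 0.01 keeps the grid finite in the ridge-dominated mode.
* penalized binary columns are standardized internally to unit population
  SD; reported coefficients are back-transformed to the original 0/1
  scale. Constant columns get β = 0 and are never retained.

λ is selected by stratified K-fold cross-validation (default 10 folds,
capped at the minority-class count so every fold sees both classes)
minimizing mean out-of-fold binomial deviance; ties prefer the stronger
penalty. Fold assignment derives from the config seed, making fits fully
deterministic. Convergence is declared at relative objective change
≤ 1e-7 (configurable); non-converged λ points are flagged in the fit
diagnostics.

The solver was cross-checked against two independent implementations:
scikit-learn's saga elastic-net logistic regression (no-covariate case,
agreement ~1e-5) and R glmnet with `penalty.factor` zeros on the
covariate block (agreement ~1e-5 after accounting for glmnet's internal
rescaling of penalty factors); the glmnet coefficients are frozen into
the test suite.

### Per-cluster p-values

The retention rule needs a p-value per cluster alongside the penalized β.
The package uses a covariate-adjusted Rao score test: the null logistic
model (intercept + SC covariates) is fitted once by Newton's method with
a tiny ridge (1e-8) so complete separation inside an SC cannot diverge,
and for each cluster column the statistic U²/V is referred to χ²(1),
where U = xᵀ(y − p₀) and V is the information of x after projecting out
the null design. With no covariates this reduces exactly to the Pearson
chi-squared of the 2×2 carrier-by-K-locus table. Whether the original
analysis used pre-fit univariate p-values or post-selection quantities is
not documented; the score test is the package's documented default, and
its type-I error under a lineage-structured null is verified to sit in
[0.03, 0.07] at the nominal 5% level. Bonferroni correction uses
N = number of clusters in the filtered matrix for that resolution.

## Predictor evaluation

A retained predictor is scored as a binary classifier of its K-locus:
TP = carrier isolate with the K-locus, FP = carrier without it, FN =
non-carrier with it, TN = non-carrier without it; precision, recall,
F1 and MCC follow the standard formulas with explicit degeneracy
conventions (zero denominators give 0, flagged). SC-level evaluation
collapses to one unit per SC under the *any-isolate* rule — an SC is
predictor- or K-positive if any member isolate is — because prophage
acquisition is sporadic within lineages and a majority rule would hide
recent gains; a majority rule is available as an option.

Bootstrap CIs are percentile intervals over (default) 100 resamples of
isolates with replacement. Full rows are resampled — TN comes along with
TP/FP/FN — because MCC and F1 need it. Replicates where a metric's
denominator is degenerate are excluded from that metric's quantiles
rather than imputed as 0 (imputation would bias CIs for rare K-loci);
their count is reported, and a metric whose replicates are all undefined
is flagged unavailable.

SC-concordance, used by curation, is the Jaccard overlap between the
predictor-positive and K-positive SC sets — a numerical stand-in for
visually checking that a predictor tracks the K-locus along the
phylogeny.

## Selection and curation

Candidates for one K-locus are pooled across all six clustering
resolutions. Selection filters to isolate-level precision ≥ 0.8, takes
the argmax of F1 × MCC, and reports it only if F1 ≥ 0.5 and MCC ≥ 0.5;
ties break by higher precision, then recall, then lexicographic (level
label, cluster id), making selection order-independent.

Curation grades a predictor *strong* when it is GWAS-retained with
isolate and SC precision ≥ 0.8, F1 ≥ 0.5, MCC ≥ 0.5 and SC-concordance
≥ 0.5; *likely* when GWAS-retained with isolate precision ≥ 0.8 and
either recall ≥ 0.2 at some level or the isolate-level metric gates
passing; otherwise *none*. These thresholds are a reconstruction — the
original curation framework is only qualitatively described — and all of
them are exposed in `CurationRules`. Every rule outcome is logged in the
call's `reasons`. Under the default synthetic benchmark the SC-precision
gate is the binding constraint: the planted predictor is selected in
~100% of seeds but graded strong in only ~70%, because a handful of
false-positive carriers scattered over distinct SCs can pull SC-level
precision just below 0.8 under the any-isolate rule.

## Prophage region consensus

Detection intervals from two tools are pooled per contig, merged wherever
they overlap or touch (adjacency merges; "union" is closed under it),
extended by 2 kb on both sides (clipped to the contig) and re-merged. QC
records — trims or splits with completeness and confidence — replace
each extended region by sub-regions, which are re-extended by 2 kb and
retained iff completeness ≥ 50%, confidence in {low, medium, high} and
length ≥ 2 kb. Length is measured after re-extension by default (the
retention criteria are stated after the second extension in the source
protocol); a flag measures the trimmed interval instead. When QC splits
a region, each sub-region is filtered independently. Regions without any
QC record are dropped. Coordinates are 0-based half-open internally and
1-based inclusive in GFF3 output.

## Annotation and diversity

ECOD hits per PC80 cluster are filtered at probability ≥ 0.70, reduced to
the best hit per X-level, and reported as the top ≤ 5 distinct T-levels.
A PC50 cluster is labelled by the modal T-level combination of its member
PC80 annotations (members without annotation contribute the empty
combination; ties prefer larger combinations, then lexicographic), with
an independent flag when any member carries the pectin-lyase-like fold
207.2.1. RBPs are called from PHROG hits whose category contains "tail
fiber" (fibre normalized) or "tail spike" at probability ≥ 0.90 and
query/subject coverage ≥ 0.50; RBP domains are ECOD T-levels at
probability ≥ 0.90 and template coverage ≥ 0.10, multi-domain allowed.
The two probability floors (0.70 for PC80 reporting, 0.90 for RBP
calling/domains) are distinct config keys and never conflated.

K-locus diversity of an RBP cluster is the Gini–Simpson index 1 − Σp²
over member K-locus fractions (0 = all members share one K-locus,
upper bound 1 − 1/m for m loci), computed for clusters with ≥ 10 members
from ≥ 3 SCs. The inverse-Simpson alternative was considered and
rejected because the documented 0-to-1 range matches the Gini–Simpson
form. Near-complete prophages (completeness ≥ 90%) are stratified per
K-locus into single-domain, multi-domain, RBP-without-domain and no-RBP
classes; for RBP-without-domain prophages, genes within ±2 positions of
an RBP are scanned for enzymatic domains.

## Phage variants

wGRR(A, B) = Σ id(Aᵢ, Bᵢ) / min(|A|, |B|) over bidirectional best hits
with identities as fractions — the formula is the field's standard
definition, adopted here as an assumption since only the clustering
threshold (0.95) is documented in the source. Variants are connected
components (single linkage) of the graph with edges wGRR ≥ threshold,
labelled by their lexicographically smallest member. Every prophage
record is counted; no within-isolate deduplication is applied.

## Synthetic data generator

The generator emulates the study's data structure, not its sequences:

* **Population.** SC sizes are symmetric Dirichlet-multinomial
  (concentration 5 by default) with each SC seeded by one isolate so none
  is empty. Each SC draws a dominant K-locus uniformly with replacement
  (several SCs may share one, which is what makes eligibility and
  SC-level evaluation meaningful); each isolate keeps its SC's dominant
  K-locus with probability 1 − k_switch_rate (default 0.9) and otherwise
  switches uniformly — the model of sporadic capsule swaps.
* **Repertoires.** Background clusters are carried i.i.d. at frequencies
  drawn uniformly from [0.05, 0.30]. A planted true-RBP cluster is
  carried with probability `sensitivity` by target-K isolates and `fpr`
  otherwise; a lineage confounder tracks one SC (by default the largest
  SC dominated by the target K-locus, the worst case for the GWAS)
  irrespective of capsule; a correlated copy equals its parent column
  with independent bit flips.
* **Cross-resolution structure.** Columns are planted at the default
  resolution (identity 50/coverage 50). At each looser level a planted
  family may merge with one random background family (union of carriers);
  at each stricter level it may split into two random halves of its
  carriers. Merges/splits apply only to planted families — the minimal
  mechanism that exercises cross-level selection. The truth object maps
  every planted family to its cluster ids at all six levels.
* **Companion tables.** Each isolate gets one synthetic contig with one
  true prophage span, two-tool detections jittered around it, a QC record
  with known completeness/confidence, and PHROG/ECOD hit rows consistent
  with each planted cluster's kind (true RBPs get tail-fiber calls and a
  configurable ECOD T-level, 207.2.1 by default).

What the generator does **not** model: sequence evolution, within-SC
phylogeny, recombination, correlated background carriage (background
clusters are independent given their frequency), multi-contig assemblies,
or K-locus call errors. Passing tests therefore demonstrate statistical
behaviour of the pipeline under a faithful abstraction of the study
design, not performance on real assemblies.

Randomness: every operation derives a child generator by hashing
(master seed, operation name), so adding operations never perturbs
existing draws, and identical (config, seed) gives bit-identical outputs.

## Benchmark sizes and determinism

The default benchmark — 500 isolates, 25 SCs, switch rate 0.1, 200
background clusters, one planted true RBP (sensitivity 0.9, fpr 0.01) and
one lineage confounder — is run for 20 seeds with and without covariates;
association runs use the default clustering level, which always hosts the
planted family as a single cluster, keeping the benchmark's solver time
within a desktop-scale budget; cross-resolution selection is exercised on
six-level fixtures separately. Score-test calibration uses 2,000
lineage-structured null clusters; bootstrap coverage uses 300 datasets of
400 isolates at true precision 0.8; the metric oracle enumerates all
46,376 confusion tables with total ≤ 30; the interval oracle compares
1,000 random instances against a per-base boolean-array implementation.

Outputs are deterministic given seeds on a fixed host. The numba kernel
is compiled with fastmath and linear algebra goes through the host BLAS,
so floating-point results can differ in the last bits across CPU
microarchitectures; the golden-file regression therefore freezes the
integer/string-valued stages (simulation tables, region consensus) and
checks the float-bearing report stage by within-host re-run comparison.

## Known limitations

* The p-value definition (score test) and the wGRR formula are documented
  assumptions where the source protocol is silent.
* Curation thresholds are a reconstruction; the strong/likely boundary in
  particular is configurable and should be calibrated against expert
  curation when real data are available.
* The elastic-net grouping effect is only observable between the two α
  modes for *near*-duplicate clusters: for bit-identical duplicates both
  modes share weight across all copies whenever any ridge component is
  present, so duplicate counts cannot distinguish them.
* SC labels are treated as error-free; misassigned lineages would leak
  structure past the covariates.
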