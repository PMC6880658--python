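# Methods

`lldnet` implements a complete symptom-network analysis workflow for
late-life depression (LLD) cohorts rated on the 10-item MADRS with comorbid
anxiety measured by the 21-item BAI, together with a synthetic-cohort
generator that provides gold-standard truth for every stage.

## Data model and cohort rules

A cohort is a per-subject table of 10 ordinal MADRS items (0–6), a BAI sum
(0–63, optionally with the 21 items), age, sex, education years,
diagnosis-history exclusion flags, and an optional anxiety-group label.
Eligibility retains subjects with MADRS sum ≥ 10 (inclusive) and none of
the excluded diagnosis flags (bipolar disorder, schizophrenia, other mental
disorder, dementia). The anxiety split assigns BAI sum ≥ 16 (the
moderate-anxiety boundary) to the high-anxiety group.

Rows with any missing MADRS/BAI value are rejected at read time
(complete-case analysis); we do not impute. This is a package policy, not a
claim about how any particular clinical study handled missingness.

## Synthetic cohorts

The generator uses the latent-Gaussian threshold model that underlies
polychoric correlation: latent symptoms `z ~ N(0, Σ)` with `Σ` the
unit-variance standardization of the inverse of a sparse precision matrix;
observed items arise by thresholding the standardized marginals. Thresholds
are placed at `(k + 0.5 − μ_j)/σ_j` (a discretized normal), with item
means/SDs loosely matching a community sample of elderly depressed
outpatients (mean age ≈ 74, ≈ 72% female, education ≈ 6 years); covariates
are sampled accordingly but without claiming distributional fidelity.

A scalar latent anxiety factor `a ~ N(0,1)` can enter in two ways:

* **item loadings** (`anxiety_loading`) — anxiety correlates with specific
  symptoms;
* **severity shift** (`severity_shift`) — every latent symptom shifts by
  `severity_shift · a`. This is the confounding knob: it raises overall
  severity in the high-anxiety stratum while leaving the *partial
  correlation structure identical* in both strata, encoding "anxiety
  worsens severity rather than changing psychopathology" as a generative
  null.

BAI sums in the presets are produced by rank-based inverse-CDF coupling: a
noisy copy of `a` is ranked and mapped through a fixed discrete marginal
(two truncated-normal lobes meeting at the cutoff, with exactly 462/776 of
the mass below 16). This preserves monotone dependence on latent anxiety
while pinning the low/high split at (462, 314) deterministically for
n = 776 — convenient for reproducing a fixed participant flow. Setting all
loadings and the shift to zero provably decouples BAI from the items.

Presets: `baseline_lld` (three symptom clusters — dysphoric
apathy/retardation {items 1, 2, 6, 7, 8}, psychic anxiety {3, 9, 10},
vegetative {4, 5} — with the strongest edges inside clusters, one negative
sleep–pessimism edge, and anxiety decoupled), `confounded_anxiety`
(severity shift 0.5, chosen once so the BAI split exhibits a ≈ 8–9-point
MADRS-sum gap, matching the magnitude reported for real anxious-depression
cohorts), and `null_two_group` (fully decoupled; the two BAI groups are
exchangeable). The baseline edge weights (0.15–0.45 partial correlation)
were fixed by a one-time Monte-Carlo calibration so that (a) penalized
estimation at n = 776 recovers the support with sensitivity/specificity
≥ 0.8 and (b) the strength ranking puts reported sadness, pessimistic
thought and suicidal thought on top — the "core symptom" configuration.

What the generator does *not* emulate: item-level floor/ceiling skew beyond
the discretized normal, informative missingness, measurement error
structure of self-report vs clinician rating, or medication effects.
Passing tests therefore validate the statistical machinery, not clinical
generalizability.

## Association estimation

Ordinal–ordinal pairs use the two-step polychoric estimator: thresholds
from inverse-normal cumulative marginal proportions, then a bounded scalar
maximization (tolerance 1e−6, ρ ∈ [−0.999, 0.999]) of the bivariate-normal
cell likelihood over the contingency table. The bivariate normal CDF is a
vectorized Genz/Drezner–Wesolowsky quadrature (`lldnet._bvn`), accurate to
~1e−14 and fast enough to refit the full 45-pair matrix hundreds of times
inside bootstrap and permutation loops.

Empty cells contribute nothing to the ML criterion and need no treatment in
general tables; in 2×2 tables an empty cell makes the MLE degenerate at
±1, so there the standard 0.5 continuity correction is applied. The
two-step (rather than full-information) estimator matches common practice
and is dramatically cheaper.

The anxiety node uses the BAI *sum* treated as continuous via the two-step
polyserial estimator (Pearson available by configuration); a 64-category
ordinal treatment would add cost without measurable benefit at these sample
sizes. If the assembled matrix has negative eigenvalues, it is repaired by
eigenvalue clipping plus unit-diagonal rescaling and flagged.

## Network estimation

The Gaussian graphical model is fitted by graphical lasso (coordinate
descent, off-diagonal penalty only) on a log-spaced path of 100 penalties
from λ_max (the largest absolute off-diagonal correlation) down to
0.01·λ_max. Model selection minimizes
EBIC = −2·loglik + E·log n + 4γ·E·log P with γ = 0 by default (= BIC);
EBIC ties resolve toward the sparser (larger-λ) model. Edge weights are the
partial correlations −K_ij/√(K_ii·K_jj). Estimation is deterministic;
per-penalty solutions warm-start from the previous penalty, which changes
results only below the 1e−6 dual-gap tolerance. The solver is
cross-checked in tests against the exact 2-node soft-threshold solution and
a derivative-free direct minimization on 3-node problems.

## Centrality

Strength is Σ|w|; closeness and betweenness use shortest paths with edge
length 1/|w| (stronger association = shorter distance), the convention for
signed association networks. Closeness is 1/Σd over *reachable* nodes (0
for isolated nodes); betweenness splits credit fractionally across tied
shortest paths. Both are verified against exhaustive simple-path
enumeration on all networks of ≤ 6 nodes.

## Resampling

Edge accuracy uses the nonparametric bootstrap (default 1000 resamples;
percentile 2.5/97.5 intervals — percentile rather than BCa, matching
common practice in this literature). Centrality stability uses the
case-dropping bootstrap; the CS coefficient is the largest drop proportion
at which subsample strength still correlates ≥ 0.7 (Spearman, robust to
monotone distortion) with the full-sample strength in ≥ 95% of resamples.
All randomness flows from a single integer seed.

## Network comparison

The permutation comparison refits the *entire* polychoric + graphical
lasso + EBIC chain on every permutation (pool subjects, re-split at the
original sizes), which is costlier than re-inverting but faithful to how
the observed networks were obtained. Statistics: global strength difference
|Σ|w_A| − Σ|w_B||, global structure (maximum absolute single-edge
difference), and per-edge differences with Holm adjustment. p-values use
the plus-one estimator (never exactly 0; default 1000 permutations). The
pooled table is sorted by subject id before permuting, so seed-matched
results are invariant to which group is labelled A.

## Propensity-score matching

A multivariable logistic regression of high-anxiety membership on MADRS
sum, age, sex and education years yields propensity scores; matching is
greedy 1:1 nearest neighbor without replacement on the logit, caliper
0.25 SD of the logit propensity (the Rosenbaum–Rubin convention;
raw-logit calipers available), unmatched subjects discarded. Pairs are
formed **closest-first**: the globally least-different available pair is
matched, then the next. A fixed processing order (e.g. descending treated
propensity) systematically pairs each treated subject with a control below
it when the distributions are shifted, leaving a one-sided residual
imbalance of ~0.15 SD on the matched severity means; closest-first pairing
removes that bias (median post-match SMD < 0.01 on the confounded preset)
while remaining greedy and deterministic (distance ties break by input
order). The phrase "least difference … were paired" in the matching
literature describes exactly this rule. Balance is reported as
standardized mean differences before/after, using the pre-match pooled SD.

An optional literal "per-covariate scores summed" mode is not provided; the
single multivariable logistic model is the method the standard matching
toolchain implements.

## Group statistics

Independent comparisons use the Welch t-test (from raw data or printed
summaries; pooled-variance mode is deliberately absent), paired
comparisons the one-sample t on differences, and sex ratios the χ² test
with Yates continuity correction — required to reproduce borderline
published values such as p = 1.00 when two proportions differ by a single
count. All p-values are carried at full precision and rounded only for
presentation; α = .05.

## Pipeline

`run_study` executes: eligibility → baseline network + centrality +
bootstrap → anxiety-augmented network → BAI split → pre-matching network
comparison + demographics report → matching → post-matching comparison,
writing a JSON manifest of counts and artifact paths. Per-stage seeds are
derived from one master seed by SHA-256 hashing of the stage name (stable
under stage reordering; always < 2³¹).

## Monte-Carlo problem sizes

Simulation-based checks run at reduced sizes chosen to keep the full suite
fast while retaining statistical meaning; honest error bands are computed
for the reduced replicate counts rather than reusing bands stated for
larger designs:

* permutation-test calibration: 20 null replicates, 150 subjects/arm,
  100 permutations, 10-λ path; rejection count bounded by the binomial
  97.5% bound at α = .05 and mean null p required near 1/2;
* severity-shift-only null after matching: 15 replicates, 100 permutations,
  non-significance required in ≥ 80%;
* support recovery: 20 replicates at n = 776 with the default 100-λ path;
* matching balance: 50 replicates, SMD < 0.1 required in ≥ 90%;
* edge-level detection power: one replicate at 500/arm with 1000
  permutations (Holm over 45 edges needs raw p < .05/45, hence the large
  permutation count);
* acceptance script: 200 permutations and a 20-λ path for the end-to-end
  synthetic study.

## Known limitations

* The NCT refit-per-permutation design makes large permutation counts
  expensive; the permutation test's validity does not depend on the path
  resolution, so shorter λ paths are used inside permutation loops.
* Polychoric standard errors are not produced (only bootstrap intervals).
* The matching module implements greedy 1:1 caliper matching only — no
  optimal assignment, weighting, or replacement.
* Closeness on disconnected graphs is reachable-set based and therefore not
  comparable across nodes with different reachable sets.
* The generator's rank-coupled BAI marginal fixes the anxiety prevalence;
  it is a device for reproducible participant flow, not an estimate of any
  population's BAI distribution.
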