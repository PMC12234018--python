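# Methods

## The latent severity model

Severity is modelled as a single latent factor η measured by three
standardized indicators: cognitive eating-disorder symptoms (a 0–6 global
score computed *without* the two overvaluation items, to avoid overlap with
the covariate that may define severity groups), a depression total, and an
anxiety total. Because different instruments are used per treatment
setting (CESD vs PHQ-9 for depression; OASIS vs GAD-7 for anxiety), every
indicator is z-scored within level-of-care stratum (sample sd, denominator
n−1) before modelling.

The model is `y_k = m_k + λ·η + ε_k` with η ~ N(0, 1) and independent
normal residuals. Identification fixes the latent variance at 1; the
loading λ is *shared* by all three indicators (an equal-loadings
constraint; a free-loadings variant is deliberately out of scope because it
is poorly identified with three indicators) and constrained to λ ≥ 0 to
resolve the sign indeterminacy. That leaves 7 free parameters: λ, three
manifest means, three residual variances. The implied moments are
μ = (m₁, m₂, m₃) and Σ = λ²·11′ + diag(σ₁², σ₂², σ₃²).

Estimation is full-information maximum likelihood: each row contributes the
log-density of its observed sub-vector under the corresponding marginal of
(μ, Σ). Rows are grouped by missingness pattern and reduced to sufficient
statistics (count, mean, scatter), so an objective evaluation is O(number
of patterns) regardless of n; gradients are analytic; residual variances
are optimized on the log scale (L-BFGS-B, objective tolerance 1e-8).
Starting values are deterministic — λ = 0.5, sample means, half sample
variances — with two fixed fallback restarts (λ = 0.2, 0.9) on
nonconvergence. Rows with all three indicators missing are rejected rather
than silently dropped; a zero-variance indicator is an error.

## SEM Tree

A candidate split of a node's rows at threshold t on covariate x sends
x < t left and x ≥ t right (the threshold itself routes right, so group
definitions read "≥ t"). Its score is LR = 2(LL_left + LL_right −
LL_parent), all three from models refit on the respective row sets. Since
both children re-estimate the full 7-parameter vector, the LR is referred
to χ² with 7 df. Child fits warm-start from the parent's estimates (a pure
speed optimization; the optimum is unchanged).

Split selection uses the fair criterion to control covariates' differing
numbers of response levels:

1. randomly halve the node's rows;
2. on half 1, score every candidate threshold of every offered covariate
   and keep each covariate's best;
3. score each covariate's selected threshold on held-out half 2;
4. the covariate with the largest half-2 improvement wins, and the split is
   retained only if its half-2 p clears α (default 0.05) Bonferroni-divided
   by the number of covariates offered at the node;
5. the reported LR, p, and child sizes of a retained split are recomputed
   on the full node sample.

Retention is decided on the half-2 (confirmation) p because, conditional on
the threshold chosen from half 1, that statistic is exactly χ²₇ under the
null; deciding on the recomputed full-sample p would re-use the selection
half and inflate the type-I rate. In null simulations (no covariate
effect, two covariates, n = 600) the split-retention rate is ≈5%,
consistent with the nominal level; modest finite-sample inflation is
possible in small or highly imbalanced children.

Candidate thresholds are the midpoints between consecutive distinct
covariate values observed in the selection half — this covers cutpoints
that are not attainable scores, such as 3.75 on the 0.5-increment
overvaluation grid. For near-continuous covariates the candidate set is
capped (default 48) by falling back to an equally-spaced quantile grid;
otherwise a bootstrapped noise covariate would cost O(n) model refits per
node. Other defaults: minimum node size 30 (≈ the smallest subgroup a
clinical sample of this kind supports; a node must have ≥ 2×30 rows to be
searched, and every evaluated child ≥ 30), no depth limit. Rows missing
the split covariate contribute to the node's model fit but not to split
evaluation, and are unassigned at prediction time (no surrogate splits).
Leaves are labelled 1..K in left-to-right order, i.e. ascending severity
interval. Trees serialize to JSON deterministically (a fixed seed
reproduces the tree byte-for-byte).

## SEM Forest

Each of n_trees (default 100) trees is grown on a bootstrap resample of
size n, with vars_per_split (default 1) covariates drawn uniformly at
random as the candidate set at each node — with two covariates and one
variable per split, the covariates compete head-to-head. Importance of a
covariate is out-of-bag permutation importance in −2LL units: permute the
covariate's values among a tree's out-of-bag rows, re-route those rows
through the tree, and record the increase in the summed leaf-model −2LL
over the intact routing (1 permutation per tree by default, seeded). The
table reports the sum across trees. A covariate never used by a tree's
splits contributes exactly 0 for that tree, so a never-selected covariate
scores exactly 0 overall. Importance can be slightly negative for weak
covariates; under a null effect it is centred at 0.

## Severity schemes and comparisons

Four schemes label each patient:

* **semtree** — leaves of a grown tree, or of the shipped reference tree
  (`data/published_tree.json`, a synthetic fixture built from the
  reported cutpoints 1.25/3.75/4.75/5.75 — thresholds only, no fitted
  parameters);
* **dsm5** — weekly compensatory frequency (28-day capped total ÷ 4) banded
  mild [1, 4), moderate [4, 8), severe [8, 14), extreme [14, ∞); below
  1/week is flagged `subthreshold` and excluded from comparisons rather
  than forced into "mild";
* **clinical_overvaluation** — clinical iff either overvaluation item ≥ 4;
* **purging_count** — number of purging methods with ≥1 episode in 28 days;
  the questionnaire merges laxative and diuretic use into one frequency
  item, so the default method set is {vomiting, laxative/diuretic use}
  (exercise is not purging); `none` is excluded from this scheme's
  comparisons.

For each scheme × characteristic (with pairwise deletion, and excluding any
characteristic that defines the scheme — compensatory frequency for dsm5,
overvaluation for the other three), Levene's test (center = mean; median
optionally) gates the ANOVA: classical one-way F when p ≥ .05, Welch F
(statsmodels, Satterthwaite df) otherwise. Partial η² is always
SS_effect/(SS_effect + SS_error) from the classical decomposition; for
two-group schemes it is t²/(t² + df) so all schemes summarize on one
scale. The variance summary reports min/max/mean η² per scheme and all
pairwise ratios of means.

Planned contrasts use the Helmert family — group j versus the pooled
higher-severity groups j+1..K — whose coefficient vectors sum to zero and
are pairwise orthogonal under equal weights; with unequal group sizes the
same (unweighted) coefficient vectors are retained. The cumulative-pool
alternative ("groups 1..j vs the rest") was rejected because it is not an
orthogonal family. Welch-type contrasts use per-group variances with
Satterthwaite df; classical contrasts use the omnibus MSE with N−K df.
Cohen's d for a contrast is the difference of the two pooled sides' means
divided by their pooled sd (not the omnibus MSE). Note that the Welch and
classical F are identical under equal variances and sizes only at K = 2
(where both reduce to the t); for K > 2 the Welch denominator correction
is strictly > 1 even in the balanced case.

## The synthetic-cohort generator

The generator emulates the features the analysis depends on: two
overvaluation items drawn as a correlated bivariate normal (default latent
r = 0.80) rounded and clipped to the 0–6 integer grid (item mean 4.3, sd
1.5 — a treatment-seeking, high-overvaluation population; discretization
attenuates the realized correlation to ≈0.75); composite = item mean, so
0.5-increment values; planted groups from composite cutpoints, each
shifting the latent mean (η has unit variance within group); indicators
λη + ε with defaults λ = 0.8, residual variances 0.36 (unit total
variance); anxiety missing completely at random at 35%; level-of-care
strata (residential .757 / PHP .189 / outpatient .054) with affine
instrument scales per stratum, so stratified z-scoring exactly inverts the
scaling; negative-binomial 28-day compensatory counts (vomiting mean 20,
laxative/diuretic 6, exercise 10) with a weak log-linear dependence on η
(slope 0.15) — weak but nonzero, because a literally zero behavioural
signal would make "behaviour-based schemes explain less variance" trivially
true; binge counts likewise (mean 8, slope 0.05). Ground truth (group
label, η) goes to a JSON sidecar, never into the analysis CSV.

What it does **not** emulate: non-MCAR missingness, floor/ceiling effects
in the instrument totals (the affine scales can exceed nominal ranges),
item-level questionnaire structure, demographic covariates, or any
treatment-response dynamics. Passing tests therefore show the *method*
recovers planted structure under its own assumptions, not that real BN
cohorts satisfy those assumptions.

## Validation problem sizes

The test suite validates at desk scale: oracle equivalence on 50 fixtures
of n = 200; parameter recovery over 20 cohorts of n = 2000; single-cutpoint
recovery over 50 searches at n = 1000 and two-cutpoint tree recovery over
50 cohorts at n = 2000; type-I control over 200 null cohorts at n = 600;
importance ordering over 20 twenty-tree forests at n = 1000; and one
end-to-end run at n = 1500. `scripts/acceptance.py` recomputes the same
quantities at comparable sizes from a user-supplied seed. All simulated
checks are seeded and deterministic.

## Known limitations

* The χ²₇ reference for split LRs is asymptotic; very small children
  (near the 30-row floor) are slightly anti-conservative.
* Permutation importance re-routes but does not refit leaves; it measures
  routing relevance, not refitted fit gain.
* The published-threshold reference tree is a synthetic fixture carrying
  thresholds only; its node counts are descriptive.
* With identical seeds for cohort generation and tree growth the two
  random streams coincide; use distinct seeds (as the CLI and scripts do)
  to keep halving independent of the data.
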