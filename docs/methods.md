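# Methods

This note documents the statistical models implemented in `tubetask`, the
conventions chosen where several were defensible, and what the synthetic-data
generator does and does not emulate.

## Individual laterality

For a subject with `R` right- and `L` left-hand bimanual insertions, the
handedness index is `HI = (R - L) / (R + L)`, in [-1, 1]. Preference classes
come from the binomial z score against an even-split null,
`z = (R - n/2) / sqrt(n/4)` with `n = R + L`: right-handed if `z > 1.96`,
left-handed if `z < -1.96`, otherwise ambipreferent. Two conventions are
deliberate and isolated in `laterality.binomial_z` / `laterality.classify`:

* **No continuity correction.** The tube-task literature quotes plain
  normal-approximation z scores; the convention is documented here and in one
  function so it can be swapped if desired.
* **Boundary ties are ambipreferent.** The class boundaries are strict
  inequalities, so `z = ±1.96` exactly stays ambipreferent.

Inclusion thresholds mirror the study protocol: at least 30 insertions in at
least 6 bouts per subject (both inclusive), and at least 15 subjects per
species for species-level direction tests. Genus summaries pool subjects, so
a genus `n` is the sum of its species `n`s. Reported percentages are rounded
half-up to one decimal.

## Population-level tests

Direction is tested per group with a two-sided one-sample t-test of subject
HIs against zero. The left/right/ambipreferent tally is tested with a Pearson
chi-square (df = 2) against a clade-specific baseline: the clade's expected
ambipreferent share with the remaining "handed" mass split evenly between
left and right, `p_left = p_right = (1 - p_ambi) / 2`. Humans are excluded
from the hominoid baseline — their extreme right bias would otherwise define
the null their own row is tested against.

The clade mean can be taken over individuals (pooled) or over species
(unweighted mean of species frequencies). The default is **individual
pooling**: recomputing the packaged table's chi-square p-values from its own
counts reproduces 36 of 38 published species p-values and 21 of 22 genus
p-values to the printed precision under pooling, versus 6 of 38 under species
means, which settles the ambiguity empirically. The species-mean variant
remains available (`weighting="species"`).

Bonferroni correction uses the number of groups tested as the family size
(38 species / 22 genera for the packaged table). With m = 38 the corrected
significance threshold sits at 0.05/38 ≈ 0.0013, which separates the
published starred and unstarred rows.

### Known defects in the packaged table

The packaged `table1.csv` transcribes the published species table. Three
entries of the source rendering are internally inconsistent and were
reconciled against the published test results, which pin down the intended
counts: one species' right/ambipreferent counts were transposed, one
printed percentage triple contradicts its own counts, and one printed p-value
duplicates the row above it. A handful of printed percentages differ by 0.1
from exact rounding because the source forces each row to sum to 100%. The
fixture-reproduction tests therefore assert agreement within 0.1 percentage
points with exact agreement for the unaffected entries.

## Phylogenetic signal (Pagel's lambda)

A species-level trait x on a tree with tip covariance matrix C (shared
root-to-MRCA branch length; diagonal = root-to-tip distance) is modelled as
MVN(mu·1, sigma² · C_lambda), where C_lambda multiplies the off-diagonal of C
by lambda in [0, 1]. mu and sigma² are profiled in closed form (GLS mean and
ML variance); lambda is optimized by bounded Brent restarted from a 5-point
grid (tolerance 1e-8), which also guards against local optima and detects
flat surfaces (star phylogenies) — flatness raises a warning and is flagged
on the result. The no-signal null (lambda = 0) is assessed by a likelihood
ratio test against chi-square with 1 df. Because lambda = 0 lies on the
boundary of the parameter space this reference distribution is conservative;
when the ML estimate itself is 0 the statistic is exactly 0 and p = 1, which
is the published behaviour for lateralization direction. Trees are used in
native time units; lambda and the GLS estimates are invariant to global
branch-length rescaling.

## Ancestral states under Brownian motion

Ancestral estimates are the joint maximum-likelihood states under pure BM
(lambda = 1): the BM likelihood factorizes into independent Gaussian
increments along edges, so maximizing over internal states solves a weighted
tree-Laplacian linear system with tips clamped; the root estimate equals the
GLS mean automatically. Estimation variances are the internal block of the
inverse precision scaled by the ML rate. ASR is computed on the untransformed
tree rather than the lambda-rescaled one — the common default of the tooling
generation this mirrors; estimates under a fitted lambda < 1 would shrink
internal nodes further toward the root mean. Zero-length edges are floored at
1e-12 to keep the system nonsingular.

## PGLS with multi-model inference

Species means (MeanHI for direction, MeanAbsHI for strength) are regressed on
up to three predictors — ecology (0 = arboreal, 1 = terrestrial), habitual
foraging-related tool use (0/1), log10 female endocranial volume (ml) — with
residual covariance sigma²·C_lambda and lambda estimated per model by ML.
All 2^3 = 8 predictor subsets (including the intercept-only NULL) are ranked
by AICc with `k` = intercept + slopes + residual variance; lambda is *not*
counted, which reproduces the published df column (NULL = 2, one-term = 3,
full = 5). Akaike weights are proportional to exp(-delta/2). Ties in AICc
break toward fewer terms, then lexicographic term order, for determinism.

Per-term effects use the conditional model average: the weighted mean over
only the models containing the term with renormalized weights, and the
revised model-averaging standard error
`sqrt(sum_m w_m (se_m² + (b_m - b̄)²))`; p-values use a normal reference.
Coefficient standard errors within each model use the unbiased residual
variance RSS/(n - p) on the whitened scale, while the reported log-likelihood
(and hence AICc) is the ML one. Collinearity is checked with VIFs
(1/(1 - R²_j) from regressing each predictor on the others) and residual
normality with the Shapiro-Wilk test on whitened residuals of the best model.

The three published analyses are wired in `run_model_suite`: direction on
species with n ≥ 15 (humans included), direction excluding humans, and
strength on all species. Ecology coding is user input (the original
per-species coding is distributed separately from the summary table and is
never hard-coded here); the sign conventions above make a terrestrial-lifestyle
effect positive for direction and negative for strength, matching the
published coefficient table.

## Bayesian phylogenetic multilevel model

Subject-level HI or |HI| is modelled as Gaussian:

    y_i = b0 + b_age·subadult_i + b_sex·male_i + u_{s(i)} + e_i,
    u ~ MVN(0, sigma_species² · A),  e_i ~ N(0, sigma_resid²),

with A the tree's covariance scaled to unit diagonal (a correlation matrix),
separating tree shape from the scale of the species effect. A Gaussian
response for a bounded index follows the original modelling choice; near the
-1/1 boundaries the model can place mass outside the support, which is a
known approximation. Priors: flat on coefficients, half-Student-t(3, 0, 2.5)
on both standard deviations — weakly informative on the response scale of an
index bounded by 1, and configurable.

The sampler is blocked Gibbs. Coefficients are drawn from their conditional
with the species effects integrated out (a Woodbury identity keeps all
matrix work at species dimension); this collapsed update eliminates the slow
random walk between the intercept and the mean species effect. Species
effects then come from their joint Gaussian conditional, and the two SDs are
updated by slice sampling on the log scale. Chains are seeded independently
from a root seed, so runs are bit-reproducible; split R-hat and effective
sample size (via ArviZ) are attached to every fit, with R-hat > 1.01 raising
a warning (or a nonzero exit in strict mode). Exclusions follow the study
design: humans, chimpanzees (overrepresentation), Tonkean macaques (no age
data), unsexed subjects; defaults are 4 chains × 2000 iterations with 1000
warmup. A "notable" effect is one whose equal-tailed 95% credible interval
excludes zero.

## Synthetic data

The generator produces a pure-birth tree rescaled to unit height, species
latent traits by one MVN draw from sigma²·C_lambda, and subjects whose
right-hand probability is logit-normal around the species latent direction:
`logit(p_i) ~ N(mu_s + age/sex shifts, tau_s²)`, `R_i ~ Binom(n_i, p_i)`
with insertion counts uniform on 30–155 (a shifted negative-binomial option
matches the observed mean of about 51). Strength is controlled by the
within-species spread tau_s, whose log evolves on the tree — so the defaults
(lambda_strength = 0.9, lambda_direction = 0) reproduce the structure of the
real data: heritable strength, unheritable direction. Ecology effects can be
injected on the latent direction (logit shift) and latent strength (log-tau
shift).

What the generator does *not* emulate: bout-sequence autocorrelation,
zoo-specific housing effects, literature/original data mixing, and the exact
species-abundance distribution. Two quantitative consequences matter for
interpreting tests. First, the map from latent spread to mean |HI| saturates:
tau = 3 yields species MeanAbsHI around 0.65, and pushing species means above
0.8 (langur-like) needs tau around 6. Second, binomial sampling noise acts as
measurement error on species means, attenuating the fitted lambda on
MeanAbsHI below its latent value (median around 0.7 over replicates at a
latent 0.9). Recovery of lambda is unbiased when traits are simulated
directly at species level, which is what the phylogenetic acceptance checks
use; the end-to-end check asserts the qualitative contrast (strong strength
signal, no direction signal). Passing these tests therefore demonstrates
correctness of the estimators under their own assumptions, not that real
tube-task data meet those assumptions.

For PGLS parameter recovery the response is simulated directly on the
measurement scale (`y = Xb + MVN(0, sigma²·C_lambda)`) with a BM rate of
0.03, chosen so the species-level residual spread (about 0.17 at the tips)
matches the published strength analysis; an injected ecology effect of -0.15
then has a signal-to-noise ratio comparable to the published table. For the
multilevel model, data are drawn from the model itself (balanced species
assignment, sigma_species = 0.1, sigma_resid = 0.2 — the within-species |HI|
spread of the real data is of this order).

## Problem sizes and numerical choices

Simulation-based checks use 200-tip trees with 100 replicates for lambda
recovery, 38-tip trees with 200 replicates for PGLS sign recovery, 1000
subjects for multilevel-effect recovery, and 25 replicates for interval
calibration; these sizes give stable Monte-Carlo estimates while keeping a
full run in minutes on one core. Cholesky factorization underlies all
likelihood evaluations; covariance matrices from valid trees are positive
definite, with a 1e-12 jitter only where simulated draws require it.
Ultrametricity is checked with relative tolerance 1e-6. The lambda search
tolerance is 1e-8; AICc ties break deterministically as described above.

## Known limitations

* The z-score convention (no continuity correction) can disagree with the
  exact binomial test near the threshold; classes are stable for the
  insertion counts used here but boundary subjects are convention-dependent.
* The LRT for lambda is conservative at the boundary; no mixture reference
  is applied.
* ASR assumes pure BM; directional trends or rate shifts would bias node
  estimates.
* The Gaussian multilevel model ignores the bounded support of HI.
* External headline numbers (the published lambda of 0.89, ancestral-node
  values, exact PGLS coefficients) depend on the 10kTrees phylogeny and the
  published predictor coding, which are user-supplied inputs, not package
  data.
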