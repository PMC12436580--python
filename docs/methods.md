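# Methods

`epdscat` evaluates computer-adaptive short forms of a 10-item
postpartum depression screen (the EPDS family: ten 0–3 items, total
0–30). This note describes the models, algorithms and numerical
choices, what the synthetic-data generator does and does not emulate,
and the design decisions made where the design was genuinely open.

## Measurement model

Item responses follow Samejima's graded response model (GRM) in
slope–intercept form. For item *i* with 4 ordered categories and latent
trait vector θ,

    P*_{i,k}(θ) = logistic(a_i·θ + d_{i,k}),   k = 1,2,3,
    P_{i,k}(θ)  = P*_{i,k}(θ) − P*_{i,k+1}(θ),  P*_{i,0} = 1, P*_{i,4} = 0,

with no 1.7 scaling constant. For unidimensional reporting the
difficulty parametrisation is b_{i,k} = −d_{i,k}/a_i. Three factor
structures are supported, all *simple structure* (each item loads on
exactly one factor):

* one factor — a single depression–anxiety severity;
* two factors — anxiety (items 3–5) vs anhedonia–depression (items 1,
  2, 6–10);
* three factors — anhedonia (items 1–2), anxiety (items 3–5),
  depression (items 6–10).

The latent prior is multivariate normal with zero mean, unit variances
and a free correlation matrix Σ (fixed-variance identification). Item
10 is the suicidal-ideation (SI) item; any nonzero recorded response
counts as endorsement.

Item Fisher information is
I_i(θ) = Σ_k (∇P_{i,k})(∇P_{i,k})ᵀ / P_{i,k}; under simple structure it
is rank ≤ 1 with its only nonzero diagonal entry on the loaded factor.
Category probabilities are floored at 1e−10 whenever divided by or
logged, so information and log-likelihoods stay finite at extreme θ.

## Estimation

Marginal maximum likelihood via EM on a rectangular quadrature grid
over [−6, 6]: 61 points for one factor, 31 per dimension for two, 25
for three. (Scoring and adaptive testing use a lighter 15-point grid in
three dimensions; estimation needs the denser one. The grid must
resolve the prior's correlation ridge — with factor correlations near
0.85 the conditional SD per dimension is ~0.5, and grids of 15–19
points per dimension bias the Σ update upward until the correlations
run away to a degenerate corr → 1 solution with a visibly worse
marginal likelihood.) Prior grid weights are the multivariate normal
density at the nodes, renormalised, and are refreshed whenever Σ
changes.

The E-step never materialises the full node × respondent posterior:
because the grid is a tensor product and each item's likelihood depends
on one factor's coordinate only, per-factor likelihood tables are
contracted against the prior tensor (staged `einsum`) to get marginal
likelihoods, axis marginals and posterior second moments directly. The M-step
maximises the expected complete-data log-likelihood item by item with
bounded L-BFGS-B (analytic gradient) on an ordered-increment
parametrisation (d_1, gaps g_2, g_3 > 0), so the strict intercept
ordering d_{i,1} > d_{i,2} > d_{i,3} holds by construction. Σ is
updated as the average posterior second moment of θ, rescaled to unit
diagonal, clipped to ±0.995 off-diagonal and eigenvalue-floored to stay
positive definite.

Initialisation is deterministic: slopes 1.0, intercepts at the logits
of marginal cumulative category frequencies, Σ = identity; estimation
involves no randomness. Convergence: maximum absolute parameter change
< 1e−4 (or 500 cycles, flagged unconverged). The observed-data
log-likelihood is monotone across cycles up to the Σ-rescaling step;
for one-factor fits it is monotone exactly (within 1e−8), and the test
suite asserts this.

Model comparison uses AIC = −2ℓ + 2p and BIC = −2ℓ + p·log N with
p = 10 slopes + 30 intercepts + D(D−1)/2 correlations. Marginal
log-likelihoods computed on different per-dimension grids are not
comparable across D; `estimate.marginal_loglik` re-evaluates any fitted
model on a caller-chosen common grid, and the nesting check (3-factor ≥
2-factor ≥ 1-factor) is asserted on a shared 21-point grid.

An item category never observed in the data makes its intercept
unidentifiable; the fitter either refuses (`on_empty_category="fail"`)
or proceeds with the bounded M-step pinning that category's probability
near zero (`"collapse"`).

## Scoring

Trait scores are EAP (posterior mean on the quadrature grid) with
posterior SDs from the posterior second moment. EAP estimates shrink
toward the prior mean; the cohort-level correction divides each
dimension by √ρ_d, where

    ρ_d = Var(θ̂_d) / (Var(θ̂_d) + mean SE_d²)

is the empirical reliability, restoring approximately unit variance.
The formula is isolated in `score.empirical_reliability_and_correct` so
an alternative correction can be swapped in.

Expected total scores map a trait estimate back to the 0–30 scale:
T(θ) = Σ_i Σ_k k·P_{i,k}(θ), always over the full 10-item bank (the
estimate carries the information from whichever items were
administered). T is continuous and weakly increasing in every
coordinate.

**Correction and classification.** Adaptive tests stopped after ~5
items have empirical reliability around 0.65, so dividing by √ρ
inflates borderline estimates enough to move expected totals by one to
two points near the clinical cutoff, pushing nearly every borderline
patient past it (false-negative rate ~0, positive rate inflated by
several points). Expected totals therefore default to the *raw* EAP
estimate (`CATConfig.expected_total_on="raw"`); the corrected traits
are still computed and reported, and `"corrected"` switches the totals
over.

## Adaptive testing (real-data simulation)

The engine replays each patient's recorded full-length responses: items
are selected adaptively, "answers" are read from the record, and no
response is ever generated or altered. Selection:

* one factor — first item by maximum information at θ = 0; later items
  by maximum posterior-weighted information, MPWI_i = Σ_q w_q·I_i(θ_q)
  with w the current posterior on the grid;
* multifactor — maximum (optionally weighted) trace of I_i at the
  current EAP estimate (T-rule), including the start at θ = 0. Trace
  weights default to equal.

Ties break to the lowest item index; the simulation is fully
deterministic. Termination: stop once the maximum absolute change in
the trait estimate between successive items falls below δ (default
0.05), with at least `min_items` = 2 administered (a change needs two
estimates), or when `max_items`/the bank is exhausted. The max-abs norm
across dimensions is used for multifactor change; per-dimension
alternatives can be emulated through the config. The SI item takes part
in ordinary adaptive selection; `si_always_administered=True` forces it
before the test ends (off by default, matching a plain simulation in
which the adaptive rule may skip it).

The cohort engine is vectorised: posteriors for all patients are an
(N × Q) matrix and per-item probability/information tables are
precomputed at the nodes, so a 2,000-patient simulation runs in well
under a second. `run_cat_for_patient` is the N = 1 case of the same
code path.

## Classification and evaluation

Full-length classification follows routine clinical cutoffs: high risk
if total ≥ 13 or SI endorsed; moderate if 8 ≤ total ≤ 12; low
otherwise; moderate-or-high is a positive screen. The adaptive screen
is positive iff the expected total ≥ 8 or the *recorded* SI response is
nonzero — the override uses the recorded answer whether or not the
adaptive test administered that item. "Truth" for predictive values is
the full-length classification (the evaluation has no clinical
diagnosis; the full test is the implicit reference standard).

NPV = TN/(TN+FN), PPV = TP/(TP+FP), FNR = FN/(FN+TP), with Wilson 95%
intervals; zero-denominator metrics are reported as undefined rather
than NaN. Internal consistency is Cronbach's α with the Feldt
F-distribution interval. Agreement between predicted and observed
totals is Pearson r with the Fisher-z interval.

The fairness audit restricts to full-test positives, tabulates FN/TP
per demographic group, and runs a Pearson chi-square test of
homogeneity (no continuity correction) on the groups × {FN, TP} table;
groups with zero full-test positives are dropped with a warning and the
degrees of freedom shrink accordingly. Expected counts below 5 trigger
a warning suggesting an exact test. Parity ratios divide each group's
FNR by the named reference group's.

## Synthetic cohorts

The generator emulates a large routine postpartum screening program:
10 four-category items, demographic mix 54/12/12/10/7/4/1 percent
(White / AAPI / Other / Hispanic White / Black / Multiracial /
Unknown), age ~ N(34.26, 4.89²) truncated to [18, 54] (schema fidelity
only), and a positive-screen rate near 11–12%.

Latent severity is multivariate normal with unit variances; group trait
shifts default to zero (a fairness null — every group shares one
generating process). Factor correlations default to 0.85: subscales of
a short screen are strongly related, and this is what lets an item on
one factor stabilise the others' estimates during adaptive testing.
Responses invert the cumulative curves with a single uniform draw per
item. All randomness flows through one `numpy.random.default_rng`
(PCG64) generator, so a fixed seed reproduces a cohort byte-for-byte.

Item parameters for the emulated screen are not published, so bank
generation draws them from calibrated ranges chosen once: slopes
uniform on (1.8, 3.0); first thresholds b₁ uniform on (0.85, 1.45) with
ordered gaps uniform on (0.6, 1.0); the SI item's first threshold
uniform on (2.0, 2.3), reflecting how rarely suicidal ideation is
endorsed (~4%) relative to other symptoms. These ranges jointly
reproduce the screening profile the pipeline is meant to exercise:
positive rate ≈ 11.5% on average over bank draws, SI endorsement ≈ 4%,
median adaptive-test length ≈ 5 items (one factor) to 6 (three
factors), and r ≈ 0.97 between adaptive and full-length totals. Steep
slopes with moderately hard thresholds matter here: they place
low-severity respondents in the flat region of the response curves, so
their estimates stabilise after a few items, which is what makes the
adaptive test short.

What the generator does **not** emulate: item-level differential
functioning across groups (responses depend on group only through
optional trait shifts), missing responses, repeated screens, and any
real item-margin structure beyond the marginal positive rate. Passing
tests on these cohorts show the machinery is correct and calibrated
under the stated generating process; they do not show how a specific
real item bank would behave.

## Experiment sizes

The test suite and the acceptance script scale their experiments as:
kernel oracles on single items (instant); recovery at N = 5,000 with
three replicates; adaptive-test agreement at N = 2,000; fairness-null
calibration with 500 replicate cohorts of N = 3,000 (four equal groups,
so expected FN counts per group are ~10 and the chi-square asymptotics
apply — a 1% group would have expected FN below one and invalidate the
asymptotic test); the acceptance script's main study uses a
three-factor generating cohort of N = 4,000 with all three models
fitted. The recovery experiment draws its generating bank without the
SI threshold elevation: the SI item's top category is endorsed by only
a handful of patients per 5,000, so its intercept is not identifiable
at that sample size and would dominate the RMSE with noise.

## Known limitations

* Only logistic-link graded responses, simple structure, D ≤ 3;
  no nominal/partial-credit models or within-item multidimensionality.
* No item-parameter standard errors, and no limited-information fit
  statistics (M2/RMSEA/TLI/CFI); model comparison is AIC/BIC only.
* The Σ update is the standard second-moment rescale, not a constrained
  M-step maximiser; monotonicity of the marginal log-likelihood is
  exact only for fixed Σ.
* The fairness audit is FNR parity only (no equalised odds or
  calibration-within-groups), and the chi-square test needs adequate
  expected counts — small groups should be pooled or tested exactly.
* Live (interactive) administration, item-exposure control and content
  balancing are out of scope; the engine is a replay simulator.
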