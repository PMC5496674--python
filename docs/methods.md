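# Methods

## Model

We model a longitudinal outcome observed on `n` individuals at common,
zero-aligned times.  The population mixes two latent classes.  A *stable*
individual (label `r_i = 0`) follows the linear trend `α + β t`.  A
*change* individual (`r_i = 1`) follows the same trend up to a fixed,
known change-point `c` and thereafter declines with slope `β + δ`; the
post-change intercept is forced to `α − δc` so the two segments join
continuously (the broken-stick constraint).  Observation errors are
i.i.d. Gaussian with precision `τ = 1/σ²`, independent within and between
individuals.

The change-magnitude `δ` is restricted to the strictly negative reals: the
direction of the change (accelerated decline) is treated as known a
priori, which aids identifiability — without the restriction the stable
class and a change class with `δ = 0` are exchangeable.  A consequence
worth keeping in mind is that `P(δ < 0) = 1` by construction, so the
existence of a change is assessed through `P(δ < h)` for a small negative
threshold `h` rather than through a point null.

Class membership is Bernoulli with common probability `p_r`.  Because the
mixture makes the marginal likelihood awkward, the labels are kept in the
parameter space (data augmentation); conditional on `r` the likelihood
factorises into ordinary Gaussian terms.

Defaults are calibrated to cognitive decline on an MMSE-like 0–30 scale:
`(α, β, δ) = (25, −1, −2)`, `c = 5` years, five waves at years
(0, 2, 4, 6, 8), and error precisions `τ ∈ {0.05, 0.1, 0.2}`
(σ ≈ 4.47, 3.16, 2.24).  Outcomes are treated as continuous and are not
clipped to the scale; under σ² = 20 simulated values can leave [0, 30].

## Drop-out model

Attrition is monotone with a single drop-out time: every individual is
observed at all waves up to `t_d = 4`; with probability `p_d` they are
never observed again, otherwise they complete the schedule.  The drop-out
indicator is independent of the label and of the outcomes (MCAR), so the
missingness mechanism contributes only a constant to the likelihood and
can be ignored by inference; its entire effect is to thin the information
past the change-point.  Under the default design `t_d < c`, so dropped-out
individuals carry *no* information about their own label — their posterior
change probability is exactly `p_r` — and classification is only well
defined for individuals observed past `c`.

The design metric this package is organised around is the **expected
post-change-point sample size** `n(1 − p_d)`: the expected number of
individuals still observed at the final wave.  Different `(n, p_d)` pairs
with equal `n(1 − p_d)` behave comparably, which collapses a
two-dimensional design question to one axis.

Deliberately not modelled: per-wave hazards, outcome-dependent (MAR/MNAR)
drop-out, covariates in the class-membership probability, random effects,
and unknown or individual-specific change-point locations.

## Priors and sampler

Priors are vague and proper: `α, β ~ N(0, 10²)`, `δ ~ Half-N(0, 10²)` on
the negative reals, `τ ~ Gamma(1, 1)` (shape–rate), `r_i ~ Bern(p_r)`.

One sweep of the sampler performs four scalar Metropolis–Hastings updates
followed by an exact Gibbs draw of every label:

* `α`, `β`, `τ`: symmetric Gaussian random walks.  Proposals with
  `τ ≤ 0` are rejected through the prior's zero density (no reflection).
* `δ`: multiplicative update `δ′ = δ·X`, `log X ~ N(0, s²)`, which
  preserves the sign.  This proposal is asymmetric; the acceptance ratio
  includes the Hastings/Jacobian factor `q(δ|δ′)/q(δ′|δ) = |δ′|/|δ|`, so
  the chain targets the stated posterior exactly.  See the note below on
  what happens when this factor is omitted.
* labels: each `r_i` is drawn from its exact full conditional
  `P(r_i = 1 | ·) = p_r L_i1 / (p_r L_i1 + (1 − p_r) L_i0)`, computed on
  the log scale.  Gibbs is used rather than an MH move because the
  conditional is available in closed form and has the lowest variance.

Every proposal standard deviation is the product of a fixed base scale
(1.2 for `α`, 0.85 for `β` and `τ`, 1.0 for the log-scale `δ` step) and
the deterministic sample-size factor `f(n) = log 25 / log n`, which
shrinks proposals as the posterior tightens so that mixing is comparable
across the sample sizes of a design grid.  `f` is defined for `n ≥ 2` but
exceeds 1 below `n = 25`; such runs are permitted with a warning.  No
adaptive tuning is performed.

Acceptance rates under these scales are healthy for `α` and `δ`
(~0.1–0.4 across the default grid) but low for `β` (~0.02–0.12) and very
low for `τ` (~0.004–0.04): the `τ` posterior standard deviation
(~0.005–0.05 at these designs) is one to two orders of magnitude below
the fixed proposal scale.  The run lengths used make the effective sample
size adequate anyway; users porting these settings to other outcome
scales should revisit the `τ` base scale.

Chains run for 10⁵ iterations by default; the first 10³ are discarded and
every 50th retained thereafter, giving 1,980 retained draws.  Per-
individual posterior change probabilities are the means of the retained
label draws.

Initialisation: `α₀` is the mean first-wave outcome, `β₀` the pooled
least-squares slope of the pre-change-point observations, `δ₀ = −0.1`,
`τ₀ = 1`, and labels drawn Bernoulli(`p_r`).  The full initial state is
recorded in the chain metadata.  The sampler is a pure function of the
observation times, outcomes, settings and seed — the simulator's truth
columns are never read, and perturbing them changes nothing.

The hot loop is compiled with numba; `mh_update_scalar`,
`label_change_probabilities` and `update_labels` expose the identical
single-step mathematics in plain NumPy, and the test suite checks the two
paths agree and that the chain matches a brute-force grid integration of
the posterior on a two-individual fixture.

### The Jacobian correction and detection probability

`ChainSettings.delta_proposal_correction = False` switches the Hastings
factor off, reproducing the behaviour of implementations that treat the
multiplicative `δ` proposal as symmetric.  The uncorrected chain does not
target the posterior: its invariant measure acquires an extra `1/|δ|`
factor, which is flat in `log|δ|` and non-integrable at zero, so in
weak-likelihood scenarios the chain can wander arbitrarily close to
`δ = 0` and sit there for long stretches.  The symptoms are
characteristic: apparently bimodal `δ` samples (one lump near the truth,
one hugging zero), posterior-median absolute errors for `δ` near `|δ|`
itself, and detection probabilities `P(δ < −0.05)` far below what the
exact posterior gives.  Under the exact sampler, the posterior at the
default effect size concentrates well away from zero in every cell of the
default grid — detection probability is essentially 1 even at expected
post-change-point sample sizes of ~10–20 — which we verified against both
brute-force grid integration and an independent Gibbs implementation of
the same model.  For reference, the prior alone puts mass 0.996 below
−0.05, so detection values near 0.5 cannot arise from a posterior that is
actually being sampled correctly.  The option exists to make that failure
mode reproducible and visible, not for inference; everything else in the
package uses the corrected sampler.

## Summaries

Per fitted chain and parameter `ω ∈ {α, β, δ, τ}` we record the posterior
median, the posterior variance, and the length of the 95% highest-
posterior-density interval; per scenario cell (a `(τ, p_d, k)` triple) we
aggregate across replicates: the mean absolute error of the medians
against the generating value (which varies across cells only for `τ`),
the mean variance, and the mean HPD length (the average length criterion,
ALC).  `τ` summaries are additionally reported relative to the true `τ`
so cells with different noise levels are comparable.

The HPD estimator is the empirical shortest window: the narrowest
contiguous run of `⌈level·N⌉` sorted draws, ties broken toward the
smallest lower bound.  It is deterministic given the draws and needs no
density estimate.  When the posterior is multimodal a single shortest
interval overstates the concentrated mass; we still report it, and flag
that ALC values from visibly bimodal chains should be read with care.

Change-point detection is summarised by `P(δ < h)` — the fraction of
retained draws below `h` — at `h = −0.05` (existence of a change) and at
`h = −2` and `h = −3` (calibration around the default true magnitude).

Classification is summarised by ROC/AUROC of the posterior change
probabilities against the simulation truth.  AUROC is computed by the
rank (Mann–Whitney) statistic with half credit for ties, which equals the
trapezoidal area under the threshold-swept ROC curve; the test suite
cross-checks both an O(n²) pairwise count and scikit-learn.  Replicates
in which only one class is present (common at small `k`) record a missing
AUROC and reduce that cell's effective replicate count rather than
failing the run.  AUROC is reported over all individuals, over the
post-change-point subset, and over the dropped-out subset; the first is
diluted toward 0.5 by the label-free dropped-out individuals, the last
sits at 0.5 by construction, so the post-change-point AUROC is the
meaningful classification measure.  Its large-sample ceiling is set by
the noise: with post-change residual contrasts `u = (1, 3)` at the last
two waves, the limiting AUROC is `Φ(|δ|·√(τ·Σu²/2))` ≈ 0.84, 0.92, 0.98
at `τ = 0.05, 0.1, 0.2` — reproduced by the sampler in the tests.

A LOWESS wrapper (statsmodels, configurable span) is provided for
smoothing summary curves over the design axis; styling is left to the
user.

## Study runner

`StudyConfig` spans the default grid: 3 error-precisions × 5 drop-out
probabilities × 150 replicates × 9 sample sizes `k`, i.e. 20,250 fitted
chains.  Within one `(τ, p_d, replicate)` cell a single cohort of 500
individuals is simulated once and every `k` is fitted on its first-`k`
subset — nested subsets preserve the within-replicate correlation across
sample sizes.  Cell seeds derive deterministically from
`(master seed, grid indices, replicate)` via `SeedSequence`, so any
dataset or chain can be regenerated in isolation and results are
invariant to execution order and worker count (process-level parallelism
via joblib).  Per-cell results are checkpointed as JSON; interrupted runs
resume, per-cell failures are recorded in a manifest without aborting the
grid, and the summary table carries `expected_post_cp_n = k(1 − p_d)` as
the design axis.

The full default grid is a cluster-scale computation and is not run in
the test suite; the runner's correctness is exercised on reduced grids
(determinism under re-runs and worker counts, checkpoint resume, the
strictly ordered post-change-point AUROC across `τ`, and the design-axis
column), with the scenario-level quantities checked directly at their own
scales.

## Problem sizes used by the checks

The acceptance script uses 20 replicates per detection scenario
(`n = 100, p_d = 0.1` for the post-change-point-90 cells; `n = 250,
p_d = 0.2` for the 200 cell) and 10 replicates at `n = 500, p_d = 0.1`
for the limiting AUROC, with 30,000-iteration chains (1,000 burn-in,
thin 25).  At these sample sizes the summaries are insensitive to the
shortened chains; replicate-to-replicate variation dominates.  The
parameter-recovery check runs one full-length (10⁵) chain at `n = 500`.

## What the simulator does and does not emulate

The generator reproduces the stated study conditions exactly: fixed
common observation times, a single MCAR drop-out event, Bernoulli class
membership, Gaussian noise, and truth stored separately from the data so
fitting stays blind.  Real cohorts differ in ways the simulator
deliberately omits: irregular and individual-specific visit times,
outcome-dependent attrition, floor/ceiling effects and discreteness of
bounded scales, between-individual heterogeneity in intercepts, slopes
and change-point timing, and covariates.  Passing tests therefore
demonstrate correctness of the method under the idealised design, and the
design guidance (detection and classification versus
`expected post-change-point sample size`) should be read as a best case:
identifiability can only degrade under the omitted complications.

## Known limitations

* The change-point `c` and class probability `p_r` are treated as known;
  estimating them (or `p_d`) is out of scope.
* The sign restriction on `δ` means every fitted individual gets a
  non-trivial change probability even when the true `δ` is negligible;
  labels are only interpretable once a meaningful change-magnitude is
  established.
* The fixed `τ` proposal scale mixes slowly (see above); fine for the
  default designs, worth retuning elsewhere.
* The shortest-window HPD interval, and hence the ALC, is a blunt summary
  for bimodal posteriors.
* AUROC with very few post-change-point individuals is noisy, and
  undefined when a subset contains a single class; such replicates are
  recorded as missing rather than imputed.
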