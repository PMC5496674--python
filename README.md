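# cpdesign

Study-design evaluation for Bayesian broken-stick change-point models with
unlabelled sub-groups and incomplete follow-up.

## The problem

Longitudinal ageing studies of cognition (e.g. MMSE scores observed every
couple of years) often contain a mixture of individuals: most decline
steadily, but a sub-group switches to *accelerated* decline at some point —
a strong precursor of mortality and loss of quality of life.  When planning
such a study the designer must know: at what first-wave sample size, and
under how much attrition and measurement noise, can the existence of the
accelerated-decline sub-group be detected, and how accurately can
individuals be classified into it?

`cpdesign` answers this by simulation.  It implements

* a **two-class broken-stick model** — individual *i* with latent label
  *rᵢ* ∈ {0, 1} has mean outcome

  ```
  y_ij = α + β t_ij + ε_ij                     if r_i = 0, or r_i = 1 and t_ij ≤ c
  y_ij = (α − δc) + (β + δ) t_ij + ε_ij        if r_i = 1 and t_ij > c
  ```

  with a change-point *c* common to all changers, change-magnitude δ < 0,
  and i.i.d. Gaussian errors with precision τ = 1/σ²;

* a **monotone MCAR drop-out simulator**: individuals are observed on a
  fixed schedule, may drop out at a single time *t_d* with probability
  *p_d* independently of everything else, and never return;

* a **data-augmented Metropolis–Hastings-within-Gibbs sampler** for the
  posterior π(α, β, δ, τ, r | y) with priors α, β ∼ N(0, 10²),
  δ ∼ Half-N(0, 10²) on the negative reals, τ ∼ Gamma(1, 1),
  rᵢ ∼ Bernoulli(p_r), and proposal dispersions scaled by
  f(n) = log 25 / log n so mixing is comparable across sample sizes;

* the **design summaries**: mean absolute error of posterior medians,
  mean posterior variance, the 95% average length criterion (ALC, via the
  empirical shortest HPD interval), the change-point detection probability
  P(δ < h) (default h = −0.05), and the classification AUROC of the
  per-individual posterior change probabilities — over all individuals and
  over the subset observed past the change-point, the only ones for whom
  classification is well defined;

* a **scenario-grid runner** over error-precisions × drop-out
  probabilities × sample sizes × replicates, with deterministic per-cell
  seeds, checkpointing, and the *expected post-change-point sample size*
  n(1 − p_d) as the design axis.

## Worked example

```python
import cpdesign as cp

shape = cp.ShapeParams(alpha=25, beta=-1, delta=-2, change_point=5, tau=0.1)
scenario = cp.Scenario(n=200, shape=shape, p_r=0.5, p_d=0.3, seed=1)
data = cp.simulate_dataset(scenario)

settings = cp.ChainSettings(iterations=30_000, burn_in=1_000, thin=25, seed=2)
chain = cp.run_chain(data, settings, change_point=5.0, p_change=0.5)

for p in ("alpha", "beta", "delta", "tau"):
    print(f"{p:>6}: median {chain.posterior_median(p):7.3f}   "
          f"95% HPD length {cp.alc(chain.draws(p)):6.3f}")
print("P(delta < -0.05):", cp.prob_below(chain.draws_delta, -0.05))
idx = cp.post_cp_indices(data, 5.0)
print("AUROC (post-change-point):",
      round(cp.auroc(chain.label_prob[idx], data.true_labels[idx]), 3))
```

prints

```
 alpha: median  24.683   95% HPD length  0.772
  beta: median  -0.988   95% HPD length  0.220
 delta: median  -1.551   95% HPD length  0.809
   tau: median   0.093   95% HPD length  0.020
P(delta < -0.05): 1.0
AUROC (post-change-point): 0.905
```

The sampler — fitted blind to the truth columns — recovers the generating
trajectory (25, −1, −2) and noise precision 0.1 within posterior
uncertainty, puts all posterior change-magnitude mass below the detection
threshold, and classifies the individuals observed past the change-point
with AUROC ≈ 0.9, the noise-limited ceiling at this error-precision.

The same steps are available from a shell:

```
cpdesign simulate --n 200 --tau 0.1 --pd 0.3 --seed 1 --out toy
cpdesign fit --data toy_data.csv --change-point 5 --out toy_chain
cpdesign study --config study.yaml --out runs/grid
```

`cpdesign fit` refuses input files containing truth columns, keeping
inference blinded.

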