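# Methods

`cognoise` models two classic signatures of cognitive noise — 1/f-scaled
fluctuations and heavy-tailed trial-by-trial changes — as by-products of a
mind that approximates Bayesian inference by Markov chain Monte Carlo
sampling over a hypothesis space. This note records the models, the
estimators, the synthetic-data conditions, and the numerical choices.

## Sampling models of behavior

A hypothesis space carries a target distribution P(H):

* **Time estimation.** H is a candidate duration; P(H) is Gaussian with
  mean near the target interval (1/3, 1 or 3 s) and a free SD. Each
  MCMC sample is read out directly as one produced duration; draws at or
  below 0.01 s are clipped to that floor (the floor exists only to keep
  durations positive; fitted parameter ranges make it rare).
* **Free naming.** H is a position in a 2-D semantic plane holding named
  items grouped into categories; P(H) is a Gaussian mixture fitted to
  the item coordinates by EM. Samples arrive at exponentially
  distributed intervals (a Poisson clock with rate `rate`, default
  1/s); the item "in mind" is the nearest name to the sampler's
  position, and a response is emitted whenever that nearest name
  changes. The inter-response interval (IRI) is the elapsed clock time,
  so it is on average proportional to the number of samples between
  name changes. An alternative readout divides the Euclidean path
  length travelled between name changes by a speed parameter.

Three samplers generate the hypothesis sequence:

* **RWM** — isotropic Gaussian proposals of scale `rwm_scale`,
  Metropolis acceptance.
* **HMC** — leapfrog integration (`hmc_step`, `hmc_leaps` steps,
  identity mass, no adaptation), Metropolis correction on the
  Hamiltonian error.
* **MC³** (Metropolis-coupled MCMC / parallel tempering) — M chains
  (default 4) at temperatures T_m = r^(m-1) (geometric ladder, default
  r = 3), each taking RWM steps on P(H)^(1/T_m); after every sweep
  (configurable `swap_every`) one uniformly chosen adjacent pair
  proposes a state exchange accepted with probability
  min(1, exp[(log p(h_j) − log p(h_i)) (1/T_i − 1/T_j)]). Only the
  cold (T=1) chain is read out as behavior.

Behavior generation applies **no burn-in**: sessions begin wherever the
sampler begins, because human sessions include their transients, and the
low-frequency structure of short sessions partly *is* that transient.
Distributional tests of the samplers themselves discard 10³ iterations.

## Exponent estimation

* **Spectral exponent α.** Welch-averaged periodogram — mean-detrended
  rectangular windows of length min(512, n/2) with 50% overlap — then
  12 logarithmically spaced frequency bins on (f_min, 0.1)
  cycles/sample. Within each nonempty bin the mean log10 frequency and
  mean log10 power form one point; α is minus the OLS slope. Binning
  averages of points lying exactly on a log-log line preserve the line,
  so an exact S(f) = f^−α spectrum is recovered to machine precision.
  The fit uses only f < 0.1, strictly. α ∈ [0.5, 1.5] is classified as
  1/f scaling.
* **Tail exponent μ.** Continuous power-law maximum likelihood
  μ̂ = 1 + n / Σ ln(x_i/xmin), with xmin selected to minimize the
  Kolmogorov–Smirnov distance between the empirical tail and the fitted
  law. Candidate cutoffs are the unique data values leaving ≥ 10 tail
  points, thinned to at most 200 by quantiles. μ ∈ (1, 3] is classified
  as heavy-tailed (boundary conventions follow the printed intervals
  literally). A Vuong-style normalized log-likelihood ratio compares
  the fitted power-law tail against a shifted-exponential tail on the
  same points; positive values favor the power law, with a two-sided
  normal p-value.
* **Conventions per task.** Time estimation drops estimates ≥ 3× the
  target (resting periods), fits α to the estimate sequence and μ to
  absolute successive changes. Naming fits α to the IRI sequence
  indexed by response number and μ to the raw IRIs (matching how the
  two tasks' histograms are conventionally displayed); a config switch
  exposes the other convention.

## Synthetic data and ground truth

* `gen_fgn(n, α, seed)` builds a unit-variance series with power
  spectrum exactly ∝ f^−α by spectral synthesis (deterministic
  amplitudes, uniform random phases). This fixes the quantity under
  test — the spectral slope — by construction; it is only approximately
  a stationary fractional Gaussian noise in distribution, which is the
  reason spectral synthesis was chosen over Davies–Harte. `gen_fbm`
  integrates it.
* `gen_pareto(n, μ, xmin, seed)` uses the inverse CDF
  x = xmin·u^(−1/(μ−1)).
* `gen_levy_flight` draws Pareto step lengths with uniform headings —
  heavy tails with a flat spectrum, the classic contrast case; its
  converse is `gen_fbm`, whose successive changes are Gaussian.
* `gen_semantic_space(n_names, n_categories, within, between, seed)`
  scatters category centers with SD `between` and names around them
  with SD `within`. Defaults emulate the experiments' scales: naming
  sessions of up to 1024 responses with mean IRI ≈ 5 s; timing
  sessions of 512+ estimates.

## The co-occurrence study regime

The package's stock demonstration that one sampler produces both
signatures at once uses MC³:

* **Timing**: target 1 s with SD 0.15 s, proposal scale 0.2×SD, ladder
  ratio 8, M = 4, swaps every sweep. The cold chain's local walk gives
  the low-frequency spectral rise; occasional swaps with explorer
  chains inject the large jumps that make |Δestimate| heavy-tailed.
* **Naming** (`synthetic.naming_study`): the 64-name/8-category space
  (seed 0), a mixture fitted with K = 13 components (overclustered
  relative to the 8 categories; the component count is a free
  configuration choice), proposal scale 0.03, ladder ratio 2.1, M = 4,
  rate 2/s, sampler started at the sharpest mixture mode. Overclustering
  gives the target a few narrow high-peak components among broad ones;
  the cold chain alternates between dwelling near sharp components and
  roaming diffuse ones, and tempering swaps move it between regimes at
  many timescales. The IRI series then shows both 1/f scaling and a
  heavy tail in ~90% of seeded sessions, with mean IRI ≈ 5–6 s —
  close to the behavioral scale it emulates. In flat, homogeneous
  mixtures the count readout is nearly white, so the heterogeneity of
  component sharpness is load-bearing, not incidental.

What passing these synthetic checks does **not** show: that human
semantic spaces have this geometry, that observed exponents arise from
tempered sampling, or that the estimators are unbiased on nonstationary
human sessions. The generators emulate scale and structure, not content.

## ABC model comparison

Autocorrelated series make exact likelihoods impractical, so models are
scored likelihood-free. For one participant with observed summary
(α̂, μ̂): draw parameters from the prior, simulate a full session of the
observed length, summarize it the same way, and accept draws whose
standardized Euclidean distance to the observed summary is within ε.

* **Priors** (all seeded): proposal scales and HMC step log-uniform on
  [10⁻³, 1] in units of the target SD (timing) or the coordinate SD of
  the space (naming); HMC leaps uniform on {1..50}; MC³ temperature
  ratio log-uniform on [1.5, 10] with M = 4; timing target mean uniform
  on [0.5, 2]× the nominal target and SD log-uniform on [0.01, 1]×;
  Poisson rate log-uniform on [0.1, 10]/s.
* **Distance and tolerance**: each summary coordinate is standardized
  by the pooled SD across all models' simulations for that participant;
  ε is the 5th percentile of the pooled distances, shared across models
  so acceptance fractions are directly comparable. log marginal
  likelihood = log(accepted / valid); simulations too degenerate to
  summarize (e.g., too few responses within the iteration budget — 6–8
  iterations per requested response) are excluded from numerator and
  denominator and their fraction is visible via `n_valid`. Zero
  acceptances floor the estimate at log 1/(n_sims+1) with a flag.
* **Group level**: column sums of the participants × models log-ML
  matrix; per-participant best-fit counts with ties split equally; and
  protected exceedance probabilities from variational random-effects
  model selection (Dirichlet prior α₀ = 1, ψ-function updates),
  exceedance probabilities by 10⁵ seeded Dirichlet draws, protection by
  the Bayes omnibus risk BOR = 1/(1+exp(F1−F0)):
  pxp = (1−BOR)·EP + BOR/K.
* **Posterior predictives**: modal (α, μ) of the accepted draws by a
  30-bin histogram (ties to the lower bin), classified like data and
  cross-tabulated against the observed classification.
* Naming-task batches run on compiled (numba) per-replicate kernels;
  their RNG stream is seeded and reproducible but distinct from the
  numpy Generator stream used elsewhere.

## Problem sizes

The shipped tests and the acceptance script validate estimator recovery
at n = 1024 (α) and n = 5000 (μ) over 10–20 seeds; mode-mixing over 10⁵
sweeps; co-occurrence over 12–20 sessions of 512–1024 responses; and
ABC recovery with 6–10 synthetic participants at 256 responses and
800–2000 simulations per model — sizes chosen to keep the full
validation run in minutes while leaving each check's Monte Carlo error
well inside its tolerance.

## Known limitations

* The semantic space is synthetic; real embeddings are out of scope, so
  absolute comparisons with published per-participant exponents are not
  meaningful.
* ABC summaries are two numbers; models that differ only in features
  invisible to (α̂, μ̂) are not distinguishable.
* The power-law/exponential comparison uses the normal approximation to
  the Vuong statistic, which is anti-conservative for very small tails
  (hence the 10-point minimum).
* `gen_fgn` matches the target spectrum exactly but is only
  asymptotically equivalent to fractional Gaussian noise.
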