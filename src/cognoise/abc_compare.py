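"""Likelihood-free comparison of the three sampling algorithms.

Autocorrelated behavioral series make exact likelihoods intractable, but
simulating a sampler is cheap, so models are scored by Approximate
Bayesian Computation: draw parameters from a prior, simulate a full
behavioral series, summarize it by the exponent pair (α̂, μ̂), and accept
the draw when its summary lands within a tolerance ε of the observed
summary (standardized Euclidean distance). The accepted fraction among
valid simulations estimates the marginal likelihood.

Group level, per-participant log marginal likelihoods feed a
random-effects Bayesian model selection: a variational Dirichlet
posterior over model frequencies yields exceedance probabilities, and the
Bayes omnibus risk (the posterior probability that all models are equally
frequent) "protects" them: pxp_k = (1 - BOR) * EP_k + BOR / K.

Finally, the accepted simulations give posterior-predictive modal (α, μ)
per participant, classified the same way as the data and cross-tabulated
against the observed classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp, psi

from . import readout, samplers, synthetic, targets
from .noise_stats import (
    AnalysisConfig,
    NoiseClassification,
    classify_noise,
    fit_spectral_exponent,
    fit_tail_exponent,
    power_spectrum,
    successive_changes,
)

__all__ = [
    "SummaryPair",
    "ABCResult",
    "GroupComparison",
    "default_priors",
    "sample_prior",
    "simulate_summary",
    "abc_fit",
    "abc_compare_participant",
    "group_compare",
    "protected_exceedance_probability",
    "posterior_predictive_classification",
    "posterior_mode",
]

MODELS = ("rwm", "hmc", "mc3")


@dataclass
class SummaryPair:
    """The two summary statistics ABC compares directly."""

    alpha_hat: float
    mu_hat: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha_hat) and np.isfinite(self.mu_hat)):
            raise ValueError("summary statistics must be finite")


@dataclass
class ABCResult:
    """Accepted simulations and derived scores for one participant-model."""

    model: str
    n_sims: int
    n_valid: int
    epsilon: float
    accepted: dict[str, np.ndarray]  # params + alpha/mu/distance at accepted draws
    log_ml: float
    pp_modal_alpha: float
    pp_modal_mu: float
    zero_accepted: bool = False
    # full (valid) simulation pool, kept so tolerances can be re-examined
    sim_alpha: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    sim_mu: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    sim_distance: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def n_accepted(self) -> int:
        return int(self.accepted["alpha"].size)


@dataclass
class GroupComparison:
    models: tuple[str, ...]
    group_log_ml: np.ndarray
    best_fit_counts: np.ndarray
    pxp: np.ndarray


# ---------------------------------------------------------------------------
# priors

# (family, low, high); scales are relative to the target's own SD (timing)
# or to the coordinate SD of the semantic space (naming)
_SAMPLER_PRIORS = {
    "rwm": {"rwm_scale": ("loguniform", 1e-3, 1.0)},
    "hmc": {
        "hmc_step": ("loguniform", 1e-3, 1.0),
        "hmc_leaps": ("randint", 1, 50),
    },
    "mc3": {
        "rwm_scale": ("loguniform", 1e-3, 1.0),
        "temp_ratio": ("loguniform", 1.5, 10.0),
    },
}


def default_priors(task: str) -> dict[str, dict[str, tuple]]:
    """Weakly informative priors spanning qualitatively distinct sampler
    regimes, per model. Timing adds target mean/sd (relative to the
    nominal target); naming adds the Poisson sample rate."""
    priors: dict[str, dict[str, tuple]] = {}
    for model in MODELS:
        p = dict(_SAMPLER_PRIORS[model])
        if task == "timing":
            p["target_mean_rel"] = ("uniform", 0.5, 2.0)
            p["target_sd_rel"] = ("loguniform", 0.01, 1.0)
        elif task == "naming":
            p["rate"] = ("loguniform", 0.1, 10.0)
        else:
            raise ValueError(f"unknown task {task!r}")
        priors[model] = p
    return priors


def sample_prior(prior: dict[str, tuple], n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw ``n`` parameter vectors; seed-reproducible via ``rng``."""
    draws: dict[str, np.ndarray] = {}
    for name, (family, lo, hi) in prior.items():
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"prior bounds for {name} must be finite")
        if family == "uniform":
            draws[name] = rng.uniform(lo, hi, size=n)
        elif family == "loguniform":
            draws[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        elif family == "randint":
            draws[name] = rng.integers(lo, hi + 1, size=n)
        else:
            raise ValueError(f"unknown prior family {family!r}")
    return draws


# ---------------------------------------------------------------------------
# batched simulation

class _BatchGaussian:
    """Gaussian target with per-replicate mean and sd (timing ABC)."""

    dim = 1

    def __init__(self, mean: np.ndarray, sd: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)

    def _params_for(self, shape):
        m, s = self.mean, self.sd
        while m.ndim < len(shape):
            m, s = m[..., None], s[..., None]
        return m, s

    def log_density(self, point):
        x = np.asarray(point)[..., 0]
        m, s = self._params_for(x.shape)
        z = (x - m) / s
        return -0.5 * z * z - np.log(s) - 0.5 * np.log(2 * np.pi)

    def grad_log_density(self, point):
        x = np.asarray(point)
        m, s = self._params_for(x[..., 0].shape)
        return -(x - m[..., None]) / s[..., None] ** 2


def _run_model_batch(model, draws, task, n_iter, rng, nominal_target, space, mixture):
    """Cold-chain traces (B, n_iter, d) for a batch of prior draws.

    Timing runs on the vectorized numpy kernels (1-D Gaussian targets are
    cheap); naming runs on the compiled per-replicate kernels, since the
    mixture-target leapfrog volume dominates the fitting cost.
    """
    b = next(iter(draws.values())).size
    if task == "timing":
        mean = draws["target_mean_rel"] * nominal_target
        sd = draws["target_sd_rel"] * nominal_target
        target = _BatchGaussian(mean, sd)
        unit = sd
        init = mean[:, None]
        kw: dict = {}
        if model == "rwm":
            kw["rwm_scale"] = draws["rwm_scale"] * unit
        elif model == "hmc":
            kw["hmc_step"] = draws["hmc_step"] * unit
            kw["hmc_leaps"] = draws["hmc_leaps"].astype(int)
        elif model == "mc3":
            kw["rwm_scale"] = draws["rwm_scale"] * unit
            kw["mc3_temps"] = draws["temp_ratio"][:, None] ** np.arange(4)[None, :]
        else:
            raise ValueError(f"unknown model {model!r}")
        return samplers.run_batch(target, model, n_iter, init, rng, **kw)

    from . import _fast

    unit = float(space.coords.std())
    init = np.repeat(
        synthetic.sharpest_mode(mixture)[None, :], b, axis=0
    )
    means, prec, logc = _fast.mixture_tables(mixture)
    seed = int(rng.integers(2**31))
    if model == "rwm":
        return _fast.rwm_gmm_batch(init, draws["rwm_scale"] * unit, n_iter, means, prec, logc, seed)
    if model == "hmc":
        return _fast.hmc_gmm_batch(
            init, draws["hmc_step"] * unit, draws["hmc_leaps"].astype(np.int64),
            n_iter, means, prec, logc, seed,
        )
    if model == "mc3":
        temps = np.ascontiguousarray(draws["temp_ratio"][:, None] ** np.arange(4)[None, :])
        return _fast.mc3_gmm_batch(
            init, draws["rwm_scale"] * unit, temps, 1, n_iter, means, prec, logc, seed
        )
    raise ValueError(f"unknown model {model!r}")


def _summaries_timing(traces, nominal_target, cfg):
    alphas = np.full(traces.shape[0], np.nan)
    mus = np.full(traces.shape[0], np.nan)
    for i, tr in enumerate(traces):
        est = np.maximum(tr[:, 0], readout.ESTIMATE_FLOOR)
        est = est[est < 3.0 * nominal_target]
        alphas[i], mus[i] = _exponents(est, est_changes=True, cfg=cfg)
    return alphas, mus


def _summaries_naming(traces, draws, space, length, cfg, rng):
    b = traces.shape[0]
    alphas = np.full(b, np.nan)
    mus = np.full(b, np.nan)
    rates = draws["rate"]
    # nearest-name indices in moderate chunks to bound memory
    for start in range(0, b, 64):
        stop = min(start + 64, b)
        idx = targets.nearest_index(space, traces[start:stop])
        for j in range(start, stop):
            row = idx[j - start]
            changes = np.flatnonzero(np.diff(row) != 0) + 1
            if changes.size < length:
                continue  # too few responses within the iteration budget
            waits = rng.exponential(1.0 / rates[j], size=row.size)
            arrival = np.cumsum(waits)
            times = arrival[changes]
            iris = np.diff(np.concatenate(([arrival[0]], times)))[:length]
            alphas[j], mus[j] = _exponents(
                iris, est_changes=cfg.naming_mu_on_changes, cfg=cfg
            )
    return alphas, mus


def _exponents(values, est_changes, cfg):
    """(α̂, μ̂) for one series; NaNs when the series is degenerate."""
    try:
        spectrum = power_spectrum(values, cfg.window_len, cfg.overlap)
        alpha = fit_spectral_exponent(spectrum, cfg.f_max, cfg.n_bins).alpha
        tail_data = successive_changes(values) if est_changes else values
        tail_data = tail_data[tail_data > 0]
        mu = fit_tail_exponent(tail_data, max_candidates=cfg.max_xmin_candidates).mu
    except (ValueError, FloatingPointError):
        return np.nan, np.nan
    if not (np.isfinite(alpha) and np.isfinite(mu)):
        return np.nan, np.nan
    return alpha, mu


def _simulate_batch(
    model: str,
    draws: dict[str, np.ndarray],
    task: str,
    length: int,
    rng: np.random.Generator,
    *,
    nominal_target: float | None = None,
    space: targets.SemanticSpace | None = None,
    mixture: targets.MixtureTarget | None = None,
    cfg: AnalysisConfig | None = None,
    naming_iter_factor: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Summary pair (α̂, μ̂) per prior draw; NaN marks invalid simulations."""
    cfg = cfg or AnalysisConfig()
    if task == "timing":
        if nominal_target is None:
            raise ValueError("timing simulation needs the nominal target")
        traces = _run_model_batch(model, draws, task, length, rng, nominal_target, None, None)
        return _summaries_timing(traces, nominal_target, cfg)
    if task == "naming":
        if space is None:
            space = synthetic.default_space(seed=0)
        if mixture is None:
            mixture = synthetic.default_mixture(space, seed=0)
        n_iter = naming_iter_factor * length
        traces = _run_model_batch(model, draws, task, n_iter, rng, None, space, mixture)
        return _summaries_naming(traces, draws, space, length, cfg, rng)
    raise ValueError(f"unknown task {task!r}")


def simulate_summary(
    model: str,
    params: dict[str, float],
    task: str,
    length: int,
    seed: int,
    **kwargs,
) -> SummaryPair | None:
    """End-to-end pipeline for one parameter vector: sampler + readout +
    exponent estimation. Returns None when the simulated behavior is too
    degenerate to summarize (e.g., too few IRIs). Deterministic in seed."""
    draws = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in params.items()}
    rng = np.random.default_rng(seed)
    a, m = _simulate_batch(model, draws, task, length, rng, **kwargs)
    if not (np.isfinite(a[0]) and np.isfinite(m[0])):
        return None
    return SummaryPair(float(a[0]), float(m[0]))


# ---------------------------------------------------------------------------
# ABC scoring


def _result_from_pool(
    model, draws, alphas, mus, observed, scale, epsilon, n_sims, *, allow_empty=False
) -> ABCResult:
    valid = np.isfinite(alphas) & np.isfinite(mus)
    if valid.sum() == 0:
        if not allow_empty:
            raise ValueError(f"model {model}: no valid simulations")
        # group comparison: a model whose prior cannot even produce a
        # summarizable series scores the zero-acceptance floor
        return ABCResult(
            model=model, n_sims=n_sims, n_valid=0, epsilon=float(epsilon),
            accepted={k: v[:0] for k, v in draws.items()}
            | {"alpha": np.empty(0), "mu": np.empty(0), "distance": np.empty(0)},
            log_ml=float(np.log(1.0 / (n_sims + 1.0))),
            pp_modal_alpha=np.nan, pp_modal_mu=np.nan, zero_accepted=True,
        )
    a, m = alphas[valid], mus[valid]
    dist = np.hypot(
        (a - observed.alpha_hat) / scale[0], (m - observed.mu_hat) / scale[1]
    )
    keep = dist <= epsilon
    n_acc = int(keep.sum())
    zero = n_acc == 0
    log_ml = (
        np.log(1.0 / (n_sims + 1.0)) if zero else float(np.log(n_acc / valid.sum()))
    )
    accepted = {k: v[valid][keep] for k, v in draws.items()}
    accepted["alpha"] = a[keep]
    accepted["mu"] = m[keep]
    accepted["distance"] = dist[keep]
    return ABCResult(
        model=model,
        n_sims=n_sims,
        n_valid=int(valid.sum()),
        epsilon=float(epsilon),
        accepted=accepted,
        log_ml=log_ml,
        pp_modal_alpha=posterior_mode(a[keep]) if n_acc else np.nan,
        pp_modal_mu=posterior_mode(m[keep]) if n_acc else np.nan,
        zero_accepted=zero,
        sim_alpha=a,
        sim_mu=m,
        sim_distance=dist,
    )


def log_ml_at(result: ABCResult, epsilon: float) -> float:
    """Re-score a stored simulation pool at a different tolerance."""
    n_acc = int((result.sim_distance <= epsilon).sum())
    if n_acc == 0:
        return float(np.log(1.0 / (result.n_sims + 1.0)))
    return float(np.log(n_acc / result.n_valid))


def abc_fit(
    observed: SummaryPair,
    model: str,
    prior: dict[str, tuple],
    n_sims: int,
    seed: int,
    *,
    task: str = "naming",
    length: int = 256,
    epsilon: float | None = None,
    epsilon_quantile: float = 0.05,
    scale: tuple[float, float] | None = None,
    **sim_kwargs,
) -> ABCResult:
    """Rejection ABC for a single model.

    When ``epsilon``/``scale`` are not given (standalone use) the
    tolerance is the ``epsilon_quantile`` of this model's own simulated
    distances and the standardization uses this model's simulation SDs;
    :func:`abc_compare_participant` instead pools both across models so
    acceptance fractions are comparable.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    rng = np.random.default_rng(seed)
    draws = sample_prior(prior, n_sims, rng)
    alphas, mus = _simulate_batch(model, draws, task, length, rng, **sim_kwargs)
    valid = np.isfinite(alphas) & np.isfinite(mus)
    if valid.sum() == 0:
        raise ValueError("no valid simulations")
    if scale is None:
        scale = _robust_scale(alphas[valid], mus[valid])
    if epsilon is None:
        dist = np.hypot(
            (alphas[valid] - observed.alpha_hat) / scale[0],
            (mus[valid] - observed.mu_hat) / scale[1],
        )
        epsilon = float(np.quantile(dist, epsilon_quantile))
    return _result_from_pool(model, draws, alphas, mus, observed, scale, epsilon, n_sims)


def _robust_scale(a: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    sa, sm = float(a.std()), float(m.std())
    return (sa if sa > 0 else 1.0, sm if sm > 0 else 1.0)


def abc_compare_participant(
    observed: SummaryPair,
    n_sims: int,
    seed: int,
    *,
    task: str = "naming",
    length: int = 256,
    priors: dict[str, dict[str, tuple]] | None = None,
    epsilon_quantile: float = 0.05,
    models: tuple[str, ...] = MODELS,
    **sim_kwargs,
) -> dict[str, ABCResult]:
    """ABC for all models on one participant, with the distance
    standardization and the tolerance ε (the ``epsilon_quantile`` of
    distances) shared across models, so accepted fractions — and hence
    log marginal likelihoods — are directly comparable."""
    priors = priors or default_priors(task)
    seeds = np.random.SeedSequence(seed).spawn(len(models))
    pools = {}
    for model, ss in zip(models, seeds):
        rng = np.random.default_rng(ss)
        draws = sample_prior(priors[model], n_sims, rng)
        alphas, mus = _simulate_batch(model, draws, task, length, rng, **sim_kwargs)
        pools[model] = (draws, alphas, mus)
    all_a = np.concatenate([p[1] for p in pools.values()])
    all_m = np.concatenate([p[2] for p in pools.values()])
    valid = np.isfinite(all_a) & np.isfinite(all_m)
    if valid.sum() == 0:
        raise ValueError("no valid simulations under any model")
    scale = _robust_scale(all_a[valid], all_m[valid])
    pooled_dist = np.hypot(
        (all_a[valid] - observed.alpha_hat) / scale[0],
        (all_m[valid] - observed.mu_hat) / scale[1],
    )
    epsilon = float(np.quantile(pooled_dist, epsilon_quantile))
    return {
        model: _result_from_pool(
            model, draws, alphas, mus, observed, scale, epsilon, n_sims,
            allow_empty=True,
        )
        for model, (draws, alphas, mus) in pools.items()
    }


# ---------------------------------------------------------------------------
# group level


def group_compare(
    log_ml: np.ndarray,
    models: tuple[str, ...] = MODELS,
    *,
    seed: int = 0,
    n_draws: int = 100_000,
) -> GroupComparison:
    """Group scores from a participants x models log-marginal-likelihood
    matrix: column sums, per-participant best-fit tallies (ties split
    equally), and protected exceedance probabilities."""
    lml = np.asarray(log_ml, dtype=float)
    if lml.ndim != 2 or lml.size == 0:
        raise ValueError("log_ml must be a nonempty (participants, models) matrix")
    if lml.shape[1] != len(models):
        raise ValueError("one column per model required")
    if not np.all(np.isfinite(lml)):
        raise ValueError("log_ml entries must be finite")
    counts = np.zeros(lml.shape[1])
    row_max = lml.max(axis=1, keepdims=True)
    is_max = lml == row_max
    counts = (is_max / is_max.sum(axis=1, keepdims=True)).sum(axis=0)
    pxp = protected_exceedance_probability(lml, seed=seed, n_draws=n_draws)
    return GroupComparison(
        models=tuple(models),
        group_log_ml=lml.sum(axis=0),
        best_fit_counts=counts,
        pxp=pxp,
    )


def _dirichlet_bms(lml: np.ndarray, alpha0: float = 1.0, max_iter: int = 500, tol: float = 1e-8):
    """Variational random-effects model selection over model frequencies.

    Returns the Dirichlet posterior parameters, per-participant model
    responsibilities, and the free energies of the frequency model (F1)
    and the null model of equal frequencies (F0), whose comparison gives
    the Bayes omnibus risk.
    """
    n, k = lml.shape
    a0 = np.full(k, alpha0)
    alpha = a0.copy()
    g = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        e_log_r = psi(alpha) - psi(alpha.sum())
        log_u = lml + e_log_r
        g_new = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = a0 + g_new.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < tol:
            alpha, g = alpha_new, g_new
            break
        alpha, g = alpha_new, g_new
    e_log_r = psi(alpha) - psi(alpha.sum())
    # F1: expected log joint minus entropies (standard VB free energy)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_g = -np.where(g > 0, g * np.log(g), 0.0).sum()
    kl_dir = (
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        - gammaln(a0.sum())
        + gammaln(a0).sum()
        + ((alpha - a0) * e_log_r).sum()
    )
    f1 = float((g * lml).sum() + (g * e_log_r).sum() + ent_g - kl_dir)
    # F0: all models equally frequent (fixed r = 1/K)
    f0 = float(logsumexp(lml - np.log(k), axis=1).sum())
    return alpha, g, f1, f0


def _exceedance(alpha: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    draws = rng.dirichlet(alpha, size=n_draws)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=alpha.size) / n_draws


def _protect(ep: np.ndarray, bor: float) -> np.ndarray:
    """pxp = (1 - BOR) * EP + BOR / K."""
    return (1.0 - bor) * ep + bor / ep.size


def protected_exceedance_probability(
    log_ml: np.ndarray,
    *,
    seed: int = 0,
    n_draws: int = 100_000,
    alpha0: float = 1.0,
) -> np.ndarray:
    """Probability each model is the most frequent in the population,
    protected by the Bayes omnibus risk BOR = 1/(1 + exp(F1 - F0))."""
    lml = np.asarray(log_ml, dtype=float)
    if lml.ndim != 2 or lml.shape[1] < 2 or lml.shape[0] < 1:
        raise ValueError("need a (participants >= 1, models >= 2) matrix")
    if not np.all(np.isfinite(lml)):
        raise ValueError("log_ml entries must be finite")
    # stabilize: per-row shifts cancel in both the VB responsibilities and F1-F0
    lml = lml - lml.max(axis=1, keepdims=True)
    alpha, _, f1, f0 = _dirichlet_bms(lml, alpha0)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    rng = np.random.default_rng(seed)
    ep = _exceedance(alpha, n_draws, rng)
    return _protect(ep, bor)


def posterior_mode(values: np.ndarray, bins: int = 30) -> float:
    """Histogram mode over the accepted range; ties take the lower bin."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    if v.max() == v.min():
        return float(v[0])
    hist, edges = np.histogram(v, bins=bins)
    b = int(np.argmax(hist))  # argmax takes the first (lower) max bin
    return float(0.5 * (edges[b] + edges[b + 1]))


def posterior_predictive_classification(
    results: list[ABCResult],
    observed: list[NoiseClassification],
) -> dict:
    """Cross-tabulate posterior-predictive modal classifications against
    the observed ones: a 2x2 table per flag, rows = predictive yes/no,
    columns = observed yes/no. Participants with no accepted simulations
    are excluded and counted."""
    if len(results) != len(observed):
        raise ValueError("one result per observed classification required")
    tables = {
        "one_over_f": np.zeros((2, 2), dtype=int),
        "heavy_tail": np.zeros((2, 2), dtype=int),
    }
    excluded = 0
    for res, obs in zip(results, observed):
        if res.n_accepted == 0 or not (
            np.isfinite(res.pp_modal_alpha) and np.isfinite(res.pp_modal_mu)
        ):
            excluded += 1
            continue
        pred = classify_noise(res.pp_modal_alpha, res.pp_modal_mu)
        for key, p_flag, o_flag in (
            ("one_over_f", pred.is_one_over_f, obs.is_one_over_f),
            ("heavy_tail", pred.is_heavy_tailed, obs.is_heavy_tailed),
        ):
            tables[key][0 if p_flag else 1, 0 if o_flag else 1] += 1
    tables["excluded"] = excluded
    return tables
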