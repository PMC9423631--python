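"""Synthetic series with known exponents, and full synthetic participants.

These generators play two roles: they validate the estimators (a series
built with spectral slope α or tail exponent μ should give those numbers
back), and they emulate the two behavioral experiments at their actual
scales — time-estimation sessions of 512+ productions around targets of
1/3, 1 or 3 seconds, and naming sessions of up to 1024 responses over a
patchy 2-D semantic space with a mean IRI of about 5 seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import readout, samplers, targets

__all__ = [
    "GeneratorSpec",
    "gen_fgn",
    "gen_fbm",
    "gen_pareto",
    "gen_levy_flight",
    "gen_semantic_space",
    "gen_participant",
    "default_space",
    "default_mixture",
]

# experiment-scale defaults
N_TIMING = 512
N_NAMING = 1024
TIMING_TARGETS = (1.0 / 3.0, 1.0, 3.0)


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic series: which generator,
    its parameters, the length, and the seed. Round-trips through JSON so
    a generated dataset is reproducible from its sidecar spec."""

    kind: str  # fgn | fbm | pareto | levy_flight | participant
    n: int = 1024
    seed: int = 0
    params: dict = field(default_factory=dict)

    _KINDS = ("fgn", "fbm", "pareto", "levy_flight", "participant")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.n < 16:
            raise ValueError("n must be >= 16")

    def generate(self):
        p = self.params
        if self.kind == "fgn":
            return gen_fgn(self.n, p.get("alpha", 1.0), self.seed)
        if self.kind == "fbm":
            return gen_fbm(self.n, p.get("alpha", 1.0), self.seed)
        if self.kind == "pareto":
            return gen_pareto(self.n, p.get("mu", 2.0), p.get("xmin", 1.0), self.seed)
        if self.kind == "levy_flight":
            return gen_levy_flight(self.n, p.get("mu", 2.0), self.seed)[0]
        params = {k: v for k, v in p.items() if k not in ("model", "task")}
        return gen_participant(
            p.get("model", "mc3"), params, p.get("task", "timing"), self.n, self.seed
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"kind": self.kind, "n": self.n, "seed": self.seed, "params": self.params})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorSpec":
        return cls(**json.loads(Path(path).read_text()))


def gen_fgn(n: int, alpha: float, seed: int) -> np.ndarray:
    """Gaussian series with power spectrum ∝ f**(-alpha), by spectral
    synthesis: deterministic amplitudes, independent uniform phases,
    inverse-transformed and standardized to unit variance.

    α = 0 is white noise; α = 2 is a random-walk-like spectrum. The
    construction fixes the spectral slope exactly, which is the property
    the estimators are validated against; it is only approximately a
    stationary fractional-Gaussian-noise process in distribution.
    """
    if not 0 <= alpha <= 2:
        raise ValueError(f"alpha must be in [0, 2], got {alpha}")
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phase)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phase[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def gen_fbm(n: int, alpha: float, seed: int) -> np.ndarray:
    """Integrated spectral-synthesis noise (a fractional-Brownian-motion
    style trajectory): the cumulative sum of :func:`gen_fgn`. Its
    successive changes are Gaussian — the classic contrast case that has
    long-range structure but no heavy tails."""
    return np.cumsum(gen_fgn(n, alpha, seed))


def _pareto_icdf(u, mu: float, xmin: float):
    """Inverse CDF of the continuous power law: x = xmin * u**(-1/(mu-1))
    maps u ~ Uniform(0, 1] onto P(l) ∼ l**-mu; u = 1 gives xmin."""
    return xmin * np.asarray(u) ** (-1.0 / (mu - 1.0))


def gen_pareto(n: int, mu: float, xmin: float = 1.0, seed: int = 0) -> np.ndarray:
    """Power-law (Pareto) draws with tail exponent mu and lower bound xmin."""
    if mu <= 1:
        raise ValueError("mu must exceed 1 (tail not normalizable otherwise)")
    if xmin <= 0:
        raise ValueError("xmin must be positive")
    rng = np.random.default_rng(seed)
    u = 1.0 - rng.random(n)  # in (0, 1], avoids division by zero
    return _pareto_icdf(u, mu, xmin)


def gen_levy_flight(n: int, mu: float, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Lévy flight: power-law step lengths with uniform random headings.

    Returns ``(steps, positions)`` where ``positions`` is the (n+1, 2)
    walked path starting at the origin. The step-length series is
    heavy-tailed but serially independent — heavy tails with a flat
    spectrum.
    """
    if not 1 < mu <= 3:
        raise ValueError("mu must be in (1, 3]")
    rng = np.random.default_rng(seed)
    u = 1.0 - rng.random(n)
    steps = _pareto_icdf(u, mu, 1.0)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    disp = steps[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    positions = np.vstack([np.zeros(2), np.cumsum(disp, axis=0)])
    return steps, positions


def gen_semantic_space(
    n_names: int,
    n_categories: int,
    within_spread: float = 1.0,
    between_spread: float = 10.0,
    seed: int = 0,
) -> targets.SemanticSpace:
    """A patchy synthetic semantic plane: category centers scattered with
    SD ``between_spread``, names scattered around their center with SD
    ``within_spread``. Names are distributed across categories as evenly
    as possible."""
    if n_categories < 1 or n_names < n_categories:
        raise ValueError("need n_names >= n_categories >= 1")
    if within_spread <= 0 or between_spread <= 0:
        raise ValueError("spreads must be positive")
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, between_spread, size=(n_categories, 2))
    cat_of = np.arange(n_names) % n_categories
    coords = centers[cat_of] + rng.normal(0.0, within_spread, size=(n_names, 2))
    names = [f"item_{i:03d}" for i in range(n_names)]
    cats = [f"cat_{c}" for c in cat_of]
    return targets.SemanticSpace(names, coords, cats)


def default_space(seed: int = 0) -> targets.SemanticSpace:
    """The stock naming environment: 64 names in 8 well-separated patches."""
    return gen_semantic_space(64, 8, within_spread=1.0, between_spread=10.0, seed=seed)


def default_mixture(space: targets.SemanticSpace, seed: int = 0) -> targets.MixtureTarget:
    """Mixture target fitted to a semantic space, one component per
    category (or 4 components when the space has no category labels)."""
    k = len(set(space.categories)) if space.categories else 4
    return targets.fit_mixture(space.coords, k, seed)


def sharpest_mode(mixture: targets.MixtureTarget) -> np.ndarray:
    """Component mean with the highest density: the sampler's natural
    starting thought (the sharpest patch in mind at session start)."""
    peaks = mixture.log_density(mixture.means)
    return mixture.means[int(np.argmax(peaks))]


def naming_study(seed: int = 0):
    """The stock naming-study environment: the 64-name/8-category space
    with a sub-category-resolution mixture target (overclustered GMM,
    K=13) whose components span a wide range of sharpness. The sampler
    starts at the sharpest mode. Returns (space, mixture, start).

    Overclustering matters: splitting name clusters gives the target a
    few narrow, high-peak components alongside broad ones, so the sampler
    alternates between dwelling in sharp patches and roaming diffuse
    ones over many timescales — the dynamics that carry the 1/f and
    heavy-tail signatures into the IRI series.
    """
    space = gen_semantic_space(64, 8, 1.0, 5.0, seed=seed)
    mixture = targets.fit_mixture(space.coords, 13, seed=1)
    return space, mixture, sharpest_mode(mixture)


# sampler/readout parameters of the co-occurrence study regime (naming)
NAMING_STUDY_PARAMS = {
    "rwm_scale": 0.03,
    "temp_ratio": 2.1,
    "n_chains": 4,
    "swap_every": 1,
    "rate": 2.0,
}

# co-occurrence study regime for time estimation: proposal and target SD
# relative to the 1 s target; wide ladder so explorer chains inject jumps
TIMING_STUDY_PARAMS = {
    "target_mean": 1.0,
    "target_sd": 0.15,
    "target": 1.0,
    "rwm_scale": 0.03,  # 0.2 x target_sd
    "temp_ratio": 8.0,
    "n_chains": 4,
    "swap_every": 1,
}


def gen_participant(
    model: str,
    params: dict,
    task: str,
    n: int,
    seed: int,
    *,
    space: targets.SemanticSpace | None = None,
    mixture: targets.MixtureTarget | None = None,
    init: np.ndarray | None = None,
    max_iter_factor: int = 400,
):
    """One synthetic participant: target + sampler + readout, end to end.

    ``params`` holds sampler settings (``rwm_scale``, ``hmc_step``,
    ``hmc_leaps``, ``mc3_temps`` / ``temp_ratio`` / ``n_chains``), target
    parameters for timing (``target_mean``, ``target_sd``, ``target``),
    and the Poisson ``rate`` for naming. Timing returns a
    :class:`~cognoise.readout.TimeEstimateSeries` of length exactly
    ``n``; naming keeps sampling (in chunks) until ``n`` responses or an
    iteration cap of ``max_iter_factor * n``, and raises if fewer than
    n/2 responses materialize by then.
    """
    rng = np.random.default_rng(seed)
    if task == "timing":
        mean = float(params.get("target_mean", params.get("target", 1.0)))
        sd = float(params.get("target_sd", 0.1 * mean))
        target = targets.GaussianTarget(mean, sd)
        settings = _settings_for(model, params, seed)
        trace = samplers.run_sampler(target, settings, n, initial=mean)
        return readout.time_estimates_from_trace(
            trace, float(params.get("target", mean))
        )
    if task == "naming":
        if space is None:
            space = default_space(seed=0)
        if mixture is None:
            mixture = default_mixture(space, seed=0)
        rate = float(params.get("rate", 1.0))
        chunk = max(4 * n, 512)
        cap = max_iter_factor * n
        settings = _settings_for(model, params, seed)
        if init is None:
            init = sharpest_mode(mixture)
        all_xy = []
        total = 0
        state_trace = None
        while total < cap:
            run_n = min(chunk, cap - total)
            sub = samplers.SamplerSettings(**{**_settings_kwargs(settings), "seed": int(rng.integers(2**31))})
            start = init if state_trace is None else state_trace
            tr = samplers.run_sampler(mixture, sub, run_n, initial=start)
            all_xy.append(tr.samples)
            state_trace = tr.samples[-1]
            total += run_n
            xy = np.concatenate(all_xy)
            series = readout.iris_from_trace_count(
                xy, space, rate, np.random.default_rng(int(seed) + 1)
            )
            if len(series) >= n:
                return readout.IRISeries(series.iris[:n], series.labels[:n])
        if len(series) < n // 2:
            raise RuntimeError(
                f"sampler produced only {len(series)} responses in {cap} iterations"
            )
        return series
    raise ValueError(f"unknown task {task!r}")


def _settings_for(model: str, params: dict, seed: int) -> samplers.SamplerSettings:
    kw: dict = {"algorithm": model, "seed": int(seed)}
    if "rwm_scale" in params:
        kw["rwm_scale"] = float(params["rwm_scale"])
    if "hmc_step" in params:
        kw["hmc_step"] = float(params["hmc_step"])
    if "hmc_leaps" in params:
        kw["hmc_leaps"] = int(params["hmc_leaps"])
    if "mc3_temps" in params:
        kw["mc3_temps"] = np.asarray(params["mc3_temps"], dtype=float)
    elif "temp_ratio" in params:
        kw["mc3_temps"] = samplers.geometric_ladder(
            int(params.get("n_chains", 4)), float(params["temp_ratio"])
        )
    if "swap_every" in params:
        kw["swap_every"] = int(params["swap_every"])
    return samplers.SamplerSettings(**kw)


def _settings_kwargs(s: samplers.SamplerSettings) -> dict:
    return {
        "algorithm": s.algorithm,
        "rwm_scale": s.rwm_scale,
        "hmc_step": s.hmc_step,
        "hmc_leaps": s.hmc_leaps,
        "mc3_temps": s.mc3_temps,
        "swap_every": s.swap_every,
        "seed": s.seed,
    }
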