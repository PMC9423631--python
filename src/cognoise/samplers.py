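"""MCMC hypothesis samplers: Random Walk Metropolis, Hamiltonian Monte
Carlo, and Metropolis-coupled MCMC (parallel tempering).

The three algorithms share one convention: a state is an array whose last
axis is the hypothesis dimension, and every leading axis is a batch of
independent replicate chains. A single chain is just the batch-free case.
MC³ states carry an extra chain axis, shape ``(..., M, d)``; only the cold
(T=1) chain contributes behavioral samples, while hotter chains explore a
flattened copy of the target and occasionally swap states with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SamplerSettings",
    "SampleTrace",
    "rwm_step",
    "hmc_step",
    "mc3_sweep",
    "run_sampler",
    "geometric_ladder",
]

ALGORITHMS = ("rwm", "hmc", "mc3")


def geometric_ladder(n_chains: int, ratio: float = 3.0) -> np.ndarray:
    """Temperature ladder T_m = ratio**(m-1), starting at exactly 1."""
    if n_chains < 1:
        raise ValueError("need at least one chain")
    if ratio <= 1:
        raise ValueError("temperature ratio must exceed 1")
    return ratio ** np.arange(n_chains, dtype=float)


@dataclass
class SamplerSettings:
    """Algorithm choice plus every tunable the algorithms expose.

    ``mc3_temps`` defaults to a geometric ladder with ratio 3 over
    ``mc3_chains`` chains; the first temperature must be exactly 1.
    """

    algorithm: str = "rwm"
    rwm_scale: float = 0.5
    hmc_step: float = 0.1
    hmc_leaps: int = 10
    mc3_chains: int = 4
    mc3_temps: np.ndarray | None = None
    swap_every: int = 1
    seed: int = 0

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {
            "algorithm": self.algorithm,
            "rwm_scale": self.rwm_scale,
            "hmc_step": self.hmc_step,
            "hmc_leaps": self.hmc_leaps,
            "mc3_temps": np.asarray(self.mc3_temps).tolist(),
            "swap_every": self.swap_every,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "SamplerSettings":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        payload["mc3_temps"] = np.asarray(payload["mc3_temps"], dtype=float)
        return cls(**payload)

    def __post_init__(self) -> None:
        self.algorithm = self.algorithm.lower()
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; use one of {ALGORITHMS}")
        if self.rwm_scale <= 0 or self.hmc_step <= 0:
            raise ValueError("proposal scales must be positive")
        if self.hmc_leaps < 0:
            raise ValueError("hmc_leaps must be nonnegative")
        if self.swap_every < 1:
            raise ValueError("swap_every must be >= 1")
        if self.mc3_temps is None:
            self.mc3_temps = geometric_ladder(self.mc3_chains)
        self.mc3_temps = np.asarray(self.mc3_temps, dtype=float)
        if self.mc3_temps[0] != 1.0:
            raise ValueError("temperature ladder must start at exactly 1")
        if np.any(np.diff(self.mc3_temps) <= 0):
            raise ValueError("temperature ladder must be strictly increasing")
        self.mc3_chains = int(self.mc3_temps.size)


@dataclass
class SampleTrace:
    """Ordered cold-chain states plus acceptance/swap bookkeeping."""

    samples: np.ndarray  # (n_iterations, d)
    accept_flags: np.ndarray  # (n_iterations,) bool
    swap_events: list[tuple[int, tuple[int, int], bool]]
    settings: SamplerSettings

    @property
    def dim(self) -> int:
        return self.samples.shape[1]

    def __len__(self) -> int:
        return self.samples.shape[0]

    def to_csv(self, path: str | Path) -> None:
        cols = {"iteration": np.arange(len(self))}
        cols["x"] = self.samples[:, 0]
        if self.dim > 1:
            cols["y"] = self.samples[:, 1]
        cols["accepted"] = self.accept_flags.astype(int)
        pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# core kernels (batched; carry cached log-densities to avoid re-evaluation)


def _rwm_core(state, logp, target, scale, rng, inv_temp=1.0):
    """One batched RWM transition on the tempered density logp * inv_temp."""
    noise = rng.standard_normal(state.shape)
    proposal = state + np.asarray(scale)[..., None] * noise
    logp_new = target.log_density(proposal)
    log_ratio = np.asarray(inv_temp) * (logp_new - logp)
    accept = np.log(rng.random(state.shape[:-1])) < log_ratio
    new_state = np.where(accept[..., None], proposal, state)
    new_logp = np.where(accept, logp_new, logp)
    return new_state, new_logp, accept


def _hmc_core(state, logp, target, step, leaps, rng):
    """One batched HMC transition: leapfrog + Metropolis on -ΔH.

    ``leaps`` may vary per batch element; integration is masked so each
    element stops after its own leap count. Non-finite gradients or
    positions reject the transition for that element.
    """
    step = np.asarray(step, dtype=float)[..., None]
    leaps = np.asarray(leaps, dtype=int)
    p = rng.standard_normal(state.shape)
    kinetic0 = 0.5 * (p * p).sum(axis=-1)
    q = state.copy()
    g = target.grad_log_density(q)
    bad = ~np.all(np.isfinite(g), axis=-1)
    max_leaps = int(leaps.max()) if leaps.size else int(leaps)
    for i in range(max_leaps):
        active = (i < leaps)[..., None]
        p = np.where(active, p + 0.5 * step * g, p)
        q = np.where(active, q + step * p, q)
        g_new = target.grad_log_density(q)
        bad |= np.squeeze(active, -1) & ~np.all(np.isfinite(g_new), axis=-1)
        g = np.where(np.isfinite(g_new), g_new, 0.0)
        p = np.where(active, p + 0.5 * step * g, p)
    logp_new = target.log_density(q)
    kinetic1 = 0.5 * (p * p).sum(axis=-1)
    with np.errstate(invalid="ignore"):
        log_ratio = (logp_new - kinetic1) - (logp - kinetic0)
    log_ratio = np.where(bad | ~np.isfinite(logp_new), -np.inf, log_ratio)
    accept = np.log(rng.random(state.shape[:-1])) < log_ratio
    new_state = np.where(accept[..., None], q, state)
    new_logp = np.where(accept, logp_new, logp)
    return new_state, new_logp, accept


def _mc3_core(states, logps, target, scale, temps, do_swap, rng):
    """One batched MC³ sweep: per-chain tempered RWM, then an optional
    adjacent-pair swap proposal.

    ``states`` has shape (..., M, d); ``temps`` broadcasts to (..., M).
    Returns the swap bookkeeping (pair index, accepted) for each batch
    element, or None when no swap was proposed.
    """
    temps = np.asarray(temps, dtype=float)
    inv_temps = 1.0 / temps
    states, logps, accept = _rwm_core(states, logps, target, scale, rng, inv_temps)
    n_chains = states.shape[-2]
    swap = None
    if do_swap and n_chains > 1:
        batch_shape = states.shape[:-2]
        lo = rng.integers(0, n_chains - 1, size=batch_shape)
        idx_lo = lo[..., None]
        idx_hi = idx_lo + 1
        logp_lo = np.take_along_axis(logps, idx_lo, axis=-1)[..., 0]
        logp_hi = np.take_along_axis(logps, idx_hi, axis=-1)[..., 0]
        beta_lo = np.take_along_axis(np.broadcast_to(inv_temps, logps.shape), idx_lo, axis=-1)[..., 0]
        beta_hi = np.take_along_axis(np.broadcast_to(inv_temps, logps.shape), idx_hi, axis=-1)[..., 0]
        log_ratio = (logp_hi - logp_lo) * (beta_lo - beta_hi)
        swap_accept = np.log(rng.random(batch_shape)) < log_ratio
        chain_idx = np.arange(n_chains)
        # permutation view: where accepted, chains lo and lo+1 exchange states
        perm = np.broadcast_to(chain_idx, logps.shape).copy()
        sel = swap_accept[..., None]
        np.put_along_axis(perm, idx_lo, np.where(sel, idx_hi, idx_lo), axis=-1)
        np.put_along_axis(perm, idx_hi, np.where(sel, idx_lo, idx_hi), axis=-1)
        logps = np.take_along_axis(logps, perm, axis=-1)
        states = np.take_along_axis(states, perm[..., None], axis=-2)
        swap = (lo, swap_accept)
    return states, logps, accept, swap


# ---------------------------------------------------------------------------
# public single-step wrappers


def _check_state(target, state) -> np.ndarray:
    state = np.atleast_1d(np.asarray(state, dtype=float))
    logp = target.log_density(state)
    if not np.all(np.isfinite(logp)):
        raise ValueError("log-density at the current state is not finite")
    return state


def rwm_step(state, target, scale, rng):
    """One Random Walk Metropolis step: isotropic Gaussian proposal,
    accept with probability min(1, P(h')/P(h))."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    state = _check_state(target, state)
    new_state, _, accept = _rwm_core(state, target.log_density(state), target, scale, rng)
    return new_state, bool(accept)


def hmc_step(state, target, step, leaps, rng):
    """One Hamiltonian Monte Carlo step: Gaussian momentum, ``leaps``
    leapfrog steps of size ``step``, Metropolis-accept on exp(-ΔH)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if leaps < 0:
        raise ValueError("leaps must be nonnegative")
    state = _check_state(target, state)
    new_state, _, accept = _hmc_core(
        state, target.log_density(state), target, step, leaps, rng
    )
    return new_state, bool(accept)


def mc3_sweep(states, target, settings: SamplerSettings, rng, *, do_swap: bool = True):
    """One MC³ sweep over all chains.

    Each chain m takes an RWM step on the tempered density logp/T_m; when
    ``do_swap``, a uniformly chosen adjacent pair proposes to exchange
    states with probability min(1, exp[(logp_j - logp_i)(1/T_i - 1/T_j)]).
    Returns ``(new_states, cold_accepted, swap_record)`` where
    ``swap_record`` is ``(pair, accepted)`` or None.
    """
    states = np.asarray(states, dtype=float)
    temps = settings.mc3_temps
    if states.shape[-2] != temps.size:
        raise ValueError("one state per temperature required")
    logps = target.log_density(states)
    if not np.all(np.isfinite(logps)):
        raise ValueError("log-density at a chain state is not finite")
    states, logps, accept, swap = _mc3_core(
        states, logps, target, settings.rwm_scale, temps, do_swap, rng
    )
    record = None
    if swap is not None:
        lo, ok = swap
        record = ((int(lo), int(lo) + 1), bool(ok))
    return states, accept[..., 0], record


# ---------------------------------------------------------------------------
# full runs


def run_sampler(target, settings: SamplerSettings, n_iterations: int, initial) -> SampleTrace:
    """Run the configured sampler and record the cold-chain trace.

    The trace has exactly ``n_iterations`` cold-chain states (MC³ explorer
    chains never appear in it), per-iteration cold-chain acceptance flags,
    and for MC³ the list of swap proposals. Fully reproducible from
    ``settings.seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(settings.seed)
    d = target.dim
    init = np.atleast_1d(np.asarray(initial, dtype=float)).reshape(d)
    if not np.isfinite(target.log_density(init)):
        raise ValueError("initial state has non-finite log-density")

    samples = np.empty((n_iterations, d))
    accept_flags = np.empty(n_iterations, dtype=bool)
    swap_events: list[tuple[int, tuple[int, int], bool]] = []

    algo = settings.algorithm
    if algo in ("rwm", "hmc"):
        state = init
        logp = target.log_density(state)
        for i in range(n_iterations):
            if algo == "rwm":
                state, logp, acc = _rwm_core(state, logp, target, settings.rwm_scale, rng)
            else:
                state, logp, acc = _hmc_core(
                    state, logp, target, settings.hmc_step, settings.hmc_leaps, rng
                )
            samples[i] = state
            accept_flags[i] = acc
    elif algo == "mc3":
        m = settings.mc3_chains
        states = np.tile(init, (m, 1))
        logps = target.log_density(states)
        for i in range(n_iterations):
            do_swap = (i + 1) % settings.swap_every == 0
            states, logps, acc, swap = _mc3_core(
                states, logps, target, settings.rwm_scale, settings.mc3_temps, do_swap, rng
            )
            samples[i] = states[0]
            accept_flags[i] = acc[0]
            if swap is not None:
                lo, ok = swap
                swap_events.append((i, (int(lo), int(lo) + 1), bool(ok)))
    else:  # pragma: no cover - guarded in SamplerSettings
        raise ValueError(f"unknown algorithm {algo!r}")

    return SampleTrace(samples, accept_flags, swap_events, settings)


def run_batch(
    target,
    algorithm: str,
    n_iterations: int,
    initial: np.ndarray,
    rng: np.random.Generator,
    *,
    rwm_scale=None,
    hmc_step=None,
    hmc_leaps=None,
    mc3_temps=None,
    swap_every: int = 1,
) -> np.ndarray:
    """Vectorized replicate runs: ``initial`` is (B, d); per-replicate
    parameters are scalars or length-B arrays. Returns cold-chain samples
    of shape (B, n_iterations, d).

    This is the engine behind likelihood-free fitting, where thousands of
    parameter draws must each produce a behavioral series.
    """
    algorithm = algorithm.lower()
    init = np.asarray(initial, dtype=float)
    if init.ndim != 2:
        raise ValueError("initial must be (B, d)")
    b, d = init.shape
    out = np.empty((b, n_iterations, d))
    if algorithm in ("rwm", "hmc"):
        state = init
        logp = target.log_density(state)
        for i in range(n_iterations):
            if algorithm == "rwm":
                state, logp, _ = _rwm_core(state, logp, target, rwm_scale, rng)
            else:
                state, logp, _ = _hmc_core(state, logp, target, hmc_step, hmc_leaps, rng)
            out[:, i] = state
    elif algorithm == "mc3":
        temps = np.asarray(mc3_temps, dtype=float)
        if temps.ndim == 1:
            temps = np.broadcast_to(temps, (b, temps.size))
        m = temps.shape[1]
        states = np.repeat(init[:, None, :], m, axis=1)
        logps = target.log_density(states)
        scale = np.asarray(rwm_scale, dtype=float)
        scale = scale[..., None] if scale.ndim == 1 else scale
        for i in range(n_iterations):
            do_swap = (i + 1) % swap_every == 0
            states, logps, _, _ = _mc3_core(states, logps, target, scale, temps, do_swap, rng)
            out[:, i] = states[:, 0]
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return out
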