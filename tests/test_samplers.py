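"""MCMC kernels: acceptance rules, reversibility, stationarity, mixing."""

import numpy as np
import pytest
from scipy import stats

from cognoise import samplers
from cognoise.samplers import (
    SamplerSettings,
    hmc_step,
    mc3_sweep,
    rwm_step,
    run_sampler,
)
from cognoise.targets import GaussianTarget


class TestSettings:
    def test_ladder_must_start_at_one(self):
        with pytest.raises(ValueError):
            SamplerSettings(algorithm="mc3", mc3_temps=np.array([2.0, 4.0]))

    def test_ladder_must_increase(self):
        with pytest.raises(ValueError):
            SamplerSettings(algorithm="mc3", mc3_temps=np.array([1.0, 3.0, 2.0]))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            SamplerSettings(algorithm="nuts")

    def test_default_ladder_is_geometric(self):
        s = SamplerSettings(algorithm="mc3", mc3_chains=4)
        assert np.allclose(s.mc3_temps, [1, 3, 9, 27])

    def test_json_round_trip(self, tmp_path):
        s = SamplerSettings(algorithm="mc3", rwm_scale=0.7, seed=5,
                            mc3_temps=np.array([1.0, 2.5, 6.25]))
        s.to_json(tmp_path / "s.json")
        back = SamplerSettings.from_json(tmp_path / "s.json")
        assert back.algorithm == "mc3"
        assert back.rwm_scale == 0.7
        assert np.allclose(back.mc3_temps, s.mc3_temps)
        assert back.seed == 5


class TestRwmStep:
    def test_uphill_always_accepted(self):
        """A proposal with higher density is accepted even when the uniform
        draw is at its least favorable value."""

        class StubRng:
            def standard_normal(self, shape):
                return -np.ones(shape)  # propose toward the mode (uphill)

            def random(self, shape=None):
                return np.full(shape if shape is not None else (), 1.0 - 1e-12)

        t = GaussianTarget(0.0, 1.0)
        new, acc = rwm_step(np.array([3.0]), t, 0.5, StubRng())
        assert acc and new[0] == pytest.approx(2.5)

    def test_metropolis_acceptance_probability(self):
        """Log-ratio of exactly -log 2 must accept with probability 1/2."""
        t = GaussianTarget(0.0, 1.0)
        x0 = 0.0
        x1 = np.sqrt(2 * np.log(2))  # logp(x1) - logp(x0) = -log 2
        n, hits = 40_000, 0
        rng = np.random.default_rng(9)
        for _ in range(n):
            # replay the kernel's accept rule directly
            hits += np.log(rng.random()) < (t.log_density(x1) - t.log_density(x0))
        assert hits / n == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_detailed_balance_on_discretized_target(self, rng):
        """Empirical transition counts on a 5-point rounded state space obey
        detailed balance within Monte Carlo error."""
        t = GaussianTarget(0.0, 1.0)
        state = np.array([0.0])
        grid = np.arange(-2, 3)
        counts = np.zeros((5, 5))
        occup = np.zeros(5)
        prev = 2
        for _ in range(100_000):
            state, _ = rwm_step(state, t, 1.5, rng)
            cur = int(np.clip(np.round(state[0]), -2, 2)) + 2
            counts[prev, cur] += 1
            occup[prev] += 1
            prev = cur
        flow = counts * 1.0
        for i in range(5):
            for j in range(i + 1, 5):
                f_ij, f_ji = flow[i, j], flow[j, i]
                se = np.sqrt(f_ij + f_ji)
                assert abs(f_ij - f_ji) < 3 * se + 1e-9

    def test_nonfinite_state_rejected(self, rng):
        t = GaussianTarget(0.0, 1.0)
        with pytest.raises(ValueError):
            rwm_step(np.array([np.inf]), t, 0.5, rng)


class TestHmcStep:
    def test_leapfrog_reversibility(self):
        """Integrate forward, negate momentum, integrate back: returns to start."""
        t = GaussianTarget(0.0, 1.0)
        step, leaps = 0.1, 8
        q0 = np.array([1.3])
        p = np.array([0.7])
        q, mom = q0.copy(), p.copy()
        for _ in range(leaps):
            mom = mom + 0.5 * step * t.grad_log_density(q)
            q = q + step * mom
            mom = mom + 0.5 * step * t.grad_log_density(q)
        mom = -mom
        for _ in range(leaps):
            mom = mom + 0.5 * step * t.grad_log_density(q)
            q = q + step * mom
            mom = mom + 0.5 * step * t.grad_log_density(q)
        assert np.allclose(q, q0, atol=1e-8)
        assert np.allclose(-mom, p, atol=1e-8)

    def test_zero_leaps_is_identity_and_accepted(self, rng):
        t = GaussianTarget(0.0, 1.0)
        new, acc = hmc_step(np.array([0.4]), t, 0.1, 0, rng)
        assert acc and new[0] == pytest.approx(0.4)

    def test_high_acceptance_at_small_step(self, rng):
        t = GaussianTarget(0.0, 1.0)
        state = np.array([0.0])
        acc = 0
        for _ in range(1000):
            state, a = hmc_step(state, t, 0.1, 10, rng)
            acc += a
        assert acc / 1000 > 0.95


class TestMc3Sweep:
    def test_single_chain_reduces_to_rwm(self):
        t = GaussianTarget(0.0, 1.0)
        s_mc3 = SamplerSettings(algorithm="mc3", rwm_scale=0.8, mc3_temps=np.array([1.0]), seed=5)
        s_rwm = SamplerSettings(algorithm="rwm", rwm_scale=0.8, seed=5)
        tr_m = run_sampler(t, s_mc3, 500, 0.2)
        tr_r = run_sampler(t, s_rwm, 500, 0.2)
        assert np.array_equal(tr_m.samples, tr_r.samples)

    def test_identical_positions_swap_always_accepted(self, rng):
        t = GaussianTarget(0.0, 1.0)
        s = SamplerSettings(algorithm="mc3", rwm_scale=1e-9, mc3_temps=np.array([1.0, 4.0]))
        for _ in range(20):
            states = np.array([[0.5], [0.5]])
            # with scale ~ 0 both chains stay put, so logp_i == logp_j and the
            # swap log-ratio is exactly 0 -> always accepted
            _, _, record = mc3_sweep(states, t, s, rng)
            assert record is not None and record[1]

    def test_wrong_chain_count_rejected(self, rng):
        t = GaussianTarget(0.0, 1.0)
        s = SamplerSettings(algorithm="mc3", mc3_chains=4)
        with pytest.raises(ValueError):
            mc3_sweep(np.zeros((2, 1)), t, s, rng)

    def test_mode_mixing_contrast(self, bimodal_1d):
        """MC3 shuttles between well-separated modes; RWM with a local
        proposal stays in its starting mode over the same budget."""
        n = 30_000
        s = SamplerSettings(algorithm="mc3", rwm_scale=1.0, seed=11)
        tr = run_sampler(bimodal_1d, s, n, 5.0)
        occ = (tr.samples[:, 0] > 0).mean()
        assert 0.35 <= occ <= 0.65
        s = SamplerSettings(algorithm="rwm", rwm_scale=1.0, seed=11)
        tr = run_sampler(bimodal_1d, s, n, 5.0)
        assert (tr.samples[:, 0] < 0).mean() < 0.05
        # HMC with a local step size is gradient-guided and just as modal
        s = SamplerSettings(algorithm="hmc", hmc_step=0.2, hmc_leaps=5, seed=11)
        tr = run_sampler(bimodal_1d, s, n, 5.0)
        assert (tr.samples[:, 0] < 0).mean() < 0.05


class TestRunSampler:
    def test_seed_determinism(self):
        t = GaussianTarget(0.0, 1.0)
        for algo in ("rwm", "hmc", "mc3"):
            s = SamplerSettings(algorithm=algo, seed=42)
            a = run_sampler(t, s, 300, 0.0)
            b = run_sampler(t, s, 300, 0.0)
            assert np.array_equal(a.samples, b.samples)
            assert np.array_equal(a.accept_flags, b.accept_flags)

    def test_bookkeeping_lengths(self):
        t = GaussianTarget(0.0, 1.0)
        tr = run_sampler(t, SamplerSettings(seed=0), 123, 0.0)
        assert len(tr) == 123
        assert tr.accept_flags.shape == (123,)

    @pytest.mark.parametrize("algo,kw", [
        ("rwm", {"rwm_scale": 2.0}),
        ("hmc", {"hmc_step": 0.15, "hmc_leaps": 12}),
        ("mc3", {"rwm_scale": 2.0}),
    ])
    def test_stationary_distribution_is_standard_normal(self, algo, kw):
        t = GaussianTarget(0.0, 1.0)
        s = SamplerSettings(algorithm=algo, seed=7, **kw)
        tr = run_sampler(t, s, 21_000, 0.0)
        kept = tr.samples[1000::2, 0]
        se = kept.std() / np.sqrt(len(kept) / 10)  # crude ESS deflation
        assert abs(kept.mean()) < 3 * se
        assert 0.9 < kept.var() < 1.1

    def test_ks_against_standard_normal(self):
        t = GaussianTarget(0.0, 1.0)
        s = SamplerSettings(algorithm="rwm", rwm_scale=2.5, seed=21)
        tr = run_sampler(t, s, 100_000, 0.0)
        thinned = tr.samples[::10, 0]
        assert stats.kstest(thinned, "norm").pvalue > 0.01

    def test_trace_csv_export(self, tmp_path):
        t = GaussianTarget(0.0, 1.0)
        tr = run_sampler(t, SamplerSettings(seed=0), 50, 0.0)
        tr.to_csv(tmp_path / "trace.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "trace.csv")
        assert list(df.columns) == ["iteration", "x", "accepted"]
        assert len(df) == 50


class TestRunBatch:
    def test_batch_matches_moments(self, rng):
        t = GaussianTarget(0.0, 1.0)
        out = samplers.run_batch(t, "rwm", 4000, np.zeros((16, 1)), rng, rwm_scale=2.0)
        kept = out[:, 1000:, 0]
        assert abs(kept.mean()) < 0.05
        assert abs(kept.var() - 1.0) < 0.1

    def test_batch_mc3_per_replicate_ladders(self, rng, bimodal_1d):
        temps = np.array([[1.0, 3.0, 9.0, 27.0], [1.0, 5.0, 25.0, 125.0]])
        out = samplers.run_batch(
            bimodal_1d, "mc3", 2000, np.full((2, 1), 5.0), rng,
            rwm_scale=np.array([1.0, 1.0]), mc3_temps=temps,
        )
        assert out.shape == (2, 2000, 1)
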