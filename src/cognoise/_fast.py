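"""Compiled inner loops for batch simulation over 2-D Gaussian-mixture
targets.

Likelihood-free fitting needs tens of thousands of full sampler runs;
these numba kernels run one replicate per scalar inner loop, which is
orders of magnitude faster than stepping a vectorized batch through
Python. Each kernel seeds numba's own RNG, so traces are reproducible
from the seed (the stream is independent of numpy Generator streams).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rwm_gmm_batch", "hmc_gmm_batch", "mc3_gmm_batch", "mixture_tables"]


def mixture_tables(mixture):
    """Flatten a MixtureTarget into the arrays the kernels consume:
    means (K,2), precisions (K,2,2), and log(w_k) + log-normalizer."""
    logc = np.log(mixture.weights) + mixture._log_norm
    return (
        np.ascontiguousarray(mixture.means),
        np.ascontiguousarray(mixture._prec),
        np.ascontiguousarray(logc),
    )


@njit(cache=True, fastmath=True)
def _logp(x, y, means, prec, logc):
    k = means.shape[0]
    m = -1.0e300
    vals = np.empty(k)
    for j in range(k):
        dx = x - means[j, 0]
        dy = y - means[j, 1]
        q = prec[j, 0, 0] * dx * dx + 2.0 * prec[j, 0, 1] * dx * dy + prec[j, 1, 1] * dy * dy
        v = logc[j] - 0.5 * q
        vals[j] = v
        if v > m:
            m = v
    s = 0.0
    for j in range(k):
        s += np.exp(vals[j] - m)
    return m + np.log(s)


@njit(cache=True, fastmath=True)
def _logp_grad(x, y, means, prec, logc):
    k = means.shape[0]
    m = -1.0e300
    vals = np.empty(k)
    for j in range(k):
        dx = x - means[j, 0]
        dy = y - means[j, 1]
        q = prec[j, 0, 0] * dx * dx + 2.0 * prec[j, 0, 1] * dx * dy + prec[j, 1, 1] * dy * dy
        v = logc[j] - 0.5 * q
        vals[j] = v
        if v > m:
            m = v
    s = 0.0
    gx = 0.0
    gy = 0.0
    for j in range(k):
        w = np.exp(vals[j] - m)
        s += w
        dx = x - means[j, 0]
        dy = y - means[j, 1]
        gx += w * (-(prec[j, 0, 0] * dx + prec[j, 0, 1] * dy))
        gy += w * (-(prec[j, 0, 1] * dx + prec[j, 1, 1] * dy))
    return m + np.log(s), gx / s, gy / s


@njit(cache=True, fastmath=True)
def rwm_gmm_batch(init, scale, n_iter, means, prec, logc, seed):
    np.random.seed(seed)
    b = init.shape[0]
    out = np.empty((b, n_iter, 2))
    for i in range(b):
        x = init[i, 0]
        y = init[i, 1]
        lp = _logp(x, y, means, prec, logc)
        s = scale[i]
        for t in range(n_iter):
            xp = x + s * np.random.randn()
            yp = y + s * np.random.randn()
            lpp = _logp(xp, yp, means, prec, logc)
            if np.log(np.random.rand()) < lpp - lp:
                x, y, lp = xp, yp, lpp
            out[i, t, 0] = x
            out[i, t, 1] = y
    return out


@njit(cache=True, fastmath=True)
def hmc_gmm_batch(init, step, leaps, n_iter, means, prec, logc, seed):
    np.random.seed(seed)
    b = init.shape[0]
    out = np.empty((b, n_iter, 2))
    for i in range(b):
        x = init[i, 0]
        y = init[i, 1]
        lp = _logp(x, y, means, prec, logc)
        eps = step[i]
        nl = leaps[i]
        for t in range(n_iter):
            px = np.random.randn()
            py = np.random.randn()
            h0 = -lp + 0.5 * (px * px + py * py)
            qx, qy = x, y
            _, gx, gy = _logp_grad(qx, qy, means, prec, logc)
            for _ in range(nl):
                px += 0.5 * eps * gx
                py += 0.5 * eps * gy
                qx += eps * px
                qy += eps * py
                lq, gx, gy = _logp_grad(qx, qy, means, prec, logc)
                px += 0.5 * eps * gx
                py += 0.5 * eps * gy
            lq = _logp(qx, qy, means, prec, logc)
            h1 = -lq + 0.5 * (px * px + py * py)
            if np.isfinite(h1) and np.log(np.random.rand()) < h0 - h1:
                x, y, lp = qx, qy, lq
            out[i, t, 0] = x
            out[i, t, 1] = y
    return out


@njit(cache=True, fastmath=True)
def mc3_gmm_batch(init, scale, temps, swap_every, n_iter, means, prec, logc, seed):
    np.random.seed(seed)
    b = init.shape[0]
    m = temps.shape[1]
    out = np.empty((b, n_iter, 2))
    for i in range(b):
        xs = np.empty(m)
        ys = np.empty(m)
        lps = np.empty(m)
        for c in range(m):
            xs[c] = init[i, 0]
            ys[c] = init[i, 1]
            lps[c] = _logp(xs[c], ys[c], means, prec, logc)
        s = scale[i]
        for t in range(n_iter):
            for c in range(m):
                xp = xs[c] + s * np.random.randn()
                yp = ys[c] + s * np.random.randn()
                lpp = _logp(xp, yp, means, prec, logc)
                if np.log(np.random.rand()) < (lpp - lps[c]) / temps[i, c]:
                    xs[c], ys[c], lps[c] = xp, yp, lpp
            if m > 1 and (t + 1) % swap_every == 0:
                lo = np.random.randint(0, m - 1)
                hi = lo + 1
                lr = (lps[hi] - lps[lo]) * (1.0 / temps[i, lo] - 1.0 / temps[i, hi])
                if np.log(np.random.rand()) < lr:
                    xs[lo], xs[hi] = xs[hi], xs[lo]
                    ys[lo], ys[hi] = ys[hi], ys[lo]
                    lps[lo], lps[hi] = lps[hi], lps[lo]
            out[i, t, 0] = xs[0]
            out[i, t, 1] = ys[0]
    return out
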