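"""Signature statistics of cognitive noise.

Two exponents summarize a behavioral series:

* the spectral exponent α, from S(f) ∼ 1/f**α fitted by least squares to
  the log-binned, Welch-averaged power spectrum at low frequencies
  (f < 0.1 cycles/sample); α in [0.5, 1.5] counts as 1/f noise;
* the tail exponent μ, from P(l) ∼ l**-μ fitted by continuous power-law
  maximum likelihood with the lower cutoff xmin chosen to minimize the
  Kolmogorov–Smirnov distance; μ in (1, 3] counts as a heavy tail. A
  stricter check compares the power-law tail against an exponential tail
  with a Vuong-style normalized log-likelihood ratio.

For time estimation μ is fitted to absolute successive changes in the
estimates (after discarding estimates ≥ 3x the target, which are treated
as resting periods); for naming it is fitted to the raw inter-response
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .readout import IRISeries, TimeEstimateSeries

__all__ = [
    "PowerSpectrum",
    "SpectralFit",
    "TailFit",
    "NoiseClassification",
    "AnalysisConfig",
    "filter_time_estimates",
    "successive_changes",
    "power_spectrum",
    "fit_spectral_exponent",
    "fit_tail_exponent",
    "tail_model_comparison",
    "classify_noise",
    "analyze_series",
]

logger = logging.getLogger(__name__)

ONE_OVER_F_RANGE = (0.5, 1.5)  # closed interval for α
HEAVY_TAIL_RANGE = (1.0, 3.0)  # half-open (1, 3] for μ


@dataclass
class PowerSpectrum:
    freqs: np.ndarray  # cycles/sample, 0 < f <= 0.5
    power: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass
class SpectralFit:
    alpha: float
    intercept: float
    f_max: float
    n_bins: int
    r_squared: float


@dataclass
class TailFit:
    mu: float
    xmin: float
    n_tail: int
    lr_stat: float
    lr_p: float
    proper: bool = True  # μ > 1, i.e. the fitted tail is normalizable


@dataclass
class NoiseClassification:
    is_one_over_f: bool
    is_heavy_tailed: bool
    alpha: float
    mu: float


@dataclass
class AnalysisConfig:
    """Analysis-stage knobs; defaults reproduce the standard pipeline."""

    f_max: float = 0.1
    n_bins: int = 12
    window_len: int | None = None  # default min(512, n // 2)
    overlap: float = 0.5
    naming_mu_on_changes: bool = False  # μ on |ΔIRI| instead of raw IRIs
    timing_mu_on_changes: bool = True  # μ on |Δestimate| (the default convention)
    max_xmin_candidates: int = 200


def filter_time_estimates(series: TimeEstimateSeries) -> TimeEstimateSeries:
    """Drop estimates at or above 3x the target (presumed resting periods).

    Order is preserved; the removed count is logged and attached as
    ``n_removed_``.
    """
    keep = series.estimates < 3.0 * series.target
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_time_estimates removed %d of %d estimates (>= 3x target)",
                    removed, len(series))
    out = TimeEstimateSeries(series.estimates[keep], series.target)
    out.n_removed_ = removed  # type: ignore[attr-defined]
    return out


def successive_changes(series) -> np.ndarray:
    """Absolute first differences |x_{i+1} - x_i| of an ordered series."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series of length >= 2")
    return np.abs(np.diff(x))


def power_spectrum(series, window_len: int | None = None, overlap: float = 0.5) -> PowerSpectrum:
    """Welch-averaged periodogram: mean-detrended rectangular windows with
    the given fractional overlap; frequencies in cycles/sample."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if window_len is None:
        window_len = min(512, n // 2)
    if window_len < 16:
        raise ValueError("window_len must be >= 16")
    if n < window_len:
        raise ValueError(f"series of length {n} shorter than one window ({window_len})")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    noverlap = int(window_len * overlap)
    freqs, power = signal.welch(
        x,
        fs=1.0,
        window="boxcar",
        nperseg=window_len,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    n_windows = 1 + (n - window_len) // (window_len - noverlap) if window_len > noverlap else 1
    keep = freqs > 0
    return PowerSpectrum(freqs[keep], power[keep], n_windows)


def fit_spectral_exponent(
    spectrum: PowerSpectrum, f_max: float = 0.1, n_bins: int = 12
) -> SpectralFit:
    """α from an OLS line through the log-binned low-frequency spectrum.

    Frequencies below ``f_max`` are grouped into ``n_bins`` logarithmically
    spaced bins; within each nonempty bin the mean log10-frequency and mean
    log10-power form one fit point. α is minus the fitted slope.
    """
    sel = (spectrum.freqs < f_max) & (spectrum.power > 0)
    f = spectrum.freqs[sel]
    p = spectrum.power[sel]
    if f.size < 3:
        raise ValueError("too few positive-power frequencies below f_max")
    edges = np.logspace(np.log10(f.min()) - 1e-12, np.log10(f_max), n_bins + 1)
    which = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)
    log_f, log_p = np.log10(f), np.log10(p)
    xs, ys = [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            xs.append(log_f[m].mean())
            ys.append(log_p[m].mean())
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} nonempty log-bins below f_max; need >= 3")
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs_a, ys_a, 1)
    resid = ys_a - (slope * xs_a + intercept)
    ss_tot = float(((ys_a - ys_a.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return SpectralFit(
        alpha=float(-slope),
        intercept=float(intercept),
        f_max=f_max,
        n_bins=len(xs),
        r_squared=r2,
    )


def _powerlaw_mle(tail: np.ndarray, xmin: float) -> float:
    """Continuous power-law MLE: μ = 1 + n / Σ ln(x_i / xmin)."""
    s = float(np.log(tail / xmin).sum())
    if s <= 0:
        return np.inf
    return 1.0 + tail.size / s


def _ks_distance(tail_sorted: np.ndarray, xmin: float, mu: float) -> float:
    n = tail_sorted.size
    cdf = 1.0 - (tail_sorted / xmin) ** (1.0 - mu)
    lo = np.arange(n) / n
    hi = np.arange(1, n + 1) / n
    return float(max(np.max(cdf - lo), np.max(hi - cdf)))


def fit_tail_exponent(
    values,
    xmin: float | None = None,
    *,
    min_tail: int = 10,
    max_candidates: int = 200,
) -> TailFit:
    """Power-law tail fit with KS-optimal lower cutoff.

    Candidate cutoffs are the unique data values leaving at least
    ``min_tail`` points in the tail (thinned to ``max_candidates`` by
    quantiles when numerous); the cutoff minimizing the KS distance
    between the empirical tail and its fitted power law wins. Passing an
    explicit ``xmin`` skips the search. The Vuong comparison against an
    exponential tail is computed at the chosen cutoff.
    """
    x = np.sort(np.asarray(values, dtype=float))
    x = x[x > 0]
    if x.size < min_tail:
        raise ValueError(f"need at least {min_tail} positive values, got {x.size}")
    if xmin is None:
        cands = np.unique(x[: x.size - min_tail + 1])
        if cands.size == 0:
            raise ValueError("no candidate xmin leaves enough tail points")
        if cands.size > max_candidates:
            q = np.linspace(0, 1, max_candidates)
            cands = np.unique(np.quantile(cands, q))
        best = (np.inf, cands[0], np.inf)
        for c in cands:
            tail = x[x >= c]
            if tail.size < min_tail:
                continue
            mu = _powerlaw_mle(tail, c)
            if not np.isfinite(mu):
                continue
            ks = _ks_distance(tail, c, mu)
            if ks < best[0]:
                best = (ks, c, mu)
        if not np.isfinite(best[2]):
            raise ValueError("degenerate data: power-law MLE undefined at every cutoff")
        _, xmin, mu = best
    else:
        tail = x[x >= xmin]
        if tail.size < min_tail:
            raise ValueError("fewer than min_tail points above the given xmin")
        mu = _powerlaw_mle(tail, xmin)
    tail = x[x >= xmin]
    if np.isfinite(mu) and np.unique(tail).size > 1:
        lr_stat, lr_p = tail_model_comparison(tail, xmin)
    else:
        lr_stat, lr_p = np.nan, np.nan
    return TailFit(
        mu=float(mu),
        xmin=float(xmin),
        n_tail=int(tail.size),
        lr_stat=float(lr_stat),
        lr_p=float(lr_p),
        proper=bool(mu > 1),
    )


def tail_model_comparison(values, xmin: float) -> tuple[float, float]:
    """Vuong-style normalized log-likelihood ratio, power law vs
    exponential, both fitted by MLE to the tail x >= xmin.

    Positive values favor the power law; the p-value comes from the
    normal approximation to the standardized ratio.
    """
    x = np.asarray(values, dtype=float)
    tail = x[x >= xmin]
    if tail.size < 10:
        raise ValueError("need at least 10 tail points")
    if np.unique(tail).size == 1:
        raise ValueError("degenerate tail: all values equal")
    mu = _powerlaw_mle(tail, xmin)
    mean_excess = float(tail.mean() - xmin)
    if mean_excess <= 0:
        raise ValueError("degenerate tail: zero mean excess")
    lam = 1.0 / mean_excess
    if np.isfinite(mu):
        ll_pl = np.log(mu - 1.0) - np.log(xmin) - mu * np.log(tail / xmin)
    else:  # all mass at xmin; dominated by any proper density
        ll_pl = np.full(tail.size, -np.inf)
    ll_exp = np.log(lam) - lam * (tail - xmin)
    d = ll_pl - ll_exp
    n = d.size
    sd = float(d.std())
    mean_d = float(d.mean())
    if sd == 0:
        stat = 0.0 if mean_d == 0 else np.sign(mean_d) * np.inf
    else:
        stat = np.sqrt(n) * mean_d / sd
    p = 2.0 * stats.norm.sf(abs(stat)) if np.isfinite(stat) else 0.0
    return float(stat), float(p)


def classify_noise(alpha: float, mu: float) -> NoiseClassification:
    """Boundary-inclusive classification: α in [0.5, 1.5] is 1/f scaling,
    μ in (1, 3] is a heavy tail."""
    if not (np.isfinite(alpha) and np.isfinite(mu)):
        raise ValueError("alpha and mu must be finite")
    lo_a, hi_a = ONE_OVER_F_RANGE
    lo_m, hi_m = HEAVY_TAIL_RANGE
    return NoiseClassification(
        is_one_over_f=bool(lo_a <= alpha <= hi_a),
        is_heavy_tailed=bool(lo_m < mu <= hi_m),
        alpha=float(alpha),
        mu=float(mu),
    )


def analyze_series(
    series: TimeEstimateSeries | IRISeries,
    kind: str | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[SpectralFit, TailFit, NoiseClassification]:
    """The full two-exponent pipeline for one behavioral series.

    Time estimation: apply the 3x-target filter, fit α to the estimate
    sequence and μ to absolute successive changes. Naming: fit α to the
    IRI sequence (indexed by response number) and μ to the raw IRIs.
    ``config`` switches the μ convention and the spectral settings.
    """
    cfg = config or AnalysisConfig()
    if kind is None:
        kind = "timing" if isinstance(series, TimeEstimateSeries) else "naming"
    if kind == "timing":
        if not isinstance(series, TimeEstimateSeries):
            raise TypeError("timing analysis requires a TimeEstimateSeries")
        filtered = filter_time_estimates(series)
        values = filtered.estimates
        tail_data = successive_changes(values) if cfg.timing_mu_on_changes else values
    elif kind == "naming":
        if not isinstance(series, IRISeries):
            raise TypeError("naming analysis requires an IRISeries")
        values = series.iris
        tail_data = successive_changes(values) if cfg.naming_mu_on_changes else values
    else:
        raise ValueError(f"unknown task kind {kind!r}")
    if values.size < 2:
        raise ValueError("series too short to analyze")
    spectrum = power_spectrum(values, cfg.window_len, cfg.overlap)
    spec_fit = fit_spectral_exponent(spectrum, cfg.f_max, cfg.n_bins)
    tail_fit = fit_tail_exponent(
        tail_data[tail_data > 0], max_candidates=cfg.max_xmin_candidates
    )
    cls = classify_noise(spec_fit.alpha, tail_fit.mu)
    return spec_fit, tail_fit, cls
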