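"""Hypothesis-space target distributions P(H).

Two families cover the two tasks: a unimodal :class:`GaussianTarget` over
possible durations (time estimation), and a :class:`MixtureTarget` — a
Gaussian mixture over a 2-D semantic plane of named items (free naming).
The mixture formalizes a *patchy* mental representation: clusters of
semantically related items separated by low-probability regions.

All densities accept batched points (leading axes are broadcast), which is
what lets the samplers run many replicate chains in one vectorized pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "GaussianTarget",
    "MixtureTarget",
    "SemanticSpace",
    "log_density",
    "grad_log_density",
    "fit_mixture",
    "nearest_name",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianTarget:
    """Unimodal Gaussian over a 1-D hypothesis space (durations, seconds)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")

    @property
    def dim(self) -> int:
        return 1

    def log_density(self, point) -> np.ndarray:
        x = _as_points(point, 1)[..., 0]
        z = (x - self.mean) / self.sd
        return -0.5 * z * z - np.log(self.sd) - 0.5 * _LOG_2PI

    def grad_log_density(self, point) -> np.ndarray:
        x = _as_points(point, 1)
        return -(x - self.mean) / self.sd**2


@dataclass
class MixtureTarget:
    """Gaussian mixture over the 2-D semantic plane.

    weights sum to 1; each covariance is symmetric positive-definite.
    Cholesky factors and precisions are cached at construction.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    _log_w: np.ndarray = field(init=False, repr=False)
    _prec: np.ndarray = field(init=False, repr=False)
    _log_norm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be 1-D")
        k = self.weights.size
        if self.means.shape != (k, 2) or self.covariances.shape != (k, 2, 2):
            raise ValueError("means must be (K, 2) and covariances (K, 2, 2)")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")
        if not np.allclose(self.covariances, np.swapaxes(self.covariances, 1, 2)):
            raise ValueError("covariances must be symmetric")
        try:
            chol = np.linalg.cholesky(self.covariances)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariances must be positive-definite") from exc
        self._prec = np.linalg.inv(self.covariances)
        log_det = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
        with np.errstate(divide="ignore"):
            self._log_w = np.log(self.weights)
        self._log_norm = -0.5 * (2 * _LOG_2PI + log_det)

    @property
    def dim(self) -> int:
        return 2

    @property
    def n_components(self) -> int:
        return self.weights.size

    def _component_log_density(self, point) -> np.ndarray:
        """Per-component log N(x; m_k, S_k), shape (..., K)."""
        x = _as_points(point, 2)
        d = x[..., None, :] - self.means  # (..., K, 2)
        quad = np.einsum("...ki,kij,...kj->...k", d, self._prec, d)
        return self._log_norm - 0.5 * quad

    def log_density(self, point) -> np.ndarray:
        comp = self._component_log_density(point) + self._log_w
        return logsumexp(comp, axis=-1)

    def grad_log_density(self, point) -> np.ndarray:
        x = _as_points(point, 2)
        comp = self._component_log_density(x) + self._log_w
        resp = np.exp(comp - logsumexp(comp, axis=-1, keepdims=True))
        d = x[..., None, :] - self.means
        comp_grad = -np.einsum("kij,...kj->...ki", self._prec, d)
        return np.einsum("...k,...ki->...i", resp, comp_grad)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MixtureTarget":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["weights"]),
            np.asarray(payload["means"]),
            np.asarray(payload["covariances"]),
        )


@dataclass
class GaussianMixture1D:
    """Gaussian mixture on the line; the standard stress test for
    mode-hopping samplers (two well-separated modes defeat local kernels)."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (self.weights.shape == self.means.shape == self.sds.shape):
            raise ValueError("weights, means, sds must have equal shapes")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("sds must be positive")

    @property
    def dim(self) -> int:
        return 1

    def _comp(self, point) -> np.ndarray:
        x = _as_points(point, 1)
        z = (x - self.means) / self.sds
        return -0.5 * z * z - np.log(self.sds) - 0.5 * _LOG_2PI + np.log(self.weights)

    def log_density(self, point) -> np.ndarray:
        return logsumexp(self._comp(point), axis=-1)

    def grad_log_density(self, point) -> np.ndarray:
        x = _as_points(point, 1)
        comp = self._comp(point)
        resp = np.exp(comp - logsumexp(comp, axis=-1, keepdims=True))
        g = (resp * (-(x - self.means) / self.sds**2)).sum(axis=-1)
        return g[..., None]


@dataclass
class SemanticSpace:
    """Named items at fixed 2-D coordinates, optionally grouped by category."""

    names: list[str]
    coords: np.ndarray
    categories: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("names must be unique")
        if self.coords.shape != (len(self.names), 2):
            raise ValueError("coords must be (n_names, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.categories is not None and len(self.categories) != len(self.names):
            raise ValueError("categories must match names in length")

    def __len__(self) -> int:
        return len(self.names)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"name": self.names, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )
        if self.categories is not None:
            df["category"] = self.categories
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SemanticSpace":
        df = pd.read_csv(path)
        missing = {"name", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"semantic-space CSV missing columns: {sorted(missing)}")
        cats = df["category"].astype(str).tolist() if "category" in df.columns else None
        return cls(df["name"].astype(str).tolist(), df[["x", "y"]].to_numpy(), cats)


def _as_points(point, dim: int) -> np.ndarray:
    """Coerce to (..., dim), accepting bare scalars/arrays for dim=1."""
    x = np.asarray(point, dtype=float)
    if dim == 1:
        if x.ndim == 0 or x.shape[-1] != 1:
            x = x[..., None]
        return x
    if x.ndim == 0 or x.shape[-1] != dim:
        raise ValueError(f"point must have last dimension {dim}, got shape {x.shape}")
    return x


def log_density(target, point) -> np.ndarray:
    """Log of the target density P(H) at ``point`` (batched over leading axes)."""
    return target.log_density(point)


def grad_log_density(target, point) -> np.ndarray:
    """Gradient of ``log_density`` with respect to the point."""
    return target.grad_log_density(point)


def nearest_name(space: SemanticSpace, point) -> str:
    """Item whose coordinate is Euclidean-nearest to ``point``.

    Ties resolve to the lowest index, so the result is deterministic.
    """
    if len(space) == 0:
        raise ValueError("semantic space is empty")
    return space.names[int(nearest_index(space, point))]


def nearest_index(space: SemanticSpace, point) -> np.ndarray:
    """Index of the nearest item; batched points give batched indices."""
    if len(space) == 0:
        raise ValueError("semantic space is empty")
    x = _as_points(point, 2)
    d2 = ((x[..., None, :] - space.coords) ** 2).sum(axis=-1)
    return np.argmin(d2, axis=-1)


def fit_mixture(
    points: np.ndarray,
    n_components: int,
    seed: int,
    *,
    covariance_type: str = "full",
    tol: float = 1e-8,
    max_iter: int = 500,
    ridge: float = 1e-6,
) -> MixtureTarget:
    """Maximum-likelihood Gaussian mixture via EM.

    Initialization is k-means++-style seeding of the means from ``seed``;
    covariances start at the pooled sample covariance. EM runs until the
    mean log-likelihood improves by less than ``tol`` or ``max_iter``
    iterations. Each M-step adds ``ridge`` to covariance diagonals so
    degenerate clusters stay invertible. The per-iteration mean
    log-likelihood trace is attached as ``em_log_likelihoods_`` (it is
    nondecreasing, the standard EM guarantee).

    ``covariance_type`` may be ``full``, ``diag`` or ``spherical``.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = x.shape[0]
    k = int(n_components)
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= K <= n points, got K={k}, n={n}")
    if covariance_type not in ("full", "diag", "spherical"):
        raise ValueError(f"unknown covariance_type {covariance_type!r}")
    rng = np.random.default_rng(seed)

    means = _kmeanspp_init(x, k, rng)
    pooled = np.cov(x.T, bias=True) if n > 1 else np.eye(2)
    pooled = np.atleast_2d(pooled) + ridge * np.eye(2)
    covs = np.repeat(pooled[None], k, axis=0)
    weights = np.full(k, 1.0 / k)

    ll_trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        mix = MixtureTarget(weights, means, covs)
        comp = mix._component_log_density(x) + mix._log_w  # (n, K)
        ll = float(logsumexp(comp, axis=1).mean())
        ll_trace.append(ll)
        resp = np.exp(comp - logsumexp(comp, axis=1, keepdims=True))
        nk = resp.sum(axis=0)
        weights = nk / n
        # guard empty components: keep previous mean, wide covariance
        safe_nk = np.maximum(nk, 1e-12)
        means = resp.T @ x / safe_nk[:, None]
        d = x[:, None, :] - means  # (n, K, 2)
        covs = np.einsum("nk,nki,nkj->kij", resp, d, d) / safe_nk[:, None, None]
        if covariance_type == "diag":
            covs = covs * np.eye(2)
        elif covariance_type == "spherical":
            iso = np.trace(covs, axis1=1, axis2=2) / 2.0
            covs = iso[:, None, None] * np.eye(2)
        covs = covs + ridge * np.eye(2)
        if ll - prev < tol:
            break
        prev = ll

    weights = weights / weights.sum()
    result = MixtureTarget(weights, means, covs)
    result.em_log_likelihoods_ = np.asarray(ll_trace)  # type: ignore[attr-defined]
    return result


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: squared-distance-weighted greedy center selection."""
    n = x.shape[0]
    centers = np.empty((k, 2))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = x[rng.integers(n)]
            continue
        centers[j] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((x - centers[j]) ** 2).sum(axis=1))
    return centers
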