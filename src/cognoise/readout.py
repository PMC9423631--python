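"""From hypothesis samples to observable behavior.

Time estimation: each cold-chain sample *is* the produced duration (a
direct readout), floored at a small positive value.

Free naming: samples arrive at random times from a Poisson clock; the item
"in mind" is the nearest name to the sampler's position in the semantic
plane, and a response is emitted the moment that nearest name changes.
The inter-response interval (IRI) is therefore the summed inter-arrival
times over the run of samples whose nearest name stayed constant — on
average proportional to the number of samples between name changes. An
alternative readout maps IRIs to the distance travelled through the plane
instead of elapsed Poisson time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .samplers import SampleTrace
from .targets import SemanticSpace

__all__ = [
    "TimeEstimateSeries",
    "IRISeries",
    "time_estimates_from_trace",
    "iris_from_trace_count",
    "iris_from_trace_distance",
]

ESTIMATE_FLOOR = 0.01  # seconds; direct readouts are clipped here, not resampled


@dataclass
class TimeEstimateSeries:
    """Ordered duration productions (seconds) around a nominal target."""

    estimates: np.ndarray
    target: float

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.target <= 0:
            raise ValueError("target duration must be positive")
        if self.estimates.size and np.any(self.estimates <= 0):
            raise ValueError("estimates must be positive")

    def __len__(self) -> int:
        return self.estimates.size


@dataclass
class IRISeries:
    """Ordered inter-response intervals (seconds) with reported labels."""

    iris: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.iris = np.asarray(self.iris, dtype=float)
        if self.iris.size != len(self.labels):
            raise ValueError("iris and labels must have equal length")
        if self.iris.size and np.any(self.iris <= 0):
            raise ValueError("IRIs must be positive")
        for a, b in zip(self.labels, self.labels[1:]):
            if a == b:
                raise ValueError("consecutive labels must differ")

    def __len__(self) -> int:
        return self.iris.size


def time_estimates_from_trace(trace: SampleTrace, target: float) -> TimeEstimateSeries:
    """Direct readout: estimates are the cold-chain sample values.

    Samples at or below the floor are clipped to ``ESTIMATE_FLOOR`` (the
    fitting priors keep mass far from zero, so clipping is rare).
    """
    if trace.dim != 1:
        raise ValueError("time estimation requires a 1-D trace")
    estimates = np.maximum(trace.samples[:, 0], ESTIMATE_FLOOR)
    return TimeEstimateSeries(estimates, target)


def _change_points(trace_xy: np.ndarray, space: SemanticSpace) -> tuple[np.ndarray, np.ndarray]:
    """Indices where the nearest name changes, and the nearest-name index
    per sample. Vectorized over the whole trace."""
    from .targets import nearest_index

    idx = nearest_index(space, trace_xy)
    changes = np.flatnonzero(np.diff(idx) != 0) + 1
    return changes, idx


def iris_from_trace_count(
    trace: SampleTrace | np.ndarray,
    space: SemanticSpace,
    rate: float,
    rng: np.random.Generator,
) -> IRISeries:
    """Poisson-clock readout.

    Each sample is assigned an Exponential(rate) inter-arrival time; a
    response fires whenever the nearest name changes, and its IRI is the
    elapsed clock time since the previous response (the clock starts at
    the first sample's arrival).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    xy = _trace_xy(trace)
    if len(space) == 0:
        raise ValueError("semantic space is empty")
    n = xy.shape[0]
    if n < 2:
        return IRISeries(np.empty(0), [])
    changes, idx = _change_points(xy, space)
    # inter-arrival times; the wait for each sample i>0 follows sample i-1
    waits = rng.exponential(1.0 / rate, size=n)
    arrival = np.cumsum(waits)
    if changes.size == 0:
        return IRISeries(np.empty(0), [])
    times = arrival[changes]
    iris = np.diff(np.concatenate(([arrival[0]], times)))
    labels = [space.names[int(i)] for i in idx[changes]]
    return IRISeries(iris, labels)


def iris_from_trace_distance(
    trace: SampleTrace | np.ndarray,
    space: SemanticSpace,
    speed: float,
) -> IRISeries:
    """Distance-travelled readout: IRI = path length of the trace segment
    between successive name changes, divided by ``speed``. Segments of
    zero length emit nothing (the sampler never left the previous name)."""
    if speed <= 0:
        raise ValueError("speed must be positive")
    xy = _trace_xy(trace)
    if len(space) == 0:
        raise ValueError("semantic space is empty")
    n = xy.shape[0]
    if n < 2:
        return IRISeries(np.empty(0), [])
    changes, idx = _change_points(xy, space)
    if changes.size == 0:
        return IRISeries(np.empty(0), [])
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path = np.concatenate(([0.0], np.cumsum(seg)))
    times = path[changes]
    iris = np.diff(np.concatenate(([path[0]], times))) / speed
    labels = [space.names[int(i)] for i in idx[changes]]
    keep = iris > 0
    return IRISeries(iris[keep], [l for l, k in zip(labels, keep) if k])


def _trace_xy(trace) -> np.ndarray:
    if isinstance(trace, SampleTrace):
        if trace.dim != 2:
            raise ValueError("naming readout requires a 2-D trace")
        return trace.samples
    xy = np.asarray(trace, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("trace must be (n, 2)")
    return xy
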