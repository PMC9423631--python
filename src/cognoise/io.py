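"""CSV readers/writers for behavioral series and run configuration.

Series travel as plain CSV (`index,estimate_s` for timing,
`index,iri_s[,label]` for naming); configs and reports as JSON. Malformed
rows are rejected with their line numbers so bad inputs fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .noise_stats import AnalysisConfig
from .readout import IRISeries, TimeEstimateSeries

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "RunConfig",
]


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of one run; written beside every output."""

    task: str = "timing"
    target: float = 1.0
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    n_sims: int = 2000
    epsilon_quantile: float = 0.05
    length: int = 256
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        analysis = AnalysisConfig(**payload.pop("analysis", {}))
        return cls(analysis=analysis, **payload)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_series_csv(path: str | Path, task: str, target: float | None = None):
    """Load a behavioral series, validating values row by row.

    Timing files need an ``estimate_s`` column (and a ``target`` either in
    the file or as an argument); naming files need ``iri_s`` and
    optionally ``label``. Nonpositive or non-numeric values raise with
    the offending line number (header = line 1).
    """
    df = pd.read_csv(path)
    if task == "timing":
        col = "estimate_s"
    elif task == "naming":
        col = "iri_s"
    else:
        raise ValueError(f"unknown task {task!r}")
    if col not in df.columns:
        raise ValueError(f"{path}: missing required column {col!r}")
    values = pd.to_numeric(df[col], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(values) | (values <= 0))
    if bad.size:
        line = int(bad[0]) + 2  # header is line 1
        raise ValueError(
            f"{path}: line {line}: {col} must be a positive number, "
            f"got {df[col].iloc[bad[0]]!r}"
        )
    if task == "timing":
        if target is None:
            if "target" not in df.columns:
                raise ValueError(f"{path}: timing series needs a target column or argument")
            target = float(df["target"].iloc[0])
        return TimeEstimateSeries(values, target)
    if "label" in df.columns:
        labels = df["label"].astype(str).tolist()
    else:
        labels = [f"r{i}" if i % 2 else f"q{i}" for i in range(values.size)]
    return IRISeries(values, labels)


def write_series_csv(series, path: str | Path) -> None:
    if isinstance(series, TimeEstimateSeries):
        df = pd.DataFrame(
            {
                "index": np.arange(len(series)),
                "estimate_s": series.estimates,
                "target": series.target,
            }
        )
    elif isinstance(series, IRISeries):
        df = pd.DataFrame(
            {
                "index": np.arange(len(series)),
                "iri_s": series.iris,
                "label": series.labels,
            }
        )
    else:
        raise TypeError(f"cannot write {type(series).__name__} as a series CSV")
    df.to_csv(path, index=False)
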