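"""Wolpaw information transfer rate and session summary statistics.

Bits per selection follow Wolpaw's formula

    ψ = log₂N + P·log₂P + (1 − P)·log₂((1 − P)/(N − 1)),

where P is the probability of a correct selection and N the number of
possible commands; the rate in bits/min is ψ times the number of
selections per minute, 60/T for one selection every T seconds.  P at or
below chance (1/N) is clamped to ψ = 0 with a warning; P = 1 is the
log₂N limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["wolpaw_bits", "itr_bits_per_min", "TimingSummary",
           "summarize_times", "accuracy_table"]


def _validate_pn(P: float, N: int) -> None:
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if not (0.0 <= P <= 1.0):
        raise ValueError(f"P must be a probability in [0, 1], got {P}")


def wolpaw_bits(P: float, N: int) -> float:
    """Bits per selection ψ(P, N); 0 (with a warning) at or below chance."""
    _validate_pn(P, N)
    if P <= 1.0 / N:
        warnings.warn(
            f"accuracy P={P} is at or below chance 1/{N}; ITR clamped to 0",
            stacklevel=2)
        return 0.0
    if P == 1.0:
        return float(np.log2(N))
    return float(np.log2(N) + P * np.log2(P)
                 + (1.0 - P) * np.log2((1.0 - P) / (N - 1)))


def itr_bits_per_min(P: float, N: int, T: float) -> float:
    """ψ(P, N) × (60 / T): bits per selection times selections per minute."""
    if T <= 0:
        raise ValueError(f"selection time T must be positive, got {T}")
    return wolpaw_bits(P, N) * 60.0 / T


@dataclass
class TimingSummary:
    """Per-class mean / sample standard deviation / count of latencies."""

    mean: Dict[str, float]
    std: Dict[str, Optional[float]]
    n: Dict[str, int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_s": self.mean, "std_s": self.std,
                             "n": self.n})


def summarize_times(times_by_class: Mapping[str, Sequence[float]]
                    ) -> TimingSummary:
    """Arithmetic mean and n−1 sample std per event class.

    Values are kept at full precision; round only for display.  A class
    with a single observation gets ``std = None``; empty classes are
    rejected.
    """
    mean: Dict[str, float] = {}
    std: Dict[str, Optional[float]] = {}
    n: Dict[str, int] = {}
    for cls, values in times_by_class.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"no observations for class {cls!r}")
        mean[cls] = float(v.mean())
        std[cls] = float(v.std(ddof=1)) if v.size >= 2 else None
        n[cls] = int(v.size)
    return TimingSummary(mean, std, n)


def accuracy_table(reports: Mapping[str, "EvalReport"]) -> pd.DataFrame:
    """Tabulate per-condition accuracies (synthetic re-runs).

    ``reports`` maps a condition name (e.g. "O1", "BIPOLAR", "2s") to an
    :class:`hybridbci.classifier.EvalReport`.  The table is labeled
    synthetic: it summarizes simulator re-runs, not recorded EEG.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for name, rep in reports.items():
        rows.append({"condition": name, "accuracy_pct": rep.accuracy,
                     "error_rate": rep.error_rate, "n_test": rep.n_test,
                     "data": "synthetic"})
    return pd.DataFrame(rows).set_index("condition")
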