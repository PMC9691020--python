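"""Shared data containers for time-domain fluorescence records.

A :class:`Transient` is a stopped-flow fluorescence trace (mant or
donor-quench channel) with condition metadata; a :class:`LifetimeDecay`
is a TCSPC photon-count histogram.  Both are thin, validated wrappers
around numpy arrays, used throughout the fitting modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Transient", "LifetimeDecay"]


@dataclass(frozen=True)
class Transient:
    """A time-stamped fluorescence signal with condition metadata.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing, ``time[0] >= 0``.
    signal : array of float
        Fluorescence in arbitrary units, same length as ``time``.
    meta : dict
        Condition metadata.  Conventional keys: ``construct`` ("WT" or
        "E525K"), ``fragment`` ("S1" or "HMM-15HPZ-GFP"), ``kcl_mM``,
        ``ligand_uM``, ``channel`` ("mant" or "donor-quench"), ``prep``.
    """

    time: np.ndarray
    signal: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "signal", signal)
        if time.ndim != 1 or signal.shape != time.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if time.size < 10:
            raise ValueError(f"transient needs >= 10 points, got {time.size}")
        if not (np.all(np.isfinite(time)) and np.all(np.isfinite(signal))):
            raise ValueError("transient contains non-finite values")
        if time[0] < 0:
            raise ValueError("time must start at >= 0 s")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class LifetimeDecay:
    """A TCSPC photon-count decay histogram.

    ``t_ns`` holds channel-centre times in nanoseconds; ``counts`` the
    photon counts per channel.  ``low_counts`` flags histograms with
    fewer than 1000 total photons, for which a two-exponential fit is
    unreliable.
    """

    t_ns: np.ndarray
    counts: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)
    low_counts: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ns, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "t_ns", t)
        object.__setattr__(self, "counts", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("t_ns and counts must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_ns must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())
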