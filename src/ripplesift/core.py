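"""Core data containers shared across the analysis pipeline.

All modalities live on a single session clock, in seconds from session
start.  Voltages are microvolts, positions centimetres, rates Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LfpSignal", "SpikeTrain", "PositionTrack", "Epoch", "EpochTable"]


@dataclass
class LfpSignal:
    """Uniformly sampled LFP voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in microvolts.
    rate_hz : float
        Sampling rate.  Must exceed 1620 Hz so that the upper edge of the
        ripple detection band (810 Hz) sits below Nyquist.
    layer : str
        Anatomical layer tag, ``"pyramidale"`` or ``"radiatum"``.
    t0_s : float
        Session time of the first sample.
    """

    samples: np.ndarray
    rate_hz: float
    layer: str = "pyramidale"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("LFP samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz

    def index_at(self, t_s: float) -> int:
        """Sample index nearest to session time ``t_s``."""
        i = int(round((t_s - self.t0_s) * self.rate_hz))
        return min(max(i, 0), self.n - 1)


@dataclass
class SpikeTrain:
    """Spike times (s) of one sorted single unit."""

    unit_id: int
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            self.times_s = np.sort(self.times_s)

    @property
    def n(self) -> int:
        return self.times_s.size


@dataclass
class PositionTrack:
    """Timestamped 2-D trajectory, nominally sampled at 30 Hz.

    ``speed_cm_s`` is filled lazily by :func:`ripplesift.spatial.compute_speed`
    the first time it is requested.
    """

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    speed_cm_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=np.float64)
        self.x_cm = np.asarray(self.x_cm, dtype=np.float64)
        self.y_cm = np.asarray(self.y_cm, dtype=np.float64)
        if not (self.t_s.size == self.x_cm.size == self.y_cm.size):
            raise ValueError("track arrays must have equal length")
        if self.t_s.size >= 2 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("track timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return self.t_s.size

    def speed(self) -> np.ndarray:
        if self.speed_cm_s is None:
            from .spatial import compute_speed

            self.speed_cm_s = compute_speed(self)
        return self.speed_cm_s

    def speed_at(self, t_s) -> np.ndarray:
        """Speed at arbitrary session times (nearest-sample lookup)."""
        sp = self.speed()
        idx = np.searchsorted(self.t_s, np.atleast_1d(t_s))
        idx = np.clip(idx, 0, self.n - 1)
        left = np.clip(idx - 1, 0, self.n - 1)
        use_left = np.abs(self.t_s[left] - np.atleast_1d(t_s)) < np.abs(
            self.t_s[idx] - np.atleast_1d(t_s)
        )
        idx = np.where(use_left, left, idx)
        out = sp[idx]
        return out if np.ndim(t_s) else float(out[0])

    def nearest_index(self, t_s) -> np.ndarray:
        """Index of the tracking sample nearest in time to each ``t_s``."""
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        idx = np.searchsorted(self.t_s, t)
        idx = np.clip(idx, 0, self.n - 1)
        left = np.clip(idx - 1, 0, self.n - 1)
        use_left = np.abs(self.t_s[left] - t) < np.abs(self.t_s[idx] - t)
        return np.where(use_left, left, idx)


@dataclass
class Epoch:
    """Behavioral epoch: a rest or foraging block."""

    label: str  # "rest" | "forage"
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        self.start_s = float(self.start_s)
        self.end_s = float(self.end_s)
        if self.end_s <= self.start_s:
            raise ValueError("epoch must have positive duration")
        if self.label not in ("rest", "forage"):
            raise ValueError(f"unknown epoch label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t_s) -> np.ndarray:
        return (np.asarray(t_s) >= self.start_s) & (np.asarray(t_s) < self.end_s)


@dataclass
class EpochTable:
    """Ordered, non-overlapping sequence of epochs covering a session."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start_s < a.end_s:
                raise ValueError("epochs overlap")

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def session_end_s(self) -> float:
        return self.epochs[-1].end_s if self.epochs else 0.0

    def epoch_of(self, t_s: float) -> int:
        """Index of the epoch containing session time ``t_s`` (-1 if none)."""
        for i, ep in enumerate(self.epochs):
            if ep.start_s <= t_s < ep.end_s:
                return i
        return -1

    def foraging(self) -> list[tuple[int, Epoch]]:
        return [(i, e) for i, e in enumerate(self.epochs) if e.label == "forage"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [e.label for e in self.epochs],
                "start_s": [e.start_s for e in self.epochs],
                "end_s": [e.end_s for e in self.epochs],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EpochTable":
        return cls(
            [
                Epoch(str(r.label), float(r.start_s), float(r.end_s))
                for r in df.itertuples()
            ]
        )
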