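"""Single-unit firing-rate modulation by high-frequency events.

For each unit and event class, spikes within +/-500 ms of each event are
binned at 20 ms to form a peri-event rate matrix (one row per event).
Modulation is a paired Wilcoxon signed-rank test between the baseline
rate (mean over -500 to -400 ms) and the during-event rate (mean over the
100 ms centered on the event), each event an independent observation; a
unit is modulated when p < 0.05.  Units are then categorised by which
event classes modulate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SpikeTrain

__all__ = [
    "PeriEventRateMatrix",
    "ModulationResult",
    "peri_event_rates",
    "modulation_test",
    "modulation_overlap",
]

WINDOW_S = 0.5
BIN_S = 0.020
N_BINS = int(round(2 * WINDOW_S / BIN_S))  # 50
BASELINE_S = (-0.5, -0.4)
DURING_S = (-0.05, 0.05)
MIN_EVENTS = 10
ALPHA = 0.05


@dataclass
class PeriEventRateMatrix:
    """Events x 50 peri-event rate bins (Hz), 20 ms bins over +/-500 ms."""

    rates_hz: np.ndarray  # (n_events, N_BINS)
    event_times_s: np.ndarray

    def __post_init__(self) -> None:
        if self.rates_hz.shape[1] != N_BINS:
            raise ValueError(f"expected {N_BINS} bins")
        if np.any(self.rates_hz < 0):
            raise ValueError("rates must be non-negative")

    def mean_rate_vector(self) -> np.ndarray:
        return self.rates_hz.mean(axis=0)


@dataclass
class ModulationResult:
    """Outcome of the signed-rank modulation test for one unit x class."""

    unit_id: int
    event_class: str
    n_events: int
    rate_baseline_hz: float
    rate_event_hz: float
    p_value: float
    modulated: bool
    direction: int  # +1 rate increase, -1 decrease, 0 no change


def _window_counts(times: np.ndarray, events: np.ndarray, a: float, b: float):
    lo = np.searchsorted(times, events + a)
    hi = np.searchsorted(times, events + b)
    return hi - lo


def peri_event_rates(spikes: SpikeTrain, event_times_s) -> PeriEventRateMatrix:
    """Bin each event's peri-event spikes into the 50 x 20 ms rate vector."""
    events = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    if events.size == 0:
        raise ValueError("need at least one event")
    t = spikes.times_s
    rates = np.empty((events.size, N_BINS))
    edges = -WINDOW_S + BIN_S * np.arange(N_BINS + 1)
    for i, ev in enumerate(events):
        counts = np.diff(np.searchsorted(t, ev + edges))
        rates[i] = counts / BIN_S
    return PeriEventRateMatrix(rates, events)


def modulation_test(
    spikes: SpikeTrain,
    event_times_s,
    event_class: str = "",
    min_events: int = MIN_EVENTS,
    alpha: float = ALPHA,
) -> ModulationResult:
    """Paired signed-rank test of during-event vs baseline firing rate.

    Two-sided; with all paired differences zero the test is undefined and
    the unit is conservatively reported as not modulated (p = 1).
    """
    events = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    if events.size < min_events:
        raise ValueError(
            f"need at least {min_events} events, got {events.size}"
        )
    t = spikes.times_s
    # round window widths to the microsecond so equal-width windows get a
    # bit-identical rate scale: otherwise float subtraction turns exact
    # count ties into spurious tiny paired differences
    w_bl = round(BASELINE_S[1] - BASELINE_S[0], 6)
    w_du = round(DURING_S[1] - DURING_S[0], 6)
    bl = _window_counts(t, events, *BASELINE_S) / w_bl
    du = _window_counts(t, events, *DURING_S) / w_du
    rate_bl = float(bl.mean())
    rate_du = float(du.mean())
    if np.all(du == bl):
        p = 1.0
    else:
        _, p = stats.wilcoxon(
            du, bl, zero_method="wilcox",
            alternative="two-sided", method="auto",
        )
        p = float(p)
    direction = int(np.sign(rate_du - rate_bl))
    return ModulationResult(
        unit_id=spikes.unit_id,
        event_class=event_class,
        n_events=int(events.size),
        rate_baseline_hz=rate_bl,
        rate_event_hz=rate_du,
        p_value=p,
        modulated=bool(p < alpha),
        direction=direction,
    )


def modulation_overlap(results: dict[str, ModulationResult]) -> str:
    """Categorise a unit by which of the two event classes modulate it.

    Expects results keyed ``"ripple-like"`` and ``"pHFO"`` (each from at
    least 10 events); returns one of ``"ripple-like only"``,
    ``"pHFO only"``, ``"both"``, ``"neither"``.
    """
    for key in ("ripple-like", "pHFO"):
        if key not in results:
            raise ValueError(f"missing modulation result for {key!r}")
    rl = results["ripple-like"].modulated
    ph = results["pHFO"].modulated
    if rl and ph:
        return "both"
    if rl:
        return "ripple-like only"
    if ph:
        return "pHFO only"
    return "neither"
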