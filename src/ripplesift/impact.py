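"""Where pHFOs occur in space and what they do to place coding.

Three analyses per foraging epoch:

* an event rate map — pHFO occurrence as a point process over position,
  binned and smoothed exactly like spike maps, with Skaggs information;
* a shuffle null — event times redrawn 1000 times uniformly from the
  epoch's tracking samples (occupancy-weighted), giving a 5-95 percentile
  band for "spatially random" information;
* targeted down-sampling — for units with at least 1% of spikes inside
  pHFO cores (100 ms around the peak), remove exactly those spikes,
  recompute spatial information, and compare the improvement to 1000
  equal-count random removals; significant when above the 95th
  percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import Epoch, PositionTrack, SpikeTrain
from .spatial import (
    GAUSSIAN_KERNEL_5X5,
    RateMap,
    build_rate_map,
    spatial_information,
)

__all__ = [
    "ShuffleResult",
    "DownsampleResult",
    "event_rate_map",
    "shuffle_event_info",
    "targeted_downsample",
    "improvement_vs_fraction",
]

MIN_EVENTS = 15
MIN_SPIKE_FRACTION = 0.01
EVENT_CORE_S = 0.100
N_RESAMPLES = 1000


@dataclass
class ShuffleResult:
    """Actual event-map information against its occupancy-shuffle null."""

    info_actual: float
    null_infos: np.ndarray
    band_lo: float  # 5th percentile
    band_hi: float  # 95th percentile
    verdict: str  # "inside band" | "above" | "below"

    def __post_init__(self) -> None:
        if self.band_lo > self.band_hi:
            raise ValueError("percentile band is inverted")


@dataclass
class DownsampleResult:
    """Targeted vs random spike removal for one unit's map."""

    unit_id: int
    n_spikes_in_phfo: int
    percent_of_total: float
    info_original: float
    info_targeted: float
    improvement: float
    null_improvements: np.ndarray
    significant: bool


def _batched_information(
    counts: np.ndarray, occupancy: np.ndarray, visited: np.ndarray
) -> np.ndarray:
    """Skaggs information for a stack of count maps sharing one occupancy.

    ``counts`` has shape (n_maps, ny, nx); smoothing, masking and the
    information formula are bit-identical to the single-map path.
    """
    den = ndimage.convolve(visited.astype(float), GAUSSIAN_KERNEL_5X5,
                           mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(occupancy > 0, counts / np.where(occupancy > 0, occupancy, 1.0), 0.0)
    raw = np.where(visited, raw, 0.0)
    kern = GAUSSIAN_KERNEL_5X5[None]
    from scipy.signal import fftconvolve

    num = fftconvolve(raw, kern, mode="same", axes=(1, 2))
    num = np.clip(num, 0.0, None)  # fft roundoff can leave tiny negatives
    ok = visited & (den > 0)
    occ_v = occupancy[ok]
    p = occ_v / occ_v.sum()
    r = num[:, ok] / den[ok]
    mean_rate = (p * r).sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = r / mean_rate
        term = np.where(rel > 0, p * rel * np.log2(np.where(rel > 0, rel, 1.0)), 0.0)
    return term.sum(axis=1)


def _bin_flat_indices(ratemap: RateMap, track: PositionTrack, idx: np.ndarray):
    nx = len(ratemap.x_edges) - 1
    ix = np.clip(
        np.searchsorted(ratemap.x_edges, track.x_cm[idx], side="right") - 1,
        0, nx - 1,
    )
    iy = np.clip(
        np.searchsorted(ratemap.y_edges, track.y_cm[idx], side="right") - 1,
        0, len(ratemap.y_edges) - 2,
    )
    return iy * nx + ix


def event_rate_map(
    event_times_s: np.ndarray,
    track: PositionTrack,
    epoch: Epoch,
    min_events: int = MIN_EVENTS,
) -> tuple[RateMap, float]:
    """Occurrence map of pHFOs over position plus its spatial information.

    Events are located at the nearest tracking sample and treated as a
    point process with the same binning, smoothing and visited rules as
    spike maps.  Epochs with ``min_events`` or fewer events are refused.
    """
    event_times_s = np.asarray(event_times_s, dtype=float)
    sel = epoch.contains(event_times_s)
    if sel.sum() <= min_events:
        raise ValueError(
            f"need more than {min_events} events in the epoch, got {int(sel.sum())}"
        )
    m = build_rate_map(event_times_s[sel], track, epoch)
    return m, spatial_information(m)


def shuffle_event_info(
    event_times_s: np.ndarray,
    track: PositionTrack,
    epoch: Epoch,
    n_shuffles: int = N_RESAMPLES,
    seed: int = 0,
    min_events: int = MIN_EVENTS,
) -> ShuffleResult:
    """Occupancy-weighted shuffle null for the event-map information.

    Each shuffle redraws the event times uniformly (with replacement)
    from the epoch's tracking timestamps and recomputes the information
    with identical map parameters.
    """
    if n_shuffles <= 0:
        raise ValueError("need a positive number of shuffles")
    base_map, actual = event_rate_map(event_times_s, track, epoch, min_events)
    rng = np.random.default_rng(seed)
    tr_idx = np.flatnonzero(epoch.contains(track.t_s))
    n_ev = int(epoch.contains(np.asarray(event_times_s)).sum())
    ny, nx = base_map.occupancy_s.shape

    draws = rng.choice(tr_idx, size=(n_shuffles, n_ev), replace=True)
    flat = _bin_flat_indices(base_map, track, draws.ravel()).reshape(draws.shape)
    counts = np.zeros((n_shuffles, ny * nx))
    row = np.repeat(np.arange(n_shuffles), n_ev)
    np.add.at(counts, (row, flat.ravel()), 1.0)
    counts = counts.reshape(n_shuffles, ny, nx)

    nulls = _batched_information(counts, base_map.occupancy_s, base_map.visited)
    lo, hi = np.percentile(nulls, [5, 95])
    if actual > hi:
        verdict = "above"
    elif actual < lo:
        verdict = "below"
    else:
        verdict = "inside band"
    return ShuffleResult(actual, nulls, float(lo), float(hi), verdict)


def spikes_in_events(
    spike_times_s: np.ndarray,
    event_times_s: np.ndarray,
    core_s: float = EVENT_CORE_S,
) -> np.ndarray:
    """Boolean mask of spikes falling in any event's 100 ms core window."""
    t = np.asarray(spike_times_s, dtype=float)
    ev = np.sort(np.asarray(event_times_s, dtype=float))
    if ev.size == 0:
        return np.zeros(t.size, dtype=bool)
    j = np.searchsorted(ev, t)
    half = core_s / 2
    near_r = (j < ev.size) & (np.abs(ev[np.minimum(j, ev.size - 1)] - t) <= half)
    near_l = (j > 0) & (np.abs(t - ev[np.maximum(j - 1, 0)]) <= half)
    return near_l | near_r


def targeted_downsample(
    spikes: SpikeTrain,
    event_times_s: np.ndarray,
    track: PositionTrack,
    epoch: Epoch,
    n_random: int = N_RESAMPLES,
    seed: int = 0,
) -> DownsampleResult:
    """Remove pHFO-core spikes and compare to equal-count random removal.

    Significant when the targeted improvement in spatial information
    exceeds the 95th percentile of the random-removal improvements.
    """
    t = spikes.times_s[epoch.contains(spikes.times_s)]
    if t.size == 0:
        raise ValueError("unit has no spikes in the epoch")
    in_ev = spikes_in_events(t, event_times_s)
    n_in = int(in_ev.sum())
    frac = n_in / t.size
    if n_in == 0:
        raise ValueError("no spikes during pHFOs; down-sampling undefined")
    if frac < MIN_SPIKE_FRACTION:
        raise ValueError(
            f"only {100 * frac:.2f}% of spikes during pHFOs (< 1% threshold)"
        )

    base_map = build_rate_map(t, track, epoch)
    info_orig = spatial_information(base_map)
    targeted = build_rate_map(t[~in_ev], track, epoch,
                              bounds=(base_map.x_edges[0], base_map.x_edges[-1],
                                      base_map.y_edges[0], base_map.y_edges[-1]))
    # identical grid/mask parameters across original and down-sampled maps
    assert np.array_equal(targeted.x_edges, base_map.x_edges)
    info_targ = spatial_information(targeted)
    improvement = info_targ - info_orig

    rng = np.random.default_rng(seed)
    idx_track = track.nearest_index(t)
    flat = _bin_flat_indices(base_map, track, idx_track)
    ny, nx = base_map.occupancy_s.shape
    full_counts = np.zeros(ny * nx)
    np.add.at(full_counts, flat, 1.0)

    removals = np.empty((n_random, ny * nx))
    for k in range(n_random):
        drop = rng.choice(t.size, size=n_in, replace=False)
        c = full_counts.copy()
        np.subtract.at(c, flat[drop], 1.0)
        removals[k] = c
    nulls = _batched_information(
        removals.reshape(n_random, ny, nx), base_map.occupancy_s, base_map.visited
    ) - info_orig
    significant = bool(improvement > np.percentile(nulls, 95))
    return DownsampleResult(
        unit_id=spikes.unit_id,
        n_spikes_in_phfo=n_in,
        percent_of_total=100.0 * frac,
        info_original=float(info_orig),
        info_targeted=float(info_targ),
        improvement=float(improvement),
        null_improvements=nulls,
        significant=significant,
    )


def improvement_vs_fraction(
    results: list[DownsampleResult],
) -> tuple[float, float, float]:
    """OLS fit of information improvement vs percent of spikes removed.

    Uses only maps whose targeted improvement beat the random null, as
    the population summary does.  Returns ``(slope, intercept, r_squared)``.
    """
    sig = [r for r in results if r.significant]
    if len(sig) < 3:
        raise ValueError("need at least 3 significant maps for the fit")
    x = np.array([r.percent_of_total for r in sig])
    y = np.array([r.improvement for r in sig])
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
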