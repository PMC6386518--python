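"""Firing-rate maps and place-coding metrics.

Maps are built on a fixed 5 x 5 cm grid anchored at the arena bounding-box
corner.  Raw rate per bin is spikes / occupancy; smoothing uses the 5 x 5
Gaussian kernel (sigma of about one bin) with renormalisation over the
visited support so no rate leaks into unvisited territory.  A bin counts
as visited only if the tracked path came within 2.5 cm of it and it was
occupied for at least 150 ms.

Metrics: Skaggs spatial information per spike
``I = sum_i P_i (R_i/R) log2(R_i/R)``, spatial sparsity
``(sum_i P_i R_i)^2 / sum_i P_i R_i^2``, split-half map stability
(Pearson r), and the proportion of units whose best map peaks above 2 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import Epoch, PositionTrack, SpikeTrain

__all__ = [
    "GAUSSIAN_KERNEL_5X5",
    "BIN_SIZE_CM",
    "RateMap",
    "compute_speed",
    "build_rate_map",
    "spatial_information",
    "split_half_correlation",
    "spatial_sparsity",
    "active_proportion",
]

BIN_SIZE_CM = 5.0
MIN_OCCUPANCY_S = 0.150
PATH_DISTANCE_CM = 2.5
ACTIVE_PEAK_HZ = 2.0
SPEED_SMOOTH_S = 0.250

# 5x5 Gaussian smoothing kernel (SD ~ one bin); sums to exactly 1.
GAUSSIAN_KERNEL_5X5 = np.array(
    [
        [0.0025, 0.0125, 0.0200, 0.0125, 0.0025],
        [0.0125, 0.0625, 0.1000, 0.0625, 0.0125],
        [0.0200, 0.1000, 0.1600, 0.1000, 0.0200],
        [0.0125, 0.0625, 0.1000, 0.0625, 0.0125],
        [0.0025, 0.0125, 0.0200, 0.0125, 0.0025],
    ]
)


def compute_speed(track: PositionTrack) -> np.ndarray:
    """Running speed (cm/s) from the tracked positions.

    Positions are smoothed with a 250 ms moving average before the
    central-difference derivative, which suppresses tracker jitter that
    would otherwise inflate speed at rest.
    """
    if track.n < 2:
        raise ValueError("need at least two tracking samples")
    dt = np.median(np.diff(track.t_s))
    win = max(1, int(round(SPEED_SMOOTH_S / dt)))
    kernel = np.ones(win) / win
    # reflect-padded moving average keeps the series length and avoids
    # edge droop that would create spurious speed at epoch boundaries
    pad = win // 2
    xs = np.convolve(np.pad(track.x_cm, pad, mode="edge"), kernel, mode="same")
    ys = np.convolve(np.pad(track.y_cm, pad, mode="edge"), kernel, mode="same")
    xs = xs[pad : pad + track.n] if pad else xs
    ys = ys[pad : pad + track.n] if pad else ys
    vx = np.gradient(xs, track.t_s)
    vy = np.gradient(ys, track.t_s)
    return np.hypot(vx, vy)


@dataclass
class RateMap:
    """Binned occupancy and smoothed firing-rate matrix for one epoch."""

    occupancy_s: np.ndarray  # (ny, nx) seconds per bin
    spike_counts: np.ndarray  # (ny, nx) raw counts
    rate_hz: np.ndarray  # (ny, nx) smoothed rate, NaN where unvisited
    visited: np.ndarray  # (ny, nx) bool
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def peak_hz(self) -> float:
        if not self.visited.any():
            return 0.0
        return float(np.nanmax(self.rate_hz[self.visited]))


def _bin_edges(lo: float, hi: float, bin_cm: float) -> np.ndarray:
    n = max(1, int(np.ceil((hi - lo) / bin_cm - 1e-9)))
    return lo + bin_cm * np.arange(n + 1)


def _bin_positions(x, y, x_edges, y_edges):
    ix = np.clip(np.searchsorted(x_edges, x, side="right") - 1, 0, len(x_edges) - 2)
    iy = np.clip(np.searchsorted(y_edges, y, side="right") - 1, 0, len(y_edges) - 2)
    return ix, iy


def _visited_mask(occ_s, x, y, x_edges, y_edges) -> np.ndarray:
    """Visited = occupied >= 150 ms AND path within 2.5 cm of the bin."""
    ny, nx = occ_s.shape
    # distance from each bin centre to the nearest tracked point, via a
    # fine-grained occupancy grid and a distance transform
    fine = 1.0  # cm resolution of the distance grid
    fx = np.arange(x_edges[0], x_edges[-1] + fine, fine)
    fy = np.arange(y_edges[0], y_edges[-1] + fine, fine)
    hit = np.zeros((fy.size, fx.size), dtype=bool)
    jx = np.clip(np.round((x - x_edges[0]) / fine).astype(int), 0, fx.size - 1)
    jy = np.clip(np.round((y - y_edges[0]) / fine).astype(int), 0, fy.size - 1)
    hit[jy, jx] = True
    dist = ndimage.distance_transform_edt(~hit, sampling=fine)
    cx = 0.5 * (x_edges[:-1] + x_edges[1:])
    cy = 0.5 * (y_edges[:-1] + y_edges[1:])
    bx = np.clip(np.round((cx - x_edges[0]) / fine).astype(int), 0, fx.size - 1)
    by = np.clip(np.round((cy - y_edges[0]) / fine).astype(int), 0, fy.size - 1)
    near_path = dist[np.ix_(by, bx)] < PATH_DISTANCE_CM
    return (occ_s >= MIN_OCCUPANCY_S) & near_path


def smooth_masked(raw: np.ndarray, visited: np.ndarray) -> np.ndarray:
    """Kernel smoothing restricted to the visited support.

    The kernel is renormalised per bin over the visited neighbourhood, so
    a uniform map stays exactly uniform and unvisited bins contribute
    nothing.  Returns NaN outside the visited mask.
    """
    data = np.where(visited, raw, 0.0)
    num = ndimage.convolve(data, GAUSSIAN_KERNEL_5X5, mode="constant")
    den = ndimage.convolve(visited.astype(float), GAUSSIAN_KERNEL_5X5, mode="constant")
    out = np.full_like(num, np.nan)
    ok = visited & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def _occupancy(track: PositionTrack, sel: np.ndarray, x_edges, y_edges):
    dt = np.empty(track.n)
    dt[:-1] = np.diff(track.t_s)
    dt[-1] = dt[-2] if track.n > 1 else 0.0
    ix, iy = _bin_positions(track.x_cm[sel], track.y_cm[sel], x_edges, y_edges)
    occ = np.zeros((len(y_edges) - 1, len(x_edges) - 1))
    np.add.at(occ, (iy, ix), dt[sel])
    return occ


def build_rate_map(
    spikes: SpikeTrain | np.ndarray,
    track: PositionTrack,
    epoch: Epoch,
    bin_cm: float = BIN_SIZE_CM,
    bounds: tuple[float, float, float, float] | None = None,
) -> RateMap:
    """Occupancy-normalised, smoothed firing-rate map for one epoch.

    ``spikes`` may be a :class:`SpikeTrain` or a bare array of event times,
    which lets the same machinery produce event-rate maps (e.g. pHFO
    occurrence maps).  Spike positions are taken from the tracking sample
    nearest in time.
    """
    sel = epoch.contains(track.t_s)
    if not sel.any():
        raise ValueError("epoch has no tracking samples")
    if bounds is None:
        bounds = (
            float(track.x_cm[sel].min()),
            float(track.x_cm[sel].max()),
            float(track.y_cm[sel].min()),
            float(track.y_cm[sel].max()),
        )
    x_edges = _bin_edges(bounds[0], bounds[1], bin_cm)
    y_edges = _bin_edges(bounds[2], bounds[3], bin_cm)

    occ = _occupancy(track, sel, x_edges, y_edges)
    visited = _visited_mask(
        occ, track.x_cm[sel], track.y_cm[sel], x_edges, y_edges
    )

    times = spikes.times_s if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    times = times[(times >= epoch.start_s) & (times < epoch.end_s)]
    counts = np.zeros_like(occ)
    if times.size:
        idx = track.nearest_index(times)
        ix, iy = _bin_positions(track.x_cm[idx], track.y_cm[idx], x_edges, y_edges)
        np.add.at(counts, (iy, ix), 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(occ > 0, counts / np.where(occ > 0, occ, 1.0), 0.0)
    rate = smooth_masked(raw, visited)
    return RateMap(occ, counts, rate, visited, x_edges, y_edges)


def _p_and_r(ratemap: RateMap):
    v = ratemap.visited
    occ = ratemap.occupancy_s[v]
    p = occ / occ.sum()
    r = ratemap.rate_hz[v]
    return p, r


def spatial_information(ratemap: RateMap) -> float:
    """Skaggs information per spike (bits): ``sum P_i (R_i/R) log2(R_i/R)``."""
    p, r = _p_and_r(ratemap)
    mean_rate = float(np.sum(p * r))
    if mean_rate <= 0:
        raise ValueError("mean rate is zero; spatial information undefined")
    rel = r / mean_rate
    pos = rel > 0
    return float(np.sum(p[pos] * rel[pos] * np.log2(rel[pos])))


def spatial_sparsity(ratemap: RateMap) -> float:
    """``(sum P_i R_i)^2 / sum P_i R_i^2``; 1 for a uniform map."""
    p, r = _p_and_r(ratemap)
    denom = float(np.sum(p * r**2))
    if denom <= 0:
        raise ValueError("all-zero map; sparsity undefined")
    return float(np.sum(p * r) ** 2 / denom)


def split_half_correlation(
    spikes: SpikeTrain,
    track: PositionTrack,
    epoch: Epoch,
    bin_cm: float = BIN_SIZE_CM,
    bounds: tuple[float, float, float, float] | None = None,
) -> float:
    """Pearson r between rate maps of the two temporal halves of an epoch.

    Bins unvisited in either half are excluded.
    """
    mid = 0.5 * (epoch.start_s + epoch.end_s)
    if bounds is None:
        sel = epoch.contains(track.t_s)
        bounds = (
            float(track.x_cm[sel].min()),
            float(track.x_cm[sel].max()),
            float(track.y_cm[sel].min()),
            float(track.y_cm[sel].max()),
        )
    m1 = build_rate_map(
        spikes, track, Epoch(epoch.label, epoch.start_s, mid), bin_cm, bounds
    )
    m2 = build_rate_map(
        spikes, track, Epoch(epoch.label, mid, epoch.end_s), bin_cm, bounds
    )
    both = m1.visited & m2.visited
    if both.sum() < 10:
        import warnings

        warnings.warn("fewer than 10 bins visited in both halves; r is unstable")
    a, b = m1.rate_hz[both], m2.rate_hz[both]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def active_proportion(peak_rates_by_unit: dict[int, list[float]]) -> float:
    """Fraction of units with at least one map peaking above 2 Hz."""
    if not peak_rates_by_unit:
        raise ValueError("no units supplied")
    n_active = sum(
        1
        for peaks in peak_rates_by_unit.values()
        if peaks and max(peaks) > ACTIVE_PEAK_HZ
    )
    return n_active / len(peak_rates_by_unit)
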