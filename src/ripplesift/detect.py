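"""Detection of high-frequency oscillation (HFO) events in CA1 LFP.

The detector mirrors the classic ripple/fast-ripple pipeline: band-pass
the pyramidal-layer trace 140-800 Hz with an equiripple FIR, compute a
five-point sliding RMS, flag excursions above mean + 3.5 SD of the RMS,
merge excursions closer than 6 ms, require at least five oscillation
cycles above 3 SD of the rectified filtered trace, and finally keep only
events whose spectral peak above 150 Hz dominates the 75-125 Hz
(fast-gamma) band.  Threshold statistics are computed per behavioral
epoch so state-dependent baselines cannot bias detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal

from .core import Epoch, EpochTable, LfpSignal

__all__ = [
    "DetectionParams",
    "HfoEvent",
    "bandpass_ripple",
    "sliding_rms",
    "detect_candidates",
    "cycle_criterion",
    "spectral_validation",
    "amplitude_cv",
    "detect_events",
]


@dataclass(frozen=True)
class DetectionParams:
    """Constants of the detection algorithm (all thresholds in SD units)."""

    stop1_hz: float = 140.0
    pass_lo_hz: float = 150.0
    pass_hi_hz: float = 800.0
    stop2_hz: float = 810.0
    stop_ripple: float = 5.6e-4  # desired stopband deviation
    pass_ripple: float = 2.8e-2  # desired passband deviation
    rms_window_samples: int = 5
    rms_threshold_sd: float = 3.5
    merge_gap_ms: float = 6.0
    min_peaks: int = 5
    peak_threshold_sd: float = 3.0
    spectral_window_s: float = 0.100
    spectral_band_lo: tuple[float, float] = (75.0, 125.0)
    spectral_band_hi: tuple[float, float] = (150.0, 600.0)

    def __post_init__(self) -> None:
        if min(self.rms_threshold_sd, self.peak_threshold_sd, self.merge_gap_ms) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class HfoEvent:
    """One detected high-frequency event.

    ``envelope_amp_uv`` and ``peak_freq_hz`` are filled by the
    classification stage; ``speed_cm_s`` by the behavioral join.
    """

    start_s: float
    end_s: float
    peak_time_s: float
    peak_filtered_amp_uv: float
    epoch: int = -1
    envelope_amp_uv: float = np.nan
    peak_freq_hz: float = np.nan
    label: str = "unclassified"
    speed_cm_s: float = np.nan

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must have positive duration")
        if not (self.start_s <= self.peak_time_s <= self.end_s):
            raise ValueError("peak time must lie inside the event")


@lru_cache(maxsize=8)
def _design_fir(rate_hz: float, key: tuple) -> np.ndarray:
    (s1, p_lo, p_hi, s2, ds, dp) = key
    nyq = rate_hz / 2.0
    # Bellanger's estimate for the equiripple order, driven by the
    # narrowest transition band (10 Hz); forced odd for a type-I FIR.
    # The estimate can undershoot slightly, so the order is raised until
    # the measured ripple meets the designed deviations.
    df = min(p_lo - s1, s2 - p_hi) / rate_hz
    ntaps = int(round(2.0 / 3.0 * np.log10(1.0 / (10.0 * ds * dp)) / df)) | 1
    weight_stop = dp / ds  # 51.2 and 1 for the default deviations
    w = np.concatenate(
        [
            np.linspace(0, s1, 200),
            np.linspace(p_lo, p_hi, 400),
            np.linspace(s2, nyq, 200),
        ]
    )
    for _ in range(6):
        taps = signal.remez(
            ntaps,
            bands=[0, s1, p_lo, p_hi, s2, nyq],
            desired=[0, 1, 0],
            weight=[weight_stop, 1.0, weight_stop],
            fs=rate_hz,
        )
        _, h = signal.freqz(taps, worN=w, fs=rate_hz)
        mag = np.abs(h)
        stop_ok = max(mag[:200].max(), mag[-200:].max()) <= ds
        pass_ok = np.abs(mag[200:600] - 1.0).max() <= dp
        if stop_ok and pass_ok:
            break
        ntaps = (ntaps + max(2, ntaps // 20)) | 1
    return taps


def ripple_fir(rate_hz: float, params: DetectionParams = DetectionParams()) -> np.ndarray:
    """Equiripple band-pass FIR taps for the given sampling rate."""
    key = (
        params.stop1_hz,
        params.pass_lo_hz,
        params.pass_hi_hz,
        params.stop2_hz,
        params.stop_ripple,
        params.pass_ripple,
    )
    return _design_fir(float(rate_hz), key)


def bandpass_ripple(
    lfp: LfpSignal, params: DetectionParams = DetectionParams()
) -> np.ndarray:
    """Zero-net-delay 140-800 Hz band-pass of the LFP.

    The linear-phase FIR is applied once and its constant group delay
    compensated, which preserves the designed magnitude response exactly
    (unlike forward-backward filtering, which squares it).
    """
    if lfp.rate_hz < 2 * params.stop2_hz:
        raise ValueError(
            f"sampling rate {lfp.rate_hz} Hz too low for the {params.stop2_hz} Hz "
            "stopband edge"
        )
    taps = ripple_fir(lfp.rate_hz, params)
    if lfp.n < taps.size:
        raise ValueError("signal shorter than the filter order")
    delay = (taps.size - 1) // 2
    # edge-value padding keeps the filter in steady state at the borders,
    # so a constant trace maps to (tiny) DC gain rather than step transients
    padded = np.pad(lfp.samples, (delay, delay), mode="edge")
    return signal.oaconvolve(padded, taps, mode="full")[2 * delay : 2 * delay + lfp.n]


def sliding_rms(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered sliding-window RMS, same length as the input.

    At the edges the window shrinks to the available samples.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if window > x.size:
        raise ValueError("window longer than the signal")
    sq = x**2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    half_l = (window - 1) // 2
    half_r = window // 2
    i = np.arange(x.size)
    lo = np.maximum(i - half_l, 0)
    hi = np.minimum(i + half_r + 1, x.size)
    return np.sqrt((csum[hi] - csum[lo]) / (hi - lo))


def detect_candidates(
    rms: np.ndarray,
    rate_hz: float,
    params: DetectionParams = DetectionParams(),
) -> list[tuple[int, int]]:
    """Supra-threshold RMS runs, merged when the gap is at most 6 ms.

    Returns half-open sample-index intervals ``[start, stop)`` sorted and
    non-overlapping.  Threshold is ``mean + 3.5 * SD`` of the RMS trace
    passed in (callers supply one epoch at a time).
    """
    rms = np.asarray(rms, dtype=float)
    thresh = rms.mean() + params.rms_threshold_sd * rms.std()
    above = rms > thresh
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        stops = np.concatenate([stops, [above.size]])
    return merge_intervals(list(zip(starts.tolist(), stops.tolist())), rate_hz, params)


def merge_intervals(
    intervals: list[tuple[int, int]],
    rate_hz: float,
    params: DetectionParams = DetectionParams(),
) -> list[tuple[int, int]]:
    """Merge intervals whose gap is <= merge_gap_ms (boundary inclusive)."""
    if not intervals:
        return []
    gap = params.merge_gap_ms / 1000.0 * rate_hz
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def cycle_criterion(
    filtered: np.ndarray,
    intervals: list[tuple[int, int]],
    params: DetectionParams = DetectionParams(),
) -> list[tuple[int, int]]:
    """Keep intervals with >= 5 oscillation cycles above 3 SD.

    A cycle is counted as a strict local maximum of the band-passed
    signal (one per oscillation period — counting maxima of the rectified
    trace would tally half-waves and double-count); the amplitude
    threshold is 3 x the SD of the rectified epoch trace.
    """
    x = np.asarray(filtered, dtype=float)
    sd = np.abs(x).std()
    amp_thresh = params.peak_threshold_sd * sd
    kept = []
    for s, e in intervals:
        seg = x[s:e]
        if seg.size < 3:
            continue
        pk, _ = signal.find_peaks(seg, height=amp_thresh)
        if pk.size >= params.min_peaks:
            kept.append((s, e))
    return kept


def spectral_validation(
    lfp: LfpSignal,
    filtered: np.ndarray,
    intervals: list[tuple[int, int]],
    params: DetectionParams = DetectionParams(),
    epoch: int = -1,
    epoch_bounds: tuple[int, int] | None = None,
) -> list[HfoEvent]:
    """Reject fast-gamma / noise intervals by spectral comparison.

    For each interval, the FFT power of the 100 ms raw-LFP window centered
    on the filtered-amplitude peak is computed (Hann taper, zero-padded to
    1 s for a 1 Hz grid).  The event survives iff the peak power above
    150 Hz exceeds the peak power in 75-125 Hz.
    """
    import logging

    log = logging.getLogger(__name__)
    fs = lfp.rate_hz
    half = int(round(params.spectral_window_s * fs / 2))
    nfft = int(round(fs))  # 1 s zero-padding -> 1 Hz frequency grid
    lo0, lo1 = params.spectral_band_lo
    hi0, hi1 = params.spectral_band_hi
    n0, n1 = epoch_bounds if epoch_bounds is not None else (0, lfp.n)
    events = []
    rect = np.abs(filtered)
    for s, e in intervals:
        ipk = s + int(np.argmax(rect[s:e]))
        if ipk - half < n0 or ipk + half > n1:
            log.warning("event at %.3f s too close to epoch edge; skipped",
                        lfp.t0_s + ipk / fs)
            continue
        seg = lfp.samples[ipk - half : ipk + half]
        win = signal.windows.hann(seg.size)
        spec = np.abs(np.fft.rfft((seg - seg.mean()) * win, n=nfft)) ** 2
        freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
        band_lo = spec[(freqs >= lo0) & (freqs <= lo1)]
        sel_hi = (freqs > hi0) & (freqs <= hi1)
        band_hi = spec[sel_hi]
        if band_hi.size == 0 or band_hi.max() <= 0:
            continue
        if band_lo.size and band_hi.max() <= band_lo.max():
            continue
        events.append(
            HfoEvent(
                start_s=lfp.t0_s + s / fs,
                end_s=lfp.t0_s + e / fs,
                peak_time_s=lfp.t0_s + ipk / fs,
                peak_filtered_amp_uv=float(rect[ipk]),
                peak_freq_hz=float(freqs[sel_hi][np.argmax(band_hi)]),
                epoch=epoch,
            )
        )
    return events


def detect_events(
    lfp: LfpSignal,
    epochs: EpochTable | None = None,
    params: DetectionParams = DetectionParams(),
) -> list[HfoEvent]:
    """Full detection pipeline, run independently per behavioral epoch."""
    if epochs is None:
        epochs = EpochTable([Epoch("rest", lfp.t0_s, lfp.t0_s + lfp.duration_s)])
    filtered = bandpass_ripple(lfp, params)
    events: list[HfoEvent] = []
    for i, ep in enumerate(epochs):
        n0 = lfp.index_at(ep.start_s)
        n1 = lfp.index_at(ep.end_s - 0.5 / lfp.rate_hz) + 1
        seg = filtered[n0:n1]
        rms = sliding_rms(seg, params.rms_window_samples)
        cands = detect_candidates(rms, lfp.rate_hz, params)
        cands = cycle_criterion(seg, cands, params)
        cands = [(s + n0, e + n0) for s, e in cands]
        events.extend(
            spectral_validation(
                lfp, filtered, cands, params, epoch=i, epoch_bounds=(n0, n1)
            )
        )
    events.sort(key=lambda ev: ev.peak_time_s)
    return events


def amplitude_cv(events: list[HfoEvent], min_n: int = 20) -> float:
    """Coefficient of variation (SD/mean) of event peak filtered amplitudes.

    Sessions with fewer than ``min_n`` events are refused, since the CV of
    a small sample is too noisy to characterise the session.
    """
    if len(events) < min_n:
        raise ValueError(
            f"need at least {min_n} events for a stable CV, got {len(events)}"
        )
    amps = np.array([ev.peak_filtered_amp_uv for ev in events])
    return float(amps.std() / amps.mean())
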