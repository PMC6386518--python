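"""Theta power, running speed, and theta phase around pHFO events.

Works on the stratum-radiatum LFP.  Per event occurring at running speed
of at least 5 cm/s: (i) a 4 s segment centered on the event is taken and
the central 200 ms (the interictal spike) replaced by the session mean;
(ii) a Morlet time-frequency decomposition (4-20 Hz, 6-cycle wavelets)
gives mean 7-11 Hz power in three windows — baseline (-2.0 to -1.0 s),
before (-0.6 to -0.1 s), after (+0.1 to +0.6 s); (iii) running speed is
averaged over the same windows; (iv) the theta phase at event onset is
estimated by comparing causal and zero-phase 4-12 Hz Butterworth filters
on the pre-event signal and linearly extrapolating the offset-corrected
causal phase over the last six theta cycles.

Phase convention: 0 at the theta peak, increasing with time, in
[-pi, pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import LfpSignal, PositionTrack

__all__ = [
    "PeriEventTheta",
    "clip_event_artifact",
    "wavelet_power",
    "theta_power_windows",
    "speed_windows",
    "onset_phase",
    "peri_event_theta",
]

THETA_BAND_HZ = (7.0, 11.0)
PHASE_BAND_HZ = (4.0, 12.0)
WAVELET_FREQS_HZ = np.arange(4.0, 20.5, 0.5)
N_CYCLES = 6
CLIP_S = 0.200
SEGMENT_S = 4.0
WINDOWS_S = {"baseline": (-2.0, -1.0), "before": (-0.6, -0.1), "after": (0.1, 0.6)}
SPIKE_THRESHOLD_SD = 5.0
ONSET_THRESHOLD_SD = 2.0
MIN_SPEED_CM_S = 5.0


@dataclass
class PeriEventTheta:
    """Per-event theta-band power, speed, and onset phase."""

    event_id: int
    power_baseline: float = np.nan
    power_before: float = np.nan
    power_after: float = np.nan
    speed_baseline: float = np.nan
    speed_before: float = np.nan
    speed_after: float = np.nan
    onset_phase_rad: float = np.nan
    included: bool = True
    reason: str = ""


def clip_event_artifact(
    segment: np.ndarray, session_mean: float, rate_hz: float,
    clip_s: float = CLIP_S,
) -> np.ndarray:
    """Replace the central 200 ms (the interictal spike) by the session mean.

    ``segment`` must be exactly 4 s long; returns a copy.
    """
    segment = np.asarray(segment, dtype=float)
    n_expect = int(round(SEGMENT_S * rate_hz))
    if segment.size != n_expect:
        raise ValueError(f"segment must be {SEGMENT_S} s ({n_expect} samples)")
    out = segment.copy()
    half = int(round(clip_s * rate_hz / 2))
    mid = segment.size // 2
    out[mid - half : mid + half] = session_mean
    return out


def _morlet_kernel(freq: float, rate_hz: float, n_cycles: int = N_CYCLES):
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * rate_hz))
    t = np.arange(-half, half + 1) / rate_hz
    kern = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    # amplitude normalisation: a unit-amplitude sinusoid at `freq` yields
    # |coefficient| = 1, so power is directly amplitude^2 (uV^2)
    kern /= 0.5 * sigma_t * np.sqrt(2 * np.pi) * rate_hz
    return kern


def wavelet_power(
    segment: np.ndarray,
    rate_hz: float,
    freqs: np.ndarray = WAVELET_FREQS_HZ,
    n_cycles: int = N_CYCLES,
) -> np.ndarray:
    """Morlet time-frequency power matrix, shape (n_freqs, n_samples).

    Normalised so that a pure sinusoid of amplitude A yields power A^2 at
    its frequency; power is in uV^2 when the input is in uV.
    """
    segment = np.asarray(segment, dtype=float)
    out = np.empty((len(freqs), segment.size))
    for i, f in enumerate(freqs):
        coef = signal.fftconvolve(segment, _morlet_kernel(f, rate_hz), mode="same")
        out[i] = np.abs(coef) ** 2
    return out


def theta_power_windows(
    tf: np.ndarray,
    freqs: np.ndarray,
    rate_hz: float,
    event_index: int,
) -> dict[str, float]:
    """Mean 7-11 Hz power in the baseline/before/after windows."""
    band = (freqs >= THETA_BAND_HZ[0]) & (freqs <= THETA_BAND_HZ[1])
    out = {}
    for name, (a, b) in WINDOWS_S.items():
        i0 = event_index + int(round(a * rate_hz))
        i1 = event_index + int(round(b * rate_hz))
        if i0 < 0 or i1 > tf.shape[1]:
            raise ValueError(f"window {name!r} outside the segment")
        out[name] = float(tf[band, i0:i1].mean())
    return out


def speed_windows(track: PositionTrack, event_time_s: float) -> dict[str, float]:
    """Mean running speed in the same three peri-event windows."""
    sp = track.speed()
    out = {}
    for name, (a, b) in WINDOWS_S.items():
        sel = (track.t_s >= event_time_s + a) & (track.t_s < event_time_s + b)
        if not sel.any():
            raise ValueError(f"no tracking samples in window {name!r}")
        out[name] = float(sp[sel].mean())
    return out


def _spike_onset_index(x: np.ndarray, rate_hz: float) -> int | None:
    """Automated interictal-spike onset: last sub-2SD sample before the peak.

    The spike is sought in the final 300 ms; onset is where the deviation
    from baseline last rose through 2 SD and stayed above until the peak.
    """
    n1 = int(rate_hz)  # first second defines baseline statistics
    base = x[:n1].mean()
    sd = x[:n1].std()
    tail = int(0.3 * rate_hz)
    dev = np.abs(x - base)
    ipk = x.size - tail + int(np.argmax(dev[-tail:]))
    below = np.flatnonzero(dev[:ipk] < ONSET_THRESHOLD_SD * sd)
    if below.size == 0:
        return None
    return int(below[-1] + 1)


def onset_phase(
    segment: np.ndarray,
    rate_hz: float,
    band: tuple[float, float] = PHASE_BAND_HZ,
    spike_threshold_sd: float = SPIKE_THRESHOLD_SD,
    check_spike: bool = True,
) -> tuple[float | None, str]:
    """Theta phase at event onset from a 2 s pre-event segment.

    Returns ``(phase_rad, reason)``; phase is ``None`` when the event is
    excluded (sub-threshold spike, or fewer than six theta cycles before
    onset) and ``reason`` says why.

    The causal 4-12 Hz Butterworth filter can run to the end of the
    truncated signal but lags; the zero-phase filter has correct phase but
    a corrupted tail.  Their circular-mean phase offset, estimated on the
    unperturbed interior, corrects the causal phase, which is then fitted
    linearly over the last six theta cycles and extrapolated to the
    truncation point.
    """
    x = np.asarray(segment, dtype=float)
    fs = rate_hz
    if x.size < int(2 * fs):
        raise ValueError("need a 2 s pre-event segment")

    if check_spike:
        n1 = int(fs)
        base, sd = x[:n1].mean(), x[:n1].std()
        tail = int(0.3 * fs)
        if np.max(np.abs(x[-tail:] - base)) < spike_threshold_sd * sd:
            return None, "sub-threshold interictal spike"
        onset = _spike_onset_index(x, fs)
        if onset is None:
            return None, "spike onset not found"
        trunc = x[:onset]
    else:
        trunc = x

    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    zp = signal.sosfiltfilt(sos, trunc)
    causal = signal.sosfilt(sos, trunc)
    ph_zp = np.angle(signal.hilbert(zp))
    ph_c = np.unwrap(np.angle(signal.hilbert(causal)))

    # interior region free of filter start-up and hilbert edge effects
    guard = int(0.25 * fs)
    if trunc.size <= 2 * guard:
        return None, "truncated segment too short"
    interior = slice(guard, trunc.size - guard)
    offset = np.angle(np.mean(np.exp(1j * (ph_zp[interior] - ph_c[interior]))))
    corrected = ph_c + offset

    f_inst = np.median(np.diff(corrected[interior])) * fs / (2 * np.pi)
    if f_inst <= 0:
        return None, "no theta rhythm detected"
    fit_len = int(round(6.0 / f_inst * fs))
    edge_trim = int(0.025 * fs)  # hilbert end transient
    j1 = trunc.size - edge_trim
    j0 = j1 - fit_len
    if j0 < 0:
        return None, "fewer than six theta cycles available"
    tt = np.arange(j0, j1)
    slope, intercept = np.polyfit(tt, corrected[j0:j1], 1)
    phase_end = slope * (trunc.size - 1) + intercept
    return float((phase_end + np.pi) % (2 * np.pi) - np.pi), ""


def peri_event_theta(
    lfp_rad: LfpSignal,
    event_time_s: float,
    track: PositionTrack | None = None,
    session_mean: float | None = None,
    event_id: int = -1,
    compute_phase: bool = True,
) -> PeriEventTheta:
    """Full peri-event theta analysis for one pHFO during movement.

    Pads the 4 s analysis window by 0.5 s on each side before the wavelet
    transform to keep the baseline window free of convolution edge
    effects.
    """
    fs = lfp_rad.rate_hz
    out = PeriEventTheta(event_id=event_id)
    if session_mean is None:
        session_mean = float(lfp_rad.samples.mean())

    if track is not None:
        speed = track.speed_at(event_time_s)
        if speed < MIN_SPEED_CM_S:
            out.included = False
            out.reason = "speed below 5 cm/s"
            return out

    pad = int(0.5 * fs)
    half = int(SEGMENT_S * fs / 2)
    ic = lfp_rad.index_at(event_time_s)
    if ic - half - pad < 0 or ic + half + pad > lfp_rad.n:
        out.included = False
        out.reason = "event too close to recording edge"
        return out

    seg4 = lfp_rad.samples[ic - half : ic + half]
    clipped = clip_event_artifact(seg4, session_mean, fs)
    padded = np.concatenate(
        [
            lfp_rad.samples[ic - half - pad : ic - half],
            clipped,
            lfp_rad.samples[ic + half : ic + half + pad],
        ]
    )
    tf = wavelet_power(padded, fs)
    powers = theta_power_windows(tf, WAVELET_FREQS_HZ, fs, pad + half)
    out.power_baseline = powers["baseline"]
    out.power_before = powers["before"]
    out.power_after = powers["after"]

    if track is not None:
        try:
            sp = speed_windows(track, event_time_s)
        except ValueError:
            out.included = False
            out.reason = "tracking gap"
            return out
        out.speed_baseline = sp["baseline"]
        out.speed_before = sp["before"]
        out.speed_after = sp["after"]

    if compute_phase:
        pre = lfp_rad.samples[ic - int(2 * fs) : ic]
        phase, reason = onset_phase(pre, fs)
        if phase is not None:
            out.onset_phase_rad = phase
        elif not out.reason:
            out.reason = reason
    return out
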