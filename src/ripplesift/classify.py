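"""Waveform features, two-population clustering, and ROC labeling.

Each detected event is summarised by two features: the peak absolute
amplitude of the 0.2-40 Hz slow envelope in the 500 ms around the event
(the sharp wave or interictal spike it rides on), and the peak FFT
frequency above 150 Hz of the same segment.  Events from an epileptic
session are k-means clustered into two populations on the max-normalised
feature plane, then each cluster is labeled by comparing it to a control
ripple reference with a threshold-sweep ROC: a cluster whose frequency
distribution is inseparable from control (AUC < 0.8) is "ripple-like",
one separable on both features (AUC >= 0.8) is "pHFO".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.cluster import KMeans

from .core import LfpSignal
from .detect import HfoEvent

__all__ = [
    "EventFeatures",
    "RocCurve",
    "extract_features",
    "extract_features_table",
    "cluster_events",
    "roc_discrimination",
    "label_event_types",
    "classify_events",
    "AmbiguousLabelingError",
]

SEGMENT_S = 0.500
ENVELOPE_BAND_HZ = (0.2, 40.0)
FFT_RANGE_HZ = (40.0, 600.0)
FREQ_FLOOR_HZ = 150.0
AUC_THRESHOLD = 0.8


class AmbiguousLabelingError(RuntimeError):
    """Raised when the two clusters cannot be told apart against control."""


@dataclass
class EventFeatures:
    """The two classification features of one event (physical units)."""

    event_id: int
    envelope_amp_uv: float
    peak_freq_hz: float

    def __post_init__(self) -> None:
        if self.envelope_amp_uv < 0:
            raise ValueError("envelope amplitude must be non-negative")


def _slow_sos(rate_hz: float):
    return signal.butter(
        4, ENVELOPE_BAND_HZ, btype="bandpass", fs=rate_hz, output="sos"
    )


def extract_features(lfp: LfpSignal, event: HfoEvent) -> EventFeatures:
    """Envelope amplitude and peak frequency of one event.

    Uses the 500 ms raw-LFP segment centered on the event peak: the
    envelope is the maximum absolute value after a zero-phase 4th-order
    Butterworth 0.2-40 Hz band-pass; the peak frequency is the argmax of
    FFT power above 150 Hz on the 40-600 Hz grid (2 Hz resolution).
    """
    fs = lfp.rate_hz
    half = int(round(SEGMENT_S * fs / 2))
    ic = lfp.index_at(event.peak_time_s)
    if ic - half < 0 or ic + half > lfp.n:
        raise ValueError("500 ms feature window extends outside the recording")
    seg = lfp.samples[ic - half : ic + half]

    slow = signal.sosfiltfilt(_slow_sos(fs), seg)
    envelope = float(np.max(np.abs(slow)))

    spec = np.abs(np.fft.rfft(seg - seg.mean())) ** 2
    freqs = np.fft.rfftfreq(seg.size, 1.0 / fs)
    in_range = (freqs >= FFT_RANGE_HZ[0]) & (freqs <= FFT_RANGE_HZ[1])
    above = in_range & (freqs > FREQ_FLOOR_HZ)
    if not above.any():
        raise ValueError("no FFT bins above 150 Hz")
    peak_freq = float(freqs[above][np.argmax(spec[above])])
    return EventFeatures(id(event), envelope, peak_freq)


def extract_features_table(
    lfp: LfpSignal, events: list[HfoEvent]
) -> pd.DataFrame:
    """Feature table for a list of events; out-of-bounds events are dropped.

    Also writes ``envelope_amp_uv`` / ``peak_freq_hz`` back onto the event
    records.
    """
    import logging

    rows = []
    for i, ev in enumerate(events):
        try:
            f = extract_features(lfp, ev)
        except ValueError as exc:
            logging.getLogger(__name__).warning("event %d excluded: %s", i, exc)
            continue
        ev.envelope_amp_uv = f.envelope_amp_uv
        ev.peak_freq_hz = f.peak_freq_hz
        rows.append(
            {
                "event_id": i,
                "envelope_uv": f.envelope_amp_uv,
                "peak_freq_hz": f.peak_freq_hz,
                "peak_time_s": ev.peak_time_s,
                "epoch": ev.epoch,
            }
        )
    return pd.DataFrame(rows)


def cluster_events(
    features: pd.DataFrame,
    init_centroids: np.ndarray | None = None,
) -> np.ndarray:
    """Two-population k-means on the max-normalised feature plane.

    Features are normalised to the maximum across the data set being
    clustered.  With no user-supplied centroids, initialisation uses the
    events at minimum and maximum normalised envelope amplitude — a
    deterministic stand-in for by-eye centre-of-mass picking.
    """
    if len(features) < 2:
        raise ValueError("need at least two events to cluster")
    X = features[["envelope_uv", "peak_freq_hz"]].to_numpy(dtype=float)
    maxima = X.max(axis=0)
    if np.any(maxima <= 0):
        raise ValueError("degenerate features: non-positive maxima")
    Xn = X / maxima
    if np.allclose(Xn, Xn[0]):
        raise ValueError("degenerate clustering: all events identical")
    if init_centroids is None:
        lo = int(np.argmin(Xn[:, 0]))
        hi = int(np.argmax(Xn[:, 0]))
        init_centroids = Xn[[lo, hi]]
    km = KMeans(
        n_clusters=2, init=np.asarray(init_centroids, float), n_init=1,
        max_iter=300, tol=1e-6,
    )
    return km.fit_predict(Xn)


@dataclass
class RocCurve:
    """Threshold-sweep ROC for one scalar feature."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")


def roc_discrimination(
    values_pos: np.ndarray,
    values_neg: np.ndarray,
    orient_by_median: bool = False,
) -> RocCurve:
    """ROC from sweeping a criterion threshold across the pooled range.

    The first sample is the positive class: TPR(c) = P(pos > c),
    FPR(c) = P(neg > c).  With ``orient_by_median`` the sample with the
    larger median is taken as positive, so the reported AUC is >= 0.5 up
    to sampling noise (the convention used for cluster-vs-control
    comparisons).
    """
    a = np.asarray(values_pos, dtype=float)
    b = np.asarray(values_neg, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if orient_by_median and np.median(a) < np.median(b):
        a, b = b, a
    pooled = np.unique(np.concatenate([a, b]))
    # thresholds descending makes TPR and FPR jointly non-decreasing,
    # from (0, 0) at +inf-like criterion to (1, 1) below the minimum
    thr = np.concatenate([pooled[::-1], [pooled[0] - 1.0]])
    tpr = (a[None, :] > thr[:, None]).mean(axis=1)
    fpr = (b[None, :] > thr[:, None]).mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thr, tpr, fpr, auc)


def label_event_types(
    features: pd.DataFrame,
    clusters: np.ndarray,
    control_features: pd.DataFrame,
) -> dict[int, str]:
    """Name the clusters by ROC comparison against control ripples.

    ripple-like: frequency AUC vs control below 0.8 (inseparable);
    pHFO: AUC at least 0.8 on both frequency and envelope.
    Raises :class:`AmbiguousLabelingError` when both clusters separate, or
    neither does.
    """
    aucs = {}
    for c in (0, 1):
        sel = clusters == c
        if not sel.any():
            raise ValueError(f"cluster {c} is empty")
        f_auc = roc_discrimination(
            features.loc[sel, "peak_freq_hz"].to_numpy(),
            control_features["peak_freq_hz"].to_numpy(),
            orient_by_median=True,
        ).auc
        e_auc = roc_discrimination(
            features.loc[sel, "envelope_uv"].to_numpy(),
            control_features["envelope_uv"].to_numpy(),
            orient_by_median=True,
        ).auc
        aucs[c] = (f_auc, e_auc)

    def is_phfo(c):
        return aucs[c][0] >= AUC_THRESHOLD and aucs[c][1] >= AUC_THRESHOLD

    def is_ripple_like(c):
        return aucs[c][0] < AUC_THRESHOLD

    phfo = [c for c in (0, 1) if is_phfo(c)]
    rlike = [c for c in (0, 1) if is_ripple_like(c)]
    if len(phfo) == 1 and len(rlike) == 1 and phfo[0] != rlike[0]:
        return {rlike[0]: "ripple-like", phfo[0]: "pHFO", "aucs": aucs}  # type: ignore[dict-item]
    if len(rlike) == 2:
        # both clusters indistinguishable from control ripples
        return {0: "ripple-like", 1: "ripple-like", "aucs": aucs}  # type: ignore[dict-item]
    raise AmbiguousLabelingError(
        f"cannot assign ripple-like/pHFO labels; per-cluster (freq, envelope) "
        f"AUCs vs control: {aucs}"
    )


def classify_events(
    lfp: LfpSignal,
    events: list[HfoEvent],
    control_features: pd.DataFrame,
    init_centroids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Extract features, cluster, and label a session's events.

    Labels are written back onto the event records; returns the labeled
    feature table.
    """
    feats = extract_features_table(lfp, events)
    clusters = cluster_events(feats, init_centroids)
    mapping = label_event_types(feats, clusters, control_features)
    feats["cluster"] = clusters
    feats["label"] = [mapping[c] for c in clusters]
    for r in feats.itertuples():
        events[r.event_id].label = r.label
    return feats
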