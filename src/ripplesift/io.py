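"""On-disk dialects for every modality.

LFP is flat little-endian float32 with a JSON sidecar (rate, units,
layer); spikes, tracking, epochs, events and ground truth are headered
CSV.  Times are seconds (double precision), voltages microvolts,
positions centimetres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochTable, LfpSignal, PositionTrack, SpikeTrain
from .detect import HfoEvent

__all__ = [
    "write_lfp", "read_lfp",
    "write_spikes", "read_spikes",
    "write_track", "read_track",
    "write_epochs", "read_epochs",
    "write_events", "read_events",
]


class FormatError(ValueError):
    """Malformed input file."""


def write_lfp(path: str | Path, lfp: LfpSignal) -> None:
    path = Path(path)
    lfp.samples.astype("<f4").tofile(path)
    sidecar = {
        "rate_hz": lfp.rate_hz,
        "units": "uV",
        "layer": lfp.layer,
        "t0_s": lfp.t0_s,
        "dtype": "float32-le",
        "n_samples": int(lfp.n),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_lfp(path: str | Path) -> LfpSignal:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("rate_hz", "layer"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar_path} lacks {key!r}")
    samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    return LfpSignal(samples, float(meta["rate_hz"]), meta["layer"],
                     float(meta.get("t0_s", 0.0)))


def _require_columns(df: pd.DataFrame, cols: tuple, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing} in header")


def write_spikes(path: str | Path, trains: list[SpikeTrain]) -> None:
    rows = [
        {"unit_id": tr.unit_id, "time_s": t} for tr in trains for t in tr.times_s
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    _require_columns(df, ("unit_id", "time_s"), path)
    return [
        SpikeTrain(int(uid), g["time_s"].to_numpy())
        for uid, g in df.groupby("unit_id", sort=True)
    ]


def write_track(path: str | Path, track: PositionTrack) -> None:
    pd.DataFrame(
        {"time_s": track.t_s, "x_cm": track.x_cm, "y_cm": track.y_cm}
    ).to_csv(path, index=False)


def read_track(path: str | Path) -> PositionTrack:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "x_cm", "y_cm"), path)
    return PositionTrack(
        df["time_s"].to_numpy(), df["x_cm"].to_numpy(), df["y_cm"].to_numpy()
    )


def write_epochs(path: str | Path, epochs: EpochTable) -> None:
    epochs.to_frame().to_csv(path, index=False)


def read_epochs(path: str | Path) -> EpochTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"epoch file {path} not found; refusing to assume "
                          "a single full-session epoch")
    df = pd.read_csv(path)
    _require_columns(df, ("label", "start_s", "end_s"), path)
    return EpochTable.from_frame(df)


EVENT_COLUMNS = (
    "epoch", "start_s", "end_s", "peak_time_s", "peak_amp_uV",
    "envelope_uV", "peak_freq_hz", "label", "speed_cm_s",
)


def write_events(path: str | Path, events: list[HfoEvent]) -> None:
    pd.DataFrame(
        [
            {
                "epoch": ev.epoch,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "peak_time_s": ev.peak_time_s,
                "peak_amp_uV": ev.peak_filtered_amp_uv,
                "envelope_uV": ev.envelope_amp_uv,
                "peak_freq_hz": ev.peak_freq_hz,
                "label": ev.label,
                "speed_cm_s": ev.speed_cm_s,
            }
            for ev in events
        ],
        columns=EVENT_COLUMNS,
    ).to_csv(path, index=False)


def read_events(path: str | Path) -> list[HfoEvent]:
    df = pd.read_csv(path)
    _require_columns(df, ("epoch", "start_s", "end_s", "peak_time_s",
                          "peak_amp_uV"), path)
    out = []
    for r in df.itertuples():
        out.append(
            HfoEvent(
                start_s=float(r.start_s),
                end_s=float(r.end_s),
                peak_time_s=float(r.peak_time_s),
                peak_filtered_amp_uv=float(r.peak_amp_uV),
                epoch=int(r.epoch),
                envelope_amp_uv=float(getattr(r, "envelope_uV", np.nan)),
                peak_freq_hz=float(getattr(r, "peak_freq_hz", np.nan)),
                label=str(getattr(r, "label", "unclassified")),
                speed_cm_s=float(getattr(r, "speed_cm_s", np.nan)),
            )
        )
    return out
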