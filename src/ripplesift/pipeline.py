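"""One-command end-to-end session analysis.

``run_session`` chains simulate -> detect -> classify -> theta ->
modulate -> spatial -> impact -> report on a synthetic session (or on
data loaded from disk), writes every stage's table to the output
directory, and returns a JSON-compatible report.  All randomness derives
from the single configured seed, so a rerun regenerates the report
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import classify as _classify
from . import detect as _detect
from . import impact as _impact
from . import io as _io
from . import modulation as _mod
from . import spatial as _spatial
from . import synth as _synth
from . import theta as _theta

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_session"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "ripplesift_out"
    # synthetic-session parameters (flat overrides of SessionSpec fields)
    session: dict = field(default_factory=dict)
    # optional data paths; when set, simulation is skipped
    lfp_pyr_path: str | None = None
    lfp_rad_path: str | None = None
    spikes_path: str | None = None
    track_path: str | None = None
    epochs_path: str | None = None
    control_features_path: str | None = None
    # control-reference simulation (used when no control features on disk)
    control_session: dict = field(
        default_factory=lambda: {"epochs": (("rest", 300.0), ("forage", 300.0))}
    )
    n_shuffles: int = 1000
    n_random_downsamples: int = 1000

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # YAML has no tuple type; restore the canonical epoch representation
        for key in ("session", "control_session"):
            block = raw.get(key)
            if isinstance(block, dict) and "epochs" in block:
                block["epochs"] = tuple(tuple(e) for e in block["epochs"])
        return cls(**raw)


def _session_spec(overrides: dict, seed: int) -> _synth.SessionSpec:
    ov = dict(overrides)
    if "epochs" in ov:
        ov["epochs"] = tuple(tuple(e) for e in ov["epochs"])
    if "classes" in ov:
        ov["classes"] = {
            k: _synth.EventClassParams(**v) for k, v in ov["classes"].items()
        }
    return replace(_synth.epileptic_spec(**ov), seed=seed)


def control_reference_features(
    config: PipelineConfig, seed: int
) -> pd.DataFrame:
    """Feature table of control ripples, from disk or a control simulation."""
    if config.control_features_path:
        df = pd.read_csv(config.control_features_path)
        return df
    ov = dict(config.control_session)
    if "epochs" in ov:
        ov["epochs"] = tuple(tuple(e) for e in ov["epochs"])
    spec = replace(_synth.control_spec(**ov), seed=seed)
    ses = _synth.simulate_session(spec)
    events = _detect.detect_events(ses.lfp_pyr, ses.epochs)
    return _classify.extract_features_table(ses.lfp_pyr, events)


def run_session(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the session report.

    Stage outputs (events, features, theta, modulation, spatial, impact
    tables) are written as CSV under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence([int(config.seed) % 2**31, 99])
    stage_seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(
            ["simulate", "control", "shuffle", "downsample"], root.spawn(4)
        )
    }
    report: dict = {"seed": config.seed, "stage_seeds": stage_seeds, "stages": {}}

    # ---- acquire data -------------------------------------------------
    if config.lfp_pyr_path:
        lfp_pyr = _io.read_lfp(config.lfp_pyr_path)
        lfp_rad = _io.read_lfp(config.lfp_rad_path) if config.lfp_rad_path else None
        spikes = _io.read_spikes(config.spikes_path) if config.spikes_path else []
        track = _io.read_track(config.track_path) if config.track_path else None
        epochs = _io.read_epochs(config.epochs_path)
        truth = None
    else:
        spec = _session_spec(config.session, stage_seeds["simulate"])
        ses = _synth.simulate_session(spec)
        lfp_pyr, lfp_rad = ses.lfp_pyr, ses.lfp_rad
        spikes, track, epochs, truth = ses.spikes, ses.track, ses.epochs, ses.truth
        ses.truth.events.to_csv(out / "ground_truth.csv", index=False)
        _io.write_track(out / "track.csv", track)
        _io.write_epochs(out / "epochs.csv", epochs)
        _io.write_spikes(out / "spikes.csv", spikes)

    # ---- detect -------------------------------------------------------
    events = _detect.detect_events(lfp_pyr, epochs)
    report["stages"]["detect"] = {"n_events": len(events)}
    if len(events) >= 20:
        report["stages"]["detect"]["amplitude_cv"] = _detect.amplitude_cv(events)

    # ---- classify -----------------------------------------------------
    control_feats = control_reference_features(config, stage_seeds["control"])
    feats = _classify.classify_events(lfp_pyr, events, control_feats)
    if track is not None:
        for ev in events:
            ev.speed_cm_s = float(track.speed_at(ev.peak_time_s))
        feats["speed_cm_s"] = [events[i].speed_cm_s for i in feats["event_id"]]
    _io.write_events(out / "events.csv", events)
    feats.to_csv(out / "features.csv", index=False)
    class_summary = {}
    for lbl, g in feats.groupby("label"):
        class_summary[lbl] = {
            "n": int(len(g)),
            "freq_median_hz": float(g.peak_freq_hz.median()),
            "freq_iqr_hz": [float(q) for q in g.peak_freq_hz.quantile([0.25, 0.75])],
            "envelope_median_uv": float(g.envelope_uv.median()),
            "envelope_iqr_uv": [float(q) for q in g.envelope_uv.quantile([0.25, 0.75])],
        }
        if "speed_cm_s" in g:
            class_summary[lbl]["speed_median_cm_s"] = float(g.speed_cm_s.median())
    report["stages"]["classify"] = class_summary

    phfo_times = np.array(
        [ev.peak_time_s for ev in events if ev.label == "pHFO"]
    )
    rlike_times = np.array(
        [ev.peak_time_s for ev in events if ev.label == "ripple-like"]
    )
    if phfo_times.size == 0:
        report["stages"]["classify"]["notice"] = "no pHFO events detected"

    # ---- theta dynamics around pHFOs ---------------------------------
    if phfo_times.size and lfp_rad is not None and track is not None:
        session_mean = float(lfp_rad.samples.mean())
        rows = []
        for i, t0 in enumerate(phfo_times):
            pet = _theta.peri_event_theta(lfp_rad, t0, track, session_mean, i)
            rows.append(dataclasses.asdict(pet))
        theta_df = pd.DataFrame(rows)
        theta_df.to_csv(out / "theta.csv", index=False)
        inc = theta_df[theta_df.included]
        stage = {"n_events_movement": int(len(inc)), "n_excluded":
                 int((~theta_df.included).sum())}
        if len(inc) >= 10:
            drop = inc.power_baseline - inc.power_after
            stage["median_power_drop_uv2"] = float(drop.median())
            stage["after_vs_baseline_p"] = float(
                sps.wilcoxon(inc.power_after, inc.power_baseline)[1]
            )
            stage["before_vs_baseline_p"] = float(
                sps.wilcoxon(inc.power_before, inc.power_baseline)[1]
            )
            stage["median_speed_change_cm_s"] = float(
                (inc.speed_after - inc.speed_baseline).median()
            )
        report["stages"]["theta"] = stage

    # ---- unit modulation ---------------------------------------------
    mod_rows, categories = [], {}
    class_times = {"ripple-like": rlike_times, "pHFO": phfo_times}
    for tr in spikes:
        per_class = {}
        for cls, times in class_times.items():
            if times.size < _mod.MIN_EVENTS:
                continue
            res = _mod.modulation_test(tr, times, cls)
            per_class[cls] = res
            mod_rows.append(
                {
                    "unit_id": res.unit_id,
                    "event_class": cls,
                    "n_events": res.n_events,
                    "rate_bl_hz": res.rate_baseline_hz,
                    "rate_event_hz": res.rate_event_hz,
                    "p_value": res.p_value,
                    "modulated": res.modulated,
                }
            )
        if {"ripple-like", "pHFO"} <= set(per_class):
            categories[tr.unit_id] = _mod.modulation_overlap(per_class)
    mod_df = pd.DataFrame(mod_rows)
    mod_df.to_csv(out / "modulation.csv", index=False)
    mod_stage = {}
    if len(mod_df):
        for cls, g in mod_df.groupby("event_class"):
            mod_stage[cls] = {
                "n_units": int(len(g)),
                "n_modulated": int(g.modulated.sum()),
                "proportion_modulated": float(g.modulated.mean()),
            }
    if categories:
        cats = pd.Series(list(categories.values()))
        mod_stage["overlap_categories"] = cats.value_counts().to_dict()
    report["stages"]["modulation"] = mod_stage

    # ---- spatial coding ----------------------------------------------
    spatial_rows = []
    peaks_by_unit: dict[int, list[float]] = {tr.unit_id: [] for tr in spikes}
    if track is not None:
        for ei, ep in epochs.foraging():
            for tr in spikes:
                m = _spatial.build_rate_map(tr, track, ep)
                peak = m.peak_hz
                peaks_by_unit[tr.unit_id].append(peak)
                row = {"unit_id": tr.unit_id, "epoch": ei, "peak_hz": peak}
                if peak >= _spatial.ACTIVE_PEAK_HZ:
                    row["info_bits"] = _spatial.spatial_information(m)
                    row["sparsity"] = _spatial.spatial_sparsity(m)
                    row["splithalf_r"] = _spatial.split_half_correlation(
                        tr, track, ep
                    )
                spatial_rows.append(row)
    spatial_df = pd.DataFrame(spatial_rows)
    spatial_df.to_csv(out / "spatial.csv", index=False)
    sp_stage = {}
    if len(spatial_df):
        sp_stage["active_proportion"] = _spatial.active_proportion(peaks_by_unit)
        act = spatial_df.dropna(subset=["info_bits"]) if "info_bits" in spatial_df else spatial_df.iloc[0:0]
        if len(act):
            sp_stage["info_median_bits"] = float(act.info_bits.median())
            sp_stage["sparsity_median"] = float(act.sparsity.median())
            sp_stage["splithalf_median_r"] = float(act.splithalf_r.median())
    report["stages"]["spatial"] = sp_stage

    # ---- pHFO spatial impact ------------------------------------------
    if phfo_times.size == 0 or track is None:
        report["stages"]["impact"] = {"notice": "skipped: no pHFO events"}
    else:
        impact_stage: dict = {"epochs": [], "downsample": []}
        ds_results = []
        for ei, ep in epochs.foraging():
            n_in = int(ep.contains(phfo_times).sum())
            if n_in <= _impact.MIN_EVENTS:
                impact_stage["epochs"].append(
                    {"epoch": ei, "n_phfo": n_in, "notice": "too few events"}
                )
                continue
            shuf = _impact.shuffle_event_info(
                phfo_times, track, ep, config.n_shuffles,
                seed=stage_seeds["shuffle"] + ei,
            )
            impact_stage["epochs"].append(
                {
                    "epoch": ei,
                    "n_phfo": n_in,
                    "info_actual": shuf.info_actual,
                    "band": [shuf.band_lo, shuf.band_hi],
                    "verdict": shuf.verdict,
                }
            )
            for tr in spikes:
                try:
                    ds = _impact.targeted_downsample(
                        tr, phfo_times, track, ep, config.n_random_downsamples,
                        seed=stage_seeds["downsample"] + 1000 * ei + tr.unit_id,
                    )
                except ValueError:
                    continue
                ds_results.append(ds)
                impact_stage["downsample"].append(
                    {
                        "unit_id": ds.unit_id,
                        "epoch": ei,
                        "n_spikes_in_phfo": ds.n_spikes_in_phfo,
                        "percent": ds.percent_of_total,
                        "improvement": ds.improvement,
                        "significant": ds.significant,
                    }
                )
        try:
            slope, intercept, r2 = _impact.improvement_vs_fraction(ds_results)
            impact_stage["improvement_fit"] = {
                "slope": slope, "intercept": intercept, "r_squared": r2,
            }
        except ValueError as exc:
            impact_stage["improvement_fit"] = {"notice": str(exc)}
        report["stages"]["impact"] = impact_stage

    # ---- ground-truth recovery (synthetic runs only) -------------------
    if truth is not None:
        det_times = np.array([ev.peak_time_s for ev in events])
        det_labels = np.array([ev.label for ev in events])
        n_hit, n_cls = 0, 0
        for r in truth.events.itertuples():
            j = np.flatnonzero(np.abs(det_times - r.time_s) < 0.05)
            if j.size:
                n_hit += 1
                want = "pHFO" if r.cls == "pHFO" else "ripple-like"
                got = det_labels[j[np.argmin(np.abs(det_times[j] - r.time_s))]]
                n_cls += got == want
        report["stages"]["recovery"] = {
            "n_scheduled": int(len(truth.events)),
            "recall": n_hit / max(len(truth.events), 1),
            "class_agreement": n_cls / max(n_hit, 1),
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
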