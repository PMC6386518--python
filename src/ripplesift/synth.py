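"""Synthetic session generator with ground truth.

Produces complete recording sessions — pyramidal- and radiatum-layer LFP,
place-modulated spike trains, a foraging trajectory, and rest/forage epoch
structure — with the statistical structure the downstream analysis
assumes, plus a ground-truth table for recovery testing.

The generator emulates the regularities of CA1 recordings in the chronic
kainate model of temporal-lobe epilepsy:

* sharp-wave ripples (~186 Hz oscillation riding a ~245 uV slow sharp
  wave) occurring only during immobility;
* pathological HFOs (~246 Hz riding ~520 uV interictal-spike transients)
  occurring at any running speed, followed by a transient suppression of
  theta;
* movement-gated 5-12 Hz theta in stratum radiatum;
* Poisson place-field spiking whose rate is multiplied by a per-unit gain
  during the 100 ms core of each event.

Event waveforms are Hann-windowed sinusoids; sharp waves are Gaussian
bumps (SD 40 ms) and interictal spikes biphasic spike-wave transients —
the simplest shapes that satisfy every detector and classifier criterion.
The trajectory is an Ornstein-Uhlenbeck velocity process reflected at the
arena walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .core import Epoch, EpochTable, LfpSignal, PositionTrack, SpikeTrain

__all__ = [
    "EventClassParams",
    "UnitSpec",
    "SessionSpec",
    "SyntheticGroundTruth",
    "SyntheticSession",
    "generate_trajectory",
    "schedule_events",
    "synthesize_lfp",
    "synthesize_spikes",
    "simulate_session",
    "control_spec",
    "epileptic_spec",
]

REST_BOX_XY = (-30.0, -30.0)  # holding-box position, outside the arena

# median speed of a 2-D isotropic Gaussian velocity = sigma * sqrt(2 ln 2)
_RAYLEIGH_MEDIAN = np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class EventClassParams:
    """Waveform and occurrence parameters of one event class.

    Medians mirror the epileptic-hippocampus literature: ripple-class
    events oscillate near 186 Hz on ~245 uV sharp waves, pathological
    HFOs near 246 Hz on ~520 uV interictal spikes.  Within-session spread
    is narrower than pooled across-animal interquartile ranges.
    """

    name: str
    osc_freq_hz: float
    osc_freq_sd_hz: float
    n_cycles: float
    filtered_amp_uv: float
    envelope_amp_uv: float
    envelope_shape: str  # "sharp_wave" | "interictal_spike"
    rate_per_s: float
    state: str  # "immobility" | "any"
    amp_cv: float = 0.30
    envelope_cv: float = 0.25
    envelope_width_ms: float = 40.0  # Gaussian SD (sharp wave) / spike sigma

    def __post_init__(self) -> None:
        if self.rate_per_s < 0:
            raise ValueError("event rate must be non-negative")
        if self.state not in ("immobility", "any"):
            raise ValueError(f"unknown state {self.state!r}")


def _default_classes() -> dict[str, EventClassParams]:
    return {
        "ripple": EventClassParams(
            name="ripple",
            osc_freq_hz=186.0,
            osc_freq_sd_hz=12.0,
            n_cycles=12.0,
            filtered_amp_uv=100.0,
            envelope_amp_uv=245.0,
            envelope_shape="sharp_wave",
            rate_per_s=0.20,
            state="immobility",
        ),
        "pHFO": EventClassParams(
            name="pHFO",
            osc_freq_hz=246.0,
            osc_freq_sd_hz=12.0,
            n_cycles=10.0,
            filtered_amp_uv=220.0,
            envelope_amp_uv=520.0,
            envelope_shape="interictal_spike",
            rate_per_s=0.05,
            state="any",
            envelope_width_ms=12.0,
        ),
    }


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth tuning of one synthetic unit."""

    unit_id: int
    field_x_cm: float
    field_y_cm: float
    field_width_cm: float
    peak_rate_hz: float
    baseline_rate_hz: float
    gains: dict = field(default_factory=dict)  # class name -> rate gain

    def gain(self, cls: str) -> float:
        return float(self.gains.get(cls, 1.0))


@dataclass(frozen=True)
class SessionSpec:
    """Full description of a synthetic session.

    Defaults describe a standard session: 5 min rest, 10 min foraging in a
    1 m circular arena, 5 min rest, with both event classes present.
    """

    epochs: tuple = (("rest", 300.0), ("forage", 600.0), ("rest", 300.0))
    lfp_rate_hz: float = 2000.0
    tracking_rate_hz: float = 30.0
    arena_shape: str = "circle"  # "circle" (diameter) | "square" (side)
    arena_size_cm: float = 100.0
    classes: dict = field(default_factory=_default_classes)
    immobility_threshold_cm_s: float = 5.0
    min_event_gap_s: float = 0.5
    edge_margin_s: float = 2.5
    target_median_speed_cm_s: float = 6.4
    speed_tau_s: float = 0.8
    steering_rate_rad_s: float = 2.5  # how sharply the animal turns toward food
    food_reach_cm: float = 4.0
    n_units: int = 20
    units: tuple = ()  # optional explicit UnitSpec tuple; else drawn from seed
    modulated_fraction: dict = field(
        default_factory=lambda: {"ripple": 0.5, "pHFO": 0.25}
    )
    modulation_gain: float = 5.0
    baseline_rate_hz: float = 0.5
    peak_rate_hz: float = 6.0
    field_width_cm: float = 10.0
    silent_fraction: float = 0.0
    noise_sd_uv: float = 15.0
    radiatum_noise_sd_uv: float = 20.0
    theta_freq_hz: float = 8.0
    theta_amp_uv: float = 150.0
    theta_rest_gain: float = 0.2
    theta_suppression_depth: float = 0.6
    theta_suppression_s: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lfp_rate_hz <= 1600.0:
            raise ValueError("LFP rate must exceed twice the 800 Hz passband edge")
        if self.arena_size_cm <= 0:
            raise ValueError("arena size must be positive")
        for ep in self.epochs:
            if ep[1] <= 0:
                raise ValueError("epoch durations must be positive")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.epochs))

    def epoch_table(self) -> EpochTable:
        out, t = [], 0.0
        for label, dur in self.epochs:
            out.append(Epoch(label, t, t + dur))
            t += dur
        return EpochTable(out)

    def draw_units(self, rng: np.random.Generator) -> list[UnitSpec]:
        if self.units:
            return list(self.units)
        units = []
        half = self.arena_size_cm / 2.0
        for uid in range(self.n_units):
            if self.arena_shape == "circle":
                r = half * np.sqrt(rng.uniform(0, 0.85))
                ang = rng.uniform(0, 2 * np.pi)
                fx, fy = half + r * np.cos(ang), half + r * np.sin(ang)
            else:
                fx, fy = rng.uniform(0.1, 0.9, 2) * self.arena_size_cm
            silent = rng.uniform() < self.silent_fraction
            peak = 0.0 if silent else self.peak_rate_hz * rng.lognormal(0.0, 0.3)
            gains = {
                cls: (
                    self.modulation_gain
                    if rng.uniform() < self.modulated_fraction.get(cls, 0.0)
                    else 1.0
                )
                for cls in self.classes
            }
            units.append(
                UnitSpec(
                    unit_id=uid,
                    field_x_cm=float(fx),
                    field_y_cm=float(fy),
                    field_width_cm=self.field_width_cm,
                    peak_rate_hz=float(peak),
                    baseline_rate_hz=self.baseline_rate_hz,
                    gains=gains,
                )
            )
        return units


def control_spec(**overrides) -> SessionSpec:
    """Spec of a control session: ripple events only, higher modulation."""
    classes = {"ripple": _default_classes()["ripple"]}
    kw = dict(
        classes=classes,
        modulated_fraction={"ripple": 0.91},
        theta_suppression_depth=0.0,
    )
    kw.update(overrides)
    return SessionSpec(**kw)


def epileptic_spec(**overrides) -> SessionSpec:
    """Spec of an epileptic session: ripple-like plus pHFO events."""
    return SessionSpec(**overrides)


@dataclass
class SyntheticGroundTruth:
    """Scheduled events and true unit tuning for recovery testing."""

    events: pd.DataFrame  # time_s, cls, freq_hz, envelope_uv, amp_uv, speed, epoch
    units: list[UnitSpec] = field(default_factory=list)

    def modulation_flags(self) -> pd.DataFrame:
        rows = [
            {"unit_id": u.unit_id, "cls": c, "modulated": g > 1.0}
            for u in self.units
            for c, g in u.gains.items()
        ]
        return pd.DataFrame(rows)


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, stream]))


class _FoodGrid:
    """Coarse grid of remaining food: targets come from unvisited cells.

    Scattered crumbs deplete where the animal has searched, so the next
    goal is drawn from the least-visited 5 cm cells; this is what makes a
    real forager's path space-filling.
    """

    def __init__(self, spec: SessionSpec, rng: np.random.Generator):
        self.cell = 5.0
        n = int(np.ceil(spec.arena_size_cm / self.cell))
        cx = (np.arange(n) + 0.5) * self.cell
        X, Y = np.meshgrid(cx, cx)
        half = spec.arena_size_cm / 2.0
        if spec.arena_shape == "circle":
            inside = np.hypot(X - half, Y - half) <= half - 1.0
        else:
            inside = np.ones_like(X, dtype=bool)
        self.centers = np.column_stack([X[inside], Y[inside]])
        self.visits = np.zeros(len(self.centers))
        self.rng = rng

    def mark(self, pos: np.ndarray) -> None:
        d2 = np.sum((self.centers - pos) ** 2, axis=1)
        self.visits[np.argmin(d2)] += 1

    def draw_target(self) -> np.ndarray:
        lo = self.visits == self.visits.min()
        idx = self.rng.choice(np.flatnonzero(lo))
        return self.centers[idx] + self.rng.uniform(-1.5, 1.5, 2)


def generate_trajectory(spec: SessionSpec, seed: int | None = None) -> PositionTrack:
    """Random-foraging trajectory: OU velocity reflected at the walls.

    Foraging epochs follow an Ornstein-Uhlenbeck velocity process whose
    stationary speed distribution has the configured median; a steering
    term rotates the velocity toward a randomly relocating food target,
    which emulates searching for scattered crumbs and makes the path
    space-filling without changing the speed distribution (rotation
    preserves speed).  During rest epochs the animal sits motionless in
    the holding box.
    """
    seed = spec.seed if seed is None else seed
    rng = _child_rng(seed, 1)
    fs = spec.tracking_rate_hz
    dt = 1.0 / fs
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) * dt
    x = np.full(n, REST_BOX_XY[0])
    y = np.full(n, REST_BOX_XY[1])

    tau = spec.speed_tau_s
    sigma_v = spec.target_median_speed_cm_s / _RAYLEIGH_MEDIAN
    half = spec.arena_size_cm / 2.0
    center = np.array([half, half])

    for ep in spec.epoch_table():
        if ep.label != "forage":
            continue
        i0, i1 = int(round(ep.start_s * fs)), int(round(ep.end_s * fs))
        m = i1 - i0
        if m <= 0:
            raise ValueError("foraging epoch too short")
        pos = center.copy()
        vel = rng.normal(0, sigma_v, 2)
        noise = rng.normal(size=(m, 2))
        px, py = np.empty(m), np.empty(m)
        a = np.exp(-dt / tau)
        b = sigma_v * np.sqrt(1 - a**2)
        food = _FoodGrid(spec, rng)
        target = food.draw_target()
        max_turn = spec.steering_rate_rad_s * dt
        for i in range(m):
            vel = a * vel + b * noise[i]
            if spec.steering_rate_rad_s > 0:
                food.mark(pos)
                if np.hypot(*(target - pos)) < spec.food_reach_cm:
                    target = food.draw_target()
                heading = np.arctan2(vel[1], vel[0])
                want = np.arctan2(target[1] - pos[1], target[0] - pos[0])
                dang = (want - heading + np.pi) % (2 * np.pi) - np.pi
                turn = np.clip(dang, -max_turn, max_turn)
                c, s = np.cos(turn), np.sin(turn)
                vel = np.array([c * vel[0] - s * vel[1], s * vel[0] + c * vel[1]])
            pos = pos + vel * dt
            if spec.arena_shape == "circle":
                d = pos - center
                r = np.hypot(*d)
                if r > half:
                    nrm = d / r
                    pos = center + nrm * (2 * half - r)
                    vel = vel - 2 * np.dot(vel, nrm) * nrm
            else:
                for k in range(2):
                    if pos[k] < 0:
                        pos[k] = -pos[k]
                        vel[k] = -vel[k]
                    elif pos[k] > spec.arena_size_cm:
                        pos[k] = 2 * spec.arena_size_cm - pos[k]
                        vel[k] = -vel[k]
            px[i], py[i] = pos
        x[i0:i1], y[i0:i1] = px, py
    return PositionTrack(t, x, y)


def schedule_events(
    spec: SessionSpec,
    track: PositionTrack,
    seed: int | None = None,
) -> SyntheticGroundTruth:
    """Draw ground-truth event times and per-event waveform parameters.

    Classes with ``state="any"`` are homogeneous Poisson over the whole
    session; ``state="immobility"`` classes are thinned to times when the
    tracked speed is below the immobility threshold.  A minimum gap of
    500 ms between events is enforced greedily (earlier event wins).
    """
    seed = spec.seed if seed is None else seed
    rng = _child_rng(seed, 2)
    T = spec.duration_s
    speed = track.speed()

    expected = sum(c.rate_per_s for c in spec.classes.values()) * T
    if expected * spec.min_event_gap_s > 0.6 * T:
        raise ValueError(
            "event rates too high for the minimum inter-event gap constraint"
        )

    rows = []
    epochs = spec.epoch_table()
    for cls in spec.classes.values():
        n_cand = rng.poisson(cls.rate_per_s * T)
        times = np.sort(rng.uniform(0.0, T, n_cand))
        if cls.state == "immobility":
            sp = track.speed_at(times) if times.size else np.array([])
            times = times[sp < spec.immobility_threshold_cm_s]
        for t0 in times:
            ei = epochs.epoch_of(t0)
            ep = epochs.epochs[ei] if ei >= 0 else None
            if ep is None:
                continue
            if (
                t0 - ep.start_s < spec.edge_margin_s
                or ep.end_s - t0 < spec.edge_margin_s
            ):
                continue
            rows.append(
                {
                    "time_s": float(t0),
                    "cls": cls.name,
                    "freq_hz": float(rng.normal(cls.osc_freq_hz, cls.osc_freq_sd_hz)),
                    "envelope_uv": float(
                        cls.envelope_amp_uv
                        * rng.lognormal(0.0, np.sqrt(np.log(1 + cls.envelope_cv**2)))
                    ),
                    "amp_uv": float(
                        cls.filtered_amp_uv
                        * rng.lognormal(0.0, np.sqrt(np.log(1 + cls.amp_cv**2)))
                    ),
                    "speed_cm_s": float(track.speed_at(t0)),
                    "epoch": ei,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["time_s", "cls", "freq_hz", "envelope_uv", "amp_uv",
                 "speed_cm_s", "epoch"],
    ).sort_values("time_s", ignore_index=True)

    keep, last_t = [], -np.inf
    for r in df.itertuples():
        if r.time_s - last_t >= spec.min_event_gap_s:
            keep.append(r.Index)
            last_t = r.time_s
    return SyntheticGroundTruth(events=df.loc[keep].reset_index(drop=True))


def _event_waveform(cls: EventClassParams, freq: float, amp: float, env: float,
                    fs: float):
    """Oscillation + slow-envelope samples of one event, centered on t=0."""
    dur = cls.n_cycles / freq
    n_osc = max(3, int(round(dur * fs)))
    t_osc = (np.arange(n_osc) - (n_osc - 1) / 2) / fs
    osc = amp * np.hanning(n_osc) * np.sin(2 * np.pi * freq * t_osc)

    if cls.envelope_shape == "sharp_wave":
        sd = cls.envelope_width_ms / 1000.0
        n_env = int(round(8 * sd * fs))
        t_env = (np.arange(n_env) - (n_env - 1) / 2) / fs
        envelope = -env * np.exp(-(t_env**2) / (2 * sd**2))
    elif cls.envelope_shape == "interictal_spike":
        # sharp negative spike followed by a slower positive wave; the
        # wave's tail overlaps the spike peak, so the shape is rescaled by
        # the analytic overlap factor to make the net peak equal `env`
        s1 = cls.envelope_width_ms / 1000.0
        s2 = 2.0 * s1
        n_env = int(round((6 * s1 + 8 * s2) * fs))
        t_env = (np.arange(n_env) - (n_env - 1) / 2) / fs
        overlap = 0.45 * np.exp(-((3.5 * s1) ** 2) / (2 * s2**2))
        envelope = env / (1.0 - overlap) * (
            -np.exp(-(t_env**2) / (2 * s1**2))
            + 0.45 * np.exp(-((t_env - 3.5 * s1) ** 2) / (2 * s2**2))
        )
    else:
        raise ValueError(f"unknown envelope shape {cls.envelope_shape!r}")
    return osc, envelope


def synthesize_lfp(
    spec: SessionSpec,
    truth: SyntheticGroundTruth,
    track: PositionTrack,
    seed: int | None = None,
) -> tuple[LfpSignal, LfpSignal]:
    """Pyramidal- and radiatum-layer LFP traces for the scheduled events.

    Pyramidal layer: white noise + per-event windowed oscillation on its
    slow envelope transient.  Radiatum: speed-gated theta sinusoid with
    configurable post-pHFO suppression, plus the interictal-spike
    transient (shared across layers) for pHFO-class events.
    """
    seed = spec.seed if seed is None else seed
    rng = _child_rng(seed, 3)
    fs = spec.lfp_rate_hz
    n = int(round(spec.duration_s * fs))
    t_end = n / fs

    pyr = rng.normal(0.0, spec.noise_sd_uv, n)
    rad = rng.normal(0.0, spec.radiatum_noise_sd_uv, n)

    # movement-gated theta amplitude, interpolated to the LFP time base
    tt = np.arange(n) / fs
    sp = np.interp(tt, track.t_s, track.speed())
    gate = spec.theta_rest_gain + (1 - spec.theta_rest_gain) / (
        1 + np.exp(-(sp - spec.immobility_threshold_cm_s) / 1.5)
    )
    amp = spec.theta_amp_uv * gate

    for r in truth.events.itertuples():
        if r.cls in spec.classes and spec.classes[r.cls].envelope_shape == (
            "interictal_spike"
        ):
            i0 = int(round(r.time_s * fs))
            j0, j1 = i0, min(n, i0 + int(round(spec.theta_suppression_s * fs)))
            amp[j0:j1] *= 1.0 - spec.theta_suppression_depth

    rad += amp * np.sin(2 * np.pi * spec.theta_freq_hz * tt)

    def _add(dst: np.ndarray, wave: np.ndarray, center_idx: int) -> None:
        i0 = center_idx - wave.size // 2
        a, b = max(i0, 0), min(i0 + wave.size, n)
        if a < b:
            dst[a:b] += wave[a - i0 : b - i0]

    for r in truth.events.itertuples():
        if r.time_s < 0 or r.time_s > t_end:
            raise ValueError("ground-truth event outside the session")
        cls = spec.classes[r.cls]
        osc, envelope = _event_waveform(cls, r.freq_hz, r.amp_uv, r.envelope_uv, fs)
        ic = int(round(r.time_s * fs))
        _add(pyr, osc, ic)
        _add(pyr, envelope, ic)
        if cls.envelope_shape == "interictal_spike":
            _add(rad, envelope, ic)

    return (
        LfpSignal(pyr, fs, layer="pyramidale"),
        LfpSignal(rad, fs, layer="radiatum"),
    )


def synthesize_spikes(
    spec: SessionSpec,
    truth: SyntheticGroundTruth,
    track: PositionTrack,
    seed: int | None = None,
    units: list[UnitSpec] | None = None,
) -> tuple[list[SpikeTrain], list[UnitSpec]]:
    """Inhomogeneous-Poisson spike trains with place fields and event gains.

    Rate = baseline + peak * Gaussian(distance to field centre); during
    the 100 ms core of each event of class *c* the rate is multiplied by
    the unit's class-*c* gain.  Sampling is piecewise-constant on a 5 ms
    lattice.
    """
    seed = spec.seed if seed is None else seed
    rng = _child_rng(seed, 4)
    if units is None:
        units = spec.draw_units(_child_rng(seed, 5))

    dt = 0.005
    n = int(round(spec.duration_s / dt))
    tt = (np.arange(n) + 0.5) * dt
    x = np.interp(tt, track.t_s, track.x_cm)
    y = np.interp(tt, track.t_s, track.y_cm)

    gain_masks: dict[str, np.ndarray] = {}
    for cls in spec.classes:
        mask = np.zeros(n, dtype=bool)
        for t0 in truth.events.loc[truth.events.cls == cls, "time_s"]:
            a = int(np.floor((t0 - 0.05) / dt))
            b = int(np.ceil((t0 + 0.05) / dt))
            mask[max(a, 0) : min(b, n)] = True
        gain_masks[cls] = mask

    trains = []
    for u in units:
        if u.peak_rate_hz < 0 or u.baseline_rate_hz < 0:
            raise ValueError("unit rates must be non-negative")
        d2 = (x - u.field_x_cm) ** 2 + (y - u.field_y_cm) ** 2
        rate = u.baseline_rate_hz + u.peak_rate_hz * np.exp(
            -d2 / (2 * u.field_width_cm**2)
        )
        for cls, mask in gain_masks.items():
            g = u.gain(cls)
            if g != 1.0:
                rate = np.where(mask, rate * g, rate)
        counts = rng.poisson(rate * dt)
        total = int(counts.sum())
        if total == 0:
            trains.append(SpikeTrain(u.unit_id, np.array([])))
            continue
        idx = np.repeat(np.arange(n), counts)
        times = (idx + rng.uniform(size=total)) * dt
        trains.append(SpikeTrain(u.unit_id, np.sort(times)))
    return trains, units


@dataclass
class SyntheticSession:
    """Bundle of everything one synthetic session produces."""

    spec: SessionSpec
    epochs: EpochTable
    track: PositionTrack
    lfp_pyr: LfpSignal
    lfp_rad: LfpSignal
    spikes: list[SpikeTrain]
    truth: SyntheticGroundTruth


def simulate_session(spec: SessionSpec, seed: int | None = None) -> SyntheticSession:
    """Generate a full session (trajectory, events, LFP, spikes)."""
    seed = spec.seed if seed is None else seed
    track = generate_trajectory(spec, seed)
    truth = schedule_events(spec, track, seed)
    lfp_pyr, lfp_rad = synthesize_lfp(spec, truth, track, seed)
    spikes, units = synthesize_spikes(spec, truth, track, seed)
    truth.units = units
    return SyntheticSession(
        spec=spec,
        epochs=spec.epoch_table(),
        track=track,
        lfp_pyr=lfp_pyr,
        lfp_rad=lfp_rad,
        spikes=spikes,
        truth=truth,
    )
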