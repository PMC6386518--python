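"""Generator contracts: trajectory statistics, event scheduling, waveforms."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from ripplesift.core import Epoch
from ripplesift.spatial import build_rate_map
from ripplesift.synth import (
    EventClassParams,
    SessionSpec,
    epileptic_spec,
    generate_trajectory,
    schedule_events,
    simulate_session,
    synthesize_lfp,
    synthesize_spikes,
)

FORAGE = Epoch("forage", 300.0, 900.0)


def arena_interior_mask(m, spec):
    cx = 0.5 * (m.x_edges[:-1] + m.x_edges[1:])
    cy = 0.5 * (m.y_edges[:-1] + m.y_edges[1:])
    X, Y = np.meshgrid(cx, cy)
    half = spec.arena_size_cm / 2
    # bins whose full extent lies inside the circular wall
    return np.hypot(X - half, Y - half) <= half - 2.5 * np.sqrt(2)


class TestTrajectory:
    def test_zero_speed_spec_stays_at_one_point(self):
        spec = replace(epileptic_spec(), target_median_speed_cm_s=0.0,
                       steering_rate_rad_s=0.0)
        tr = generate_trajectory(spec, seed=3)
        sel = FORAGE.contains(tr.t_s)
        assert np.ptp(tr.x_cm[sel]) == 0 and np.ptp(tr.y_cm[sel]) == 0
        # exclude the box->arena teleport at the epoch boundary, which the
        # 250 ms position smoothing smears over a few samples
        interior = (tr.t_s >= 300.5) & (tr.t_s < 899.5)
        assert np.allclose(tr.speed()[interior], 0.0)

    def test_positions_inside_arena(self):
        spec = epileptic_spec(seed=4)
        tr = generate_trajectory(spec)
        sel = FORAGE.contains(tr.t_s)
        r = np.hypot(tr.x_cm[sel] - 50, tr.y_cm[sel] - 50)
        assert r.max() <= 50.0 + 1e-9

    def test_coverage_default_epoch_seed1(self):
        """A 10-min default foraging epoch visits >=95% of arena bins."""
        spec = epileptic_spec(seed=1)
        tr = generate_trajectory(spec)
        m = build_rate_map(np.array([]), tr, FORAGE, bounds=(0, 100, 0, 100))
        interior = arena_interior_mask(m, spec)
        assert m.visited[interior].mean() >= 0.95

    def test_median_speed_near_target(self):
        spec = epileptic_spec(seed=1)
        tr = generate_trajectory(spec)
        med = np.median(tr.speed()[FORAGE.contains(tr.t_s)])
        assert abs(med - spec.target_median_speed_cm_s) < 1.0

    def test_determinism(self):
        spec = epileptic_spec(seed=11)
        a, b = generate_trajectory(spec), generate_trajectory(spec)
        assert np.array_equal(a.x_cm, b.x_cm) and np.array_equal(a.y_cm, b.y_cm)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SessionSpec(epochs=(("forage", -5.0),))
        with pytest.raises(ValueError):
            SessionSpec(arena_size_cm=0.0)
        with pytest.raises(ValueError):
            SessionSpec(lfp_rate_hz=1000.0)


class TestScheduling:
    def test_zero_phfo_rate_gives_only_ripples(self):
        spec = epileptic_spec(seed=5)
        classes = dict(spec.classes)
        classes["pHFO"] = replace(classes["pHFO"], rate_per_s=0.0)
        spec = replace(spec, classes=classes)
        truth = schedule_events(spec, generate_trajectory(spec))
        assert set(truth.events.cls) == {"ripple"}

    def test_phfo_count_poisson_consistent(self):
        """0.1 /s over 600 s of eligible time gives a Poisson-consistent count."""
        spec = replace(
            epileptic_spec(seed=6),
            epochs=(("forage", 600.0),),
            classes={
                "pHFO": replace(_phfo_params(), rate_per_s=0.1)
            },
            min_event_gap_s=0.0,
            edge_margin_s=0.0,
        )
        n = len(schedule_events(spec, generate_trajectory(spec)).events)
        lam = 60.0
        lo, hi = stats.poisson.ppf([0.025, 0.975], lam)
        assert lo <= n <= hi

    def test_ripples_only_at_immobility(self, default_session):
        ev = default_session.truth.events
        ripple_speeds = ev.loc[ev.cls == "ripple", "speed_cm_s"]
        assert (ripple_speeds < default_session.spec.immobility_threshold_cm_s).all()

    def test_min_gap_enforced(self, default_session):
        t = default_session.truth.events.time_s.to_numpy()
        assert np.diff(t).min() >= default_session.spec.min_event_gap_s

    def test_infeasible_rates_rejected(self):
        spec = replace(
            epileptic_spec(seed=7),
            classes={"pHFO": replace(_phfo_params(), rate_per_s=5.0)},
        )
        with pytest.raises(ValueError, match="gap"):
            schedule_events(spec, generate_trajectory(spec))

    def test_phfo_speeds_match_occupancy(self):
        """pHFO times sample the speed distribution of the session itself."""
        spec = replace(
            epileptic_spec(seed=8),
            epochs=(("forage", 2000.0),),
            classes={"pHFO": replace(_phfo_params(), rate_per_s=0.1)},
        )
        tr = generate_trajectory(spec)
        truth = schedule_events(spec, tr)
        ev_speeds = truth.events.speed_cm_s.to_numpy()[:200]
        occ_speeds = tr.speed()[:: tr.n // 200]
        p = stats.ranksums(ev_speeds, occ_speeds).pvalue
        assert p > 0.01


def _phfo_params() -> EventClassParams:
    from ripplesift.synth import _default_classes

    return _default_classes()["pHFO"]


class TestLfpSynthesis:
    def test_no_events_zero_noise_gives_zero_trace(self):
        spec = replace(
            epileptic_spec(seed=9), noise_sd_uv=0.0,
            classes={}, epochs=(("rest", 10.0),),
        )
        tr = generate_trajectory(spec)
        truth = schedule_events(spec, tr)
        pyr, _ = synthesize_lfp(spec, truth, tr)
        assert np.allclose(pyr.samples, 0.0)

    def test_ripple_burst_spectral_peak(self):
        """186 Hz scheduled burst shows a ~186 Hz FFT peak in 100 ms around it."""
        import pandas as pd

        spec = replace(epileptic_spec(seed=10), noise_sd_uv=0.0,
                       epochs=(("rest", 20.0),))
        tr = generate_trajectory(spec)
        truth = schedule_events(spec, tr)
        truth.events = pd.DataFrame(
            [{"time_s": 10.0, "cls": "ripple", "freq_hz": 186.0,
              "envelope_uv": 0.0, "amp_uv": 100.0, "speed_cm_s": 0.0,
              "epoch": 0}]
        )
        pyr, _ = synthesize_lfp(spec, truth, tr)
        fs = pyr.rate_hz
        seg = pyr.samples[int(9.95 * fs): int(10.05 * fs)]
        spec_pow = np.abs(np.fft.rfft(seg, n=int(fs))) ** 2
        freqs = np.fft.rfftfreq(int(fs), 1 / fs)
        band = (freqs > 50) & (freqs < 600)
        peak = freqs[band][np.argmax(spec_pow[band])]
        assert abs(peak - 186.0) <= 5.0

    def test_determinism(self):
        spec = epileptic_spec(seed=12)
        tr = generate_trajectory(spec)
        truth = schedule_events(spec, tr)
        a, _ = synthesize_lfp(spec, truth, tr)
        b, _ = synthesize_lfp(spec, truth, tr)
        assert np.array_equal(a.samples, b.samples)


class TestSpikeSynthesis:
    def test_zero_peak_rate_and_baseline_gives_empty_train(self):
        from ripplesift.synth import UnitSpec

        spec = replace(epileptic_spec(seed=13), epochs=(("forage", 60.0),))
        tr = generate_trajectory(spec)
        truth = schedule_events(spec, tr)
        units = [UnitSpec(0, 50, 50, 10, 0.0, 0.0)]
        trains, _ = synthesize_spikes(spec, truth, tr, units=units)
        assert trains[0].n == 0

    def test_unmodulated_counts_match_field_expectation(self):
        """With all gains 1, event-window counts follow the field rate."""
        from ripplesift.synth import UnitSpec

        spec = replace(epileptic_spec(seed=14), epochs=(("rest", 600.0),))
        tr = generate_trajectory(spec)
        truth = schedule_events(spec, tr)
        lam = 4.0  # baseline-only unit: homogeneous Poisson at lam
        units = [UnitSpec(0, 50, 50, 10, 0.0, lam)]
        trains, _ = synthesize_spikes(spec, truth, tr, units=units)
        n = trains[0].n
        T = 600.0
        assert abs(n - lam * T) < 4 * np.sqrt(lam * T)

    def test_modulated_unit_detected(self):
        """Gain-5 ripple modulation over >=50 events is flagged p<0.05."""
        from ripplesift.modulation import modulation_test
        from ripplesift.synth import UnitSpec

        spec = replace(epileptic_spec(seed=15), epochs=(("rest", 600.0),))
        tr = generate_trajectory(spec)
        truth = schedule_events(spec, tr)
        ev = truth.events.query("cls == 'ripple'").time_s.to_numpy()
        assert len(ev) >= 50
        units = [UnitSpec(0, 50, 50, 10, 0.0, 2.0, {"ripple": 5.0})]
        trains, _ = synthesize_spikes(spec, truth, tr, units=units)
        res = modulation_test(trains[0], ev)
        assert res.modulated and res.direction > 0

    def test_determinism(self, default_session):
        ses = default_session
        trains, _ = synthesize_spikes(
            ses.spec, ses.truth, ses.track, units=ses.truth.units
        )
        assert all(
            np.array_equal(a.times_s, b.times_s)
            for a, b in zip(trains, ses.spikes)
        )
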