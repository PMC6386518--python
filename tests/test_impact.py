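"""Event maps, shuffle nulls, and targeted spike down-sampling."""

from dataclasses import replace

import numpy as np
import pytest

from ripplesift.core import Epoch, SpikeTrain
from ripplesift.impact import (
    event_rate_map,
    improvement_vs_fraction,
    shuffle_event_info,
    spikes_in_events,
    targeted_downsample,
)
from ripplesift.spatial import spatial_information
from ripplesift.synth import epileptic_spec, generate_trajectory

EPOCH = Epoch("forage", 300.0, 900.0)


@pytest.fixture(scope="module")
def track():
    return generate_trajectory(epileptic_spec(seed=60))


def uniform_event_times(track, n, rng):
    sel = np.flatnonzero(EPOCH.contains(track.t_s))
    return np.sort(track.t_s[rng.choice(sel, n, replace=False)])


class TestEventRateMap:
    def test_too_few_events_refused(self, track):
        with pytest.raises(ValueError, match="15"):
            event_rate_map(np.linspace(310, 880, 15), track, EPOCH)

    def test_count_conservation(self, track, rng):
        times = uniform_event_times(track, 20, rng)
        m, info = event_rate_map(times, track, EPOCH)
        assert m.spike_counts.sum() == 20
        assert info > 0  # 20 points cannot tile occupancy evenly

    def test_concentrated_events_high_information(self, track, rng):
        sel = np.flatnonzero(EPOCH.contains(track.t_s))
        # events only where the animal is in the north-east corner
        corner = sel[
            (track.x_cm[sel] > 65) & (track.y_cm[sel] > 65)
        ]
        times = np.sort(track.t_s[rng.choice(corner, 20, replace=False)])
        _, info_corner = event_rate_map(times, track, EPOCH)
        _, info_unif = event_rate_map(
            uniform_event_times(track, 20, rng), track, EPOCH
        )
        assert info_corner > info_unif


class TestShuffleNull:
    def test_zero_shuffles_rejected(self, track, rng):
        with pytest.raises(ValueError):
            shuffle_event_info(
                uniform_event_times(track, 20, rng), track, EPOCH, n_shuffles=0
            )

    def test_confined_events_above_band(self, track, rng):
        sel = np.flatnonzero(EPOCH.contains(track.t_s))
        quad = sel[(track.x_cm[sel] < 50) & (track.y_cm[sel] < 50)]
        times = np.sort(track.t_s[rng.choice(quad, 25, replace=False)])
        res = shuffle_event_info(times, track, EPOCH, n_shuffles=300, seed=1)
        assert res.verdict == "above"

    def test_uniform_events_coverage(self, track):
        """The 5-95 band contains a uniform draw ~90% of the time."""
        rng = np.random.default_rng(61)
        inside = 0
        n_seeds = 60
        for k in range(n_seeds):
            times = uniform_event_times(track, 25, rng)
            res = shuffle_event_info(times, track, EPOCH, n_shuffles=400,
                                     seed=100 + k)
            inside += res.verdict == "inside band"
        assert abs(inside / n_seeds - 0.90) <= 0.08

    def test_rank_uniformity_under_null(self, track):
        """Actual statistic's rank among its own shuffles is ~uniform."""
        rng = np.random.default_rng(62)
        ranks = []
        for k in range(40):
            times = uniform_event_times(track, 25, rng)
            res = shuffle_event_info(times, track, EPOCH, n_shuffles=200,
                                     seed=500 + k)
            ranks.append((res.null_infos < res.info_actual).mean())
        from scipy.stats import kstest

        assert kstest(ranks, "uniform").pvalue > 0.01


def _place_cell_with_contaminant(track, rng, in_field: bool, n_events=25,
                                 contam_frac=0.10):
    """Place-cell spikes plus event-locked contaminant spikes (~10%)."""
    from ripplesift.synth import SyntheticGroundTruth, UnitSpec, synthesize_spikes
    import pandas as pd

    spec = replace(epileptic_spec(seed=60))
    truth = SyntheticGroundTruth(events=pd.DataFrame(
        columns=["time_s", "cls", "freq_hz", "envelope_uv", "amp_uv",
                 "speed_cm_s", "epoch"]))
    unit = UnitSpec(0, 30.0, 30.0, 8.0, 8.0, 0.05)
    trains, _ = synthesize_spikes(spec, truth, track, seed=int(rng.integers(2**31)),
                                  units=[unit])
    base = trains[0].times_s
    base = base[EPOCH.contains(base)]

    sel = np.flatnonzero(EPOCH.contains(track.t_s))
    if in_field:
        d = np.hypot(track.x_cm[sel] - 30.0, track.y_cm[sel] - 30.0)
        pool = sel[d < 8.0]
    else:
        d = np.hypot(track.x_cm[sel] - 30.0, track.y_cm[sel] - 30.0)
        pool = sel[d > 25.0]
    ev_idx = rng.choice(pool, n_events, replace=False)
    events = np.sort(track.t_s[ev_idx])
    n_cont = max(1, int(contam_frac * base.size / (1 - contam_frac)))
    cont_events = rng.choice(events, n_cont, replace=True)
    contaminants = cont_events + rng.uniform(-0.05, 0.05, n_cont)
    spikes = SpikeTrain(0, np.sort(np.concatenate([base, contaminants])))
    return spikes, events


class TestTargetedDownsample:
    def test_spikes_in_events_mask(self):
        mask = spikes_in_events(
            np.array([0.9, 1.04, 1.2, 2.051]), np.array([1.0, 2.0])
        )
        assert mask.tolist() == [False, True, False, False]

    def test_below_one_percent_refused(self, track, rng):
        spikes, events = _place_cell_with_contaminant(track, rng, in_field=False)
        few = SpikeTrain(0, spikes.times_s[~spikes_in_events(
            spikes.times_s, events)])
        with pytest.raises(ValueError):
            targeted_downsample(few, events, track, EPOCH, n_random=50)

    def test_removal_counts_match(self, track, rng):
        spikes, events = _place_cell_with_contaminant(track, rng, in_field=False)
        res = targeted_downsample(spikes, events, track, EPOCH, n_random=50,
                                  seed=7)
        n_epoch = int(EPOCH.contains(spikes.times_s).sum())
        assert res.n_spikes_in_phfo == pytest.approx(
            n_epoch * res.percent_of_total / 100.0
        )

    def test_off_field_contaminants_significant(self, track):
        """Spatially uniform event-locked contaminants: targeted removal
        beats random removal in >=80% of seeds."""
        rng = np.random.default_rng(63)
        hits = 0
        n_seeds = 15
        for _ in range(n_seeds):
            spikes, events = _place_cell_with_contaminant(
                track, rng, in_field=False
            )
            res = targeted_downsample(spikes, events, track, EPOCH,
                                      n_random=300, seed=int(rng.integers(2**31)))
            hits += res.significant and res.improvement > 0
        assert hits / n_seeds >= 0.8

    def test_in_field_contaminants_not_significant(self, track):
        """Contaminants inside the field look like random spikes."""
        rng = np.random.default_rng(64)
        nulls = 0
        n_seeds = 15
        for _ in range(n_seeds):
            spikes, events = _place_cell_with_contaminant(
                track, rng, in_field=True
            )
            res = targeted_downsample(spikes, events, track, EPOCH,
                                      n_random=300, seed=int(rng.integers(2**31)))
            nulls += not res.significant
        assert nulls / n_seeds >= 0.8


class TestImprovementFit:
    def _result(self, pct, imp, sig=True):
        from ripplesift.impact import DownsampleResult

        return DownsampleResult(0, 10, pct, 1.0, 1.0 + imp, imp,
                                np.zeros(3), sig)

    def test_collinear_points_r2_one(self):
        res = [self._result(p, 0.02 * p) for p in (2.0, 5.0, 9.0, 15.0)]
        slope, _, r2 = improvement_vs_fraction(res)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(0.02)

    def test_too_few_significant_refused(self):
        res = [self._result(2.0, 0.1), self._result(3.0, 0.2),
               self._result(4.0, 0.3, sig=False)]
        with pytest.raises(ValueError):
            improvement_vs_fraction(res)

    def test_synthetic_cohort_positive_slope(self, track):
        """Contaminant fractions spanning 2-20% give a positive trend."""
        rng = np.random.default_rng(65)
        results = []
        for frac in np.linspace(0.03, 0.20, 8):
            spikes, events = _place_cell_with_contaminant(
                track, rng, in_field=False, contam_frac=frac
            )
            res = targeted_downsample(spikes, events, track, EPOCH,
                                      n_random=200, seed=int(rng.integers(2**31)))
            results.append(res)
        slope, _, r2 = improvement_vs_fraction(results)
        assert slope > 0 and r2 > 0.5
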