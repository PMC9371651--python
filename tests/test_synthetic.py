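"""Tests of the synthetic trajectory, tuning-spec and event generators."""

import numpy as np
import pytest
from scipy import stats

import dgpop
from dgpop.core import TuningSpec
from dgpop.synthetic import MotionParams, TMazeTiming, make_concentrated_spec


def untuned_spec(n, rate=0.02):
    return TuningSpec(
        baseline_rate=np.full(n, rate),
        place_center=np.zeros((n, 2)),
        place_width=np.ones(n) * 5.0,
        place_gain=np.zeros(n),
        speed_slope=np.zeros(n),
        direction_pref=np.zeros(n),
        direction_concentration=np.zeros(n),
    )


class TestTrajectory:
    def test_frame_count_and_bounds(self):
        traj = dgpop.simulate_of_trajectory(duration=1800.0, frame_rate=3.0, seed=0)
        assert traj.n_frames == 5400
        assert np.all((traj.x >= 0) & (traj.x <= traj.arena_width))
        assert np.all((traj.y >= 0) & (traj.y <= traj.arena_height))

    def test_zero_step_is_stationary(self):
        mp = MotionParams(speed_mean=0.0, speed_sigma=0.0)
        traj = dgpop.simulate_of_trajectory(duration=60.0, motion_params=mp, seed=0)
        assert np.allclose(traj.x, traj.x[0]) and np.allclose(traj.y, traj.y[0])
        kin = dgpop.compute_kinematics(traj)
        assert np.allclose(kin.speed, 0.0)

    def test_covers_most_spatial_bins(self):
        traj = dgpop.simulate_of_trajectory(seed=5)
        kin = dgpop.compute_kinematics(traj)
        state = dgpop.discretize_states(kin, traj)
        assert len(np.unique(state.position_flat)) > 80

    def test_speed_distribution_spans_all_classes(self, of_state):
        _, state = of_state
        frac = np.bincount(state.speed_class, minlength=3) / len(state.speed_class)
        assert np.all(frac > 0.02)

    def test_deterministic_given_seed(self):
        a = dgpop.simulate_of_trajectory(duration=60.0, seed=7)
        b = dgpop.simulate_of_trajectory(duration=60.0, seed=7)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    @pytest.mark.parametrize("bad", [{"duration": -1.0}, {"frame_rate": 0.0}])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            dgpop.simulate_of_trajectory(**bad)


class TestTuningSpec:
    def test_independent_gains_uncorrelated_across_seeds(self):
        # |R| < 0.25 in at least 95% of seeds at n = 70
        hits = 0
        for seed in range(40):
            spec = dgpop.make_tuning_spec(70, "independent", seed=seed)
            r = np.corrcoef(spec.place_gain, np.abs(spec.speed_slope))[0, 1]
            hits += abs(r) < 0.25
        assert hits >= 36

    def test_dependent_gains_positively_coupled(self):
        spec = dgpop.make_tuning_spec(70, "dependent", seed=3)
        r = np.corrcoef(spec.place_gain, np.abs(spec.speed_slope))[0, 1]
        assert r > 0.5

    def test_exclusive_structure_one_strong_type(self):
        spec = dgpop.make_tuning_spec(70, "exclusive", seed=4)
        strengths = np.column_stack(
            [
                spec.place_gain / spec.place_gain.max(),
                spec.speed_slope / spec.speed_slope.max(),
                spec.direction_concentration / spec.direction_concentration.max(),
            ]
        )
        n_strong = (strengths > 0.3).sum(axis=1)
        assert np.all(n_strong <= 1)

    def test_single_neuron_spec_valid(self):
        spec = dgpop.make_tuning_spec(1, "independent", seed=0)
        assert spec.n_neurons == 1
        assert -np.pi < spec.direction_pref[0] <= np.pi

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError, match="structure"):
            dgpop.make_tuning_spec(10, "entangled")

    def test_json_round_trip(self, tmp_path):
        spec = dgpop.make_tuning_spec(5, "independent", seed=9)
        path = tmp_path / "spec.json"
        spec.to_json(path)
        back = TuningSpec.from_json(path)
        assert np.allclose(spec.place_gain, back.place_gain)
        assert back.structure_label == "independent"


class TestGenerateEvents:
    def test_zero_rate_zero_events(self, of_trajectory):
        rec = dgpop.generate_events(of_trajectory, untuned_spec(3, rate=0.0), seed=0)
        assert rec.events.sum() == 0

    def test_untuned_rate_matches_poisson(self):
        # 0.02 Hz x 1800 s = 36 expected events/neuron; total over 50
        # neurons within the Poisson 99% interval
        traj = dgpop.simulate_of_trajectory(duration=1800.0, seed=31)
        rec = dgpop.generate_events(traj, untuned_spec(50), seed=32)
        total = rec.events.sum()
        lo, hi = stats.poisson.interval(0.99, 50 * 36.0)
        assert lo <= total <= hi

    def test_events_binary_and_deterministic(self, of_trajectory):
        a = dgpop.generate_events(of_trajectory, untuned_spec(4, 0.1), seed=8)
        b = dgpop.generate_events(of_trajectory, untuned_spec(4, 0.1), seed=8)
        assert set(np.unique(a.events)) <= {0, 1}
        assert np.array_equal(a.events, b.events)

    def test_strong_place_neuron_fires_in_field(self, of_trajectory):
        n = 1
        spec = TuningSpec(
            baseline_rate=np.array([0.5]),
            place_center=np.array([[20.0, 20.0]]),
            place_width=np.array([5.0]),
            place_gain=np.array([200.0]),
            speed_slope=np.zeros(n),
            direction_pref=np.zeros(n),
            direction_concentration=np.zeros(n),
        )
        rec = dgpop.generate_events(of_trajectory, spec, seed=9)
        ev = rec.events[:, 0].astype(bool)
        assert ev.sum() > 20
        d = np.hypot(of_trajectory.x[ev] - 20.0, of_trajectory.y[ev] - 20.0)
        # the mass of a 2-D Gaussian rate bump within 2 sigma is 1 - e^-2
        frac = np.mean(d <= 2 * 5.0)
        assert 0.78 <= frac <= 0.95
        assert np.median(d) < 2 * 5.0

    def test_neuron_substreams_stable_under_population_size(self, of_trajectory):
        small = dgpop.generate_events(of_trajectory, untuned_spec(2, 0.1), seed=5)
        large = dgpop.generate_events(of_trajectory, untuned_spec(6, 0.1), seed=5)
        assert np.array_equal(small.events[:, 0], large.events[:, 0])


class TestTMaze:
    def test_all_correct_when_rate_one(self):
        sess = dgpop.simulate_tmaze_session(
            n_trials=50, correct_rate=1.0, spec=untuned_spec(2), seed=0
        )
        assert sess.trials["correct"].all()
        assert (sess.trials["free_choice"] != sess.trials["forced_side"]).all()

    def test_chance_rate_with_many_trials(self):
        sess = dgpop.simulate_tmaze_session(
            n_trials=10000, correct_rate=0.5, spec=untuned_spec(1), seed=1
        )
        pct = 100.0 * sess.trials["correct"].mean()
        assert abs(pct - 50.0) < 1.5

    def test_windows_fit_every_trial(self, tmaze_session):
        timing = TMazeTiming()
        for _, tr in tmaze_session.trials.iterrows():
            t0 = tr["trial_id"] * timing.trial_duration
            assert tr["forced_turn_time_s"] + 5.0 <= t0 + timing.trial_duration
            assert tr["free_choice_turn_time_s"] - 6.0 >= t0

    def test_forced_sides_roughly_balanced(self, tmaze_session):
        n_l = (tmaze_session.trials["forced_side"] == "L").sum()
        assert 10 <= n_l <= 40

    def test_bad_timing_rejected(self):
        timing = TMazeTiming(trial_duration=8.0, forced_turn_time=6.0, free_choice_turn_time=7.0)
        with pytest.raises(ValueError):
            dgpop.simulate_tmaze_session(timing_params=timing, spec=untuned_spec(1))

    def test_invalid_correct_rate(self):
        with pytest.raises(ValueError):
            dgpop.simulate_tmaze_session(correct_rate=1.5, spec=untuned_spec(1))


def test_concentrated_spec_disjoint_subpopulations():
    spec = make_concentrated_spec(n_neurons=70, seed=0)
    place = spec.place_gain > 0
    speed = spec.speed_slope > 0
    assert place.sum() == 21 and speed.sum() == 21
    assert not np.any(place & speed)
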