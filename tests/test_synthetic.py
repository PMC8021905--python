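"""Generator contracts: exact events, pendulum geometry, cohort moments."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import cumulative_trapezoid

from gaitfm import (
    ActivitySchedule,
    ActivitySegment,
    CohortSpec,
    GaitProfile,
    LinearChangeModel,
    OutcomeSpec,
    default_cohort_spec,
    pendulum_step_length,
    perturb_sampling,
    simulate_cohort,
    simulate_gait_recording,
)
from gaitfm.preprocessing import GRAVITY_MS2


class TestGaitRecording:
    def test_periodic_walk_has_exact_ic_spacing(self):
        profile = GaitProfile(step_time_mean=0.6, step_time_sd=0.0, noise_sd=0.0)
        schedule = ActivitySchedule.single_walk(30.0)
        _, truth = simulate_gait_recording(profile, schedule, seed=0)
        assert abs(truth.ic_times.size - 50) <= 1
        assert np.allclose(np.diff(truth.ic_times), 0.6)

    def test_step_length_matches_pendulum_formula(self):
        profile = GaitProfile(vertical_excursion_h=0.02, pendulum_length_l=1.0)
        _, truth = simulate_gait_recording(
            profile, ActivitySchedule.single_walk(20.0), seed=0
        )
        expected = 2.0 * np.sqrt(2.0 * 1.0 * 0.02 - 0.02**2)  # 0.3980 m
        assert np.allclose(truth.true_step_lengths, expected, atol=1e-12)
        assert expected == pytest.approx(0.3980, abs=5e-5)

    def test_bout_interval_bounds_all_events(self):
        profile = GaitProfile()
        schedule = ActivitySchedule(
            [
                ActivitySegment("rest", 10.0),
                ActivitySegment("walk", 20.0),
                ActivitySegment("rest", 10.0),
            ]
        )
        _, truth = simulate_gait_recording(profile, schedule, seed=0)
        assert truth.true_bout_intervals == [(10.0, 30.0)]
        assert np.all(truth.ic_times >= 10.0) and np.all(truth.ic_times <= 30.0)

    def test_double_integral_reproduces_excursion(self):
        """Noiseless vertical oscillation integrates back to h within 1%."""
        h = 0.025
        profile = GaitProfile(
            vertical_excursion_h=h, impact_amplitude=0.0, toe_off_amplitude=0.0,
            noise_sd=0.0,
        )
        rec, truth = simulate_gait_recording(
            profile, ActivitySchedule.single_walk(20.0), seed=0
        )
        vert = (rec.accel[:, 0] - 1.0) * GRAVITY_MS2
        for i in range(3, 10):
            i0 = int(round(truth.ic_times[i] * 100))
            i1 = int(round(truth.ic_times[i + 1] * 100))
            seg = vert[i0 : i1 + 1]
            vel = cumulative_trapezoid(seg, dx=0.01, initial=0.0)
            pos = cumulative_trapezoid(vel, dx=0.01, initial=0.0)
            x = np.arange(pos.size)
            line = pos[0] + (pos[-1] - pos[0]) * x / (pos.size - 1)
            assert np.ptp(pos - line) == pytest.approx(h, rel=0.01)

    def test_laterality_alternates_and_moments_recover(self):
        profile = GaitProfile(step_time_mean=0.6, step_time_sd=0.03, step_time_asym=0.04)
        _, truth = simulate_gait_recording(
            profile, ActivitySchedule.single_walk(400.0), seed=5
        )
        sides = truth.laterality
        assert all(a != b for a, b in zip(sides, sides[1:]))
        steps = truth.true_step_times
        assert steps.size >= 500
        assert steps.mean() == pytest.approx(0.6, abs=0.01)
        assert steps.std() == pytest.approx(0.03, abs=0.01)
        left = steps[::2] if sides[0] == "L" else steps[1::2]
        right = steps[1::2] if sides[0] == "L" else steps[::2]
        assert abs(left.mean() - right.mean()) == pytest.approx(0.04, abs=0.01)

    def test_fc_alternates_with_ic(self):
        _, truth = simulate_gait_recording(
            GaitProfile(), ActivitySchedule.single_walk(30.0), seed=2
        )
        # each FC falls strictly between the next IC and the one after
        for i, fc in enumerate(truth.fc_times):
            assert truth.ic_times[i + 1] < fc < truth.ic_times[i + 2]

    def test_same_seed_is_bit_identical(self):
        profile = GaitProfile(step_time_sd=0.02)
        schedule = ActivitySchedule.single_walk(20.0, pad=3.0)
        r1, t1 = simulate_gait_recording(profile, schedule, seed=42)
        r2, t2 = simulate_gait_recording(profile, schedule, seed=42)
        assert np.array_equal(r1.accel, r2.accel)
        assert np.array_equal(t1.ic_times, t2.ic_times)

    def test_degenerate_walk_warns_and_is_empty(self):
        profile = GaitProfile(step_time_mean=0.6)
        schedule = ActivitySchedule([ActivitySegment("walk", 0.3)])
        with pytest.warns(UserWarning, match="shorter than one"):
            _, truth = simulate_gait_recording(profile, schedule, seed=0)
        assert truth.ic_times.size == 0

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            GaitProfile(step_time_mean=0.5, step_time_asym=0.3)
        with pytest.raises(ValueError):
            GaitProfile(vertical_excursion_h=2.0, pendulum_length_l=1.0)
        with pytest.raises(ValueError):
            GaitProfile(noise_sd=-0.1)

    def test_signal_clipped_to_dynamic_range(self):
        profile = GaitProfile(impact_amplitude=7.9, noise_sd=0.5)
        rec, _ = simulate_gait_recording(
            profile, ActivitySchedule.single_walk(10.0), seed=0
        )
        assert np.all(np.abs(rec.accel) <= 8.0)


class TestPerturbSampling:
    def test_identity_when_unperturbed(self, walk_recording):
        rec, _ = walk_recording
        out = perturb_sampling(rec, jitter_sd=0.0, drop_rate=0.0, seed=0)
        assert np.array_equal(out.timestamps, rec.timestamps)
        assert np.array_equal(out.accel, rec.accel)

    def test_drop_rate_keeps_binomial_count(self, walk_recording):
        rec, _ = walk_recording
        n = rec.timestamps.size
        out = perturb_sampling(rec, drop_rate=0.1, seed=3)
        kept = out.timestamps.size
        mean, sd = 0.9 * n, np.sqrt(n * 0.1 * 0.9)
        assert abs(kept - mean) < 5 * sd
        # values unchanged at kept samples
        idx = np.searchsorted(rec.timestamps, out.timestamps)
        assert np.array_equal(rec.accel[idx], out.accel)

    def test_jitter_keeps_monotone_timestamps(self, walk_recording):
        rec, _ = walk_recording
        out = perturb_sampling(rec, jitter_sd=0.002, seed=3)
        dt = np.diff(out.timestamps)
        assert np.all(dt > 0)
        assert np.max(np.abs(dt - 0.01)) > 0  # actually jittered

    def test_extreme_jitter_resampled_not_error(self, walk_recording):
        rec, _ = walk_recording
        out = perturb_sampling(rec, jitter_sd=0.02, seed=3)  # 2x sample period
        assert np.all(np.diff(out.timestamps) > 0)


class TestCohort:
    def test_sample_paired_d_matches_moments(self):
        spec = CohortSpec(
            outcomes=[OutcomeSpec("TUG", 13.36, 7.27, -1.69, 6.90)], n_subjects=10_000
        )
        table = simulate_cohort(spec, seed=0)
        change = table["discharge"] - table["admission"]
        d = change.mean() / change.std(ddof=1)
        assert d == pytest.approx(-1.69 / 6.90, abs=0.02)

    def test_noiseless_linear_model_is_deterministic(self):
        spec = CohortSpec(
            outcomes=[
                OutcomeSpec("y", 10, 2, -1, 2),
                OutcomeSpec("x", 5, 1, -2, 3),
            ],
            n_subjects=50,
            change_model=LinearChangeModel("y", ["x"], np.array([2.0]), noise_sd=0.0),
        )
        table = simulate_cohort(spec, seed=1)
        wide = table.pivot(index="subject_id", columns="outcome", values="admission")
        chg = (
            table.assign(chg=table["discharge"] - table["admission"])
            .pivot(index="subject_id", columns="outcome", values="chg")
        )
        assert np.allclose(chg["y"], 2.0 * chg["x"])
        assert wide.shape == (50, 2)

    def test_missingness_injects_binomial_cells(self):
        spec = default_cohort_spec(n_subjects=24, missingness=0.2)
        table = simulate_cohort(spec, seed=9)
        n_out = table["outcome"].nunique()
        missing = table[["admission", "discharge"]].isna().sum().sum()
        mean = 0.2 * 24 * n_out
        assert abs(missing - mean) < 5 * np.sqrt(mean)

    def test_too_small_cohort_refused(self):
        with pytest.raises(ValueError):
            CohortSpec(outcomes=[OutcomeSpec("y", 1, 1, 0.1, 1)], n_subjects=2)

    def test_same_seed_identical_cohort(self):
        spec = default_cohort_spec(n_subjects=12)
        t1 = simulate_cohort(spec, seed=5)
        t2 = simulate_cohort(spec, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
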