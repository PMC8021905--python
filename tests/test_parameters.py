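"""Step table arithmetic, bout panel, aggregation, step-count ICC."""
import numpy as np
import pandas as pd
import pytest

from gaitfm import (
    ActivitySchedule,
    GaitProfile,
    aggregate_subject,
    compute_step_table,
    detect_events,
    preprocess,
    simulate_gait_recording,
    step_count_validity,
    summarize_bout,
)
from gaitfm.bouts import BoutSegment, WalkingBout
from gaitfm.events import GaitEvents

FS = 100.0


def _periodic_events(n_ics=21, step=0.6, fc_after_next=0.3, start=1.0):
    """ICs every `step` s; each foot's FC `fc_after_next` after the next IC."""
    ics = start + step * np.arange(n_ics)
    fcs = ics[1:] + fc_after_next
    sides = ["L" if i % 2 == 0 else "R" for i in range(n_ics)]
    return GaitEvents(ics, fcs[:-1], sides, cwt_scale=18.0)


def _flat_vertical(duration=16.0):
    t = np.arange(0, duration, 1 / FS)
    return 0.02 * np.sin(2 * np.pi * t / 0.6)  # small oscillation, any shape


class TestStepTable:
    def test_hand_event_arithmetic(self):
        """Periodic gait, toe-off 0.3 s after the contralateral strike."""
        g = _periodic_events()
        steps = compute_step_table(g, _flat_vertical(), FS, pendulum_length=0.9)
        mid = steps.iloc[3]
        assert mid["step_time"] == pytest.approx(0.6)
        assert mid["stride_time"] == pytest.approx(1.2)
        assert mid["stance_time"] == pytest.approx(0.9)
        assert mid["swing_time"] == pytest.approx(0.3)
        assert mid["double_support_time"] == pytest.approx(0.3)
        panel = summarize_bout(steps)
        assert panel["stance_phase_pct"] == pytest.approx(75.0)
        assert panel["swing_phase_pct"] == pytest.approx(25.0)
        assert panel["double_support_phase_pct"] == pytest.approx(25.0)
        assert panel["cadence_spm"] == pytest.approx(100.0)

    def test_pendulum_step_length_closed_form(self):
        profile = GaitProfile(
            vertical_excursion_h=0.02, pendulum_length_l=1.0,
            impact_amplitude=0.0, toe_off_amplitude=0.0, noise_sd=0.0,
        )
        rec, truth = simulate_gait_recording(
            profile, ActivitySchedule.single_walk(20.0, pad=3.0), seed=0
        )
        u = preprocess(rec)
        vert = u.vertical()[u.index_at(3.0) : u.index_at(23.0)]
        from gaitfm.events import assemble_events

        g = assemble_events(truth.ic_times - 3.0, truth.fc_times - 3.0)
        steps = compute_step_table(g, vert, FS, pendulum_length=1.0)
        assert steps[steps["valid"]]["step_length"].mean() == pytest.approx(
            0.3980, rel=0.01
        )

    def test_step_length_vanishes_with_excursion(self):
        from gaitfm import pendulum_step_length

        lengths = [pendulum_step_length(1.0, h) for h in (0.05, 0.02, 0.005, 0.001)]
        assert all(a > b for a, b in zip(lengths, lengths[1:]))
        assert lengths[-1] < 0.1

    def test_implausible_excursion_flagged_invalid(self):
        g = _periodic_events()
        huge = 50.0 * _flat_vertical()  # h blows past the pendulum length
        steps = compute_step_table(g, huge, FS, pendulum_length=0.05)
        assert not steps["valid"].any()

    def test_too_few_ics_rejected(self):
        g = _periodic_events(n_ics=2)
        with pytest.raises(ValueError, match="3 initial contacts"):
            compute_step_table(g, _flat_vertical(), FS)


class TestBoutPanel:
    def test_periodic_gait_has_zero_variability_and_asymmetry(self):
        g = _periodic_events()
        panel = summarize_bout(compute_step_table(g, _flat_vertical(), FS))
        for col in panel.index:
            if col.endswith("_variability") or col.endswith("_asymmetry"):
                assert panel[col] == pytest.approx(0.0, abs=1e-9), col

    def test_stance_swing_sum_exact(self, walk_uniform):
        rec, _ = walk_uniform
        vert = rec.vertical()[rec.index_at(5.0) : rec.index_at(35.0)]
        g = detect_events(vert, FS)
        panel = summarize_bout(compute_step_table(g, vert, FS))
        assert panel["stance_phase_pct"] + panel["swing_phase_pct"] == 100.0

    def test_step_time_asymmetry_recovered(self):
        from gaitfm.events import assemble_events

        profile = GaitProfile(step_time_mean=0.6, step_time_sd=0.02,
                              step_time_asym=0.02, noise_sd=0.02)
        rec, truth = simulate_gait_recording(
            profile, ActivitySchedule.single_walk(150.0, pad=5.0), seed=8
        )
        u = preprocess(rec)
        vert = u.vertical()[u.index_at(5.0) : u.index_at(155.0)]
        assert truth.true_step_times.size >= 200
        g = assemble_events(truth.ic_times - 5.0, truth.fc_times - 5.0)
        panel = summarize_bout(compute_step_table(g, vert, FS))
        assert panel["step_time_asymmetry"] == pytest.approx(0.02, abs=0.005)

    def test_asymmetry_invariant_to_starting_label(self):
        g = _periodic_events(step=0.6)
        # introduce a systematic side offset by shifting every second IC
        ics = g.ic_times.copy()
        ics[1::2] += 0.02
        for start in ("L", "R"):
            sides = [start if i % 2 == 0 else ("R" if start == "L" else "L")
                     for i in range(ics.size)]
            gg = GaitEvents(ics, g.fc_times, sides, cwt_scale=18.0)
            panel = summarize_bout(compute_step_table(gg, _flat_vertical(), FS))
            if start == "L":
                ref = panel["step_time_asymmetry"]
            else:
                assert panel["step_time_asymmetry"] == pytest.approx(ref, abs=1e-12)

    def test_longer_bouts_estimate_variability_more_stably(self):
        """Sampling error of the SD estimate shrinks with bout length."""
        sds = {n: [] for n in (20, 200)}
        for seed in range(12):
            rng = np.random.default_rng(seed)
            for n in sds:
                steps = rng.normal(0.6, 0.03, n)
                sds[n].append(steps.std(ddof=1))
        assert np.std(sds[200]) < np.std(sds[20])


class TestAggregation:
    def _bout(self, start, dur, n_steps, cat):
        seg = BoutSegment(start, start + dur, "free_living")
        g = GaitEvents(np.linspace(start, start + dur, max(n_steps, 2)),
                       np.empty(0), ["L", "R"] * (max(n_steps, 2) // 2 + 1),
                       cwt_scale=18.0)
        return WalkingBout(seg, g, n_steps, dur, cat)

    def test_single_bout_identity(self):
        params = pd.Series({"cadence_spm": 100.0, "step_time_s": 0.6})
        summary = aggregate_subject([(self._bout(0, 20, 30, "15-30s"), params)])
        assert summary.table.loc["15-30s", "cadence_spm"] == 100.0
        assert summary.table.loc["15-30s", "n_bouts"] == 1

    def test_step_weighted_mean(self):
        b1 = self._bout(0, 10, 10, "5-15s")
        b2 = self._bout(20, 10, 30, "5-15s")
        p1 = pd.Series({"cadence_spm": 100.0})
        p2 = pd.Series({"cadence_spm": 110.0})
        summary = aggregate_subject([(b1, p1), (b2, p2)])
        assert summary.table.loc["5-15s", "cadence_spm"] == pytest.approx(107.5)

    def test_each_duration_lands_in_own_category(self):
        durations = [8, 20, 45, 90]
        cats = ["5-15s", "15-30s", "30-60s", ">60s"]
        bouts = [
            (self._bout(i * 100, d, 10, c), pd.Series({"cadence_spm": 100.0}))
            for i, (d, c) in enumerate(zip(durations, cats))
        ]
        summary = aggregate_subject(bouts)
        assert sorted(summary.table.index) == sorted(cats)
        assert (summary.table["n_bouts"] == 1).all()


class TestStepCountICC:
    def test_perfect_agreement(self):
        counts = np.array([12, 25, 31, 44, 18])
        assert step_count_validity(counts, counts) == pytest.approx(1.0)

    def test_reversed_counts_match_anova_oracle(self):
        a = np.array([10.0, 20.0, 30.0])
        b = np.array([30.0, 20.0, 10.0])
        # closed-form two-way mean squares for these vectors:
        # MSR = 0 (row means all 20), MSC = 0, MSE = 200 → ICC = -MSE/MSE...
        # compute the oracle explicitly:
        x = np.column_stack([a, b])
        grand = x.mean()
        msr = 2 * ((x.mean(axis=1) - grand) ** 2).sum() / 2
        msc = 3 * ((x.mean(axis=0) - grand) ** 2).sum() / 1
        mse = (
            ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
            / 2
        )
        expected = (msr - mse) / (msr + mse + 2 * (msc - mse) / 3)
        assert step_count_validity(a, b) == pytest.approx(expected)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a = rng.integers(10, 60, 12).astype(float)
        b = a + rng.integers(-2, 3, 12)
        ours = step_count_validity(a, b)
        data = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": ["obs", "det"] * 12,
                "score": np.column_stack([a, b]).ravel(),
            }
        )
        icc = pingouin.intraclass_corr(data, "targets", "raters", "score")
        ref = icc.set_index("Type").loc["ICC(A,1)", "ICC"]  # two-way random, absolute, single
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_detector_vs_truth_icc_high(self):
        """Synthetic trials with ±1 miscount keep ICC above 0.85."""
        rng = np.random.default_rng(2)
        true = rng.integers(15, 60, 12).astype(float)
        detected = true + rng.integers(-1, 2, 12)
        assert step_count_validity(true, detected) > 0.85

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            step_count_validity(np.array([5.0, 5.0, 5.0]), np.array([5.0, 5.0, 5.0]))
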