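import numpy as np
import pandas as pd
import pytest

from gazefield.design import TrialSpec
from gazefield.events import EventParams, detect_events
from gazefield.roi import ROI_LABELS
from gazefield.sdt import ConfusionCounts, dprime, sensitivity_table, trim_rt
from gazefield.simulate import (
    APERTURE_RADIUS_DEG,
    FeatureLayout,
    ObserverParams,
    _fixation_sequence,
    condition_gate,
    fixation_eccentricities,
    information_rate,
    simulate_cohort,
    simulate_gaze_trace,
    simulate_response,
    synthetic_roi_map,
    trigger_xy,
)


def dummy_trial(condition="full", trigger="left"):
    return TrialSpec(
        index=0, trial_type="same", condition=condition,
        study_image_id="a", test_image_id="b", trigger_position=trigger,
    )


@pytest.fixture(scope="module")
def layout(roimap):
    return FeatureLayout.from_roi_map(roimap)


class TestObserverParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(sigma_field_deg=-1, d_max=2)
        with pytest.raises(ValueError):
            ObserverParams(sigma_field_deg=1, d_max=2, lapse_rate=1.0)
        with pytest.raises(ValueError):
            ObserverParams(
                sigma_field_deg=1, d_max=2,
                roi_attraction={l: 0.1 for l in ROI_LABELS},
            )

    def test_gain_profiles(self):
        obs = ObserverParams(sigma_field_deg=2.0, d_max=2.0)
        assert obs.gain(0.0) == 1.0
        assert obs.gain(2.0) == pytest.approx(np.exp(-0.5))
        expo = ObserverParams(sigma_field_deg=2.0, d_max=2.0,
                              field_profile="exponential")
        assert expo.gain(2.0) == pytest.approx(np.exp(-1.0))


class TestGazeTrace:
    def test_trace_starts_on_trigger_dot(self, cfg, roimap):
        obs = ObserverParams.expert()
        for trig in ("left", "right", "above", "below"):
            sim = simulate_gaze_trace(
                dummy_trial(trigger=trig), obs, roimap, seed=1, cfg=cfg
            )
            assert sim.fixations[0].label == "trigger"
            expect = trigger_xy(trig, cfg)
            assert (sim.samples["x_px"].iloc[0], sim.samples["y_px"].iloc[0]) == expect

    def test_sampling_grid_covers_study_duration(self, cfg, roimap):
        sim = simulate_gaze_trace(dummy_trial(), ObserverParams.novice(), roimap,
                                  seed=2, cfg=cfg)
        assert len(sim.samples) == 3000
        assert sim.samples["t_ms"].iloc[0] == 0

    def test_fixation_targets_follow_roi_attraction(self, cfg, roimap, rng):
        obs = ObserverParams.expert()
        counts = {l: 0 for l in ROI_LABELS}
        n = 0
        for i in range(120):
            fx, _ = _fixation_sequence(3000, obs, roimap, trigger_xy("left", cfg), rng)
            for f in fx[1:]:
                counts[f.label] += 1
                n += 1
        probs = {l: obs.roi_attraction[l] / sum(obs.roi_attraction.values())
                 for l in ROI_LABELS}
        for l in ROI_LABELS:
            # 4-sigma binomial band
            se = np.sqrt(probs[l] * (1 - probs[l]) / n)
            assert abs(counts[l] / n - probs[l]) < 4 * se + 1e-9

    def test_fixation_points_lie_inside_their_roi(self, cfg, roimap, rng):
        from shapely.geometry import Point

        fx, _ = _fixation_sequence(3000, ObserverParams.novice(), roimap,
                                   trigger_xy("right", cfg), rng)
        ox, oy = roimap.frame_origin_xy
        for f in fx[1:]:
            assert roimap.shape(f.label).covers(Point(f.x_px - ox, f.y_px - oy))

    def test_noise_free_trace_recovers_ground_truth_fixations(self, cfg, roimap):
        obs = ObserverParams.novice()
        for seed in range(4):
            sim = simulate_gaze_trace(dummy_trial(), obs, roimap, seed=seed, cfg=cfg)
            _, fix = detect_events(sim.samples, EventParams(), cfg)
            assert len(fix) == len(sim.fixations)


class TestResponseModel:
    def test_condition_gates_partition_information(self, cfg, layout, rng):
        obs = ObserverParams.expert()
        for _ in range(50):
            gxy = (float(rng.uniform(200, 800)), float(rng.uniform(100, 600)))
            full = information_rate(gxy, obs, layout, "full", cfg)
            cen = information_rate(gxy, obs, layout, "central", cfg)
            per = information_rate(gxy, obs, layout, "peripheral", cfg)
            assert full == pytest.approx(cen + per, abs=1e-12)

    def test_gate_boundary_belongs_to_central(self):
        e = np.array([APERTURE_RADIUS_DEG])
        assert condition_gate(e, "central")[0] == 1.0
        assert condition_gate(e, "peripheral")[0] == 0.0

    def test_wide_field_full_view_approaches_raw_rate(self, cfg, layout):
        obs = ObserverParams(sigma_field_deg=1e6, d_max=2.0)
        gxy = layout.positions[0]
        rate = information_rate(tuple(gxy), obs, layout, "full", cfg)
        assert rate == pytest.approx(obs.info_rate_per_s, rel=1e-6)

    def test_narrow_field_peripheral_view_starves_information(self, cfg, roimap, layout, rng):
        obs = ObserverParams(sigma_field_deg=0.3, d_max=2.0)
        fx, _ = _fixation_sequence(obs.response_timeout_ms, obs, roimap,
                                   trigger_xy("left", cfg), rng)
        out = simulate_response("same", obs, layout, fx, "peripheral", rng, cfg)
        assert out.information < 0.01
        assert out.d_eff < 0.05

    def test_rt_includes_motor_delay_and_respects_timeout(self, cfg, roimap, layout, rng):
        obs = ObserverParams.expert()
        fx, _ = _fixation_sequence(obs.response_timeout_ms, obs, roimap,
                                   trigger_xy("left", cfg), rng)
        out = simulate_response("same", obs, layout, fx, "full", rng, cfg)
        assert out.rt_ms <= obs.response_timeout_ms + obs.motor_delay_ms
        assert out.rt_ms >= obs.motor_delay_ms

    def test_information_accrual_monotone_in_field_width(self, cfg, roimap, layout):
        rng = np.random.default_rng(5)
        fx, _ = _fixation_sequence(2000, ObserverParams.expert(), roimap,
                                   trigger_xy("left", cfg), rng)
        for condition in ("full", "central", "peripheral"):
            infos = []
            for sigma in (0.5, 1.0, 2.0, 4.0, 8.0):
                obs = ObserverParams(sigma_field_deg=sigma, d_max=2.0)
                out = simulate_response("same", obs, layout, fx, condition,
                                        np.random.default_rng(0), cfg)
                infos.append(out.information)
            assert all(b >= a - 1e-12 for a, b in zip(infos, infos[1:])), condition

    def test_group_by_condition_sensitivity_structure(self, cfg, roimap, layout):
        """Direction checks fixed by the gain model: full > peripheral within
        each group, and the peripheral cost is smaller for experts."""
        dps = {}
        for name, obs in (("expert", ObserverParams.expert()),
                          ("novice", ObserverParams.novice())):
            rng = np.random.default_rng(99)
            for cond in ("full", "peripheral"):
                c = dict(hits=0, misses=0, false_alarms=0, correct_rejections=0)
                for i in range(400):
                    tt = "same" if i % 2 else "different"
                    fx, _ = _fixation_sequence(obs.response_timeout_ms, obs,
                                               roimap, trigger_xy("left", cfg), rng)
                    out = simulate_response(tt, obs, layout, fx, cond, rng, cfg)
                    if tt == "same":
                        c["hits" if out.response == "same" else "misses"] += 1
                    else:
                        c["false_alarms" if out.response == "same"
                          else "correct_rejections"] += 1
                dps[(name, cond)] = dprime(ConfusionCounts(**c))
        assert dps[("expert", "full")] > dps[("expert", "peripheral")]
        assert dps[("novice", "full")] > dps[("novice", "peripheral")]
        expert_cost = dps[("expert", "full")] - dps[("expert", "peripheral")]
        novice_cost = dps[("novice", "full")] - dps[("novice", "peripheral")]
        assert expert_cost < novice_cost

    def test_fast_trials_carry_higher_information_rate(self, cfg, roimap, layout):
        obs = ObserverParams.novice()
        rng = np.random.default_rng(3)
        rows = []
        for i in range(300):
            fx, _ = _fixation_sequence(obs.response_timeout_ms, obs, roimap,
                                       trigger_xy("left", cfg), rng)
            out = simulate_response("same", obs, layout, fx, "full", rng, cfg)
            rows.append((out.rt_ms, out.information / out.rt_ms))
        df = pd.DataFrame(rows, columns=["rt", "rate"])
        assert df["rt"].corr(df["rate"]) < -0.5


class TestCohort:
    def test_seed_reproducibility(self, catalog):
        a = simulate_cohort(2, 2, master_seed=5, catalog=catalog)
        b = simulate_cohort(2, 2, master_seed=5, catalog=catalog)
        pd.testing.assert_frame_equal(a.trial_records, b.trial_records)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        ta = a.study_trace("e01", 17).samples
        tb = b.study_trace("e01", 17).samples
        pd.testing.assert_frame_equal(ta, tb)
        c = simulate_cohort(2, 2, master_seed=6, catalog=catalog)
        assert not a.trial_records["rt_ms"].equals(c.trial_records["rt_ms"])

    def test_study_trace_regeneration_is_stable(self, small_cohort):
        t1 = small_cohort.study_trace("n02", 3).samples
        t2 = small_cohort.study_trace("n02", 3).samples
        pd.testing.assert_frame_equal(t1, t2)

    def test_cohort_shapes_and_structure(self, small_cohort):
        assert len(small_cohort.trial_records) == 4 * 144
        assert set(small_cohort.trial_records["group"]) == {"expert", "novice"}
        for pid, plan in small_cohort.session_plans.items():
            plan.validate()

    def test_expert_advantage_in_grand_mean_dprime(self, small_cohort):
        kept, _, _ = trim_rt(small_cohort.trial_records)
        table = sensitivity_table(kept)
        means = table.groupby("group")["dprime"].mean()
        assert means["expert"] > means["novice"]

    def test_too_small_cohort_rejected(self, catalog):
        with pytest.raises(ValueError):
            simulate_cohort(1, 5, master_seed=0, catalog=catalog)


class TestRecovery:
    def test_field_width_ordering_recovered(self, catalog):
        from gazefield.simulate import sigma_recovery_ordering

        frac = sigma_recovery_ordering(n_replicates=5, n_per_group=2, seed=21,
                                       catalog=catalog)
        assert frac >= 0.8
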