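"""Tests of the synthetic-cohort forward model against independent oracles."""
import dataclasses

import numpy as np
import pytest

import photocif as pc
from photocif._rng import stream_rng
from photocif.errors import PhotocifError


class TestSimulateActivity:
    def test_all_dynamics_off_gives_constant_tonic(self):
        p = pc.AgrpParams(a_drop=0.0, sigma_ou=0.0)
        proto = pc.Protocol(state="fed", session_length=100.0,
                            context_entry_time=None, food_time=None)
        trace = pc.simulate_activity(p, proto, seed=0)
        np.testing.assert_array_equal(trace.activity, p.mu_fed)

    def test_bitwise_determinism(self):
        p = pc.AgrpParams()
        proto = pc.Protocol.training(rng=np.random.default_rng(0))
        a = pc.simulate_activity(p, proto, seed=5).activity
        b = pc.simulate_activity(p, proto, seed=5).activity
        np.testing.assert_array_equal(a, b)
        c = pc.simulate_activity(p, proto, seed=6).activity
        assert not np.array_equal(a, c)

    def test_food_suppression_matches_stepwise_integration_oracle(self):
        # noise off, food at 600 s: the post/pre mean difference equals the
        # sample-by-sample average of the difference-of-exponentials kernel
        p = pc.AgrpParams(sigma_ou=0.0)
        proto = pc.Protocol(state="fasted", session_length=1200.0,
                            context_entry_time=None, food_time=600.0)
        trace = pc.simulate_activity(p, proto, seed=0)
        pre = trace.activity[trace.time < 600].mean()
        post = trace.activity[trace.time >= 600].mean()

        acc, count = 0.0, 0
        for ti in trace.time:                      # independent discretisation
            if ti >= 600.0:
                d = ti - 600.0
                acc += (1 - np.exp(-d / p.tau_fast)) * np.exp(-d / p.tau_slow)
                count += 1
        assert np.isclose(pre - post, p.a_drop * acc / count, rtol=1e-12)

    def test_activity_bounded_below_at_zero(self):
        p = pc.AgrpParams(sigma_ou=3.0)  # large noise to force clipping
        proto = pc.Protocol(state="fed", session_length=300.0,
                            context_entry_time=None, food_time=None)
        trace = pc.simulate_activity(p, proto, seed=1)
        assert trace.activity.min() >= 0.0

    def test_excitation_envelope_adds_duty_scaled_plateau(self):
        p = pc.AgrpParams(sigma_ou=0.0)
        proto = pc.Protocol(state="fed", session_length=300.0,
                            context_entry_time=None, food_time=None,
                            stim_envelope=[(100.0, 200.0, "excite_20Hz_1on3off")])
        trace = pc.simulate_activity(p, proto, seed=0)
        mid = trace.activity[(trace.time > 120) & (trace.time < 180)]
        np.testing.assert_allclose(mid, p.mu_fed + 0.25 * p.a_stim, rtol=1e-6)

    def test_inhibition_clamps_toward_floor(self):
        p = pc.AgrpParams(sigma_ou=0.0)
        proto = pc.Protocol(state="fasted", session_length=300.0,
                            context_entry_time=None, food_time=None,
                            stim_envelope=[(100.0, 200.0, "inhibit_constant")])
        trace = pc.simulate_activity(p, proto, seed=0)
        mid = trace.activity[(trace.time > 120) & (trace.time < 180)]
        np.testing.assert_allclose(mid, p.stim_floor, rtol=1e-6)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(PhotocifError, match="duration"):
            pc.Protocol(session_length=100.0, context_entry_time=None,
                        food_time=10.0, bout_schedule=[(20.0, -1.0)])
        with pytest.raises(PhotocifError, match="overlap"):
            pc.Protocol(session_length=100.0, context_entry_time=None, food_time=None,
                        stim_envelope=[(0.0, 50.0, "excite_20Hz_1on3off"),
                                       (40.0, 80.0, "inhibit_constant")])
        with pytest.raises(PhotocifError, match="after food"):
            pc.Protocol(session_length=100.0, context_entry_time=None,
                        food_time=50.0, bout_schedule=[(20.0, 5.0)])


class TestRenderPhotometry:
    def test_clean_constant_render_is_constant(self, quiet_params):
        p = dataclasses.replace(quiet_params, a_drop=0.0)
        proto = pc.Protocol(state="fed", session_length=60.0,
                            context_entry_time=None, food_time=None)
        trace = pc.simulate_activity(p, proto, seed=0)
        session, _ = pc.render_photometry(trace, p, seed=0)
        assert np.ptp(session.f465) == 0 and np.ptp(session.f405) == 0

    def test_motion_artifact_identical_in_both_channels(self, fed_quiet_protocol):
        p = pc.AgrpParams(noise_sd=0.0, sigma_ou=0.0)
        trace = pc.simulate_activity(p, fed_quiet_protocol, seed=2)
        session, truth = pc.render_photometry(trace, p, seed=2)
        # with gain*activity constant and equal offsets, channel difference
        # is a pure bleach-scaled constant: motion cancels exactly
        diff = session.f465 - session.f405
        np.testing.assert_allclose(diff, p.gain * trace.activity * truth["bleach"], atol=1e-9)

    def test_raw_channel_correlates_with_artifact(self, params, fed_quiet_protocol):
        trace = pc.simulate_activity(params, fed_quiet_protocol, seed=3)
        session, truth = pc.render_photometry(trace, params, seed=3)
        assert abs(np.corrcoef(session.f465, truth["motion"])[0, 1]) > 0.5

    def test_zero_gain_render_carries_no_activity_information(self, fed_quiet_protocol):
        p = pc.AgrpParams(gain=0.0)
        t1 = pc.simulate_activity(p, fed_quiet_protocol, seed=4)
        t2 = pc.simulate_activity(
            dataclasses.replace(p, mu_fed=50.0), fed_quiet_protocol, seed=4)
        s1, _ = pc.render_photometry(t1, p, seed=4)
        s2, _ = pc.render_photometry(t2, p, seed=4)
        np.testing.assert_array_equal(s1.f465, s2.f465)

    def test_negative_activity_rejected(self, params, fed_quiet_protocol):
        trace = pc.simulate_activity(params, fed_quiet_protocol, seed=0)
        trace.activity[0] = -1.0
        with pytest.raises(PhotocifError):
            pc.render_photometry(trace, params, seed=0)


class TestSimulateTracking:
    def test_bout_covering_session_pins_eating_in_food_zone(self):
        proto = pc.Protocol(state="fasted", session_length=60.0,
                            context_entry_time=None, food_time=0.0,
                            bout_schedule=[(0.0, 60.0)])
        zones = pc.ZoneSet()
        track, eth = pc.simulate_tracking(proto, zones, seed=0)
        assert np.all(eth.behavior == "eating")
        assert np.all(zones.classify(track.x, track.y) == "food")

    def test_disabled_walk_no_bouts_travels_zero(self):
        proto = pc.Protocol(state="fed", session_length=30.0,
                            context_entry_time=None, food_time=None)
        track, _ = pc.simulate_tracking(proto, pc.ZoneSet(), seed=0, speed_cm_s=0.0)
        dist, vel = pc.locomotion_metrics(track)
        assert dist == 0.0 and vel == 0.0

    def test_trace_confined_to_arena_and_deterministic(self):
        proto = pc.Protocol.training(rng=np.random.default_rng(1))
        zones = pc.ZoneSet()
        t1, e1 = pc.simulate_tracking(proto, zones, seed=7)
        t2, e2 = pc.simulate_tracking(proto, zones, seed=7)
        np.testing.assert_array_equal(t1.x, t2.x)
        assert all(e1.behavior == e2.behavior)
        assert t1.x.min() >= 0 and t1.x.max() <= zones.arena_w
        assert t1.y.min() >= 0 and t1.y.max() <= zones.arena_h


class TestSimulateCohort:
    def test_zero_effect_zero_noise_gives_equal_intakes(self):
        groups = [pc.GroupSpec("G", 5, effect_g=0.0)]
        design = pc.CohortDesign(groups=groups, intake_noise_g=0.0,
                                 train_sd_g=0.0, session_sd_g=0.0, seed=0)
        res = pc.simulate_cohort(design, with_sessions=False)
        disc = pc.context_discrimination(res.records)
        np.testing.assert_array_equal(disc["diff_g"], 0.0)

    def test_programmed_effect_exact_without_noise(self):
        groups = [pc.GroupSpec("FASTED", 6, effect_g=0.3)]
        design = pc.CohortDesign(groups=groups, intake_noise_g=0.0,
                                 train_sd_g=0.0, session_sd_g=0.0, seed=0)
        res = pc.simulate_cohort(design, with_sessions=False)
        disc = pc.context_discrimination(res.records)
        np.testing.assert_allclose(disc["diff_g"], 0.3, atol=1e-12)

    def test_monte_carlo_mean_recovers_programmed_effect(self):
        # cohort replicates: empirical mean of A-B within 3 SEM of programmed
        groups = [pc.GroupSpec("FASTED", 10, effect_g=0.3)]
        means = []
        for i in range(1000):
            design = pc.CohortDesign(groups=groups, seed=i)
            res = pc.simulate_cohort(design, with_sessions=False)
            means.append(pc.context_discrimination(res.records)["diff_g"].mean())
        means = np.asarray(means)
        sem = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 0.3) < 3 * sem

    def test_zero_size_group_rejected(self):
        with pytest.raises(PhotocifError, match="n >= 1"):
            pc.GroupSpec("EMPTY", 0)

    def test_session_bundle_structure(self):
        design = pc.CohortDesign(groups=[pc.GroupSpec("G", 2, effect_g=0.1)],
                                 signals_per_group=1, seed=1,
                                 homecage_s=60, context_to_food_s=60, post_food_s=180)
        res = pc.simulate_cohort(design)
        assert set(k[1] for k in res.sessions) == {
            "training_d1_A", "training_d2_A", "training_d3_A", "test_A", "test_B"}
        bundle = res.sessions[("g_00", "test_A")]
        assert bundle["photometry"].event_times("food").size == 1
        assert bundle["tracking"].n_frames == bundle["ethogram"].time.size


def test_seed_splitting_is_stable_and_stream_independent():
    a = stream_rng(42, "activity", "training").standard_normal(4)
    b = stream_rng(42, "activity", "training").standard_normal(4)
    c = stream_rng(42, "motion", "training").standard_normal(4)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
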