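"""Unit tests for the isosbestic correction, z-scoring and peri-event stack."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import photocif as pc
from photocif.errors import DegenerateBaselineError, EmptyPeriEventError, PhotocifError


def make_session(f465, f405, rate=1.0, events=()):
    n = len(f465)
    return pc.PhotometrySession(time=np.arange(n) / rate, f465=f465, f405=f405,
                                rate=rate, events=list(events))


class TestComputeDff:
    def test_arithmetic(self):
        assert pc.compute_dff([2.0, 4.0], [2.0, 2.0]).tolist() == [0.0, 1.0]

    def test_identical_channels_give_zero(self):
        x = np.linspace(1, 5, 20)
        assert np.all(pc.compute_dff(x, x) == 0)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(0)
        f465 = rng.uniform(1, 10, 100)
        f405 = rng.uniform(1, 10, 100)
        oracle = np.array([(a - b) / b for a, b in zip(f465, f405)])
        np.testing.assert_array_equal(pc.compute_dff(f465, f405), oracle)

    def test_nonpositive_isosbestic_names_first_index(self):
        with pytest.raises(PhotocifError, match="index 2"):
            pc.compute_dff([1.0, 1.0, 1.0], [1.0, 1.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(PhotocifError, match="mismatch"):
            pc.compute_dff([1.0, 2.0], [1.0])

    def test_fitted_variant_removes_scaled_isosbestic(self):
        # when f465 is an affine function of f405 the fitted residual is 0
        rng = np.random.default_rng(1)
        f405 = rng.uniform(100, 200, 500)
        f465 = 1.7 * f405 + 20
        np.testing.assert_allclose(pc.fit_isosbestic_dff(f465, f405), 0, atol=1e-9)


class TestZscoreBaseline:
    def test_baseline_mean_maps_to_zero(self):
        x = np.array([1.0, 2.0, 3.0, 2.0])
        z = pc.zscore_baseline(x, np.arange(4.0), baseline=(0.0, 3.0))
        assert z[3] == 0.0

    def test_constant_baseline_is_degenerate(self):
        x = np.ones(10)
        with pytest.raises(DegenerateBaselineError):
            pc.zscore_baseline(x, np.arange(10.0), baseline=(0.0, 5.0))

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        t = np.arange(200.0)
        base = x[:50]
        mu = sum(base) / 50
        sd = (sum((v - mu) ** 2 for v in base) / 49) ** 0.5
        z = pc.zscore_baseline(x, t, baseline=(0.0, 50.0))
        np.testing.assert_allclose(z, (x - mu) / sd, atol=1e-12)

    def test_baseline_outside_range_errors(self):
        with pytest.raises(PhotocifError, match="outside"):
            pc.zscore_baseline(np.ones(5), np.arange(5.0), baseline=(-10.0, -5.0))

    @given(a=st.floats(0.1, 100), b=st.floats(-50, 50))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        t = np.arange(100.0)
        z1 = pc.zscore_baseline(x, t, baseline=(0.0, 40.0))
        z2 = pc.zscore_baseline(a * x + b, t, baseline=(0.0, 40.0))
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_own_baseline_statistics(self):
        rng = np.random.default_rng(4)
        x = rng.normal(2, 3, size=500)
        t = np.arange(500.0)
        z = pc.zscore_baseline(x, t, baseline=(0.0, 200.0))
        zb = z[:200]
        assert abs(zb.mean()) < 1e-9
        assert abs(zb.std(ddof=1) - 1.0) < 1e-9


class TestBuildPerievent:
    def test_hand_built_trace(self):
        # 10 samples at 1 Hz, one event at t=5, pre=post=2 s, z to [-2, 0)
        sig = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        m = pc.build_perievent(sig, np.arange(10.0), [5.0], pre=2, post=2)
        np.testing.assert_array_equal(m.rel_time, [-2, -1, 0, 1, 2])
        # baseline samples (rel -2, -1) are [3, 4]: mean 3.5, sd 1/sqrt(2)
        expect = (np.array([3.0, 4, 5, 6, 7]) - 3.5) / np.std([3.0, 4.0], ddof=1)
        np.testing.assert_allclose(m.values[0], expect, atol=1e-12)

    def test_edge_events_are_dropped_and_counted(self):
        sig = np.arange(10.0)
        m = pc.build_perievent(sig, np.arange(10.0), [1.0, 5.0], pre=2, post=2)
        assert m.dropped_events == 1
        assert m.n_events == 1
        assert m.event_labels == ["event_1"]

    def test_constant_signal_mean_mode_gives_zero_rows(self):
        sig = np.full(20, 7.0)
        m = pc.build_perievent(sig, np.arange(20.0), [10.0], pre=3, post=3, mode="mean")
        np.testing.assert_array_equal(m.values, 0.0)

    def test_all_events_dropped_raises(self):
        with pytest.raises(EmptyPeriEventError):
            pc.build_perievent(np.arange(10.0), np.arange(10.0), [0.5], pre=5, post=5)

    def test_baseline_must_be_pre_event(self):
        with pytest.raises(PhotocifError, match="baseline"):
            pc.build_perievent(np.arange(30.0), np.arange(30.0), [15.0],
                               pre=5, post=5, baseline=(-5.0, 2.0))


class TestWindowMeans:
    @staticmethod
    def matrix(values, rate=1.0):
        values = np.atleast_2d(values)
        n = values.shape[1]
        rel = np.arange(n, dtype=float) / rate - (n // 2) / rate
        return pc.PeriEventMatrix(values=values, rel_time=rel, baseline_window=(rel[0], 0.0),
                                  event_labels=[f"e{i}" for i in range(values.shape[0])])

    def test_zero_matrix(self):
        m = self.matrix(np.zeros((3, 21)))
        wm = pc.window_means(m, [("w", -5.0, 5.0)])
        assert (wm["mean"] == 0).all()
        assert len(wm) == 3

    def test_ramp_row_half_open_window(self):
        # row equals rel_time itself; [0, 10) at 1 Hz averages 0..9 -> 4.5
        rel = np.arange(-10.0, 11.0)
        m = pc.PeriEventMatrix(values=rel[None, :], rel_time=rel,
                               baseline_window=(-10.0, 0.0), event_labels=["e0"])
        wm = pc.window_means(m, [("w", 0.0, 10.0)])
        assert wm["mean"].iloc[0] == 4.5

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        m = self.matrix(rng.normal(size=(4, 41)))
        windows = [("a", -10.0, 0.0), ("b", 0.0, 10.0)]
        wm = pc.window_means(m, windows)
        for _, row in wm.iterrows():
            i = int(row["event"][1:])
            vals = [v for v, t in zip(m.values[i], m.rel_time)
                    if row["start_s"] <= t < row["end_s"]]
            assert np.isclose(row["mean"], np.mean(vals), atol=1e-12)

    def test_window_outside_span_errors(self):
        m = self.matrix(np.zeros((1, 21)))
        with pytest.raises(PhotocifError, match="outside"):
            pc.window_means(m, [("w", -50.0, 0.0)])

    def test_empty_window_names_window(self):
        m = self.matrix(np.zeros((1, 21)))
        with pytest.raises(PhotocifError, match="'tiny'"):
            pc.window_means(m, [("tiny", 0.25, 0.3)])


class TestBoutTriggeredAverage:
    def test_empty_onsets_raise(self, training_session):
        _, session, _ = training_session
        with pytest.raises(EmptyPeriEventError):
            pc.bout_triggered_average(session, [])

    def test_noise_free_dip_matches_integration_oracle(self, quiet_params):
        # one bout, clean render: the 0-5 s window mean must equal the
        # per-sample numerical average of the programmed dip kernel
        p = quiet_params
        proto = pc.Protocol(state="fasted", session_length=400.0,
                            context_entry_time=None, food_time=100.0,
                            bout_schedule=[(200.0, 8.0)])
        trace = pc.simulate_activity(p, proto, seed=0)
        session, _ = pc.render_photometry(trace, p, seed=0)
        m, wm = pc.bout_triggered_average(session, proto.bout_onsets, mode="mean")
        got = wm.loc[wm["window"] == "0-5 s", "mean"].iloc[0]

        rate = session.rate
        rel = np.arange(-10 * int(rate), 10 * int(rate) + 1) / rate
        dip = np.where(rel >= 0, -p.a_bout * (1 - np.exp(-np.clip(rel, 0, None) / p.tau_bout_on)), 0.0)
        # food-suppression kernel varies slowly across the 20 s window; the
        # oracle includes it exactly as the generator programs it
        d = rel + 200.0 - 100.0
        supp = -p.a_drop * (1 - np.exp(-d / p.tau_fast)) * np.exp(-d / p.tau_slow)
        latent = p.mu_fasted + dip + supp
        dff = p.gain * latent / p.offset405
        base = dff[(rel >= -10) & (rel < 0)].mean()
        oracle = (dff - base)[(rel >= 0) & (rel < 5)].mean()
        assert np.isclose(got, oracle, rtol=1e-9)


class TestDownsample:
    def test_identity_factor(self, training_session):
        _, session, _ = training_session
        out = pc.downsample(session, 1)
        np.testing.assert_array_equal(out.f465, session.f465)

    def test_constant_stays_constant(self):
        s = make_session(np.full(10, 3.0), np.full(10, 2.0))
        out = pc.downsample(s, 3)
        assert np.all(out.f465 == 3.0) and out.time.size == 3

    def test_ramp_block_means(self):
        s = make_session(np.arange(6.0) + 1, np.ones(6))
        out = pc.downsample(s, 2)
        np.testing.assert_array_equal(out.f465, [1.5, 3.5, 5.5])
        assert out.rate == s.rate / 2

    def test_bad_factor(self, training_session):
        _, session, _ = training_session
        with pytest.raises(PhotocifError):
            pc.downsample(session, 0)


def test_session_validation_rejects_nonpositive_isosbestic():
    with pytest.raises(PhotocifError, match="f405"):
        make_session(np.ones(5), np.array([1.0, 1, -1, 1, 1]))
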