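import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from spiralbeta import bursts
from spiralbeta.bursts import EnvelopeTrace
from spiralbeta.lfp import preprocess_lfp
from spiralbeta.spectral import TfrMap
from spiralbeta.synthetic import SimulationConfig, simulate_lfp_epoch

from conftest import make_epoch


def env_trace(env, fs=200.0, t0=0.0, f_peak=20.0):
    env = np.asarray(env, float)
    return EnvelopeTrace(t=t0 + np.arange(env.size) / fs, env=env, f_peak=f_peak, fs=fs)


def warped_map(rest_rows, draw_rows, freqs=None):
    """Warped TfrMap from per-frequency rest/draw mean powers."""
    rest_rows = np.asarray(rest_rows, float)
    draw_rows = np.asarray(draw_rows, float)
    if freqs is None:
        freqs = np.arange(13.0, 13.0 + rest_rows.size)
    power = np.concatenate(
        [np.tile(rest_rows[:, None], 50), np.tile(draw_rows[:, None], 100)], axis=1
    )
    return TfrMap(
        freqs=np.asarray(freqs, float),
        times=np.arange(150.0),
        power=power,
        warped=True,
        segments={"rest": slice(0, 50), "draw": slice(50, 150)},
    )


class TestFindBetaPeak:
    def test_desync_frequency_found(self):
        freqs = np.arange(13.0, 31.0)
        rest = np.ones(freqs.size)
        draw = np.ones(freqs.size)
        draw[freqs == 18.0] = 0.5  # deepest desynchronization at 18 Hz
        assert bursts.find_beta_peak(warped_map(rest, draw, freqs)) == 18.0

    def test_tie_falls_back_to_rest_peak(self):
        freqs = np.arange(13.0, 31.0)
        rest = np.ones(freqs.size)
        rest[freqs == 22.0] = 3.0
        draw = 0.9 * rest  # flat 10% desync everywhere -> tie rule engages
        assert bursts.find_beta_peak(warped_map(rest, draw, freqs)) == 22.0

    def test_no_desync_warns_and_uses_rest_peak(self):
        freqs = np.arange(13.0, 31.0)
        rest = np.ones(freqs.size)
        rest[freqs == 25.0] = 2.0
        draw = 1.5 * rest
        with pytest.warns(UserWarning, match="rest peak"):
            assert bursts.find_beta_peak(warped_map(rest, draw, freqs)) == 25.0

    def test_two_subjects_recovered_independently(self):
        cfg = SimulationConfig(noise_rms_uv=0.5)
        from spiralbeta import spectral

        for f_true in (15.0, 27.0):
            epoch, _ = simulate_lfp_epoch(
                cfg, "free", "off", f_true, seed=int(f_true), draw_duration=10.0,
                inject_bursts=[(o, 0.4, 6.0) for o in (-4.5, -3.0, -1.5)],
            )
            tfr = spectral.morlet_tfr(preprocess_lfp(epoch))
            w = spectral.timewarp_tfr(tfr, (-5.0, 0.0), (0.0, 10.0))
            assert abs(bursts.find_beta_peak(w) - f_true) <= 1.0


class TestBetaEnvelope:
    def test_in_band_sinusoid_level(self):
        t = np.arange(4000) / 200.0
        epoch = make_epoch(3.0 * np.sin(2 * np.pi * 20.0 * t), fs=200.0, t0=0.0,
                           intervals={})
        env = bursts.beta_envelope(epoch, 20.0)
        core = slice(400, -400)
        # rectified-sine mean is 2A/pi; at 10 samples/cycle the grid mean of
        # |sin| is 0.9668 * 2/pi, so allow for that discretization bias
        assert np.mean(env.env[core]) == pytest.approx(2 * 3.0 / np.pi, rel=0.05)
        assert np.mean(env.env[core]) == pytest.approx(0.9668 * 2 * 3.0 / np.pi, rel=0.01)

    def test_out_of_band_attenuated(self, sine_epoch):
        in_band = bursts.beta_envelope(preprocess_lfp(sine_epoch(20.0)), 20.0)
        out_band = bursts.beta_envelope(preprocess_lfp(sine_epoch(30.0)), 20.0)
        core = slice(400, -400)
        assert np.mean(out_band.env[core]) < 0.1 * np.mean(in_band.env[core])

    def test_zero_signal(self):
        epoch = make_epoch(np.zeros(2000), fs=200.0, t0=-6.0)
        env = bursts.beta_envelope(epoch, 20.0)
        assert np.allclose(env.env, 0.0)

    def test_band_bounds_checked(self):
        epoch = make_epoch(np.zeros(2000), fs=200.0, t0=-6.0)
        with pytest.raises(ValueError, match="outside"):
            bursts.beta_envelope(epoch, 5.0)


class TestRestThreshold:
    def test_hand_computed_percentile(self):
        assert bursts.rest_threshold([np.array([1.0, 2.0, 3.0, 4.0])]) == pytest.approx(3.25)

    def test_constant_envelope(self):
        assert bursts.rest_threshold([np.full(100, 2.5)]) == 2.5

    def test_scaling_homogeneity(self, rng):
        pools = [rng.random(200), rng.random(150)]
        t1 = bursts.rest_threshold(pools)
        t2 = bursts.rest_threshold([7.0 * p for p in pools])
        assert t2 == pytest.approx(7.0 * t1)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bursts.rest_threshold([])


def brute_force_bursts(env, t, fs, threshold, min_duration):
    """Oracle: direct per-sample scan."""
    out = []
    i, n = 0, env.size
    while i < n:
        if env[i] > threshold:
            j = i
            while j < n and env[j] > threshold:
                j += 1
            onset = t[i]
            offset = t[j] if j < n else t[-1] + 1.0 / fs
            if offset - onset >= min_duration:
                out.append((onset, offset, float(env[i:j].max())))
            i = j
        else:
            i += 1
    return out


class TestDetectBursts:
    def test_all_below_threshold(self):
        assert bursts.detect_bursts(env_trace(np.full(100, 0.5)), 1.0) == []

    def test_run_of_25_samples(self):
        env = np.zeros(200)
        env[100:125] = 2.0
        found = bursts.detect_bursts(env_trace(env), 1.0)
        assert len(found) == 1
        assert found[0].duration == pytest.approx(0.125)
        assert found[0].peak_amplitude == 2.0

    def test_run_of_15_samples_dropped(self):
        env = np.zeros(200)
        env[100:115] = 2.0
        assert bursts.detect_bursts(env_trace(env), 1.0) == []

    def test_threshold_tie_is_subthreshold(self):
        env = np.full(100, 1.0)
        assert bursts.detect_bursts(env_trace(env), 1.0) == []

    @settings(max_examples=50, deadline=None)
    @given(
        hnp.arrays(np.float64, st.integers(50, 400),
                   elements=st.floats(0, 10, allow_nan=False)),
        st.floats(0.5, 9.5),
    )
    def test_oracle_equivalence(self, env, threshold):
        trace = env_trace(env)
        found = bursts.detect_bursts(trace, threshold)
        oracle = brute_force_bursts(env, trace.t, trace.fs, threshold, 0.1)
        assert len(found) == len(oracle)
        for b, (on, off, peak) in zip(found, oracle):
            assert b.onset == on and b.offset == off and b.peak_amplitude == peak

    def test_percentile_monotonicity(self, rng):
        env = rng.random(2000)
        counts = []
        for pct in (60.0, 75.0, 90.0):
            thr = bursts.rest_threshold([env], pct)
            counts.append(len(bursts.detect_bursts(env_trace(env), thr, min_duration=0.0)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_suprathreshold_time_fraction_on_defining_pool(self, rng):
        # smooth envelope so ties are impossible; 25% of samples above threshold
        from scipy.ndimage import gaussian_filter1d

        env = gaussian_filter1d(rng.random(20000), 10)
        thr = bursts.rest_threshold([env])
        assert np.mean(env > thr) == pytest.approx(0.25, abs=0.01)

    def test_amplitude_equivariance(self, sine_epoch):
        cfg = SimulationConfig()
        epoch, _ = simulate_lfp_epoch(cfg, "free", "off", 20.0, seed=8, draw_duration=8.0)
        clean = preprocess_lfp(epoch)
        env1 = bursts.beta_envelope(clean, 20.0)
        clean2 = clean
        clean2.signal = 3.0 * clean.signal
        env2 = bursts.beta_envelope(clean2, 20.0)
        thr1 = bursts.rest_threshold([env1.env])
        thr2 = bursts.rest_threshold([env2.env])
        assert thr2 == pytest.approx(3.0 * thr1, rel=1e-9)
        b1 = bursts.detect_bursts(env1, thr1)
        b2 = bursts.detect_bursts(env2, thr2)
        assert len(b1) == len(b2)
        for u, v in zip(b1, b2):
            assert u.onset == v.onset and u.offset == v.offset
            assert v.peak_amplitude == pytest.approx(3.0 * u.peak_amplitude, rel=1e-9)


class TestAssignIntervalsAndMetrics:
    def test_straddling_burst_truncated(self):
        b = bursts.BetaBurst(onset=-0.2, offset=0.4, peak_amplitude=1.0)
        out = bursts.assign_intervals([b], {"rest": (-5.0, 0.0), "draw": (0.0, 10.0)})
        assert out[0].interval == "rest"
        assert out[0].offset == 0.0

    def test_rate(self):
        bs = [bursts.BetaBurst(onset=i, offset=i + 0.2, peak_amplitude=1.0) for i in range(5)]
        m = bursts.burst_metrics(bs, 10.0)
        assert m.rate == pytest.approx(0.5)
        assert m.n_bursts == 5

    def test_mean_duration(self):
        bs = [
            bursts.BetaBurst(onset=0.0, offset=0.1, peak_amplitude=1.0),
            bursts.BetaBurst(onset=1.0, offset=1.3, peak_amplitude=2.0),
        ]
        m = bursts.burst_metrics(bs, 5.0)
        assert m.mean_duration == pytest.approx(0.2)
        assert m.mean_amplitude == pytest.approx(1.5)

    def test_empty_flagged(self):
        m = bursts.burst_metrics([], 5.0)
        assert m.flagged and np.isnan(m.mean_duration) and m.rate == 0.0

    def test_draw_duration_factor_recovered(self):
        cfg = SimulationConfig(
            noise_rms_uv=0.3, burst_rate_rest=0.6, burst_rate_draw=0.6,
            draw_duration_factor=0.7, draw_amplitude_factor=1.0,
        )
        rest_durs, draw_durs = [], []
        for seed in range(30):
            _, injected = simulate_lfp_epoch(cfg, "free", "off", 20.0, seed=seed,
                                             draw_duration=15.0)
            for b in injected:
                (rest_durs if b.onset < 0 else draw_durs).append(b.duration)
        ratio = np.mean(draw_durs) / np.mean(rest_durs)
        assert ratio == pytest.approx(0.7, abs=0.1)
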