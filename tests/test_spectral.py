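import itertools

import numpy as np
import pytest

from spiralbeta import spectral
from spiralbeta.spectral import TfrMap
from spiralbeta.synthetic import SimulationConfig, simulate_lfp_epoch, simulate_warped_map_pair

from conftest import make_epoch


def constant_tfr(value=1.0, n_freqs=10, n_times=200, t0=-6.0, dt=0.02):
    times = t0 + np.arange(n_times) * dt
    return TfrMap(
        freqs=np.arange(4.0, 4.0 + n_freqs),
        times=times,
        power=np.full((n_freqs, n_times), float(value)),
    )


class TestMorlet:
    def test_peak_frequency(self, sine_epoch):
        tfr = spectral.morlet_tfr(lfp_pre(sine_epoch(20.0, amplitude=2.0)))
        avg = np.nanmean(tfr.power, axis=1)
        assert tfr.freqs[np.nanargmax(avg)] == 20.0

    def test_power_scales_with_amplitude_squared(self, sine_epoch):
        tfr1 = spectral.morlet_tfr(lfp_pre(sine_epoch(20.0, amplitude=1.0)))
        tfr2 = spectral.morlet_tfr(lfp_pre(sine_epoch(20.0, amplitude=2.0)))
        row = np.flatnonzero(tfr1.freqs == 20.0)[0]
        p1 = np.nanmedian(tfr1.power[row])
        p2 = np.nanmedian(tfr2.power[row])
        assert p2 / p1 == pytest.approx(4.0, rel=0.01)

    def test_onset_exclusion(self, sine_epoch):
        tfr = spectral.morlet_tfr(lfp_pre(sine_epoch(20.0)))
        assert np.all(np.isnan(tfr.power[:, np.abs(tfr.times) <= 0.1]))

    def test_two_bursts_localized(self):
        cfg = SimulationConfig(noise_rms_uv=0.1, line_noise_amp_uv=0.0)
        epoch, _ = simulate_lfp_epoch(
            cfg, "free", "off", 20.0, seed=0, draw_duration=10.0,
            inject_bursts=[(2.0, 0.5, 8.0), (6.0, 0.5, 8.0)],
        )
        from spiralbeta.lfp import preprocess_lfp

        tfr = spectral.morlet_tfr(preprocess_lfp(epoch))
        row = np.flatnonzero(tfr.freqs == 20.0)[0]
        p = tfr.power[row].copy()
        p[~np.isfinite(p)] = 0.0
        # strongest two local peaks sit at the burst centers +/- 50 ms
        t_peak1 = tfr.times[(tfr.times > 1) & (tfr.times < 4)][
            np.argmax(p[(tfr.times > 1) & (tfr.times < 4)])
        ]
        t_peak2 = tfr.times[(tfr.times > 5) & (tfr.times < 8)][
            np.argmax(p[(tfr.times > 5) & (tfr.times < 8)])
        ]
        assert abs(t_peak1 - 2.25) < 0.05
        assert abs(t_peak2 - 6.25) < 0.05


def lfp_pre(epoch):
    from spiralbeta.lfp import preprocess_lfp

    return preprocess_lfp(epoch)


class TestTimewarp:
    def test_constant_map(self):
        tfr = constant_tfr(3.0, n_times=1000)
        w = spectral.timewarp_tfr(tfr, (-5.0, 0.0), (0.0, 10.0))
        assert w.power.shape[1] == 150
        assert np.allclose(w.power, 3.0)

    def test_linear_ramp_endpoints(self):
        tfr = constant_tfr(n_times=1000)
        tfr.power = np.tile(tfr.times, (len(tfr.freqs), 1))
        w = spectral.timewarp_tfr(tfr, (-5.0, 0.0), (0.0, 10.0))
        # linear interpolation preserves linear functions: warped row stays linear
        row = w.power[0]
        diffs = np.diff(row[w.segments["draw"]])
        assert np.allclose(diffs, diffs[0], atol=1e-9)

    def test_duration_invariance(self):
        shape = lambda frac: 1.0 + np.sin(2 * np.pi * frac)  # noqa: E731
        maps = []
        for T in (12.0, 30.0):
            n = int((5 + T) / 0.02)
            times = -5.0 + np.arange(n) * 0.02
            frac = np.where(times < 0, 0.0, times / T)
            power = np.tile(shape(frac), (5, 1))
            tfr = TfrMap(freqs=np.arange(13.0, 18.0), times=times, power=power)
            maps.append(spectral.timewarp_tfr(tfr, (-5.0, 0.0), (0.0, T)).power)
        assert np.allclose(maps[0], maps[1], atol=0.01)

    def test_draw_always_100_samples(self):
        for T in (8.0, 15.0, 40.0):
            n = int((5 + T) / 0.02)
            times = -5.0 + np.arange(n) * 0.02
            tfr = TfrMap(freqs=np.arange(5.0), times=times, power=np.ones((5, n)))
            w = spectral.timewarp_tfr(tfr, (-5.0, 0.0), (0.0, T))
            assert w.segment_power("draw").shape[1] == 100
            assert w.segment_power("rest").shape[1] == 50

    def test_short_draw_flagged(self):
        tfr = constant_tfr(n_times=300)
        with pytest.raises(ValueError, match="10 native"):
            spectral.timewarp_tfr(tfr, (-5.0, 0.0), (0.0, 0.1))


class TestBaselineRelchange:
    def _warped(self, rest_val, draw_val):
        power = np.concatenate(
            [np.full((4, 50), rest_val), np.full((4, 100), draw_val)], axis=1
        )
        return TfrMap(
            freqs=np.arange(13.0, 17.0),
            times=np.arange(150.0),
            power=power,
            warped=True,
            segments={"rest": slice(0, 50), "draw": slice(50, 150)},
        )

    def test_equal_gives_zero(self):
        rel = spectral.baseline_relchange(self._warped(2.0, 2.0))
        assert np.allclose(rel.power, 0.0)

    def test_double_gives_plus_one(self):
        rel = spectral.baseline_relchange(self._warped(2.0, 4.0))
        assert np.allclose(rel.segment_power("draw"), 1.0)

    def test_generator_desync_recovered(self, rng):
        rest = 2.0 + 0.05 * rng.standard_normal((4, 50))
        draw = 1.4 + 0.05 * rng.standard_normal((4, 100))
        tfr = self._warped(2.0, 1.4)
        tfr.power = np.concatenate([rest, draw], axis=1)
        rel = spectral.baseline_relchange(tfr)
        assert np.nanmean(rel.segment_power("draw")) == pytest.approx(-0.3, abs=0.02)


class TestBandPower:
    def test_parseval_white_noise(self, rng):
        x = rng.normal(0, 3.0, 20 * 200)
        epoch = make_epoch(x, fs=200.0, t0=0.0, intervals={"all": (0.0, 20.0)})
        total = spectral.band_power(epoch, "all", (0.0, 99.99))
        assert total == pytest.approx(9.0, rel=0.05)

    def test_sinusoid_band_power(self):
        t = np.arange(20 * 200) / 200.0
        x = 2.0 * np.sin(2 * np.pi * 20 * t)
        epoch = make_epoch(x, fs=200.0, t0=0.0, intervals={"all": (0.0, 20.0)})
        beta = spectral.band_power(epoch, "all", spectral.BETA_BAND)
        gamma = spectral.band_power(epoch, "all", spectral.GAMMA_BAND)
        assert beta == pytest.approx(2.0, rel=0.05)  # A^2 / 2
        assert gamma < 0.01 * beta

    def test_silent_signal(self):
        epoch = make_epoch(np.zeros(1000), fs=200.0, t0=0.0, intervals={"all": (0.0, 5.0)})
        assert spectral.band_power(epoch, "all", (13.0, 30.0)) == 0.0

    def test_band_outside_nyquist(self):
        epoch = make_epoch(np.zeros(1000), fs=200.0, t0=0.0, intervals={"all": (0.0, 5.0)})
        with pytest.raises(ValueError, match="outside"):
            spectral.band_power(epoch, "all", (90.0, 150.0))


def brute_force_cluster_p(draw, rest, alpha=0.05):
    """Independent enumeration oracle: naive t, BFS labeling, all sign flips."""
    from scipy import stats as sps

    diff = draw - rest
    n = diff.shape[0]

    def t_map(d):
        return d.mean(0) / (d.std(0, ddof=1) / np.sqrt(n))

    def clusters(tm):
        t_crit = sps.t.ppf(alpha, n - 1)
        mask = tm <= t_crit
        seen = np.zeros_like(mask)
        out = []
        for i in range(mask.shape[0]):
            for j in range(mask.shape[1]):
                if mask[i, j] and not seen[i, j]:
                    stack, mass, members = [(i, j)], 0.0, []
                    seen[i, j] = True
                    while stack:
                        a, b = stack.pop()
                        mass += tm[a, b]
                        members.append((a, b))
                        for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                            u, v = a + da, b + db
                            if (
                                0 <= u < mask.shape[0]
                                and 0 <= v < mask.shape[1]
                                and mask[u, v]
                                and not seen[u, v]
                            ):
                                seen[u, v] = True
                                stack.append((u, v))
                    out.append(mass)
        return sorted(out)

    obs = clusters(t_map(diff))
    null = []
    for signs in itertools.product([1, -1], repeat=n):
        d = diff * np.array(signs)[:, None, None]
        cl = clusters(t_map(d))
        null.append(max(abs(m) for m in cl) if cl else 0.0)
    null = np.array(null)
    return obs, [np.mean(null >= abs(m) - 1e-9) for m in obs]


class TestClusterPermutation:
    def test_exact_enumeration_matches_oracle(self):
        draw, rest = simulate_warped_map_pair(
            6, (5, 8), effect=-0.4, noise_sd=0.3, seed=11
        )
        res = spectral.cluster_permutation_test(draw, rest, n_perm=5000)
        assert res.exact and res.n_perm == 64
        obs, pvals = brute_force_cluster_p(draw, rest)
        assert len(res.masses) == len(obs)
        assert np.allclose(sorted(res.masses), obs, atol=1e-9)
        assert np.allclose(sorted(res.p_values), sorted(pvals), atol=1e-12)

    def test_scale_invariance(self):
        draw, rest = simulate_warped_map_pair(8, (6, 10), effect=-0.3, seed=3)
        r1 = spectral.cluster_permutation_test(draw, rest, n_perm=500, seed=9)
        r2 = spectral.cluster_permutation_test(7.3 * draw, 7.3 * rest, n_perm=500, seed=9)
        assert np.allclose(r1.p_values, r2.p_values)

    def test_detects_injected_effect(self):
        mask = np.zeros((18, 50), bool)
        mask[2:13] = True  # 15-25 Hz rows of a 13-30 grid
        draw, rest = simulate_warped_map_pair(
            12, (18, 50), effect=-0.3, effect_mask=mask, noise_sd=0.25, seed=21
        )
        res = spectral.cluster_permutation_test(draw, rest, n_perm=500, seed=4)
        assert res.p_values.min() < 0.05
        sig = res.masks[int(np.argmin(res.p_values))]
        overlap = np.sum(sig & mask) / mask.sum()
        assert overlap >= 0.5

    def test_requires_equal_shapes(self):
        draw, rest = simulate_warped_map_pair(6, (4, 6), effect=0.0, seed=0)
        with pytest.raises(ValueError, match="identical shapes"):
            spectral.cluster_permutation_test(draw, rest[:, :, :-1])

    def test_requires_five_subjects(self):
        draw, rest = simulate_warped_map_pair(4, (4, 6), effect=0.0, seed=0)
        with pytest.raises(ValueError, match="5 subjects"):
            spectral.cluster_permutation_test(draw, rest)
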