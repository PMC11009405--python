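"""Time-frequency analysis and cluster-based permutation statistics.

Morlet maps (7-cycle wavelets, 4-100 Hz, 20 ms centers), linear time-warping
of rest/draw intervals onto fixed 50/100-sample segments, baseline-relative
power change, DPSS multitaper band power, and a paired sign-flip cluster
permutation test on the warped time-frequency grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.signal import fftconvolve
from scipy.signal.windows import dpss

MORLET_WIDTH = 7
TFR_FREQS_HZ = np.arange(4.0, 101.0)
TFR_STEP_S = 0.02
ONSET_EXCLUSION_S = 0.1
N_REST_SAMPLES = 50
N_DRAW_SAMPLES = 100
BETA_BAND = (13.0, 30.0)
GAMMA_BAND = (30.0, 45.0)


@dataclass
class TfrMap:
    """Time x frequency power map, optionally warped to fixed-length segments."""

    freqs: np.ndarray  # Hz
    times: np.ndarray  # s (unwarped) or warped sample index
    power: np.ndarray  # (n_freqs, n_times), microvolts^2; NaN where invalid
    warped: bool = False
    segments: dict = field(default_factory=dict)  # name -> slice into times

    def segment_power(self, name: str) -> np.ndarray:
        return self.power[:, self.segments[name]]

    def band_rows(self, band: tuple[float, float]) -> np.ndarray:
        return (self.freqs >= band[0]) & (self.freqs <= band[1])


@dataclass
class ClusterResult:
    """Clusters of suprathreshold paired-t bins with permutation p-values."""

    masks: list  # boolean (n_freqs, n_times) arrays, disjoint
    masses: np.ndarray  # summed t within each cluster, sorted by |mass| desc
    p_values: np.ndarray
    t_map: np.ndarray
    t_crit: float
    alpha_cluster: float
    n_perm: int
    tail: str
    exact: bool = False

    @property
    def any_significant(self) -> bool:
        return bool(len(self.p_values) and np.min(self.p_values) < 0.05)


def _morlet_kernel(freq: float, fs: float, width: int) -> np.ndarray:
    sigma_t = width / (2.0 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2 * sigma_t**2))
    kernel = gauss * np.exp(2j * np.pi * freq * t)
    # scale so a unit-amplitude sinusoid at `freq` yields amplitude ~1
    return kernel * (2.0 / gauss.sum())


def morlet_tfr(
    epoch,
    freqs: np.ndarray = TFR_FREQS_HZ,
    width: int = MORLET_WIDTH,
    step_s: float = TFR_STEP_S,
    onset_exclusion_s: float = ONSET_EXCLUSION_S,
) -> TfrMap:
    """Morlet wavelet power of a preprocessed epoch on a 20 ms grid.

    Edge samples without full wavelet support are NaN, as is the window of
    ``onset_exclusion_s`` on either side of the draw onset (t = 0), where
    trial alignment is unreliable.
    """
    x = epoch.signal
    fs = epoch.fs
    step = max(int(round(step_s * fs)), 1)
    times = epoch.t[::step]
    power = np.full((len(freqs), times.size), np.nan)
    dropped = []
    for i, f in enumerate(np.asarray(freqs, float)):
        kernel = _morlet_kernel(f, fs, width)
        half = (kernel.size - 1) // 2
        if kernel.size > x.size:
            dropped.append(f)
            continue
        analytic = fftconvolve(x, kernel, mode="same")
        p = np.abs(analytic) ** 2
        p[:half] = np.nan
        p[p.size - half :] = np.nan
        power[i] = p[::step]
    if dropped:
        warnings.warn(
            f"epoch too short for {width}-cycle wavelets at {dropped} Hz; rows dropped"
        )
    if onset_exclusion_s > 0:
        power[:, np.abs(times) <= onset_exclusion_s] = np.nan
    return TfrMap(freqs=np.asarray(freqs, float), times=times, power=power)


def _warp_segment(tfr: TfrMap, span: tuple[float, float], n_out: int) -> np.ndarray:
    lo, hi = span
    centers = lo + (np.arange(n_out) + 0.5) * (hi - lo) / n_out
    out = np.empty((tfr.power.shape[0], n_out))
    for i in range(tfr.power.shape[0]):
        row = tfr.power[i]
        valid = np.isfinite(row)
        if valid.sum() < 2:
            out[i] = np.nan
            continue
        out[i] = np.interp(centers, tfr.times[valid], row[valid])
    return out


def timewarp_tfr(
    tfr: TfrMap,
    rest_span: tuple[float, float],
    draw_span: tuple[float, float],
    n_rest: int = N_REST_SAMPLES,
    n_draw: int = N_DRAW_SAMPLES,
    step_s: float = TFR_STEP_S,
) -> TfrMap:
    """Warp rest/draw power linearly onto fixed 50 + 100 sample segments."""
    if tfr.warped:
        raise ValueError("map is already warped")
    if (draw_span[1] - draw_span[0]) < 10 * step_s:
        raise ValueError("draw interval shorter than 10 native TFR bins")
    rest = _warp_segment(tfr, rest_span, n_rest)
    draw = _warp_segment(tfr, draw_span, n_draw)
    power = np.concatenate([rest, draw], axis=1)
    assert power.shape[1] == n_rest + n_draw
    half = n_draw // 2
    segments = {
        "rest": slice(0, n_rest),
        "draw": slice(n_rest, n_rest + n_draw),
        "draw_early": slice(n_rest, n_rest + half),
        "draw_late": slice(n_rest + half, n_rest + n_draw),
    }
    return TfrMap(
        freqs=tfr.freqs.copy(),
        times=np.arange(power.shape[1], dtype=float),
        power=power,
        warped=True,
        segments=segments,
    )


def baseline_relchange(tfr: TfrMap, baseline: str = "rest") -> TfrMap:
    """Per-frequency relative power change (P - B) / B against the rest mean."""
    b = np.nanmean(tfr.segment_power(baseline), axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (tfr.power - b) / b
    rel[np.ravel(b == 0)] = np.nan
    return TfrMap(
        freqs=tfr.freqs.copy(),
        times=tfr.times.copy(),
        power=rel,
        warped=tfr.warped,
        segments=dict(tfr.segments),
    )


def band_power(
    epoch,
    interval: str,
    band: tuple[float, float],
    window_s: float = 1.0,
    halfbandwidth_hz: float = 2.0,
    statistic: str = "sum",
) -> float:
    """Multitaper band power of one epoch interval.

    DPSS tapers on non-overlapping ``window_s`` windows with 2 Hz smoothing,
    averaged over windows and tapers. ``statistic='sum'`` integrates the PSD
    over the band (total power, microvolts^2); ``'mean'`` averages the band
    bins instead (scale factor only).
    """
    fs = epoch.fs
    if band[0] < 0 or band[1] >= fs / 2:
        raise ValueError(f"band {band} outside [0, {fs / 2}) Hz")
    x = epoch.interval_signal(interval)
    nper = int(round(window_s * fs))
    if x.size < nper:
        raise ValueError("interval shorter than one analysis window")
    nw = halfbandwidth_hz * window_s
    n_tapers = max(int(2 * nw - 1), 1)
    tapers = dpss(nper, nw, Kmax=n_tapers)  # (K, nper), unit energy
    n_win = x.size // nper
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    psd = np.zeros(freqs.size)
    for w in range(n_win):
        seg = x[w * nper : (w + 1) * nper]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        p = (np.abs(spec) ** 2) / fs
        # one-sided PSD: double all bins except DC (and Nyquist when present)
        if nper % 2 == 0:
            p[:, 1:-1] *= 2
        else:
            p[:, 1:] *= 2
        psd += p.mean(axis=0)
    psd /= n_win
    df = freqs[1] - freqs[0]
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if statistic == "sum":
        return float(psd[sel].sum() * df)
    if statistic == "mean":
        return float(psd[sel].mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def _paired_t(diff_flat: np.ndarray) -> np.ndarray:
    n = diff_flat.shape[0]
    mean = diff_flat.mean(axis=0)
    sd = diff_flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return mean / (sd / np.sqrt(n))


def _cluster_masses(t_flat, shape, t_crit, tail, structure):
    t_map = t_flat.reshape(shape)
    mask = t_map <= t_crit if tail == "negative" else t_map >= t_crit
    labels, n_clusters = ndimage.label(mask, structure=structure)
    if n_clusters == 0:
        return labels, np.array([])
    masses = ndimage.sum_labels(t_map, labels, index=np.arange(1, n_clusters + 1))
    return labels, masses


def cluster_permutation_test(
    cond_maps: np.ndarray,
    rest_maps: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 5000,
    tail: str = "negative",
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Paired cluster-based permutation test over a time-frequency grid.

    Inputs are per-subject maps of equal shape ``(n_subjects, n_freqs,
    n_times)``. Bins whose paired t-statistic is beyond the one-sided
    ``alpha_cluster`` quantile form candidate clusters under 4-connectivity;
    cluster mass is the summed t. The null is the maximal cluster-mass
    magnitude under within-subject sign flips of the condition difference.
    When ``2**n_subjects <= n_perm`` all sign patterns are enumerated and
    p-values are exact.
    """
    cond_maps = np.asarray(cond_maps, float)
    rest_maps = np.asarray(rest_maps, float)
    if cond_maps.shape != rest_maps.shape:
        raise ValueError("condition and rest maps must have identical shapes")
    if cond_maps.ndim != 3:
        raise ValueError("maps must be (n_subjects, n_freqs, n_times)")
    n = cond_maps.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if tail not in ("negative", "positive"):
        raise ValueError(f"unknown tail {tail!r}")
    shape = cond_maps.shape[1:]
    diff = (cond_maps - rest_maps).reshape(n, -1)
    df = n - 1
    t_crit = (
        stats.t.ppf(alpha_cluster, df)
        if tail == "negative"
        else stats.t.isf(alpha_cluster, df)
    )
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity

    t_obs = _paired_t(diff)
    labels, masses = _cluster_masses(t_obs, shape, t_crit, tail, structure)

    exact = 2**n <= n_perm
    if exact:
        bits = np.arange(2**n)
        signs = 1 - 2 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

    # sign flips leave per-bin sums of squares unchanged; only means move
    sumsq = np.sum(diff**2, axis=0)
    null_max = np.zeros(signs.shape[0])
    chunk = max(1, int(5e7 // max(diff.size, 1)))
    for start in range(0, signs.shape[0], chunk):
        s = signs[start : start + chunk]
        means = s @ diff / n
        var = np.maximum(sumsq[None, :] - n * means**2, 0.0) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = means / np.sqrt(var / n)
        for k in range(t_perm.shape[0]):
            _, m = _cluster_masses(t_perm[k], shape, t_crit, tail, structure)
            null_max[start + k] = np.max(np.abs(m)) if m.size else 0.0

    order = np.argsort(-np.abs(masses))
    masses = masses[order]
    masks = [labels.reshape(shape) == (order[i] + 1) for i in range(len(order))]
    def _count(m):
        # tolerance so the identity permutation always counts against itself
        return np.sum(null_max >= abs(m) * (1 - 1e-10) - 1e-12)

    if exact:
        p_values = np.array([_count(m) / signs.shape[0] for m in masses])
    else:
        p_values = np.array([(1 + _count(m)) / (1 + signs.shape[0]) for m in masses])
    return ClusterResult(
        masks=masks,
        masses=masses,
        p_values=p_values,
        t_map=t_obs.reshape(shape),
        t_crit=float(t_crit),
        alpha_cluster=alpha_cluster,
        n_perm=int(signs.shape[0]),
        tail=tail,
        exact=exact,
    )
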