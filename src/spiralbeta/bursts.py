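"""Beta-burst detection: individual peak frequency, envelope, thresholding.

The envelope is the band-passed (individual beta peak +/- 2 Hz), rectified,
200 ms moving-average-smoothed LFP. Bursts are maximal runs of envelope
strictly above the 75th percentile of the pooled condition-specific rest
envelope, kept only when they last at least 100 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from spiralbeta.spectral import BETA_BAND, TfrMap

ENVELOPE_SMOOTH_S = 0.2
ENVELOPE_HALF_BW_HZ = 2.0
MIN_BURST_DURATION_S = 0.1
REST_PERCENTILE = 75.0
#: "similar levels" of desynchronization: relative difference below this
#: engages the rest-power fallback when picking the subject's beta peak.
PEAK_TIE_TOL = 0.05


@dataclass
class BetaBurst:
    onset: float  # s
    offset: float  # s
    peak_amplitude: float  # microvolts (smoothed envelope max)
    interval: str | None = None  # rest | draw
    subject: str = ""
    trial: str = ""
    condition: str = ""

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EnvelopeTrace:
    t: np.ndarray  # s
    env: np.ndarray  # microvolts, >= 0
    f_peak: float  # Hz
    fs: float
    threshold: float | None = None  # condition-specific, microvolts

    @property
    def band(self) -> tuple[float, float]:
        return (self.f_peak - ENVELOPE_HALF_BW_HZ, self.f_peak + ENVELOPE_HALF_BW_HZ)


@dataclass
class BurstMetrics:
    n_bursts: int
    rate: float  # bursts / s
    mean_duration: float  # s; NaN when no bursts
    mean_amplitude: float  # microvolts; NaN when no bursts
    interval_duration: float  # s
    log_mean_duration: float = field(default=np.nan)
    log_mean_amplitude: float = field(default=np.nan)
    flagged: bool = False


def find_beta_peak(
    tfr_warped: TfrMap,
    band: tuple[float, float] = BETA_BAND,
    tie_tol: float = PEAK_TIE_TOL,
) -> float:
    """Individual beta peak: frequency of deepest draw-phase desynchronization.

    Works on a subject-average warped map containing rest and draw segments.
    When the two deepest desynchronizations are within ``tie_tol`` relative
    difference — or nothing desynchronizes at all — the peak frequency of the
    rest spectrum is used instead.
    """
    rows = tfr_warped.band_rows(band)
    freqs = tfr_warped.freqs[rows]
    rest = np.nanmean(tfr_warped.segment_power("rest")[rows], axis=1)
    draw = np.nanmean(tfr_warped.segment_power("draw")[rows], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        relchange = (draw - rest) / rest
    rest_peak = float(freqs[np.nanargmax(rest)])
    if np.all(relchange >= 0) or np.all(~np.isfinite(relchange)):
        warnings.warn("no desynchronization in band; falling back to rest peak")
        return rest_peak
    order = np.argsort(relchange)  # most negative first
    deepest = relchange[order[0]]
    if len(order) > 1:
        second = relchange[order[1]]
        denom = abs(deepest)
        if denom > 0 and abs(deepest - second) / denom < tie_tol:
            return rest_peak
    return float(freqs[order[0]])


def beta_envelope(
    epoch,
    f_peak: float,
    half_bw_hz: float = ENVELOPE_HALF_BW_HZ,
    smooth_s: float = ENVELOPE_SMOOTH_S,
) -> EnvelopeTrace:
    """Band-pass at the individual beta peak, rectify, smooth 200 ms."""
    lo, hi = f_peak - half_bw_hz, f_peak + half_bw_hz
    if lo <= 4.0 or hi >= 100.0:
        raise ValueError(f"band ({lo}, {hi}) Hz outside (4, 100) Hz")
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=epoch.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epoch.signal)
    rect = np.abs(filtered)
    win = max(int(round(smooth_s * epoch.fs)), 1)
    env = uniform_filter1d(rect, size=win, mode="nearest")
    return EnvelopeTrace(t=epoch.t, env=env, f_peak=float(f_peak), fs=epoch.fs)


def rest_threshold(rest_envelopes: list[np.ndarray], percentile: float = REST_PERCENTILE) -> float:
    """Pooled percentile over all rest-interval envelope samples of a condition.

    Linear-interpolation percentile definition (numpy default).
    """
    pool = np.concatenate([np.asarray(e, float).ravel() for e in rest_envelopes]) if rest_envelopes else np.array([])
    if pool.size == 0:
        raise ValueError("empty rest envelope pool")
    return float(np.percentile(pool, percentile))


def detect_bursts(
    env: EnvelopeTrace,
    threshold: float,
    min_duration: float = MIN_BURST_DURATION_S,
) -> list[BetaBurst]:
    """Maximal runs of envelope strictly above threshold, >= ``min_duration``.

    Onset is the first suprathreshold sample time; offset the first subsequent
    sample at/below threshold (trace end + one sample period if the run is
    still open there). Ties at the threshold count as subthreshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = env.env > threshold
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    dt = 1.0 / env.fs
    out = []
    for s, e in zip(starts, stops):
        onset = env.t[s]
        offset = env.t[e] if e < env.t.size else env.t[-1] + dt
        if offset - onset < min_duration:
            continue
        out.append(
            BetaBurst(
                onset=float(onset),
                offset=float(offset),
                peak_amplitude=float(np.max(env.env[s:e])),
            )
        )
    return out


def assign_intervals(
    bursts: list[BetaBurst],
    intervals: dict,
    truncate: bool = True,
) -> list[BetaBurst]:
    """Label bursts by the interval containing their onset.

    Bursts straddling a boundary are truncated at it for duration accounting
    (set ``truncate=False`` to keep full extents). Bursts whose onset falls in
    no listed interval are dropped.
    """
    out = []
    for b in bursts:
        for name, (lo, hi) in intervals.items():
            if lo <= b.onset < hi:
                offset = min(b.offset, hi) if truncate else b.offset
                out.append(
                    BetaBurst(
                        onset=b.onset,
                        offset=offset,
                        peak_amplitude=b.peak_amplitude,
                        interval=name,
                        subject=b.subject,
                        trial=b.trial,
                        condition=b.condition,
                    )
                )
                break
    return out


def burst_metrics(bursts: list[BetaBurst], interval_duration: float) -> BurstMetrics:
    """Count, rate, mean duration/amplitude (with logs) for one interval."""
    if interval_duration <= 0:
        raise ValueError("interval duration must be positive")
    n = len(bursts)
    rate = n / interval_duration
    if n == 0:
        return BurstMetrics(
            n_bursts=0,
            rate=0.0,
            mean_duration=np.nan,
            mean_amplitude=np.nan,
            interval_duration=interval_duration,
            flagged=True,
        )
    mean_dur = float(np.mean([b.duration for b in bursts]))
    mean_amp = float(np.mean([b.peak_amplitude for b in bursts]))
    return BurstMetrics(
        n_bursts=n,
        rate=rate,
        mean_duration=mean_dur,
        mean_amplitude=mean_amp,
        interval_duration=interval_duration,
        log_mean_duration=float(np.log10(mean_dur)),
        log_mean_amplitude=float(np.log10(mean_amp)),
    )
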