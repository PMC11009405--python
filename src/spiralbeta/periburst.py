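"""Burst-triggered kinematics: pre/post-onset acceleration and trace deviation.

Mean acceleration is taken over 0.25 s windows immediately before and after
each burst onset, computed as the velocity change across the window divided
by its length (equal to the mean sample-wise acceleration under the
central-difference scheme used by :mod:`spiralbeta.kinematics`). Two control
constructions — a 50 ms linear onset grid and within-trial shuffles of the
real onsets — provide the null for the burst-locked deceleration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spiralbeta.kinematics import SpiralFit, VelocityProfile

PERI_WINDOW_S = 0.25
LINEAR_GRID_STEP_S = 0.05


@dataclass
class PeriBurstSample:
    """Paired pre/post mean accelerations around one burst onset."""

    onset: float  # s
    a_pre: float  # cm/s^2, mean over [onset - w, onset)
    a_post: float  # cm/s^2, mean over [onset, onset + w)
    delta_a: float  # a_post - a_pre
    v_onset: float  # cm/s, nearest-sample instantaneous velocity
    duration: float = np.nan  # burst covariate, s
    peak_amplitude: float = np.nan  # burst covariate, microvolts
    mode: str = "real"  # real | linear | shuffled
    subject: str = ""
    trial: str = ""
    condition: str = ""


def peri_burst_segments(
    profile: VelocityProfile,
    onsets: np.ndarray,
    draw_span: tuple[float, float] | None = None,
    window: float = PERI_WINDOW_S,
    covariates: list[dict] | None = None,
    mode: str = "real",
) -> tuple[list[PeriBurstSample], int]:
    """Pre/post mean acceleration for every eligible onset.

    Onsets without a full ``window`` margin inside the draw span (or the
    profile itself) are excluded; the exclusion count is returned alongside
    the samples. ``covariates`` optionally carries per-onset burst descriptors
    (``duration``, ``peak_amplitude``).
    """
    onsets = np.asarray(onsets, float)
    lo = profile.t[0] if draw_span is None else max(profile.t[0], draw_span[0])
    hi = profile.t[-1] if draw_span is None else min(profile.t[-1], draw_span[1])
    samples: list[PeriBurstSample] = []
    n_excluded = 0
    for i, onset in enumerate(onsets):
        if onset - window < lo or onset + window > hi:
            n_excluded += 1
            continue
        v_m, v_0, v_p = np.interp(
            [onset - window, onset, onset + window], profile.t, profile.v
        )
        a_pre = (v_0 - v_m) / window
        a_post = (v_p - v_0) / window
        j = int(np.argmin(np.abs(profile.t - onset)))
        cov = covariates[i] if covariates else {}
        samples.append(
            PeriBurstSample(
                onset=float(onset),
                a_pre=float(a_pre),
                a_post=float(a_post),
                delta_a=float(a_post - a_pre),
                v_onset=float(profile.v[j]),
                duration=float(cov.get("duration", np.nan)),
                peak_amplitude=float(cov.get("peak_amplitude", np.nan)),
                mode=mode,
            )
        )
    return samples, n_excluded


def control_onsets(
    draw_span: tuple[float, float],
    mode: str,
    real_onsets: np.ndarray | None = None,
    step: float = LINEAR_GRID_STEP_S,
    window: float = PERI_WINDOW_S,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Construct artificial burst onsets for the null analyses.

    ``linear``: a grid every ``step`` seconds over the eligible draw span.
    ``shuffled``: the same number of onsets as the real bursts, uniformly
    re-placed within the eligible span (seeded).
    """
    lo = draw_span[0] + window
    hi = draw_span[1] - window
    if hi <= lo:
        return np.array([])
    if mode == "linear":
        return np.arange(lo, hi, step)
    if mode == "shuffled":
        if real_onsets is None:
            raise ValueError("shuffled mode requires the real onsets")
        rng = np.random.default_rng(seed)
        return np.sort(rng.uniform(lo, hi, size=len(real_onsets)))
    raise ValueError(f"unknown mode {mode!r}")


def residual_deviation(
    fit: SpiralFit,
    t: np.ndarray,
    onsets: np.ndarray,
    window: float = PERI_WINDOW_S,
) -> tuple[list[tuple[float, float, float]], int]:
    """Mean |spiral-fit residual| in the pre/post windows around each onset.

    ``t`` maps the fit's per-sample residuals onto the trial clock. Onsets
    lying in the excluded first revolution are skipped and counted.
    Returns ``[(onset, dev_pre, dev_post), ...]`` and the exclusion count.
    """
    t = np.asarray(t, float)
    if t.size != fit.residuals.size:
        raise ValueError("time vector must match the fit's residuals")
    abs_res = np.abs(fit.residuals)
    out: list[tuple[float, float, float]] = []
    n_excluded = 0
    for onset in np.asarray(onsets, float):
        j = int(np.argmin(np.abs(t - onset)))
        if fit.fitted_mask is not None and not fit.fitted_mask[j]:
            n_excluded += 1
            continue
        pre = (t >= onset - window) & (t < onset)
        post = (t >= onset) & (t < onset + window)
        if not pre.any() or not post.any():
            n_excluded += 1
            continue
        out.append(
            (float(onset), float(abs_res[pre].mean()), float(abs_res[post].mean()))
        )
    return out, n_excluded
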