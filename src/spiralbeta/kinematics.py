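"""Pen-trace kinematics: velocity profiles, spiral-shape metrics, accuracy flags.

The processing chain mirrors the drawing-task analysis: a 10 Hz low-pass on
the raw pen positions, tangential velocity with Gaussian smoothing, the
radius-angle re-parameterization of the spiral, and an OLS fit of radius on
cumulative angle excluding the first revolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

#: Default low-pass cutoff for pen positions (Hz).
POSITION_LOWPASS_HZ = 10.0
#: Default Gaussian smoothing width for the velocity signal (seconds).
VELOCITY_SMOOTH_SIGMA_S = 0.025
#: Window used to locate the spiral center (seconds from trace start).
CENTER_WINDOW_S = 0.5
#: Angle assigned to the first sample, so the excluded first revolution is
#: exactly (-0.5*pi, 1.5*pi].
THETA_ORIGIN = -0.5 * np.pi


@dataclass
class KinematicTrial:
    """A timestamped pen trace with condition labels and QC flags."""

    t: np.ndarray  # s, strictly increasing
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    subject: str = ""
    drawing: str = "free"  # free | template
    stim: str = "off"  # off | on
    rotation: str | None = None  # cw | ccw | None (auto-detect)
    inaccurate: bool = False
    tremor_subject: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size < 2:
            raise ValueError("trial needs at least 2 samples")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("x/y must be finite")
        if self.drawing not in ("free", "template"):
            raise ValueError(f"unknown drawing condition {self.drawing!r}")
        if self.stim not in ("off", "on"):
            raise ValueError(f"unknown stim condition {self.stim!r}")

    @property
    def condition(self) -> str:
        return f"{self.drawing}_{self.stim}"

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class VelocityProfile:
    """Tangential velocity and sample-wise acceleration on the trial clock."""

    t: np.ndarray  # s
    v: np.ndarray  # cm/s, >= 0
    a: np.ndarray  # cm/s^2


@dataclass
class SpiralFit:
    """OLS fit of radius on unwrapped angle, first revolution excluded."""

    theta: np.ndarray  # rad, monotone increasing, theta[0] == -pi/2
    radius: np.ndarray  # cm
    slope: float  # cm/rad
    intercept: float  # cm
    rmse: float  # cm, over fitted points only
    residuals: np.ndarray  # cm, for ALL samples (line extrapolated)
    fitted_mask: np.ndarray = field(default=None)  # True where theta > 1.5*pi


def _resample_uniform(trial: KinematicTrial) -> KinematicTrial:
    dt = np.diff(trial.t)
    med = np.median(dt)
    t_new = np.arange(trial.t[0], trial.t[-1] + med / 2, med)
    return replace(
        trial,
        t=t_new,
        x=np.interp(t_new, trial.t, trial.x),
        y=np.interp(t_new, trial.t, trial.y),
    )


def preprocess_position(
    trial: KinematicTrial,
    cutoff_hz: float = POSITION_LOWPASS_HZ,
    order: int = 4,
) -> KinematicTrial:
    """Zero-phase Butterworth low-pass of the pen positions.

    Trials with timestamp jitter above 10% of the median sampling step are
    linearly resampled onto a uniform grid first.
    """
    dt = np.diff(trial.t)
    med = np.median(dt)
    if np.max(np.abs(dt - med)) > 0.1 * med:
        trial = _resample_uniform(trial)
    fs = trial.fs
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    # filtfilt needs enough samples for its edge padding; require 3 pads.
    padlen = 3 * (2 * order + 1)
    if trial.t.size <= 3 * padlen:
        raise ValueError(
            f"trial too short to filter: {trial.t.size} samples, need > {3 * padlen}"
        )
    x = signal.sosfiltfilt(sos, trial.x)
    y = signal.sosfiltfilt(sos, trial.y)
    return replace(trial, x=x, y=y)


def tangential_velocity(
    trial: KinematicTrial,
    smooth_sigma_s: float = VELOCITY_SMOOTH_SIGMA_S,
) -> VelocityProfile:
    """Instantaneous tangential velocity with Gaussian smoothing.

    Central differences in the interior, one-sided at the ends; the speed
    trace is then smoothed with a Gaussian kernel (sigma in seconds) and
    acceleration taken as its first difference over time.
    """
    if np.any(np.diff(trial.t) <= 0):
        raise ValueError("nonpositive time step")
    vx = np.gradient(trial.x, trial.t)
    vy = np.gradient(trial.y, trial.t)
    v = np.hypot(vx, vy)
    if smooth_sigma_s > 0:
        sigma_samples = smooth_sigma_s * trial.fs
        v = gaussian_filter1d(v, sigma_samples, mode="nearest")
    a = np.gradient(v, trial.t)
    return VelocityProfile(t=trial.t.copy(), v=v, a=a)


def trial_summary(profile: VelocityProfile) -> dict:
    """Mean tangential velocity of a trial and its log10.

    A zero mean velocity has no log; the trial is flagged instead of raising.
    """
    if profile.v.size == 0:
        raise ValueError("empty velocity profile")
    mean_v = float(np.mean(profile.v))
    out = {"mean_velocity": mean_v, "log_mean_velocity": np.nan, "flagged": False}
    if mean_v > 0:
        out["log_mean_velocity"] = float(np.log10(mean_v))
    else:
        out["flagged"] = True
    return out


def radius_angle_transform(
    trial: KinematicTrial,
    rotation: str | None = None,
    center: tuple[float, float] | None = None,
    center_window_s: float = CENTER_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-parameterize the trace as (cumulative angle, radius) about the center.

    The spiral center defaults to the centroid of the first ``center_window_s``
    seconds (drawing starts at the center by task design). The unwrapped angle
    is oriented so the dominant rotation increases theta — clockwise traces are
    negated, making mirrored left/right-hand spirals map identically — and
    shifted so theta[0] == -pi/2.
    """
    if center is None:
        m = trial.t <= trial.t[0] + center_window_s
        center = (float(np.mean(trial.x[m])), float(np.mean(trial.y[m])))
    dx = trial.x - center[0]
    dy = trial.y - center[1]
    radius = np.hypot(dx, dy)
    phi = np.unwrap(np.arctan2(dy, dx))
    if rotation is None:
        rotation = trial.rotation
    if rotation is None:
        rotation = "ccw" if phi[-1] >= phi[0] else "cw"
    if rotation == "cw":
        phi = -phi
    elif rotation != "ccw":
        raise ValueError(f"unknown rotation {rotation!r}")
    theta = phi - phi[0] + THETA_ORIGIN
    return theta, radius


def fit_spiral(theta: np.ndarray, radius: np.ndarray) -> SpiralFit:
    """OLS of radius on theta, excluding the first revolution.

    Points with theta <= 1.5*pi (one full revolution from the -pi/2 start)
    are excluded from the fit; residuals are nevertheless reported for every
    sample, with the fitted line extrapolated into the excluded region.
    """
    theta = np.asarray(theta, float)
    radius = np.asarray(radius, float)
    if theta[-1] - theta[0] < 3 * np.pi:
        raise ValueError(
            "net rotation below 1.5 revolutions; cannot exclude first revolution"
        )
    mask = theta > 1.5 * np.pi
    if int(mask.sum()) < 10:
        raise ValueError("fewer than 10 points beyond the first revolution")
    slope, intercept = np.polyfit(theta[mask], radius[mask], 1)
    predicted = slope * theta + intercept
    residuals = radius - predicted
    rmse = float(np.sqrt(np.mean(residuals[mask] ** 2)))
    return SpiralFit(
        theta=theta,
        radius=radius,
        slope=float(slope),
        intercept=float(intercept),
        rmse=rmse,
        residuals=residuals,
        fitted_mask=mask,
    )


def _segments_intersect_batch(p, q, a, b) -> np.ndarray:
    """Vectorized proper/touching intersection of segment (p,q) vs segments (a,b)."""

    def cross(o, d1, d2):
        return (d1[..., 0] - o[..., 0]) * (d2[..., 1] - o[..., 1]) - (
            d1[..., 1] - o[..., 1]
        ) * (d2[..., 0] - o[..., 0])

    d1 = cross(a, b, p)
    d2 = cross(a, b, q)
    d3 = cross(p, q, a)
    d4 = cross(p, q, b)
    proper = ((d1 > 0) != (d2 > 0)) & ((d3 > 0) != (d4 > 0)) & (d1 != d2) & (d3 != d4)

    def on_segment(u, v, w):
        return (
            (np.minimum(u[..., 0], v[..., 0]) <= w[..., 0])
            & (w[..., 0] <= np.maximum(u[..., 0], v[..., 0]))
            & (np.minimum(u[..., 1], v[..., 1]) <= w[..., 1])
            & (w[..., 1] <= np.maximum(u[..., 1], v[..., 1]))
        )

    touch = (
        ((d1 == 0) & on_segment(a, b, p))
        | ((d2 == 0) & on_segment(a, b, q))
        | ((d3 == 0) & on_segment(p, q, a))
        | ((d4 == 0) & on_segment(p, q, b))
    )
    return proper | touch


def detect_self_intersection(trial: KinematicTrial) -> bool:
    """True iff any two non-adjacent polyline segments of the trace intersect."""
    if trial.t.size < 4:
        raise ValueError("need at least 4 samples")
    pts = np.column_stack([trial.x, trial.y])
    starts = pts[:-1]
    ends = pts[1:]
    n = starts.shape[0]
    for i in range(n - 2):
        a = starts[i + 2 :]
        b = ends[i + 2 :]
        p = np.broadcast_to(starts[i], a.shape)
        q = np.broadcast_to(ends[i], a.shape)
        if np.any(_segments_intersect_batch(p, q, a, b)):
            return True
    return False
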