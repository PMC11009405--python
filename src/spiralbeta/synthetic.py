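"""Synthetic cohort generator with known injected ground truth.

Produces paired pen-trace and LFP trials for a cohort of subjects under the
2 x 2 design (free/template drawing x stimulation off/on):

* LFP = 1/f background + line noise + beta bursts (individual peak frequency,
  Hann-shaped envelopes, log-normal duration/amplitude) + optional 130 Hz
  stimulation artifact with suprathreshold segments;
* pen traces follow an Archimedean spiral whose tangential velocity grows
  with radius, with a burst-locked deceleration pulse injected only in the
  free-drawing condition (attenuated under stimulation).

Every random draw descends from the config seed, so identical configs give
bit-identical cohorts. Light-weight generators for calibration studies
(warped map pairs, velocity tables, velocity-noise profiles) live here too.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from spiralbeta.kinematics import KinematicTrial, VelocityProfile
from spiralbeta.lfp import LfpEpoch


@dataclass
class SimulationConfig:
    n_subjects: int = 19
    trials_per_condition: int = 12
    fs_lfp: float = 2048.0
    fs_tablet: float = 100.0  # must be <= 200
    beta_peak_range: tuple = (15.0, 28.0)  # Hz, within [13, 30]
    burst_rate_rest: float = 0.4  # bursts / s
    burst_rate_draw: float = 0.25
    burst_duration_dist: tuple = (-1.05, 0.35)  # log-normal (mu, sigma) of s
    burst_amplitude_dist: tuple = (1.4, 0.3)  # log-normal (mu, sigma) of uV
    draw_duration_factor: float = 0.7  # burst duration multiplier during draw
    draw_amplitude_factor: float = 0.8  # burst amplitude multiplier during draw
    stim_amplitude_factor: float = 0.7  # burst amplitude multiplier under stim
    coupling_decel: float = -0.8  # cm/s^2 pulse after burst onsets (free only)
    coupling_window: float = 0.25  # s
    spiral_loops: int = 5
    spiral_spacing: float = 1.5  # cm
    spiral_max_radius: float = 7.5  # cm
    noise_exponent: float = 1.5  # 1/f^chi background slope
    noise_rms_uv: float = 2.0
    line_noise_hz: float = 50.0
    line_noise_amp_uv: float = 1.5
    stim_artifact_hz: float = 130.0
    stim_artifact_amp_uv: float = 4.0
    artifact_fraction: float = 0.06  # target fraction of suprathreshold samples
    artifact_amp_uv: float = 40.0
    artifact_segment_s: float = 0.03
    rest_duration: float = 5.0  # s, rest = [-5, 0)
    pad_s: float = 2.0  # s before rest / after draw
    free_draw_duration: float = 15.0  # s (typical; not claimed faithful)
    template_draw_duration: float = 25.0
    duration_jitter_sd: float = 0.08  # log-normal sigma on draw duration
    stim_velocity_factor: float = 1.12  # multiplicative speed gain under stim
    subject_velocity_sd: float = 0.1  # SD of subject intercepts, log10 units
    subject_amplitude_sd: float = 0.2  # SD of subject burst-amplitude log factor
    position_noise_free_cm: float = 0.03
    position_noise_template_cm: float = 0.01
    tremor_fraction: float = 7.0 / 19.0
    tremor_freq_hz: float = 5.0
    tremor_amplitude_cm: float = 0.0  # off by default; flagged subjects only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_tablet > 200:
            raise ValueError("tablet sampling rate capped at 200 Hz")
        lo, hi = self.beta_peak_range
        if not (13.0 <= lo <= hi <= 30.0):
            raise ValueError("beta_peak_range must lie within [13, 30] Hz")
        for name in ("burst_rate_rest", "burst_rate_draw", "rest_duration",
                     "free_draw_duration", "template_draw_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 <= self.stim_amplitude_factor <= 1.0):
            raise ValueError("stim_amplitude_factor must be in [0, 1]")
        min_draw = min(self.free_draw_duration, self.template_draw_duration)
        if self.coupling_window >= min_draw:
            raise ValueError("coupling_window longer than the draw interval")

    @property
    def spiral_b(self) -> float:
        """Archimedean slope b in r = b * theta (cm/rad)."""
        return self.spiral_spacing / (2 * np.pi)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        for k in ("beta_peak_range", "burst_duration_dist", "burst_amplitude_dist"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SubjectEffects:
    subject: str
    f_beta: float  # Hz
    velocity_intercept: float  # log10 multiplicative speed offset
    amplitude_factor: float  # multiplicative burst-amplitude offset
    tremor: bool = False


@dataclass
class InjectedBurst:
    trial: str
    onset: float  # s
    offset: float  # s
    amplitude: float  # uV, envelope peak

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery oracles downstream."""

    bursts: dict = field(default_factory=dict)  # trial id -> list[InjectedBurst]
    coupling: dict = field(default_factory=dict)  # condition -> cm/s^2
    subject_effects: dict = field(default_factory=dict)  # subject -> SubjectEffects

    def to_json(self) -> str:
        return json.dumps(
            {
                "bursts": {
                    k: [[b.onset, b.offset, b.amplitude] for b in v]
                    for k, v in sorted(self.bursts.items())
                },
                "coupling": self.coupling,
                "subject_effects": {
                    k: asdict(v) for k, v in sorted(self.subject_effects.items())
                },
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class TrialRecord:
    subject: str
    trial_id: str
    drawing: str
    stim: str
    draw_duration: float
    kinematic: KinematicTrial
    lfp: LfpEpoch
    injected_bursts: list


@dataclass
class CohortDataset:
    config: SimulationConfig
    trials: list  # of TrialRecord
    ground_truth: GroundTruth

    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "subject": t.subject,
                "trial_id": t.trial_id,
                "drawing": t.drawing,
                "stim": t.stim,
                "draw_duration": t.draw_duration,
                "tremor_subject": t.kinematic.tremor_subject,
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# LFP synthesis


def _one_over_f_noise(n: int, fs: float, exponent: float, rms: float, rng) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nonzero = freqs > 0
    # flatten below 1 Hz so the variance does not blow up at DC
    shape[nonzero] = np.maximum(freqs[nonzero], 1.0) ** (-exponent / 2.0)
    spectrum = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _sample_bursts(
    config: SimulationConfig,
    span: tuple[float, float],
    rate: float,
    duration_factor: float,
    amplitude_factor: float,
    rng,
) -> list[tuple[float, float, float]]:
    """Poisson-process bursts (onset, duration, amplitude) within a span."""
    lo, hi = span
    n = rng.poisson(rate * (hi - lo))
    mu_d, sd_d = config.burst_duration_dist
    mu_a, sd_a = config.burst_amplitude_dist
    out = []
    for _ in range(n):
        dur = float(np.exp(rng.normal(mu_d, sd_d))) * duration_factor
        amp = float(np.exp(rng.normal(mu_a, sd_a))) * amplitude_factor
        onset = float(rng.uniform(lo, max(lo, hi - dur)))
        out.append((onset, min(onset + dur, hi) - onset, amp))
    return sorted(out)


def _merge_bursts(bursts: list[InjectedBurst]) -> list[InjectedBurst]:
    """Union of overlapping injected events (amplitude = max of the parts)."""
    if not bursts:
        return []
    bursts = sorted(bursts, key=lambda b: b.onset)
    merged = [bursts[0]]
    for b in bursts[1:]:
        last = merged[-1]
        if b.onset <= last.offset:
            merged[-1] = InjectedBurst(
                trial=last.trial,
                onset=last.onset,
                offset=max(last.offset, b.offset),
                amplitude=max(last.amplitude, b.amplitude),
            )
        else:
            merged.append(b)
    return merged


def simulate_lfp_epoch(
    config: SimulationConfig,
    drawing: str,
    stim: str,
    f_beta: float,
    seed,
    draw_duration: float | None = None,
    amplitude_factor: float = 1.0,
    subject: str = "",
    trial_id: str = "",
    inject_bursts: list | None = None,
) -> tuple[LfpEpoch, list[InjectedBurst]]:
    """One raw LFP epoch at the native rate plus its injected burst list.

    Span is ``[-rest - pad, draw_duration + pad]`` with draw onset at t = 0.
    Burst rate/duration/amplitude are modulated down during draw, and burst
    amplitude is additionally reduced by ``stim_amplitude_factor`` under
    stimulation. ``inject_bursts`` — explicit ``(onset, duration, amplitude)``
    triples — bypasses the stochastic burst sampling (recovery oracles).
    """
    lo, hi = config.beta_peak_range
    if not (lo <= f_beta <= hi):
        raise ValueError(f"f_beta {f_beta} outside beta_peak_range {config.beta_peak_range}")
    rng = np.random.default_rng(seed)
    if draw_duration is None:
        draw_duration = (
            config.free_draw_duration if drawing == "free" else config.template_draw_duration
        )
    fs = config.fs_lfp
    t0 = -(config.rest_duration + config.pad_s)
    n = int(round((draw_duration + config.pad_s - t0) * fs))
    t = t0 + np.arange(n) / fs

    x = _one_over_f_noise(n, fs, config.noise_exponent, config.noise_rms_uv, rng)
    x += config.line_noise_amp_uv * np.sin(
        2 * np.pi * config.line_noise_hz * t + rng.uniform(0, 2 * np.pi)
    )

    stim_factor = config.stim_amplitude_factor if stim == "on" else 1.0
    rest_span = (-config.rest_duration, 0.0)
    draw_span = (0.0, draw_duration)
    if inject_bursts is not None:
        raw_bursts = [
            (float(o), float(d), float(a) * stim_factor) for o, d, a in inject_bursts
        ]
    else:
        raw_bursts = _sample_bursts(
            config, rest_span, config.burst_rate_rest, 1.0,
            amplitude_factor * stim_factor, rng,
        ) + _sample_bursts(
            config, draw_span, config.burst_rate_draw, config.draw_duration_factor,
            amplitude_factor * stim_factor * config.draw_amplitude_factor, rng,
        )

    injected = []
    for onset, dur, amp in raw_bursts:
        i0 = int(round((onset - t0) * fs))
        m = int(round(dur * fs))
        if m < 2:
            continue
        envelope = amp * np.hanning(m)
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(m) / fs
        x[i0 : i0 + m] += envelope * np.sin(2 * np.pi * f_beta * tt + phase)
        injected.append(
            InjectedBurst(trial=trial_id, onset=onset, offset=onset + dur, amplitude=amp)
        )
    injected = _merge_bursts(injected)

    if stim == "on":
        x += config.stim_artifact_amp_uv * np.sin(
            2 * np.pi * config.stim_artifact_hz * t + rng.uniform(0, 2 * np.pi)
        )
        seg = max(int(round(config.artifact_segment_s * fs)), 1)
        n_seg = int(round(config.artifact_fraction * n / seg))
        for _ in range(n_seg):
            i0 = int(rng.integers(0, n - seg))
            x[i0 : i0 + seg] += config.artifact_amp_uv * rng.choice([-1.0, 1.0]) * np.hanning(seg)

    epoch = LfpEpoch(
        signal=x,
        fs=fs,
        t0=t0,
        intervals={"rest": rest_span, "draw": draw_span},
        subject=subject,
        drawing=drawing,
        stim=stim,
    )
    return epoch, injected


# --------------------------------------------------------------------------
# Kinematic synthesis


def simulate_spiral_trial(
    config: SimulationConfig,
    drawing: str,
    stim: str,
    seed,
    burst_onsets=(),
    draw_duration: float | None = None,
    velocity_multiplier: float = 1.0,
    tremor: bool = False,
    position_noise_cm: float | None = None,
    subject: str = "",
    rotation: str = "cw",
) -> KinematicTrial:
    """Archimedean-spiral pen trace with optional burst-locked deceleration.

    The base tangential velocity grows linearly over the trial (so it grows
    with radius) and is scaled to complete ``spiral_loops`` revolutions in the
    trial duration. In the free condition a pulse of ``coupling_decel`` cm/s^2
    lasting ``coupling_window`` s starts at every burst onset, attenuated by
    ``stim_amplitude_factor`` under stimulation. Template trials use a longer
    base duration and lower positional noise than free ones.
    """
    if drawing not in ("free", "template"):
        raise ValueError(f"unknown drawing condition {drawing!r}")
    rng = np.random.default_rng(seed)
    if draw_duration is None:
        draw_duration = (
            config.free_draw_duration if drawing == "free" else config.template_draw_duration
        )
    if config.coupling_window >= draw_duration:
        raise ValueError("coupling_window longer than the trial")
    for onset in burst_onsets:
        if not (0.0 <= onset <= draw_duration):
            raise ValueError(f"burst onset {onset} outside the draw span")
    if position_noise_cm is None:
        position_noise_cm = (
            config.position_noise_free_cm if drawing == "free"
            else config.position_noise_template_cm
        )

    fs = config.fs_tablet
    n = int(round(draw_duration * fs)) + 1
    t = np.arange(n) / fs
    b = config.spiral_b
    theta_max = 2 * np.pi * config.spiral_loops
    # arc length of r = b*theta: integral of sqrt(b^2 + r^2) dtheta
    th = np.linspace(0, theta_max, 4096)
    arc = np.trapezoid(np.sqrt(b**2 + (b * th) ** 2), th)

    # base speed ramps 1x -> 3x so tangential velocity grows with radius
    c = arc / (2.0 * draw_duration)
    v = c * (1.0 + 2.0 * t / draw_duration) * velocity_multiplier

    coupling = config.coupling_decel if drawing == "free" else 0.0
    if stim == "on":
        coupling *= config.stim_amplitude_factor
    if coupling != 0.0:
        pulse = np.zeros(n)
        for onset in burst_onsets:
            sel = (t >= onset) & (t < onset + config.coupling_window)
            pulse[sel] += coupling
        v = v + np.cumsum(pulse) / fs
    v = np.maximum(v, 0.05)

    # integrate theta' = v / sqrt(b^2 + r^2)
    theta = np.empty(n)
    theta[0] = 0.0
    for i in range(1, n):
        r = b * theta[i - 1]
        theta[i] = theta[i - 1] + v[i - 1] / np.hypot(b, r) / fs
    radius = b * theta
    sign = -1.0 if rotation == "cw" else 1.0
    x = radius * np.cos(sign * theta)
    y = radius * np.sin(sign * theta)

    if tremor and config.tremor_amplitude_cm > 0:
        ph = rng.uniform(0, 2 * np.pi, size=2)
        x = x + config.tremor_amplitude_cm * np.sin(2 * np.pi * config.tremor_freq_hz * t + ph[0])
        y = y + config.tremor_amplitude_cm * np.sin(2 * np.pi * config.tremor_freq_hz * t + ph[1])
    if position_noise_cm > 0:
        x = x + rng.normal(0, position_noise_cm, size=n)
        y = y + rng.normal(0, position_noise_cm, size=n)

    return KinematicTrial(
        t=t, x=x, y=y, subject=subject, drawing=drawing, stim=stim,
        rotation=rotation, tremor_subject=tremor,
    )


# --------------------------------------------------------------------------
# Cohort assembly


def draw_subject_effects(config: SimulationConfig, rng) -> list[SubjectEffects]:
    n_tremor = int(round(config.tremor_fraction * config.n_subjects))
    effects = []
    for i in range(config.n_subjects):
        effects.append(
            SubjectEffects(
                subject=f"S{i + 1:02d}",
                f_beta=float(np.round(rng.uniform(*config.beta_peak_range))),
                velocity_intercept=float(rng.normal(0, config.subject_velocity_sd)),
                amplitude_factor=float(np.exp(rng.normal(0, config.subject_amplitude_sd))),
                tremor=i < n_tremor,
            )
        )
    return effects


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Full cohort: subjects x 4 conditions x trials, kinematics + LFP paired.

    Kinematic and LFP trials share the burst onsets and the t = 0 draw-onset
    clock. All randomness descends from ``config.seed``.
    """
    root_ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root_ss.spawn(1)[0])
    effects = draw_subject_effects(config, rng)
    gt = GroundTruth(
        coupling={
            "free_off": config.coupling_decel,
            "free_on": config.coupling_decel * config.stim_amplitude_factor,
            "template_off": 0.0,
            "template_on": 0.0,
        },
        subject_effects={e.subject: e for e in effects},
    )
    trials = []
    conditions = [(d, s) for d in ("free", "template") for s in ("off", "on")]
    trial_ss = root_ss.spawn(config.n_subjects * 4 * config.trials_per_condition * 2)
    k = 0
    for eff in effects:
        for drawing, stim in conditions:
            base = (
                config.free_draw_duration if drawing == "free"
                else config.template_draw_duration
            )
            speed_mult = 10.0**eff.velocity_intercept
            if stim == "on":
                speed_mult *= config.stim_velocity_factor
            for j in range(config.trials_per_condition):
                trial_id = f"{eff.subject}_{drawing}_{stim}_{j + 1:02d}"
                jitter_rng = np.random.default_rng(trial_ss[k])
                duration = base * float(
                    np.exp(jitter_rng.normal(0, config.duration_jitter_sd))
                ) / speed_mult
                lfp, injected = simulate_lfp_epoch(
                    config, drawing, stim, eff.f_beta, trial_ss[k],
                    draw_duration=duration, amplitude_factor=eff.amplitude_factor,
                    subject=eff.subject, trial_id=trial_id,
                )
                onsets = [b.onset for b in injected if 0.0 <= b.onset < duration]
                kin = simulate_spiral_trial(
                    config, drawing, stim, trial_ss[k + 1],
                    burst_onsets=onsets, draw_duration=duration,
                    velocity_multiplier=speed_mult, tremor=eff.tremor,
                    subject=eff.subject,
                )
                gt.bursts[trial_id] = injected
                trials.append(
                    TrialRecord(
                        subject=eff.subject, trial_id=trial_id, drawing=drawing,
                        stim=stim, draw_duration=duration, kinematic=kin,
                        lfp=lfp, injected_bursts=injected,
                    )
                )
                k += 2
    return CohortDataset(config=config, trials=trials, ground_truth=gt)


# --------------------------------------------------------------------------
# Light-weight generators for calibration studies


def simulate_warped_map_pair(
    n_subjects: int,
    shape: tuple[int, int],
    effect: float,
    effect_mask: np.ndarray | None = None,
    noise_sd: float = 0.3,
    subject_sd: float = 0.1,
    baseline: float = 1.0,
    seed=None,
):
    """Paired draw/rest warped maps with a known relative power change.

    ``effect`` is the relative draw-vs-rest change (e.g. -0.3 for a 30% drop)
    applied inside ``effect_mask`` (whole map when None). Used for type-I and
    power calibration of the cluster permutation test.
    """
    rng = np.random.default_rng(seed)
    subj = baseline + rng.normal(0, subject_sd, size=(n_subjects, 1, 1))
    rest = subj + rng.normal(0, noise_sd, size=(n_subjects, *shape))
    draw = subj + rng.normal(0, noise_sd, size=(n_subjects, *shape))
    if effect != 0.0:
        mask = np.ones(shape, bool) if effect_mask is None else effect_mask
        draw = draw + np.where(mask, effect * baseline, 0.0)
    return draw, rest


def simulate_velocity_table(
    n_subjects: int = 19,
    trials_per_condition: int = 12,
    intercept: float = 0.8,
    stim_effect: float = 0.05,
    drawing_effect: float = -0.15,
    interaction: float = 0.0,
    subject_sd: float = 0.1,
    residual_sd: float = 0.08,
    seed=None,
) -> pd.DataFrame:
    """Tidy log10-velocity trial table with known fixed and random effects.

    ``drawing_effect`` is the template-minus-free contrast, ``stim_effect``
    the on-minus-off contrast, both on the log10 scale.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        u = rng.normal(0, subject_sd)
        for drawing in ("free", "template"):
            for stim in ("off", "on"):
                mu = (
                    intercept + u
                    + (stim_effect if stim == "on" else 0.0)
                    + (drawing_effect if drawing == "template" else 0.0)
                    + (interaction if (stim == "on" and drawing == "template") else 0.0)
                )
                for j in range(trials_per_condition):
                    rows.append(
                        {
                            "subject": f"S{i + 1:02d}",
                            "drawing": drawing,
                            "stim": stim,
                            "log_velocity": mu + rng.normal(0, residual_sd),
                            "inaccurate": False,
                            "tremor_subject": False,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_velocity_profile(
    duration: float,
    fs: float = 100.0,
    v0: float = 4.0,
    base_accel: float = 0.4,
    noise_sd: float = 0.0,
    noise_smooth_s: float = 0.05,
    onsets=(),
    coupling: float = 0.0,
    coupling_window: float = 0.25,
    seed=None,
) -> VelocityProfile:
    """Direct velocity-profile generator (no spiral geometry) for null studies.

    The baseline is a linear ramp (window-scale-stationary acceleration) plus
    optional smoothed Gaussian noise; coupling pulses mirror the cohort
    generator's burst-locked deceleration.
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    v = v0 + base_accel * t
    if noise_sd > 0:
        noise = rng.normal(0, noise_sd, size=n)
        if noise_smooth_s > 0:
            noise = gaussian_filter1d(noise, noise_smooth_s * fs, mode="nearest")
        v = v + noise
    if coupling != 0.0:
        pulse = np.zeros(n)
        for onset in onsets:
            pulse[(t >= onset) & (t < onset + coupling_window)] += coupling
        v = v + np.cumsum(pulse) / fs
    a = np.gradient(v, t)
    return VelocityProfile(t=t, v=v, a=a)
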