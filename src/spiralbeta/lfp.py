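"""LFP conditioning: high-pass, resampling, notch filtering, artifact repair.

Chain order (fixed): zero-phase 4 Hz high-pass at the native rate, polyphase
resampling to 200 Hz with anti-aliasing at the new Nyquist, demeaning, linear
detrending, then DFT notches at 50 and 100 Hz (plus 130 Hz under stimulation).
Stimulation epochs additionally get threshold-based segment repair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

TARGET_FS = 200.0
HIGHPASS_HZ = 4.0
NOTCH_FREQS_HZ = (50.0, 100.0)
STIM_NOTCH_HZ = 130.0
ARTIFACT_THRESHOLD_UV = 10.0
#: Half-width of the DFT notch (a 1 Hz bin around each target frequency).
NOTCH_HALF_WIDTH_HZ = 0.5


@dataclass
class LfpEpoch:
    """Single-channel LFP for one trial; draw onset defines t = 0."""

    signal: np.ndarray  # microvolts
    fs: float  # Hz
    t0: float  # time of first sample, s
    intervals: dict  # name -> (start_s, end_s), half-open [start, end)
    subject: str = ""
    drawing: str = "free"
    stim: str = "off"
    unusable: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        span = (self.t0, self.t0 + self.signal.size / self.fs)
        for name, (lo, hi) in self.intervals.items():
            if lo < span[0] - 1e-9 or hi > span[1] + 1e-9:
                raise ValueError(
                    f"interval {name!r}=({lo}, {hi}) outside epoch span {span}"
                )

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.signal.size) / self.fs

    def interval_slice(self, name: str) -> slice:
        lo, hi = self.intervals[name]
        i0 = int(np.ceil((lo - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((hi - self.t0) * self.fs - 1e-9))
        return slice(max(i0, 0), min(i1, self.signal.size))

    def interval_signal(self, name: str) -> np.ndarray:
        return self.signal[self.interval_slice(name)]


def dft_notch(
    x: np.ndarray, fs: float, freq_hz: float, half_width_hz: float = NOTCH_HALF_WIDTH_HZ
) -> np.ndarray:
    """Remove Fourier coefficients within ``half_width_hz`` of ``freq_hz``."""
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    spectrum[np.abs(freqs - freq_hz) <= half_width_hz] = 0.0
    return np.fft.irfft(spectrum, n=x.size)


def resample_lfp(epoch: LfpEpoch, target_fs: float = TARGET_FS) -> LfpEpoch:
    """Rational polyphase resampling with anti-aliasing at the target Nyquist.

    2048 -> 200 Hz is the non-integer default (up 25 / down 256). Timestamps
    are regenerated on a uniform grid anchored at the original ``t0``; interval
    boundaries are stored in seconds and therefore survive unchanged.
    """
    if target_fs >= epoch.fs:
        raise ValueError(f"target_fs {target_fs} must be below fs {epoch.fs}")
    ratio = Fraction(target_fs / epoch.fs).limit_denominator(10000)
    y = signal.resample_poly(epoch.signal, ratio.numerator, ratio.denominator, padtype="line")
    return replace(epoch, signal=y, fs=target_fs)


def preprocess_lfp(
    raw: LfpEpoch,
    target_fs: float = TARGET_FS,
    highpass_hz: float = HIGHPASS_HZ,
    notch_freqs: tuple = NOTCH_FREQS_HZ,
) -> LfpEpoch:
    """Full conditioning chain on a raw native-rate epoch.

    Stimulation epochs get the extra 130 Hz notch; artifact segment repair is
    a separate step (:func:`suppress_stim_artifact`).
    """
    if raw.signal.size / raw.fs < 1.0:
        raise ValueError("epoch shorter than 1 s")
    sos = signal.butter(4, highpass_hz, btype="high", fs=raw.fs, output="sos")
    x = signal.sosfiltfilt(sos, raw.signal)
    epoch = resample_lfp(replace(raw, signal=x), target_fs)
    x = epoch.signal
    x = x - np.mean(x)
    x = signal.detrend(x, type="linear")
    freqs = list(notch_freqs)
    if raw.stim == "on":
        freqs.append(STIM_NOTCH_HZ)
    for f in freqs:
        if f > epoch.fs / 2:
            # stimulation frequency sits above the post-resampling Nyquist;
            # any leakage appears at its alias
            f = epoch.fs - f
        x = dft_notch(x, epoch.fs, f)
    return replace(epoch, signal=x)


def suppress_stim_artifact(
    epoch: LfpEpoch,
    threshold_uv: float = ARTIFACT_THRESHOLD_UV,
) -> tuple[LfpEpoch, float]:
    """Replace suprathreshold segments by linear interpolation.

    Samples with ``|signal| > threshold_uv`` are marked; each contiguous marked
    run is replaced by a straight line between the flanking clean samples.
    Returns the repaired epoch and the fraction of samples replaced. Epochs
    losing more than half their samples are flagged unusable.
    """
    x = epoch.signal.copy()
    bad = np.abs(x) > threshold_uv
    fraction = float(np.mean(bad))
    if fraction > 0:
        idx = np.arange(x.size)
        if bad.all():
            x[:] = 0.0
        else:
            x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    out = replace(epoch, signal=x)
    if fraction > 0.5:
        warnings.warn(
            f"artifact repair removed {fraction:.0%} of samples; epoch flagged unusable"
        )
        out = replace(out, unusable=True)
    return out, fraction
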