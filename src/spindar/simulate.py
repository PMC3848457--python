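"""Seeded synthetic generators for the two validation studies.

Two families of fixtures, both with exact ground truth:

* piecewise AR(2) processes whose coefficients or innovation variance
  change at a known sample — for verifying that the sequential estimator
  tracks a change point;
* multichannel "EEG" containing 10 Hz, 500 ms oscillatory bursts every
  5 s over 3 uV-RMS white background noise at a controllable SNR — for
  end-to-end detector validation.  A forward head model is deliberately
  not simulated: bursts project onto the 33-channel montage through
  fixed spatial gains that fall off smoothly from the parietal-occipital
  electrodes, which preserves the SNR sweep the validation rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .events import EventList

__all__ = [
    "ARChangeSpec",
    "SpindleSimSpec",
    "MONTAGE_33",
    "channel_gains",
    "simulate_ar_changepoint",
    "simulate_spindle_eeg",
    "preprocess",
    "model1_spec",
    "model2_spec",
]

# 33-channel 10-10 mosaic, frontal to occipital, with coarse 2D positions
# (x lateral in [-1, 1], y anterior(+)/posterior(-)).
MONTAGE_33: dict[str, tuple[float, float]] = {
    "Fp1": (-0.3, 0.95), "Fpz": (0.0, 1.0), "Fp2": (0.3, 0.95),
    "F7": (-0.8, 0.6), "F3": (-0.4, 0.6), "Fz": (0.0, 0.6),
    "F4": (0.4, 0.6), "F8": (0.8, 0.6),
    "FC5": (-0.6, 0.3), "FC1": (-0.2, 0.3), "FC2": (0.2, 0.3), "FC6": (0.6, 0.3),
    "T7": (-1.0, 0.0), "C3": (-0.4, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.4, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.6, -0.3), "CP1": (-0.2, -0.3), "CP2": (0.2, -0.3), "CP6": (0.6, -0.3),
    "P7": (-0.8, -0.6), "P3": (-0.4, -0.6), "Pz": (0.0, -0.6),
    "P4": (0.4, -0.6), "P8": (0.8, -0.6),
    "PO7": (-0.5, -0.8), "PO3": (-0.25, -0.8), "POz": (0.0, -0.8),
    "PO4": (0.25, -0.8), "PO8": (0.5, -0.8),
    "O1": (-0.25, -0.95), "O2": (0.25, -0.95),
}


def channel_gains(labels: list[str] | None = None, sigma: float = 0.45) -> np.ndarray:
    """Spatial gains from two symmetric parietal-occipital sources.

    Gaussian fall-off from centres at (+-0.25, -0.85); normalised so the
    best-coupled channel has gain 1.
    """
    if labels is None:
        labels = list(MONTAGE_33)
    centres = [(-0.25, -0.85), (0.25, -0.85)]
    g = np.empty(len(labels))
    for i, lab in enumerate(labels):
        x, y = MONTAGE_33[lab]
        g[i] = max(
            np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
            for cx, cy in centres
        )
    return g / g.max()


def _check_stationary(coeffs: np.ndarray) -> None:
    # roots of 1 - a1 z^-1 - ... - ap z^-p must lie inside the unit circle
    poly = np.concatenate(([1.0], -np.asarray(coeffs, dtype=float)))
    roots = np.roots(poly)
    if roots.size and np.abs(roots).max() >= 1.0:
        raise ValueError(f"AR segment {coeffs} is non-stationary")


@dataclass
class ARChangeSpec:
    """Piecewise-AR process: (coefficients, innovation sd, n_samples) per segment."""

    segments: list[tuple[np.ndarray, float, int]]
    seed: int = 0
    burn_in: int = 500

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        self.segments = [
            (np.asarray(c, dtype=float).ravel(), float(sd), int(n))
            for c, sd, n in self.segments
        ]
        for c, _, n in self.segments:
            if n <= 0:
                raise ValueError("segment lengths must be positive")
            _check_stationary(c)

    @property
    def order(self) -> int:
        return max(c.size for c, _, _ in self.segments)

    @property
    def changepoints(self) -> list[int]:
        bounds = np.cumsum([n for _, _, n in self.segments])[:-1]
        return [int(b) for b in bounds]


def model1_spec(seed: int = 0) -> ARChangeSpec:
    """AR(2) coefficient change: (0.6, -0.2) -> (0.4, -0.6) at sample 2000."""
    return ARChangeSpec(
        segments=[((0.6, -0.2), 1.0, 2000), ((0.4, -0.6), 1.0, 2000)], seed=seed
    )


def model2_spec(seed: int = 0) -> ARChangeSpec:
    """AR(2) variance change: innovation sd 1 -> 2 (variance 1 -> 4) at 2000."""
    return ARChangeSpec(
        segments=[((0.6, -0.2), 1.0, 2000), ((0.6, -0.2), 2.0, 2000)], seed=seed
    )


def simulate_ar_changepoint(spec: ARChangeSpec):
    """Simulate the piecewise AR process.

    Lag values carry over continuously across segment boundaries; a
    burn-in run of the first segment is discarded so segment 1 starts in
    its stationary regime.  Returns ``(signal, changepoints)``.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.order
    n_total = sum(n for _, _, n in spec.segments)
    x = np.zeros(spec.burn_in + n_total)
    pos = 0
    for seg_i, (coeffs, sd, n_seg) in enumerate(spec.segments):
        n_run = n_seg + (spec.burn_in if seg_i == 0 else 0)
        eps = sd * rng.standard_normal(n_run)
        for k in range(n_run):
            t = pos + k
            acc = eps[k]
            for i, a in enumerate(coeffs, start=1):
                if t - i >= 0:
                    acc += a * x[t - i]
            x[t] = acc
        pos += n_run
    return x[spec.burn_in:], spec.changepoints


@dataclass
class SpindleSimSpec:
    """Multichannel burst-over-noise EEG simulation parameters.

    ``snr`` is the burst's peak amplitude on the best-coupled channel
    divided by the background RMS (amplitude factor / noise RMS).
    """

    snr: float = 3.0
    fs_gen: float = 300.0
    fs_out: float = 128.0
    n_channels: int = 33
    burst_freq_hz: float = 10.0
    burst_dur_s: float = 0.5
    burst_period_s: float = 5.0
    first_burst_s: float = 10.0
    n_bursts: int = 20
    noise_rms_uv: float = 3.0
    duration_s: float | None = None
    taper_frac: float = 0.1
    seed: int = 0
    channel_labels: list[str] = field(default_factory=lambda: list(MONTAGE_33))

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.n_channels != len(self.channel_labels):
            raise ValueError("n_channels must match channel_labels")
        last = self.first_burst_s + (self.n_bursts - 1) * self.burst_period_s
        if self.duration_s is None:
            self.duration_s = last + self.burst_dur_s + self.first_burst_s / 2
        if self.duration_s < last + self.burst_dur_s:
            raise ValueError("recording ends before the last burst")

    def truth_events(self) -> EventList:
        onsets = self.first_burst_s + self.burst_period_s * np.arange(self.n_bursts)
        return EventList(
            [(t, t + self.burst_dur_s) for t in onsets], source="truth"
        )


def simulate_spindle_eeg(spec: SpindleSimSpec):
    """Simulate bursts of alpha over white noise on the 33-channel mosaic.

    Returns ``(data, truth, labels)`` with ``data`` shaped
    (n_channels, n_samples) at ``spec.fs_gen``, in microvolts.  Each
    burst is a ``burst_freq_hz`` sinusoid with a cosine-tapered envelope
    (Tukey, ``taper_frac``), peak amplitude
    ``snr * noise_rms_uv * channel_gain``.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs_gen
    n = int(round(spec.duration_s * fs))
    gains = channel_gains(spec.channel_labels)
    data = spec.noise_rms_uv * rng.standard_normal((spec.n_channels, n))

    n_burst = int(round(spec.burst_dur_s * fs))
    envelope = sps.windows.tukey(n_burst, alpha=spec.taper_frac)
    t_burst = np.arange(n_burst) / fs
    tone = np.sin(2 * np.pi * spec.burst_freq_hz * t_burst) * envelope
    amp = spec.snr * spec.noise_rms_uv
    truth = spec.truth_events()
    for onset, _ in truth.intervals:
        i0 = int(round(onset * fs))
        data[:, i0: i0 + n_burst] += amp * np.outer(gains, tone)
    return data, truth, list(spec.channel_labels)


def preprocess(
    x: np.ndarray,
    fs_in: float,
    band: tuple[float, float] = (6.0, 15.0),
    order: int = 8,
    fs_out: float | None = None,
    zero_phase: bool = True,
):
    """Anti-aliased resampling followed by a Butterworth band-pass.

    ``order`` is the overall band-pass order; the filter is applied
    forward-backward by default (zero phase, which doubles the effective
    attenuation), with a causal option for online use.  Returns
    ``(filtered, fs)``.
    """
    x = np.asarray(x, dtype=float)
    was_1d = x.ndim == 1
    x = np.atleast_2d(x)
    fs = float(fs_in)
    if fs_out is not None and fs_out != fs_in:
        from fractions import Fraction

        frac = Fraction(fs_out / fs_in).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
        fs = fs_in * frac.numerator / frac.denominator
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} invalid for Nyquist {fs / 2} Hz")
    if order % 2:
        raise ValueError("band-pass order must be even")
    sos = sps.butter(order // 2, band, btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        y = sps.sosfiltfilt(sos, x, axis=-1)
    else:
        y = sps.sosfilt(sos, x, axis=-1)
    return (y[0] if was_1d else y), fs
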