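"""Amplitude-spectral-density (FWHM) baseline spindle detector.

The comparison detector works on sliding 1 s Hamming-windowed segments
(250 ms slide): it finds the largest spectral peak in [3, 40] Hz; when
that peak falls inside the alpha band [8, 13] Hz and its full width at
half maximum is below twice the Hamming window's noise bandwidth
(2 x 1.37 Hz at 1 Hz resolution), the segment is classified as an alpha
spindle.  A one-parameter exponential ``exp(gamma * f)`` fitted to the
spectrum estimates the 1/f-like background, and the oscillation index —
the ratio of the spectral area inside the FWHM band to the area of the
background fit over the same band — serves as a spectral SNR proxy (it
is reported, not gated on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .detect import postprocess_events
from .events import EventList

__all__ = [
    "ASDWindowResult",
    "HAMMING_NBW_HZ",
    "asd_spectrum",
    "fit_noise_exponential",
    "asd_classify_window",
    "asd_detect",
]

HAMMING_NBW_HZ = 1.37  # noise bandwidth of the Hamming window, in bins (1 Hz at 1 s)
PEAK_BAND_HZ = (3.0, 40.0)
ALPHA_BAND_HZ = (8.0, 13.0)


@dataclass
class ASDWindowResult:
    """Spectral classification of one 1 s analysis window."""

    t_start_s: float
    peak_freq_hz: float
    fwhm_hz: float | None
    gamma: float | None
    oscillation_index: float | None
    is_spindle: bool


def asd_spectrum(window_samples: np.ndarray, fs: float, pad_factor: int = 1):
    """Amplitude spectral density of one Hamming-tapered 1 s window.

    ``pad_factor`` zero-pads the FFT to refine the frequency grid below
    the native 1 Hz resolution.
    """
    x = np.asarray(window_samples, dtype=float).ravel()
    n_expected = int(round(fs))
    if x.size != n_expected:
        raise ValueError(f"window must hold exactly 1 s of samples ({n_expected})")
    nfft = x.size * int(pad_factor)
    freqs, psd = signal.periodogram(
        x, fs=fs, window="hamming", nfft=nfft, detrend=False
    )
    return freqs, np.sqrt(psd)


def fit_noise_exponential(
    freqs: np.ndarray, asd: np.ndarray, exclude_band: tuple[float, float] | None = None
) -> float:
    """Least-squares fit of ``exp(gamma * f)`` to the spectrum in [3, 40] Hz.

    ``exclude_band`` removes the spectral peak's FWHM band from the fit so
    the background estimate is not biased by the oscillation itself.
    """
    freqs = np.asarray(freqs, dtype=float)
    asd = np.asarray(asd, dtype=float)
    keep = (freqs >= PEAK_BAND_HZ[0]) & (freqs <= PEAK_BAND_HZ[1])
    if exclude_band is not None:
        keep &= ~((freqs >= exclude_band[0]) & (freqs <= exclude_band[1]))
    f, y = freqs[keep], asd[keep]
    if f.size < 3:
        raise ValueError("need at least 3 points in the fit range")

    def sse(gamma: float) -> float:
        return float(np.sum((y - np.exp(gamma * f)) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(-5.0, 5.0), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"exponential noise fit failed: {res.message}")
    return float(res.x)


def _fwhm(freqs: np.ndarray, asd: np.ndarray, i_peak: int):
    """Half-maximum crossings around the peak by linear interpolation."""
    half = asd[i_peak] / 2.0
    lo = PEAK_BAND_HZ[0]
    hi = PEAK_BAND_HZ[1]
    f_left = None
    for i in range(i_peak, 0, -1):
        if freqs[i - 1] < lo:
            break
        if asd[i - 1] < half <= asd[i]:
            f_left = np.interp(half, [asd[i - 1], asd[i]], [freqs[i - 1], freqs[i]])
            break
    f_right = None
    for i in range(i_peak, freqs.size - 1):
        if freqs[i + 1] > hi:
            break
        if asd[i + 1] < half <= asd[i]:
            f_right = np.interp(half, [asd[i + 1], asd[i]], [freqs[i + 1], freqs[i]])
            break
    if f_left is None or f_right is None:
        return None, None
    return float(f_left), float(f_right)


def asd_classify_window(
    window_samples: np.ndarray, fs: float, t_start_s: float = 0.0, pad_factor: int = 1
) -> ASDWindowResult:
    """Classify one 1 s window by the FWHM-of-the-alpha-peak criterion."""
    freqs, asd = asd_spectrum(window_samples, fs, pad_factor)
    band = (freqs >= PEAK_BAND_HZ[0]) & (freqs <= PEAK_BAND_HZ[1])
    idx = np.flatnonzero(band)
    i_peak = idx[np.argmax(asd[idx])]
    peak_freq = float(freqs[i_peak])

    fwhm = gamma = osc_index = None
    is_spindle = False
    if ALPHA_BAND_HZ[0] <= peak_freq <= ALPHA_BAND_HZ[1]:
        f_left, f_right = _fwhm(freqs, asd, i_peak)
        if f_left is not None:
            fwhm = f_right - f_left
            is_spindle = fwhm < 2.0 * HAMMING_NBW_HZ
            try:
                gamma = fit_noise_exponential(freqs, asd, exclude_band=(f_left, f_right))
                # dense grid: the FWHM band may span few native 1 Hz bins
                f_dense = np.linspace(f_left, f_right, 64)
                area_sig = np.trapezoid(np.interp(f_dense, freqs, asd), f_dense)
                area_noise = np.trapezoid(np.exp(gamma * f_dense), f_dense)
                if area_noise > 0:
                    osc_index = float(area_sig / area_noise)
            except (ValueError, RuntimeError):
                pass
    return ASDWindowResult(t_start_s, peak_freq, fwhm, gamma, osc_index, is_spindle)


def asd_detect(
    x: np.ndarray,
    fs: float,
    slide_s: float = 0.250,
    merge_gap_s: float = 0.250,
    min_dur_s: float = 0.250,
    pad_factor: int = 1,
    return_windows: bool = False,
):
    """Slide 1 s windows over a single channel and merge positive windows.

    A positive window claims its full 1 s span; overlapping spans are
    unioned, then the same 250 ms merge/prune post-processing as the SDAR
    pipeline is applied for a fair comparison.
    """
    x = np.asarray(x, dtype=float).ravel()
    win = int(round(fs))
    if x.size < win:
        raise ValueError("signal must be at least 1 s long")
    step = max(int(round(slide_s * fs)), 1)
    mask = np.zeros(x.size, dtype=bool)
    results = []
    for start in range(0, x.size - win + 1, step):
        res = asd_classify_window(x[start: start + win], fs, start / fs, pad_factor)
        results.append(res)
        if res.is_spindle:
            mask[start: start + win] = True
    events = postprocess_events(
        EventList.from_mask(mask, fs, source="asd"), merge_gap_s, min_dur_s
    )
    if return_windows:
        return events, results
    return events
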