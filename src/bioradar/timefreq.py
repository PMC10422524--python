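"""Band-limited FFT spectrum and CWT time-frequency ridge.

Two complementary representations feed the respiration features:

* the magnitude FFT spectrum restricted to the respiration band
  [0.08, 1] Hz, summarized by its peak frequency ``f_fft`` and the
  prominence ratio ``PR(f_fft)`` (an SNR surrogate);
* the continuous wavelet transform, whose per-time dominant-frequency curve
  ``fcwt`` (the ridge) tracks quasi-periodic components through
  disturbances that distort a single global FFT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as _sig

from .ranging import RangeSubSignal
from .simulate import BAND

#: complex Morlet wavelet used for ridge tracking
WAVELET = "cmor1.5-1.0"
#: number of analysis frequencies across the band (uniform 0.0125 Hz spacing)
N_FREQS = 75


@dataclass
class BandSpectrum:
    """Magnitude spectrum restricted to the respiration band."""

    k: np.ndarray  # frequency grid in band, Hz, ascending
    X: np.ndarray  # magnitude per grid point
    f_fft: float  # frequency of the maximum magnitude
    Xmax: float

    @property
    def L(self) -> int:
        return self.k.size


@dataclass
class TimeFrequencyDistribution:
    """|CWT| magnitude on a fixed log-frequency grid, columns = time."""

    freqs: np.ndarray  # ascending, Hz
    magnitude: np.ndarray  # [n_freqs, n_times]
    fs: float

    @property
    def n_times(self) -> int:
        return self.magnitude.shape[1]


@dataclass
class TimeFrequencyRidge:
    """Per-time dominant frequency of the TFD and its peak factor."""

    freq_grid: np.ndarray
    fcwt: np.ndarray  # Hz, one value per time index, each on freq_grid
    pfmax: np.ndarray
    fs: float

    @property
    def n(self) -> np.ndarray:
        return np.arange(self.fcwt.size)

    def grid_step(self, f: float) -> float:
        """Local spacing of the frequency grid at frequency ``f``."""
        steps = np.diff(self.freq_grid)
        i = np.clip(np.searchsorted(self.freq_grid, f) - 1, 0, steps.size - 1)
        return float(steps[i])


def _require_filtered(s: RangeSubSignal) -> None:
    if not s.filtered:
        raise ValueError("sub-signal must be high-pass filtered first")


def band_spectrum(s: RangeSubSignal, band: tuple[float, float] = BAND) -> BandSpectrum:
    """FFT magnitude spectrum of the complex sub-signal within ``band``.

    ``f_fft`` is the frequency of the maximum magnitude in the band; ties
    are broken toward the lowest frequency (argmax of an ascending grid).
    """
    _require_filtered(s)
    if s.T_meas <= 0:
        raise ValueError("T_meas must be > 0")
    x = np.asarray(s.series, dtype=complex)
    X = np.abs(np.fft.fft(x))
    f = np.fft.fftfreq(x.size, d=1.0 / s.fs)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        raise ValueError("no FFT bins inside the analysis band; fs or T too small")
    k = f[mask]
    Xb = X[mask]
    order = np.argsort(k)
    k, Xb = k[order], Xb[order]
    imax = int(np.argmax(Xb))  # first occurrence = lowest frequency on ties
    return BandSpectrum(k=k, X=Xb, f_fft=float(k[imax]), Xmax=float(Xb[imax]))


def prominence_ratio(sp: BandSpectrum) -> float:
    """Prominence ratio PR(f_fft) in dB.

    Ratio of the power at the band maximum to the average power of the
    remaining band points:

        PR = 10 log10( Xmax^2 / [ (sum |X|^2 - Xmax^2) / (L - 1) ] )

    A flat spectrum gives 0 dB.  When the residual power underflows (a
    noiseless synthetic tone) the ratio is capped at 120 dB.
    """
    if sp.L < 2:
        raise ValueError("need at least two band points")
    power = float(np.sum(sp.X.astype(float) ** 2))
    if power == 0.0:
        raise ValueError("all-zero spectrum has no prominence ratio")
    peak = sp.Xmax**2
    resid = (power - peak) / (sp.L - 1)
    floor = peak * 1e-12
    return 10.0 * math.log10(peak / max(resid, floor))


def cwt_frequency_grid(
    band: tuple[float, float] = BAND, n_freqs: int = N_FREQS
) -> np.ndarray:
    """Uniformly spaced analysis frequencies covering the band, ascending.

    The default 0.0125 Hz spacing resolves the breathing band well below
    the fixed 0.05 Hz half-width used by the duration features.
    """
    return np.linspace(band[0], band[1], n_freqs)


def cwt_tfd(
    s: RangeSubSignal,
    band: tuple[float, float] = BAND,
    n_freqs: int = N_FREQS,
) -> TimeFrequencyDistribution:
    """Amplitude-normalized |CWT| of the complex sub-signal on the fixed grid.

    Uses an analytic (complex Morlet) wavelet so the positive-frequency
    respiration sideband is tracked directly on the complex series.  The
    coefficients are scaled to the L1 (amplitude) convention — a unit
    sinusoid responds equally at every analysis frequency — so magnitudes
    are comparable across the band.  Edge columns inside the cone of
    influence are retained.
    """
    _require_filtered(s)
    freqs = cwt_frequency_grid(band, n_freqs)
    scales = pywt.frequency2scale(WAVELET, freqs / s.fs)
    W, _ = pywt.cwt(
        np.asarray(s.series, dtype=complex),
        scales,
        WAVELET,
        sampling_period=1.0 / s.fs,
        method="fft",
    )
    mag = np.abs(W) / np.sqrt(scales)[:, None]
    return TimeFrequencyDistribution(freqs=freqs, magnitude=mag, fs=s.fs)


def peak_factor_ridge(tfd: TimeFrequencyDistribution) -> TimeFrequencyRidge:
    """Extract the maximum-peak-factor ridge fcwt from a TFD.

    For each time column the local spectral maxima are scored by a peak
    factor PF = topographic prominence / column median magnitude; the ridge
    frequency is the maximum-PF peak (ties to the lower frequency).  A
    column with no interior local maximum falls back to its global maximum,
    scored as (max - median) / median.
    """
    if tfd.magnitude.size == 0:
        raise ValueError("empty time-frequency distribution")
    n_times = tfd.n_times
    fcwt = np.empty(n_times)
    pfmax = np.empty(n_times)
    for j in range(n_times):
        col = tfd.magnitude[:, j]
        med = float(np.median(col))
        if med <= 0:
            med = float(np.mean(col)) or 1.0
        peaks, props = _sig.find_peaks(col, prominence=0.0)
        if peaks.size:
            pf = props["prominences"] / med
            best = int(np.argmax(pf))  # first max = lowest frequency on ties
            fcwt[j] = tfd.freqs[peaks[best]]
            pfmax[j] = pf[best]
        else:
            imax = int(np.argmax(col))
            fcwt[j] = tfd.freqs[imax]
            pfmax[j] = (col[imax] - med) / med
    return TimeFrequencyRidge(freq_grid=tfd.freqs, fcwt=fcwt, pfmax=pfmax, fs=tfd.fs)
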