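"""The nine respiration features of one range sub-signal.

Four categories by associated physical quantity:

* power:      PR(f_fft) [dB], std(f_cwt) [Hz]
* frequency:  f_fft, f_cwt_mean, f_cwt_mode [Hz]
* time:       TD_cwt_mean, TD_cwt_mode [fraction of T_meas]
* secondary frequency: normalized differences Δf(fft, cwt_mean),
  Δf(fft, cwt_mode) [fraction]

TD and Δf are stored as fractions; the rendering layer multiplies by 100
when a percentage display is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ranging import RangeSubSignal, decompose_ranges, highpass_filter
from .timefreq import (
    TimeFrequencyRidge,
    band_spectrum,
    cwt_tfd,
    peak_factor_ridge,
    prominence_ratio,
)

#: feature-table column order (metadata first, then the nine features)
FEATURE_COLUMNS = [
    "PR_ffft_db",
    "std_fcwt_hz",
    "f_fft_hz",
    "f_cwt_mean_hz",
    "f_cwt_mode_hz",
    "TD_cwt_mean",
    "TD_cwt_mode",
    "dF_fft_cwt_mean",
    "dF_fft_cwt_mode",
]

META_COLUMNS = ["obs_id", "measurement_id", "range_index", "label"]


@dataclass
class FeatureVector:
    """The nine named features of one observation (measurement x range bin)."""

    obs_id: str
    measurement_id: str | None
    range_index: int
    label: str | None
    PR_ffft_db: float
    std_fcwt_hz: float
    f_fft_hz: float
    f_cwt_mean_hz: float
    f_cwt_mode_hz: float
    TD_cwt_mean: float
    TD_cwt_mode: float
    dF_fft_cwt_mean: float
    dF_fft_cwt_mode: float

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in META_COLUMNS + FEATURE_COLUMNS}


def f_cwt_mode(r: TimeFrequencyRidge) -> float:
    """Most frequent ridge frequency over the discrete CWT grid.

    The dominant frequency of the measurement — robust against brief
    disturbances that pull the mean.  Ties break toward the lower frequency.
    """
    if r.fcwt.size == 0:
        raise ValueError("empty ridge")
    values, counts = np.unique(r.fcwt, return_counts=True)  # ascending values
    return float(values[np.argmax(counts)])


def f_cwt_mean(r: TimeFrequencyRidge) -> float:
    """Arithmetic mean of the ridge; sensitive to all noise and disturbances."""
    if r.fcwt.size == 0:
        raise ValueError("empty ridge")
    return float(np.mean(r.fcwt))


def td_duration(r: TimeFrequencyRidge, center: float, halfwidth: float = 0.05) -> float:
    """Fraction of the measurement the ridge spends within center ± halfwidth.

    The fixed ±0.05 Hz half-width matches the typical fluctuation of the
    ridge when breathing is present, so a stable breath yields values near
    1 while a wandering noise ridge stays low.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    if r.fcwt.size == 0:
        raise ValueError("empty ridge")
    return float(np.mean(np.abs(r.fcwt - center) <= halfwidth))


def delta_f(fa: float, fb: float) -> float:
    """Normalized frequency difference |fa - fb| / mean(fa, fb), a fraction.

    Near zero when two independent estimators agree on the respiratory
    rate; approaches 2 for maximally discordant positive frequencies.
    """
    if fa <= 0 or fb <= 0:
        raise ValueError("frequencies must be > 0")
    return abs(fa - fb) / ((fa + fb) / 2.0)


def std_f_cwt(r: TimeFrequencyRidge) -> float:
    """Population standard deviation (divisor N) of the ridge frequencies."""
    if r.fcwt.size < 2:
        raise ValueError("ridge must have at least two samples")
    return float(np.std(r.fcwt))


def extract_features(s: RangeSubSignal) -> FeatureVector:
    """Compute all nine features of one filtered range sub-signal."""
    sp = band_spectrum(s)
    pr = prominence_ratio(sp)
    ridge = peak_factor_ridge(cwt_tfd(s))
    mode = f_cwt_mode(ridge)
    mean = f_cwt_mean(ridge)
    fv = FeatureVector(
        obs_id=s.obs_id,
        measurement_id=s.parent_id,
        range_index=s.range_index,
        label=s.label,
        PR_ffft_db=pr,
        std_fcwt_hz=std_f_cwt(ridge),
        f_fft_hz=sp.f_fft,
        f_cwt_mean_hz=mean,
        f_cwt_mode_hz=mode,
        TD_cwt_mean=td_duration(ridge, mean),
        TD_cwt_mode=td_duration(ridge, mode),
        dF_fft_cwt_mean=delta_f(sp.f_fft, mean),
        dF_fft_cwt_mode=delta_f(sp.f_fft, mode),
    )
    for c in FEATURE_COLUMNS:
        if not np.isfinite(getattr(fv, c)):
            raise ValueError(f"non-finite feature {c} for observation {fv.obs_id}")
    return fv


def feature_table(measurements, n_ranges: int = 5, cutoff: float = 0.04):
    """Decompose, filter and featurize a collection of measurements.

    Returns a pandas DataFrame with one row per observation
    (measurement x range bin) in the standard column order.
    """
    import pandas as pd

    rows = []
    for m in measurements:
        for sub in decompose_ranges(m, n_ranges):
            rows.append(extract_features(highpass_filter(sub, cutoff)).to_dict())
    return pd.DataFrame(rows, columns=META_COLUMNS + FEATURE_COLUMNS)
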