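"""Brick-wall FFT band-pass filtering and relative band power.

Epochs are filtered whole with a discrete Fourier transform and a hard
frequency mask on the half-open interval ``[f_low, f_high)``; with the six
classical bands this partitions 0.5--48 Hz, so per-epoch relative powers sum
to one. The DC bin never lies in any band, so filtering implicitly demeans.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .bands import BandDefinition, CLASSICAL_BANDS, TOTAL_RANGE

__all__ = ["bandpass_fft", "band_power", "relative_power", "relative_power_table"]


def _band_mask(n: int, fs: float, f_low: float, f_high: float) -> np.ndarray:
    f = np.abs(np.fft.fftfreq(n, 1.0 / fs))
    return (f >= f_low) & (f < f_high)


def bandpass_fft(series: np.ndarray, band: BandDefinition, fs: float,
                 axis: int = -1) -> np.ndarray:
    """Zero all FFT coefficients with ``|f|`` outside ``[f_low, f_high)``.

    Returns a real array of the same shape. Raises if the band exceeds
    Nyquist or the series is shorter than 2 samples.
    """
    series = np.asarray(series, float)
    n = series.shape[axis]
    if n < 2:
        raise ValueError("series must have at least 2 samples")
    band.validate_for_fs(fs)
    spec = np.fft.fft(series, axis=axis)
    mask = _band_mask(n, fs, band.f_low, band.f_high)
    shape = [1] * series.ndim
    shape[axis] = n
    spec = spec * mask.reshape(shape)
    return np.fft.ifft(spec, axis=axis).real


def band_power(series: np.ndarray, band: BandDefinition, fs: float,
               axis: int = -1) -> np.ndarray:
    """Sum of squared FFT magnitudes over the band's bins (both signs)."""
    series = np.asarray(series, float)
    n = series.shape[axis]
    spec = np.fft.fft(series, axis=axis)
    mask = _band_mask(n, fs, band.f_low, band.f_high)
    power = np.abs(spec) ** 2
    return np.take(power, np.flatnonzero(mask), axis=axis).sum(axis=axis)


def relative_power(
    series: np.ndarray,
    band: BandDefinition,
    fs: float,
    total_range: tuple[float, float] = TOTAL_RANGE,
    axis: int = -1,
) -> np.ndarray:
    """Band power divided by total power over ``total_range``.

    The denominator uses the same half-open bin convention, so relative
    powers over a set of bands tiling ``total_range`` sum to exactly one.
    Raises on zero total power ("silent channel").
    """
    series = np.asarray(series, float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series must be finite")
    num = band_power(series, band, fs, axis=axis)
    total_band = BandDefinition("total", total_range[0], total_range[1])
    den = band_power(series, total_band, fs, axis=axis)
    if np.any(den == 0):
        raise ValueError("silent channel: zero power in the analyzed range")
    return num / den


def relative_power_table(
    roi_series: np.ndarray,
    fs: float,
    bands: Sequence[BandDefinition] = CLASSICAL_BANDS,
    total_range: tuple[float, float] = TOTAL_RANGE,
) -> pd.DataFrame:
    """Relative power per (ROI, epoch, band) from ``roi_series`` (R, S, E).

    Returns a long-format frame with columns roi (1-based), epoch, band,
    value.
    """
    roi_series = np.asarray(roi_series, float)
    if roi_series.ndim != 3:
        raise ValueError("roi_series must be ROI x samples x epochs")
    rows = []
    for band in bands:
        vals = relative_power(roi_series, band, fs, total_range, axis=1)  # (R, E)
        r_idx, e_idx = np.meshgrid(
            np.arange(1, vals.shape[0] + 1), np.arange(vals.shape[1]), indexing="ij"
        )
        rows.append(
            pd.DataFrame(
                {
                    "roi": r_idx.ravel(),
                    "epoch": e_idx.ravel(),
                    "band": band.name,
                    "value": vals.ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
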