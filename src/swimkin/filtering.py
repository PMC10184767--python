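"""Dominant-frequency estimation and adaptive zero-phase low-pass filtering.

Digitized landmark traces carry tracking jitter; the convention in fish
kinematics is to low-pass each point series at a small multiple (default 5x)
of the oscillation frequency it carries -- body points at 5x the body-wave
frequency, fin points at 5x the fin-beat frequency.  Because every downstream
variable is timed off peaks and adduction events, the filter must be
zero-phase: a 4th-order Butterworth applied forward-backward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import FilterError, FlatSeries

__all__ = ["ScalarSeries", "dominant_frequency", "lowpass_adaptive"]


@dataclass
class ScalarSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : array of float
        One value per frame; must be finite.
    fps : float
        Sampling rate in frames per second; must be positive.
    """

    values: np.ndarray
    fps: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ScalarSeries values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ScalarSeries values must be finite")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fps


def dominant_frequency(series: ScalarSeries) -> float:
    """Frequency (Hz) of the largest spectral peak of the mean-removed series.

    A Hann window is applied before the FFT and the peak bin is refined by
    quadratic interpolation of log-magnitude across the three bins around it,
    so a pure tone is recovered to well under 1% even when it falls between
    bins.

    Raises
    ------
    FlatSeries
        If the series carries no oscillation (constant to machine precision).
    """
    x = series.values - series.values.mean()
    n = len(x)
    if n < 8:
        raise FlatSeries("series too short for spectral estimation")
    scale = max(1.0, float(np.max(np.abs(series.values))))
    if np.max(np.abs(x)) < 1e-10 * scale:
        raise FlatSeries("no oscillation detectable")

    win = np.hanning(n)
    spec = np.abs(np.fft.rfft(x * win))
    # exclude DC and Nyquist from peak search
    if len(spec) < 4:
        raise FlatSeries("no oscillation detectable")
    k = int(np.argmax(spec[1:-1])) + 1
    # quadratic interpolation on log magnitude
    a, b, c = spec[k - 1], spec[k], spec[k + 1]
    with np.errstate(divide="ignore"):
        la, lb, lc = np.log(np.maximum([a, b, c], 1e-300))
    denom = la - 2 * lb + lc
    delta = 0.0 if denom == 0 else 0.5 * (la - lc) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return (k + delta) * series.fps / n


def lowpass_adaptive(
    series: ScalarSeries, base_freq: float, multiple: float = 5.0
) -> ScalarSeries:
    """Zero-phase low-pass at ``multiple * base_freq`` Hz.

    4th-order Butterworth run forward-backward (``sosfiltfilt``) with reflect
    padding of one cutoff period, so short records (a few locomotor cycles)
    do not pick up edge transients.  Passband content at or below
    ``base_freq`` is attenuated by less than 1% in amplitude; peak timing is
    unchanged.

    Raises
    ------
    FilterError
        If the cutoff reaches the Nyquist frequency.
    """
    if base_freq <= 0:
        raise FilterError(f"base frequency must be positive, got {base_freq}")
    cutoff = multiple * base_freq
    nyq = series.fps / 2.0
    if cutoff >= nyq:
        raise FilterError(
            f"cutoff {cutoff:.3g} Hz is at or above Nyquist {nyq:.3g} Hz"
        )
    sos = sps.butter(4, cutoff, btype="low", fs=series.fps, output="sos")
    padlen = int(round(series.fps / cutoff))
    padlen = min(padlen, len(series.values) - 1)
    filt = sps.sosfiltfilt(sos, series.values, padtype="even", padlen=padlen)
    return ScalarSeries(values=filt, fps=series.fps)
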