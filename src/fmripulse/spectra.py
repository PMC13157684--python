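"""Spectral estimation and physiological bandpower.

Power spectra are one-sided rectangular-window periodograms of the demeaned
signal, with no zero padding, so that total integrated power equals the signal
variance (Parseval) and absolute bandpower — the quantity of interest — is
preserved (Welch averaging would bias it).  Bandpower integrates the PSD over
the bins whose centre frequency falls inside the band.

Physiological bands: LFO 0.01–0.1 Hz, respiratory 0.2–0.4 Hz, cardiac
heart-rate +/- 0.15 Hz.

Also provided are two closed-form oracles used in validation:

* ``alias_frequency`` — where a sinusoid above the Nyquist frequency folds to;
* ``averaging_attenuation`` — the amplitude loss of a sinusoid when n
  uniformly time-shifted copies (one per unique slice timing within a TR) are
  averaged, the Dirichlet-kernel mechanism that depresses ROI-mean cardiac
  power relative to hypersampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "PowerSpectrum",
    "BandDefinition",
    "BandpowerResult",
    "periodogram_psd",
    "make_bands",
    "bandpower",
    "alias_frequency",
    "averaging_attenuation",
    "stitching_lines_in_band",
]

BAND_NAMES = ("lfo", "resp", "cardiac", "custom")

LFO_BAND = (0.01, 0.1)
RESP_BAND = (0.2, 0.4)
CARDIAC_HALFWIDTH_HZ = 0.15


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    psd: np.ndarray  # (signal units)^2 / Hz
    fs_hz: float

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs_hz.shape != self.psd.shape:
            raise ValueError("freqs_hz and psd must have matching shapes")

    @property
    def df_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    @property
    def nyquist_hz(self) -> float:
        return self.fs_hz / 2.0

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_hz / self.df_hz))

    def total_power(self) -> float:
        """Integrated PSD = variance of the demeaned input (Parseval)."""
        return float(np.sum(self.psd) * self.df_hz)


@dataclass
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo_hz < self.hi_hz:
            raise ValueError(f"band requires 0 <= lo < hi, got [{self.lo_hz}, {self.hi_hz}]")


@dataclass
class BandpowerResult:
    roi_label: str
    band: BandDefinition
    power: float  # signal units^2
    method: str  # hypersampled_roi | roi_mean | voxelwise_mean
    warnings: list[str] = field(default_factory=list)


def periodogram_psd(values: np.ndarray, fs_hz: float) -> PowerSpectrum:
    """One-sided periodogram (boxcar window, demeaned input, no padding)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1D signal")
    if values.size < 8:
        raise ValueError(f"signal too short for a periodogram ({values.size} < 8)")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in signal; fill gaps upstream")
    freqs, psd = sp_signal.periodogram(
        values, fs=fs_hz, window="boxcar", detrend="constant", scaling="density"
    )
    return PowerSpectrum(freqs_hz=freqs, psd=psd, fs_hz=fs_hz)


def make_bands(
    f_card_hz: float, halfwidth_hz: float = CARDIAC_HALFWIDTH_HZ
) -> tuple[list[BandDefinition], bool]:
    """The three physiological bands for a given heart frequency.

    Returns (bands, overlap_flag); the flag is set when the cardiac band
    [f-halfwidth, f+halfwidth] dips into the respiratory band (f < 0.55 Hz
    at the default halfwidth).
    """
    if f_card_hz <= halfwidth_hz:
        raise ValueError(
            f"cardiac frequency {f_card_hz} Hz must exceed halfwidth {halfwidth_hz} Hz"
        )
    bands = [
        BandDefinition("lfo", *LFO_BAND),
        BandDefinition("resp", *RESP_BAND),
        BandDefinition("cardiac", f_card_hz - halfwidth_hz, f_card_hz + halfwidth_hz),
    ]
    overlap = (f_card_hz - halfwidth_hz) < RESP_BAND[1]
    if overlap:
        warnings.warn(
            f"cardiac band [{f_card_hz - halfwidth_hz:.2f}, "
            f"{f_card_hz + halfwidth_hz:.2f}] overlaps the respiratory band",
            stacklevel=2,
        )
    return bands, overlap


def bandpower(spectrum: PowerSpectrum, band: BandDefinition) -> float:
    """Integrate the PSD over bins whose centres fall in [lo, hi]."""
    if band.hi_hz > spectrum.nyquist_hz + spectrum.df_hz / 2:
        raise ValueError(
            f"band [{band.lo_hz}, {band.hi_hz}] Hz exceeds the Nyquist "
            f"frequency {spectrum.nyquist_hz:.4g} Hz"
        )
    sel = (spectrum.freqs_hz >= band.lo_hz) & (spectrum.freqs_hz <= band.hi_hz)
    return float(np.sum(spectrum.psd[sel]) * spectrum.df_hz)


def alias_frequency(f_hz: float, fs_hz: float) -> float:
    """Apparent frequency of a sinusoid at ``f_hz`` sampled at ``fs_hz``.

    f_alias = |f - round(f/fs)*fs|, always in [0, fs/2]: frequencies above the
    Nyquist fold back into the representable range (e.g. ~1 Hz cardiac sampled
    at 1.25 volumes/s appears at 0.25 Hz, inside the respiratory band).
    """
    if f_hz <= 0 or fs_hz <= 0:
        raise ValueError("frequencies must be positive")
    return float(abs(f_hz - round(f_hz / fs_hz) * fs_hz))


def averaging_attenuation(f_hz: float, tr_s: float, n_time: int) -> float:
    """Amplitude ratio in [0, 1] after averaging n time-shifted sinusoids.

    Averaging the copies of a sinusoid acquired at the ``n_time`` uniform
    slice timings within one TR multiplies its amplitude by::

        |sum_{j=0}^{n-1} exp(i*2*pi*f*j*TR/n)| / n
        = |sin(pi*f*TR)| / (n * |sin(pi*f*TR/n)|)

    with limit 1 as f -> 0.  This is the destructive interference that makes
    the conventional ROI mean underestimate cardiac power: neighbouring slice
    timings sample different cardiac phases which partially cancel.
    """
    if n_time < 1:
        raise ValueError("n_time must be >= 1")
    if n_time == 1:
        return 1.0
    phases = 2 * np.pi * f_hz * np.arange(n_time) * tr_s / n_time
    return float(np.abs(np.mean(np.exp(1j * phases))))


def stitching_lines_in_band(
    band: BandDefinition, tr_s: float, nyquist_hz: float
) -> list[float]:
    """Multiples of 1/TR inside the band — residual per-slice baseline
    differences in a stitched signal can leave spectral lines there."""
    f_volume = 1.0 / tr_s
    k = np.arange(1, int(nyquist_hz / f_volume) + 1)
    lines = k * f_volume
    return [float(f) for f in lines if band.lo_hz <= f <= band.hi_hz]
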