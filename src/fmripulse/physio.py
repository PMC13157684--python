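"""Cardiac information from the photoplethysmography (PPG) recording.

Three quantities are extracted: the fundamental heart frequency (PSD argmax
within a physiological search range), a quality score (fraction of total
signal power, excluding <0.01 Hz drift, that lies within the cardiac band —
near 1 for a clean pulse trace, near the band/bandwidth ratio for noise), and
a beat-to-beat cardiac phase.  Beats are detected as local maxima of the
band-passed PPG with a minimum separation of half a cardiac period, and the
phase at any scan time is the elapsed fraction of the surrounding beat-to-beat
interval.  This beat detector is a simple, testable stand-in for vendor- or
lab-specific pulse pickers; phase is invariant to PPG scaling and offset by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .io import PhysioRecording
from .spectra import CARDIAC_HALFWIDTH_HZ, BandDefinition, bandpower, periodogram_psd

__all__ = [
    "CardiacInfo",
    "estimate_cardiac_frequency",
    "ppg_quality",
    "detect_beats",
    "cardiac_phase",
    "analyze_ppg",
]

#: default heart-rate search range, 36-120 bpm
SEARCH_RANGE_HZ = (0.6, 2.0)

#: quality below this is flagged by QC (the exclusion threshold is a config
#: value; no published number exists for it)
DEFAULT_MIN_QUALITY = 0.3

MIN_DURATION_S = 10.0


@dataclass
class CardiacInfo:
    """Heart frequency, beat times and PPG quality for one recording."""

    f_card_hz: float
    quality: float
    beat_times_s: np.ndarray = field(default_factory=lambda: np.array([]))

    def phase_at(self, times_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cardiac phase in [0,1) at the given scan times.

        Returns (phases, valid): times outside [first beat, last beat) get
        NaN phase and valid=False.
        """
        times_s = np.atleast_1d(np.asarray(times_s, dtype=float))
        beats = self.beat_times_s
        if beats.size < 2:
            raise ValueError("phase requires at least 2 detected beats")
        idx = np.searchsorted(beats, times_s, side="right") - 1
        valid = (idx >= 0) & (idx < beats.size - 1)
        phases = np.full(times_s.shape, np.nan)
        i = idx[valid]
        phases[valid] = (times_s[valid] - beats[i]) / (beats[i + 1] - beats[i])
        return phases, valid


def _detrended_spectrum(ppg: PhysioRecording):
    samples = sp_signal.detrend(ppg.samples, type="linear")
    return periodogram_psd(samples, ppg.fs_hz)


def estimate_cardiac_frequency(
    ppg: PhysioRecording, search_range_hz: tuple[float, float] = SEARCH_RANGE_HZ
) -> float:
    """Frequency of the PPG's PSD maximum within the search range."""
    if ppg.duration_s < MIN_DURATION_S:
        raise ValueError(
            f"recording too short ({ppg.duration_s:.1f} s < {MIN_DURATION_S} s)"
        )
    if not np.all(np.isfinite(ppg.samples)):
        raise ValueError("non-finite samples in PPG")
    if np.ptp(ppg.samples) == 0:
        raise ValueError("no cardiac peak: PPG is constant")
    spec = _detrended_spectrum(ppg)
    sel = (spec.freqs_hz >= search_range_hz[0]) & (spec.freqs_hz <= search_range_hz[1])
    if not sel.any():
        raise ValueError("search range contains no frequency bins")
    if np.max(spec.psd[sel]) <= 0:
        raise ValueError("no cardiac peak: zero power in search range")
    return float(spec.freqs_hz[sel][np.argmax(spec.psd[sel])])


def ppg_quality(
    ppg: PhysioRecording,
    f_card_hz: float,
    halfwidth_hz: float = CARDIAC_HALFWIDTH_HZ,
) -> float:
    """Proportion of total PPG power inside the cardiac band.

    Total power excludes <0.01 Hz so slow baseline wander cannot deflate the
    score; the value lies in [0, 1].
    """
    spec = _detrended_spectrum(ppg)
    total = float(np.sum(spec.psd[spec.freqs_hz >= 0.01]) * spec.df_hz)
    if total <= 0:
        raise ValueError("zero total power in PPG")
    band = BandDefinition(
        "cardiac", max(f_card_hz - halfwidth_hz, 0.01), f_card_hz + halfwidth_hz
    )
    return min(bandpower(spec, band) / total, 1.0)


def detect_beats(
    ppg: PhysioRecording, f_card_hz: float, bp_halfwidth_hz: float = 0.3
) -> np.ndarray:
    """Beat times (s, scan clock) from local maxima of the band-passed PPG."""
    lo = max(f_card_hz - bp_halfwidth_hz, 0.05)
    hi = min(f_card_hz + bp_halfwidth_hz, 0.99 * ppg.fs_hz / 2)
    sos = sp_signal.butter(3, [lo, hi], btype="bandpass", fs=ppg.fs_hz, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, ppg.samples)
    min_sep = int(round(0.5 / f_card_hz * ppg.fs_hz))
    peaks, _ = sp_signal.find_peaks(filtered, distance=max(min_sep, 1))
    if peaks.size < 3:
        raise ValueError(f"only {peaks.size} beats detected; need at least 3")
    return ppg.start_offset_s + peaks / ppg.fs_hz


def cardiac_phase(
    ppg: PhysioRecording, f_card_hz: float, times_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cardiac phase in [0,1) at scan times, linear between detected beats.

    Returns (phases, valid); times outside the detected beat span are invalid.
    """
    beats = detect_beats(ppg, f_card_hz)
    info = CardiacInfo(f_card_hz=f_card_hz, quality=np.nan, beat_times_s=beats)
    return info.phase_at(times_s)


def analyze_ppg(
    ppg: PhysioRecording,
    search_range_hz: tuple[float, float] = SEARCH_RANGE_HZ,
    halfwidth_hz: float = CARDIAC_HALFWIDTH_HZ,
) -> CardiacInfo:
    """Full PPG workup: frequency, quality, and beat times."""
    f_card = estimate_cardiac_frequency(ppg, search_range_hz)
    quality = ppg_quality(ppg, f_card, halfwidth_hz)
    beats = detect_beats(ppg, f_card)
    return CardiacInfo(f_card_hz=f_card, quality=quality, beat_times_s=beats)
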