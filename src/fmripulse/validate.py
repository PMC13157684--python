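"""Methodological comparisons of the hypersampled bandpower.

Two references are used, both only meaningful on fast-sampled data where the
cardiac band fits under the per-volume Nyquist frequency:

* the ROI-mean time series (slice timing ignored) — its bandpower is depressed
  for fast oscillations by destructive interference across slice timings, the
  closed form of which is ``averaging_attenuation``;
* the ROI mean of voxel-wise bandpower — per-voxel power is blind to phase, so
  it is unaffected by pulse propagation and serves as reference for how much
  phase dispersion across the ROI costs the hypersampled (spatially averaged)
  signal.  Respiration, with its short propagation wavelength (lambda = T*v),
  is the component most attenuated this way.

Group-level modelling (mixed effects of age/sex) is exported, not fitted: the
long-format bandpower table is written ready for external model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FMRIScan, ROIMask
from .hypersample import (
    HypersampledSignal,
    SliceTimingTable,
    build_timing_table,
    detrend_linear,
    hypersample_roi,
)
from .spectra import (
    BandDefinition,
    BandpowerResult,
    bandpower,
    make_bands,
    periodogram_psd,
)

__all__ = [
    "PowerComparison",
    "roi_mean_power",
    "voxelwise_mean_power",
    "hypersampled_power",
    "compare_power_sets",
    "propagation_sensitivity_suite",
    "export_bandpower_table",
]


@dataclass
class PowerComparison:
    """OLS regression (y on x, with intercept) between two power measures."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    pairs: list[tuple[float, float]]


def _band_results(
    spectrum, bands: list[BandDefinition], roi_label: str, method: str
) -> list[BandpowerResult]:
    return [
        BandpowerResult(
            roi_label=roi_label, band=b, power=bandpower(spectrum, b), method=method
        )
        for b in bands
    ]


def roi_mean_power(
    scan: FMRIScan, mask: ROIMask, bands: list[BandDefinition]
) -> list[BandpowerResult]:
    """Bandpower of the detrended ROI-mean series at the per-volume rate.

    Slice timing is ignored, as in conventional ROI analysis.  A band above
    the per-volume Nyquist frequency is an error — exactly the situation
    (e.g. a ~1 Hz cardiac band at TR = 0.8 s) that hypersampling exists to
    fix.
    """
    series = detrend_linear(scan.data[mask.mask].mean(axis=0))
    spectrum = periodogram_psd(series, 1.0 / scan.tr_s)
    return _band_results(spectrum, bands, mask.label, "roi_mean")


def voxelwise_mean_power(
    scan: FMRIScan, mask: ROIMask, bands: list[BandDefinition]
) -> list[BandpowerResult]:
    """ROI mean of per-voxel bandpower at the per-volume rate.

    Power is computed voxel by voxel (phase-blind, hence unaffected by pulse
    propagation) and averaged across the ROI.
    """
    from scipy import signal as sp_signal

    series = detrend_linear(scan.data[mask.mask].astype(float))
    if series.shape[1] < 8:
        raise ValueError("per-voxel series too short for a periodogram")
    fs = 1.0 / scan.tr_s
    freqs, psd = sp_signal.periodogram(
        series, fs=fs, window="boxcar", detrend="constant", scaling="density", axis=-1
    )
    df = freqs[1] - freqs[0]
    nyq = fs / 2.0
    results = []
    for band in bands:
        if band.hi_hz > nyq + df / 2:
            raise ValueError(
                f"band [{band.lo_hz}, {band.hi_hz}] Hz exceeds the per-volume "
                f"Nyquist frequency {nyq:.4g} Hz"
            )
        sel = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
        per_voxel = psd[:, sel].sum(axis=1) * df
        results.append(
            BandpowerResult(
                roi_label=mask.label,
                band=band,
                power=float(per_voxel.mean()),
                method="voxelwise_mean",
            )
        )
    return results


def hypersampled_power(
    scan: FMRIScan,
    mask: ROIMask,
    bands: list[BandDefinition],
    table: SliceTimingTable | None = None,
    gap_policy: str = "interpolate",
) -> tuple[list[BandpowerResult], HypersampledSignal]:
    """Bandpower of the hypersampled ROI signal (rate n_time/TR)."""
    if table is None:
        table = build_timing_table(scan)
    sig = hypersample_roi(scan, mask, table, gap_policy=gap_policy)
    spectrum = periodogram_psd(sig.values, sig.fs_hz)
    return _band_results(spectrum, bands, mask.label, "hypersampled_roi"), sig


def compare_power_sets(
    x: np.ndarray | list[float], y: np.ndarray | list[float]
) -> PowerComparison:
    """OLS slope/intercept of y on x, Pearson r and its two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for regression")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return PowerComparison(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=int(x.size),
        pairs=list(zip(x.tolist(), y.tolist())),
    )


def propagation_sensitivity_suite(
    specs: list | None = None, gap_policy: str = "interpolate"
) -> dict:
    """Hypersampled / voxelwise power ratio per band across phantom specs.

    With a fast cardiac wave, a slow respiratory wave and coherent LFO, the
    respiratory ratio should be the lowest: its short wavelength disperses
    phase across the ROI and the spatial average destructively interferes.
    Returns a report dict with per-spec, per-ROI band ratios and the ordering
    flag ``resp_most_attenuated``.
    """
    from .phantom import generate_phantom, preset_spec

    if specs is None:
        specs = [preset_spec("propagation_demo")]
    report = {"specs": [], "resp_most_attenuated": True}
    for spec in specs:
        scan, _ppg, masks, truth = generate_phantom(spec)
        table = build_timing_table(scan)
        bands, _ = make_bands(truth.cardiac_freq_hz)
        entry = {"seed": spec.seed, "rois": {}}
        for label, mask in masks.items():
            hyper, _ = hypersampled_power(scan, mask, bands, table, gap_policy)
            voxel = voxelwise_mean_power(scan, mask, bands)
            ratios = {
                h.band.name: h.power / v.power if v.power > 0 else np.nan
                for h, v in zip(hyper, voxel)
            }
            entry["rois"][label] = ratios
            if not ratios["resp"] < min(ratios["lfo"], ratios["cardiac"]):
                report["resp_most_attenuated"] = False
        report["specs"].append(entry)
    return report


def export_bandpower_table(
    results: list[BandpowerResult],
    path,
    participant: str = "NA",
    scan_id: str = "NA",
    age: float | None = None,
    sex: str | None = None,
) -> pd.DataFrame:
    """Write a tidy long-format table ready for external mixed-model fitting.

    Columns: participant, scan, roi, band, method, power, log_power, age, sex.
    """
    rows = [
        {
            "participant": participant,
            "scan": scan_id,
            "roi": r.roi_label,
            "band": r.band.name,
            "method": r.method,
            "power": r.power,
            "log_power": np.log(r.power) if r.power > 0 else np.nan,
            "age": age,
            "sex": sex,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return frame
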