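"""Data-driven segmentation of pulsatile vascular voxels.

Large cerebral arteries and the superior sagittal sinus carry a strong,
reproducible cardiac waveform.  The segmentation exploits this: fMRI volumes
are randomly split into two halves, each half is retrospectively realigned to
the cardiac cycle (volume-wise PPG phase, binned into ``n_phase_bins`` bins),
and the voxel-wise Pearson correlation between the two binned waveforms scores
how reproducible the voxel's pulsatility is.  Voxels above ``r_threshold``
inside an anatomical search region become the vessel mask.

The defaults (10 phase bins, r >= 0.5) are package choices, surfaced in the
run report; the volume-level cardiac phase is evaluated at the scan's mean
slice offset — a constant per-voxel timing offset shifts both half waveforms
identically, so the correlation is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import FMRIScan, ROIMask
from .physio import CardiacInfo
from .hypersample import detrend_linear

__all__ = [
    "SegmentationConfig",
    "cardiac_realign",
    "split_half_pulsatility_map",
    "segment_vessels",
]


@dataclass
class SegmentationConfig:
    n_phase_bins: int = 10
    r_threshold: float = 0.5
    seed: int = 0
    min_voxels: int = 5
    keep_largest_component: bool = True

    def __post_init__(self) -> None:
        if self.n_phase_bins < 4:
            raise ValueError("need at least 4 cardiac phase bins")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")


def _bin_means(
    series2d: np.ndarray, bins: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of each row of ``series2d`` grouped by the per-column bin label.

    Returns (means (rows, n_bins) with NaN for empty bins, counts)."""
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.zeros((series2d.shape[0], n_bins))
    np.add.at(sums.T, bins, series2d.T)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[:, counts == 0] = np.nan
    return means, counts


def cardiac_realign(
    voxel_series: np.ndarray, volume_phases: np.ndarray, n_phase_bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Bin a detrended voxel series by cardiac phase.

    Returns (waveform, valid_bins): ``waveform[b]`` is the mean of the
    detrended values whose volume phase falls in bin b = floor(phase * n);
    empty bins are NaN/invalid.  More than half the bins empty is an error —
    the cardiac cycle is then too poorly sampled to realign.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    volume_phases = np.asarray(volume_phases, dtype=float)
    if voxel_series.shape != volume_phases.shape:
        raise ValueError("series and phases must have equal length")
    if np.any((volume_phases < 0) | (volume_phases >= 1)):
        raise ValueError("phases must lie in [0, 1)")
    detrended = detrend_linear(voxel_series)
    bins = np.minimum((volume_phases * n_phase_bins).astype(int), n_phase_bins - 1)
    means, counts = _bin_means(detrended[None, :], bins, n_phase_bins)
    valid = counts > 0
    if (~valid).sum() > n_phase_bins / 2:
        raise ValueError(
            f"{int((~valid).sum())} of {n_phase_bins} cardiac phase bins are empty"
        )
    return means[0], valid


def split_half_pulsatility_map(
    scan: FMRIScan,
    cardiac_info: CardiacInfo,
    config: SegmentationConfig | None = None,
    _forced_split: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Voxel-wise split-half cardiac-aligned reproducibility correlation.

    Volumes with a defined cardiac phase are randomly permuted (seeded) into
    two equal halves; each half is phase-binned per voxel and the two binned
    waveforms correlated.  Returns a 3D map in [-1, 1] (0 where a voxel or
    bin set is degenerate).  ``_forced_split`` injects an explicit pair of
    volume-index arrays (testing hook; duplicates allowed).
    """
    config = config or SegmentationConfig()
    n_bins = config.n_phase_bins
    times = np.arange(scan.n_volumes) * scan.tr_s + float(
        np.mean(scan.slice_offsets_s)
    )
    phases, valid = cardiac_info.phase_at(times)
    usable = np.flatnonzero(valid)
    if usable.size < 4 * n_bins:
        raise ValueError(
            f"only {usable.size} volumes have a cardiac phase; need at least "
            f"{4 * n_bins} for {n_bins} phase bins per half"
        )

    if _forced_split is not None:
        half_a, half_b = (np.asarray(h, dtype=int) for h in _forced_split)
    else:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(usable)
        half_a, half_b = perm[: usable.size // 2], perm[usable.size // 2 :]

    flat = scan.data.reshape(-1, scan.n_volumes).astype(float)
    detrended = detrend_linear(flat)
    bins = np.zeros(phases.size, dtype=int)
    bins[valid] = np.minimum((phases[valid] * n_bins).astype(int), n_bins - 1)

    wave_a, counts_a = _bin_means(detrended[:, half_a], bins[half_a], n_bins)
    wave_b, counts_b = _bin_means(detrended[:, half_b], bins[half_b], n_bins)
    shared = (counts_a > 0) & (counts_b > 0)
    if (~shared).sum() > n_bins / 2:
        raise ValueError(
            f"{int((~shared).sum())} of {n_bins} phase bins are empty in at "
            "least one half"
        )
    a = wave_a[:, shared] - wave_a[:, shared].mean(axis=1, keepdims=True)
    b = wave_b[:, shared] - wave_b[:, shared].mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    r[~np.isfinite(r)] = 0.0
    return r.reshape(scan.spatial_shape)


def segment_vessels(
    pulsatility_map: np.ndarray,
    search_mask: ROIMask,
    config: SegmentationConfig | None = None,
    label: str = "custom",
) -> ROIMask:
    """Threshold the reproducibility map inside an anatomical search region."""
    config = config or SegmentationConfig()
    pulsatility_map = np.asarray(pulsatility_map, dtype=float)
    if pulsatility_map.shape != search_mask.mask.shape:
        raise ValueError("pulsatility map and search mask grids differ")
    selected = (pulsatility_map >= config.r_threshold) & search_mask.mask
    if config.keep_largest_component and selected.any():
        labelled, n_comp = ndimage.label(selected)
        if n_comp > 1:
            sizes = np.bincount(labelled.ravel())[1:]
            selected = labelled == (int(np.argmax(sizes)) + 1)
    if selected.sum() < config.min_voxels:
        raise ValueError(
            f"unreliable vessel segmentation: {int(selected.sum())} voxels "
            f"above r={config.r_threshold} (need >= {config.min_voxels})"
        )
    return ROIMask(mask=selected, label=label)
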