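"""Reading and writing of on-disk artifacts.

Images and masks are NIfTI-1 (handled by nibabel); slice timing comes from a
BIDS JSON sidecar ("SliceTiming", seconds per slice, referenced to volume
start) or is derived from (n_slices, mb_factor, tr_s, ordering) parameters;
physiological recordings are single-column text/TSV; motion traces are
whitespace-delimited text (one absolute-displacement column or six
mcflirt-style parameters).

No resampling is ever performed: a mask whose grid does not match the scan is
an error, never a warning, because hypersampling is meaningless on mismatched
geometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FMRIScan",
    "ROIMask",
    "PhysioRecording",
    "MotionTrace",
    "slice_offsets_from_params",
    "load_fmri",
    "save_fmri",
    "load_mask",
    "save_mask",
    "load_physio",
    "save_physio",
    "load_motion",
    "save_motion",
]

#: tolerance for TR / slice-timing agreement between metadata sources (s)
TIMING_TOL_S = 1e-3

#: tolerance for affine agreement between a scan and its masks
AFFINE_TOL = 1e-3

ROI_LABELS = ("artery", "SSS", "GM", "WM", "custom")


@dataclass
class FMRIScan:
    """A 4D fMRI acquisition with its slice-timing metadata.

    ``data`` is (x, y, z, t) signal intensity in arbitrary units.
    ``slice_offsets_s[s]`` is the acquisition offset of slice ``s`` within a
    TR, so volume ``k`` of slice ``s`` is acquired at ``k * tr_s +
    slice_offsets_s[s]`` seconds.
    """

    data: np.ndarray
    tr_s: float
    slice_offsets_s: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.slice_offsets_s = np.asarray(self.slice_offsets_s, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"not a time series: expected 4D data, got {self.data.ndim}D"
            )
        if not self.tr_s > 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if self.n_volumes < 2:
            raise ValueError("a time series needs at least 2 volumes")
        if self.slice_offsets_s.shape != (self.data.shape[2],):
            raise ValueError(
                f"slice_offsets_s has length {len(self.slice_offsets_s)}, "
                f"but data has {self.data.shape[2]} slices"
            )
        if np.any(self.slice_offsets_s < 0) or np.any(
            self.slice_offsets_s >= self.tr_s
        ):
            raise ValueError("slice offsets must lie in [0, tr_s)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths (mm) from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class ROIMask:
    """A boolean 3D region-of-interest mask on a scan's grid."""

    mask: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.mask.ndim}D")
        if not self.mask.any():
            raise ValueError("empty ROI")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PhysioRecording:
    """A physiological (PPG) trace aligned to the fMRI acquisition.

    ``start_offset_s`` is the time of the first physio sample relative to the
    start of the first fMRI volume (0 = recording starts with the scan).
    """

    samples: np.ndarray
    fs_hz: float
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.size == 0:
            raise ValueError("empty physio recording")
        if self.duration_s < 10.0:
            warnings.warn(
                f"physio recording is only {self.duration_s:.1f} s; "
                "cardiac estimates below 10 s are unreliable",
                stacklevel=2,
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_offset_s + np.arange(self.samples.size) / self.fs_hz


@dataclass
class MotionTrace:
    """Per-volume absolute displacement in millimetres."""

    displacement_mm: np.ndarray

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float).ravel()
        if self.displacement_mm.size == 0:
            raise ValueError("empty motion trace")
        if np.any(self.displacement_mm < 0):
            raise ValueError("absolute displacement must be non-negative")

    def __len__(self) -> int:
        return self.displacement_mm.size


# ---------------------------------------------------------------------------
# slice timing


def slice_offsets_from_params(
    n_slices: int,
    mb_factor: int,
    tr_s: float,
    ordering: str = "ascending",
) -> np.ndarray:
    """Derive per-slice acquisition offsets from acquisition parameters.

    With multiband factor ``mb_factor``, slices ``s`` and ``s + n_time`` are
    excited simultaneously (``n_time = n_slices / mb_factor``), so slice ``s``
    belongs to timing group ``s % n_time``.  Groups are played out either in
    ascending order or interleaved (even groups first, then odd), each at a
    multiple of ``tr_s / n_time``.
    """
    if n_slices % mb_factor != 0:
        raise ValueError(
            f"n_slices={n_slices} is not divisible by mb_factor={mb_factor}"
        )
    n_time = n_slices // mb_factor
    if ordering == "ascending":
        acquisition_order = np.arange(n_time)
    elif ordering == "interleaved":
        acquisition_order = np.concatenate(
            [np.arange(0, n_time, 2), np.arange(1, n_time, 2)]
        )
    else:
        raise ValueError(f"unknown slice ordering {ordering!r}")
    # rank[g] = position of timing group g in the within-TR acquisition order
    rank = np.empty(n_time, dtype=int)
    rank[acquisition_order] = np.arange(n_time)
    group_of_slice = np.arange(n_slices) % n_time
    return rank[group_of_slice] * (tr_s / n_time)


def _read_sidecar(path: Path) -> tuple[np.ndarray, float | None]:
    with open(path) as fh:
        meta = json.load(fh)
    if "SliceTiming" not in meta:
        raise ValueError(f"sidecar {path} has no SliceTiming field")
    return np.asarray(meta["SliceTiming"], dtype=float), meta.get("RepetitionTime")


def load_fmri(
    image_path: str | Path,
    sidecar_path: str | Path | None = None,
    *,
    timing_params: dict | None = None,
) -> FMRIScan:
    """Load a 4D NIfTI plus its slice-timing metadata into an :class:`FMRIScan`.

    Slice timing must be available either from a BIDS JSON sidecar
    (``sidecar_path``) or from ``timing_params`` with keys ``n_slices``,
    ``mb_factor``, ``tr_s`` and optional ``ordering``.  The sidecar is the
    source of truth; if both are supplied and disagree by more than 1 ms on
    any slice, an error is raised (hypersampling with wrong timings is
    meaningless).  TR is taken from the sidecar if present, else from the
    NIfTI header, with a >1 ms mismatch between the two raising an error.
    """
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"not a time series: {image_path} is {data.ndim}D")

    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0

    sidecar_offsets = sidecar_tr = None
    if sidecar_path is not None:
        sidecar_offsets, sidecar_tr = _read_sidecar(Path(sidecar_path))
        if sidecar_offsets.size != data.shape[2]:
            raise ValueError(
                f"sidecar has {sidecar_offsets.size} slice timings but image "
                f"has {data.shape[2]} slices"
            )

    if sidecar_tr is not None:
        tr_s = float(sidecar_tr)
        if header_tr > 0 and abs(header_tr - tr_s) > TIMING_TOL_S:
            raise ValueError(
                f"RepetitionTime {tr_s} s disagrees with header TR {header_tr} s"
            )
    elif timing_params is not None and "tr_s" in timing_params:
        tr_s = float(timing_params["tr_s"])
        if header_tr > 0 and abs(header_tr - tr_s) > TIMING_TOL_S:
            raise ValueError(
                f"tr_s parameter {tr_s} s disagrees with header TR {header_tr} s"
            )
    elif header_tr > 0:
        tr_s = header_tr
    else:
        raise ValueError("TR not available from sidecar, parameters, or header")

    derived_offsets = None
    if timing_params is not None:
        derived_offsets = slice_offsets_from_params(
            timing_params.get("n_slices", data.shape[2]),
            timing_params["mb_factor"],
            tr_s,
            timing_params.get("ordering", "ascending"),
        )
        if derived_offsets.size != data.shape[2]:
            raise ValueError(
                f"timing parameters describe {derived_offsets.size} slices but "
                f"image has {data.shape[2]}"
            )

    if sidecar_offsets is not None:
        if derived_offsets is not None and np.any(
            np.abs(sidecar_offsets - derived_offsets) > TIMING_TOL_S
        ):
            raise ValueError(
                "sidecar SliceTiming and derived parameter timings disagree "
                "by more than 1 ms"
            )
        offsets = sidecar_offsets
    elif derived_offsets is not None:
        offsets = derived_offsets
    else:
        raise ValueError(
            "slice timing unavailable: supply a sidecar or timing parameters"
        )

    return FMRIScan(data=data, tr_s=tr_s, slice_offsets_s=offsets, affine=img.affine)


def save_fmri(
    scan: FMRIScan, image_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Write a scan as NIfTI (+ optional BIDS sidecar with SliceTiming)."""
    img = nib.Nifti1Image(np.asarray(scan.data), scan.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = scan.tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(image_path))
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "RepetitionTime": scan.tr_s,
                    "SliceTiming": [float(v) for v in scan.slice_offsets_s],
                },
                fh,
                indent=2,
            )


def load_mask(path: str | Path, scan: FMRIScan, label: str = "custom") -> ROIMask:
    """Load a 3D NIfTI mask onto a scan's grid (nonzero voxels become True)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.shape != scan.spatial_shape:
        raise ValueError(
            f"mask shape {data.shape} does not match scan grid {scan.spatial_shape}"
        )
    if np.any(np.abs(img.affine - scan.affine) > AFFINE_TOL):
        raise ValueError("mask affine does not match scan affine")
    return ROIMask(mask=data != 0, label=label)


def save_mask(roi: ROIMask, path: str | Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(
        roi.mask.astype(np.uint8), np.eye(4) if affine is None else affine
    )
    nib.save(img, str(path))


def load_physio(
    path: str | Path, fs_hz: float, start_offset_s: float = 0.0
) -> PhysioRecording:
    """Load a single-column physio trace sampled at ``fs_hz``."""
    try:
        raw = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric rows in physio file {path}") from exc
    return PhysioRecording(
        samples=raw[:, 0], fs_hz=fs_hz, start_offset_s=start_offset_s
    )


def save_physio(rec: PhysioRecording, path: str | Path) -> None:
    np.savetxt(str(path), rec.samples, fmt="%.8g")


def load_motion(path: str | Path, n_volumes: int | None = None) -> MotionTrace:
    """Load a motion trace: one displacement column, or six mcflirt columns.

    Six-parameter files (rx ry rz tx ty tz) are reduced to the Euclidean norm
    of the three translations, the default displacement formula; users with
    other conventions should precompute a single column.
    """
    try:
        raw = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric rows in motion file {path}") from exc
    if raw.shape[1] == 1:
        disp = np.abs(raw[:, 0])
    elif raw.shape[1] == 6:
        disp = np.linalg.norm(raw[:, 3:6], axis=1)
    else:
        raise ValueError(
            f"motion file must have 1 or 6 columns, got {raw.shape[1]}"
        )
    if n_volumes is not None and disp.size != n_volumes:
        raise ValueError(
            f"motion trace has {disp.size} rows but scan has {n_volumes} volumes"
        )
    return MotionTrace(displacement_mm=disp)


def save_motion(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), trace.displacement_mm, fmt="%.8g")
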