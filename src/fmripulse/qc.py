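"""Scan- and ROI-level quality gates.

Three exclusions, with boundary semantics encoded exactly as stated:

* motion — a scan fails if *more than* 15% of volumes show absolute
  displacement exceeding 1 mm (exactly 15% passes).  Hypersampling needs
  exact slice timing and is therefore incompatible with motion correction,
  so motion can only be gated, never fixed.
* PPG — the recording fails below a minimum quality (in-band power fraction,
  default 0.3; the threshold is configuration, not a published value).
* coverage — an ROI fails if it spans *fewer than half* plus one of the
  unique slice timings, i.e. it passes only when covered > n_time / 2.

All decisions are pure functions of their inputs and thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import MotionTrace, PhysioRecording, ROIMask
from .hypersample import SliceTimingTable
from .physio import DEFAULT_MIN_QUALITY, CardiacInfo

__all__ = ["QCReport", "qc_motion", "qc_ppg", "qc_coverage", "build_report"]

MAX_ABS_MOTION_MM = 1.0
MAX_MOTION_FRACTION = 0.15


@dataclass
class QCReport:
    motion_pass: bool
    motion_fraction: float
    ppg_pass: bool
    ppg_quality: float
    coverage: dict[str, tuple[bool, int, int]] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return (
            self.motion_pass
            and self.ppg_pass
            and all(ok for ok, _, _ in self.coverage.values())
        )

    def failing_gates(self) -> list[str]:
        gates = []
        if not self.motion_pass:
            gates.append("motion")
        if not self.ppg_pass:
            gates.append("ppg")
        gates += [
            f"coverage:{roi}" for roi, (ok, _, _) in self.coverage.items() if not ok
        ]
        return gates

    def to_dict(self) -> dict:
        return {
            "motion_pass": self.motion_pass,
            "motion_fraction": self.motion_fraction,
            "ppg_pass": self.ppg_pass,
            "ppg_quality": self.ppg_quality,
            "coverage": {
                roi: {"pass": ok, "covered": cov, "n_time": nt}
                for roi, (ok, cov, nt) in self.coverage.items()
            },
            "overall_pass": self.overall_pass,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QCReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            motion_pass=d["motion_pass"],
            motion_fraction=d["motion_fraction"],
            ppg_pass=d["ppg_pass"],
            ppg_quality=d["ppg_quality"],
            coverage={
                roi: (v["pass"], v["covered"], v["n_time"])
                for roi, v in d["coverage"].items()
            },
        )


def qc_motion(
    trace: MotionTrace,
    max_abs_mm: float = MAX_ABS_MOTION_MM,
    max_fraction: float = MAX_MOTION_FRACTION,
) -> tuple[bool, float]:
    """Pass iff at most ``max_fraction`` of volumes exceed ``max_abs_mm``."""
    disp = trace.displacement_mm
    fraction = float(np.count_nonzero(disp > max_abs_mm)) / disp.size
    return fraction <= max_fraction, fraction


def qc_ppg(
    ppg: PhysioRecording | None,
    cardiac_info: CardiacInfo,
    min_quality: float = DEFAULT_MIN_QUALITY,
) -> tuple[bool, float]:
    """Pass iff the PPG quality score reaches ``min_quality``."""
    quality = float(cardiac_info.quality)
    return quality >= min_quality, quality


def qc_coverage(
    mask: ROIMask, timing_table: SliceTimingTable
) -> tuple[bool, int, int]:
    """Pass iff the ROI spans more than half of the unique slice timings."""
    voxels_per_slice = mask.mask.sum(axis=(0, 1))
    covered_groups = np.unique(
        timing_table.group_of_slice[np.flatnonzero(voxels_per_slice > 0)]
    )
    covered = int(covered_groups.size)
    return covered > timing_table.n_time / 2, covered, timing_table.n_time


def build_report(
    motion: MotionTrace,
    cardiac_info: CardiacInfo,
    masks: dict[str, ROIMask],
    timing_table: SliceTimingTable,
    min_quality: float = DEFAULT_MIN_QUALITY,
    max_abs_mm: float = MAX_ABS_MOTION_MM,
    max_fraction: float = MAX_MOTION_FRACTION,
) -> QCReport:
    motion_pass, fraction = qc_motion(motion, max_abs_mm, max_fraction)
    ppg_pass, quality = qc_ppg(None, cardiac_info, min_quality)
    coverage = {
        roi: qc_coverage(mask, timing_table) for roi, mask in masks.items()
    }
    return QCReport(
        motion_pass=motion_pass,
        motion_fraction=fraction,
        ppg_pass=ppg_pass,
        ppg_quality=quality,
        coverage=coverage,
    )
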