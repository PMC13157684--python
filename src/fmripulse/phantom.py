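"""Synthetic multiband fMRI phantoms with known physiological ground truth.

The phantom emulates a 2D multiband EPI acquisition of a brain whose signal is
a sum of compartment-specific sinusoidal oscillations in the three
physiological bands — LFO (0.01–0.1 Hz), respiratory (0.2–0.4 Hz) and cardiac
(~0.5–2 Hz) — sampled at each voxel's true slice-acquisition time
``k*TR + offset[slice]``, plus an optional per-slice baseline gradient and
additive white Gaussian noise.  Each oscillation may propagate as a travelling
wave from a source voxel: a voxel at Euclidean distance d (mm) sees the
component delayed by d / speed, so its phase lags by 2*pi*f*d/v — the
wavelength lambda = T*v controls how much phase disperses across a region.
A matched photoplethysmography trace (periodic pulse at the cardiac
frequency) is generated alongside.

What it deliberately does not model: BOLD neuronal signal, motion, EPI
distortion or k-space effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FMRIScan, PhysioRecording, ROIMask, slice_offsets_from_params

__all__ = [
    "Oscillation",
    "Compartment",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "default_components",
    "preset_spec",
    "PRESETS",
]

_FREQ_RANGES = {"lfo": (0.01, 0.1), "resp": (0.2, 0.4), "cardiac": (0.5, 2.0)}


@dataclass
class Oscillation:
    """One physiological component: frequency, harmonics, propagation speed.

    ``speed_m_s=None`` means coherent (infinite speed, zero phase lag).
    Harmonic h has amplitude 1/h relative to the fundamental.
    """

    name: str
    freq_hz: float
    n_harmonics: int = 1
    speed_m_s: float | None = None

    def __post_init__(self) -> None:
        if self.name in _FREQ_RANGES:
            lo, hi = _FREQ_RANGES[self.name]
            if not lo <= self.freq_hz <= hi:
                raise ValueError(
                    f"{self.name} frequency {self.freq_hz} Hz outside [{lo}, {hi}]"
                )
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.speed_m_s is not None and self.speed_m_s <= 0:
            raise ValueError("propagation speed must be positive")


@dataclass
class Compartment:
    """A labelled voxel set with per-component oscillation amplitudes."""

    label: str
    mask: np.ndarray  # 3D boolean
    amplitudes: dict[str, float]  # component name -> amplitude (a.u.)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        for name, amp in self.amplitudes.items():
            if amp < 0:
                raise ValueError(f"amplitude for {name} must be >= 0")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int]
    tr_s: float
    n_volumes: int
    mb_factor: int
    compartments: list[Compartment]
    components: dict[str, Oscillation]
    ordering: str = "ascending"
    voxel_size_mm: float = 2.5
    source_voxel: tuple[int, int, int] = (0, 0, 0)
    noise_sd: float = 0.0
    slice_baseline: float = 1.0  # baseline spans [0, slice_baseline] across slices
    seed: int = 0
    ppg_fs_hz: float = 100.0
    ppg_n_harmonics: int = 3

    def __post_init__(self) -> None:
        nz = self.shape[2]
        if nz % self.mb_factor != 0:
            raise ValueError(
                f"nz={nz} must be divisible by mb_factor={self.mb_factor}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ppg_fs_hz < 50:
            raise ValueError("PPG sampling rate must be >= 50 Hz")
        for comp in self.compartments:
            if comp.mask.shape != tuple(self.shape):
                raise ValueError(
                    f"compartment {comp.label} mask shape {comp.mask.shape} "
                    f"!= grid {self.shape}"
                )
            for name in comp.amplitudes:
                if name not in self.components:
                    raise ValueError(f"unknown component {name!r} in {comp.label}")

    @property
    def n_time(self) -> int:
        return self.shape[2] // self.mb_factor

    @property
    def slice_offsets_s(self) -> np.ndarray:
        return slice_offsets_from_params(
            self.shape[2], self.mb_factor, self.tr_s, self.ordering
        )


@dataclass
class GroundTruth:
    """Exact continuous-time per-compartment, per-band signal power.

    ``band_power[label][band]`` is the summed amp^2/2 of all sinusoids
    (fundamentals and harmonics) falling inside the band; propagation shifts
    phases only and never changes this per-voxel power.
    """

    band_power: dict[str, dict[str, float]]
    cardiac_freq_hz: float
    bands: dict[str, tuple[float, float]]
    amplitudes: dict[str, dict[str, float]] = field(default_factory=dict)


def _sinusoid_lines(osc: Oscillation, amp: float) -> list[tuple[float, float]]:
    """(frequency, amplitude) of fundamental + harmonics for one component."""
    return [(h * osc.freq_hz, amp / h) for h in range(1, osc.n_harmonics + 1)]


def _ground_truth(spec: PhantomSpec) -> GroundTruth:
    f_card = spec.components["cardiac"].freq_hz if "cardiac" in spec.components else 1.0
    bands = {
        "lfo": (0.01, 0.1),
        "resp": (0.2, 0.4),
        "cardiac": (f_card - 0.15, f_card + 0.15),
    }
    table: dict[str, dict[str, float]] = {}
    amps: dict[str, dict[str, float]] = {}
    for comp in spec.compartments:
        powers = {b: 0.0 for b in bands}
        for name, amp in comp.amplitudes.items():
            for f, a in _sinusoid_lines(spec.components[name], amp):
                for band, (lo, hi) in bands.items():
                    if lo <= f <= hi:
                        powers[band] += a**2 / 2.0
        table[comp.label] = powers
        amps[comp.label] = dict(comp.amplitudes)
    return GroundTruth(
        band_power=table, cardiac_freq_hz=f_card, bands=bands, amplitudes=amps
    )


def _delays_s(spec: PhantomSpec, osc: Oscillation, voxels: np.ndarray) -> np.ndarray:
    """Per-voxel propagation delay (s) for one component; 0 when coherent."""
    if osc.speed_m_s is None:
        return np.zeros(len(voxels))
    src = np.asarray(spec.source_voxel, dtype=float)
    dist_mm = np.linalg.norm((voxels - src) * spec.voxel_size_mm, axis=1)
    return dist_mm / 1000.0 / osc.speed_m_s


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[FMRIScan, PhysioRecording, dict[str, ROIMask], GroundTruth]:
    """Simulate a multiband acquisition of the phantom.

    Voxel v in compartment c, slice s, volume k takes the value::

        baseline(s) + sum_comp sum_h (amp_c,comp / h) *
            sin(2*pi*h*f_comp*(k*TR + offset[s] - delay_comp(v))) + N(0, noise_sd)

    All randomness flows from ``spec.seed`` through one generator.
    """
    nx, ny, nz = spec.shape
    nt = spec.n_volumes
    offsets = spec.slice_offsets_s
    rng = np.random.default_rng(spec.seed)

    # acquisition time of (slice, volume)
    t = offsets[:, None] + spec.tr_s * np.arange(nt)[None, :]  # (nz, nt)

    data = np.zeros((nx, ny, nz, nt))
    if spec.slice_baseline != 0 and nz > 1:
        baseline = spec.slice_baseline * np.arange(nz) / (nz - 1)
        data += baseline[None, None, :, None]

    for comp in spec.compartments:
        voxels = np.argwhere(comp.mask)  # (V, 3)
        iz = voxels[:, 2]
        for name, amp in comp.amplitudes.items():
            if amp == 0:
                continue
            osc = spec.components[name]
            tau = _delays_s(spec, osc, voxels)  # (V,)
            for f, a in _sinusoid_lines(osc, amp):
                wave = a * np.sin(2 * np.pi * f * (t[iz, :] - tau[:, None]))
                data[voxels[:, 0], voxels[:, 1], iz, :] += wave

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    scan = FMRIScan(data=data, tr_s=spec.tr_s, slice_offsets_s=offsets, affine=affine)

    # PPG: periodic pulse with peaks at multiples of the cardiac period
    f_card = spec.components["cardiac"].freq_hz if "cardiac" in spec.components else 1.0
    tp = np.arange(int(round(nt * spec.tr_s * spec.ppg_fs_hz))) / spec.ppg_fs_hz
    ppg = np.zeros_like(tp)
    for h in range(1, spec.ppg_n_harmonics + 1):
        ppg += np.cos(2 * np.pi * h * f_card * tp) / h
    physio = PhysioRecording(samples=ppg, fs_hz=spec.ppg_fs_hz, start_offset_s=0.0)

    masks = {c.label: ROIMask(mask=c.mask, label=c.label) for c in spec.compartments}
    return scan, physio, masks, _ground_truth(spec)


# ---------------------------------------------------------------------------
# presets


def default_components(
    cardiac_freq_hz: float = 1.1,
    lfo_freq_hz: float = 0.05,
    resp_freq_hz: float = 0.3,
    cardiac_speed_m_s: float | None = 2.0,
    resp_speed_m_s: float | None = 0.1,
    lfo_speed_m_s: float | None = None,
    cardiac_harmonics: int = 1,
) -> dict[str, Oscillation]:
    """Standard component set: coherent LFO, slow respiratory wave (0.1 m/s),
    fast cardiac wave (2 m/s)."""
    return {
        "lfo": Oscillation("lfo", lfo_freq_hz, speed_m_s=lfo_speed_m_s),
        "resp": Oscillation("resp", resp_freq_hz, speed_m_s=resp_speed_m_s),
        "cardiac": Oscillation(
            "cardiac",
            cardiac_freq_hz,
            n_harmonics=cardiac_harmonics,
            speed_m_s=cardiac_speed_m_s,
        ),
    }


#: per-compartment amplitudes mirroring the dominance patterns of the four
#: regions: cardiac-dominant arteries, mixed SSS, LFO-dominant GM/WM
_PRESET_AMPLITUDES = {
    "artery": {"lfo": 0.2, "resp": 0.25, "cardiac": 1.0},
    "SSS": {"lfo": 0.4, "resp": 0.45, "cardiac": 0.8},
    "GM": {"lfo": 1.0, "resp": 0.15, "cardiac": 0.15},
    "WM": {"lfo": 0.5, "resp": 0.1, "cardiac": 0.08},
}


def _slab_compartments(
    shape: tuple[int, int, int], amplitudes: dict[str, dict[str, float]]
) -> list[Compartment]:
    """Partition the z-axis into equal slabs, one compartment per label."""
    nz = shape[2]
    labels = list(amplitudes)
    edges = np.linspace(0, nz, len(labels) + 1).astype(int)
    comps = []
    for label, z0, z1 in zip(labels, edges[:-1], edges[1:]):
        mask = np.zeros(shape, dtype=bool)
        mask[:, :, z0:z1] = True
        comps.append(Compartment(label=label, mask=mask, amplitudes=amplitudes[label]))
    return comps


def preset_spec(name: str, seed: int = 0, noise_sd: float = 0.2, **overrides):
    """Build a ready-to-run PhantomSpec for a named acquisition preset.

    ``hcp_like``: 72 slices, MB 8, TR 0.8 s, 488 volumes, 2.0 mm voxels.
    ``local_like``: 40 slices, MB 8, TR 0.366 s, 500 volumes, 2.5 mm voxels.
    ``propagation_demo``: local-like grid with a single 50 mm compartment,
    fast cardiac (3 m/s), slow respiratory (0.05 m/s) and coherent LFO waves.
    """
    if name == "hcp_like":
        shape, tr, nvol, vox = (8, 8, 72), 0.8, 488, 2.0
        components = overrides.pop("components", None) or default_components()
        comps = _slab_compartments(shape, _PRESET_AMPLITUDES)
    elif name == "local_like":
        shape, tr, nvol, vox = (8, 8, 40), 0.366, 500, 2.5
        components = overrides.pop("components", None) or default_components()
        comps = _slab_compartments(shape, _PRESET_AMPLITUDES)
    elif name == "propagation_demo":
        shape, tr, nvol, vox = (8, 8, 40), 0.366, 500, 2.5
        components = overrides.pop("components", None) or default_components(
            cardiac_speed_m_s=3.0, resp_speed_m_s=0.05
        )
        mask = np.zeros(shape, dtype=bool)
        mask[:, :, 10:30] = True  # 20 slices x 2.5 mm = 50 mm extent
        comps = [
            Compartment(
                label="roi",
                mask=mask,
                amplitudes={"lfo": 0.8, "resp": 0.8, "cardiac": 0.8},
            )
        ]
    else:
        raise ValueError(f"unknown preset {name!r}")
    spec_kwargs = dict(
        shape=shape,
        tr_s=tr,
        n_volumes=nvol,
        mb_factor=8,
        compartments=comps,
        components=components,
        voxel_size_mm=vox,
        noise_sd=noise_sd,
        seed=seed,
    )
    spec_kwargs.update(overrides)
    return PhantomSpec(**spec_kwargs)


PRESETS = ("hcp_like", "local_like", "propagation_demo")
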