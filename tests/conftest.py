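import numpy as np
import pytest

from fmripulse.phantom import Compartment, Oscillation, PhantomSpec


def single_component_spec(
    f_hz: float,
    amp: float = 1.0,
    *,
    shape=(4, 4, 8),
    tr_s: float = 0.8,
    n_volumes: int = 64,
    mb_factor: int = 2,
    noise_sd: float = 0.0,
    speed_m_s: float | None = None,
    seed: int = 0,
    slice_baseline: float = 1.0,
    voxel_size_mm: float = 2.5,
) -> PhantomSpec:
    """A phantom with one sinusoidal component filling the whole grid."""
    name = "lfo" if f_hz <= 0.1 else ("resp" if f_hz <= 0.4 else "cardiac")
    mask = np.ones(shape, dtype=bool)
    return PhantomSpec(
        shape=shape,
        tr_s=tr_s,
        n_volumes=n_volumes,
        mb_factor=mb_factor,
        compartments=[Compartment("roi", mask, {name: amp})],
        components={name: Oscillation(name, f_hz, speed_m_s=speed_m_s)},
        noise_sd=noise_sd,
        seed=seed,
        slice_baseline=slice_baseline,
        voxel_size_mm=voxel_size_mm,
    )


@pytest.fixture(scope="session")
def hcp_cardiac_phantom():
    """Noiseless coherent 1.1 Hz cardiac phantom at the 72-slice/MB-8/TR-0.8
    acquisition geometry (above the per-volume Nyquist of 0.625 Hz)."""
    from fmripulse.phantom import generate_phantom

    spec = single_component_spec(
        1.1, shape=(4, 4, 72), tr_s=0.8, n_volumes=488, mb_factor=8
    )
    scan, ppg, masks, truth = generate_phantom(spec)
    return spec, scan, ppg, masks, truth
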