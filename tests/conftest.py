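import numpy as np
import pytest

from vncstudy import CTVolume, PhantomGeometry, PhantomSpec, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A down-scaled phantom (~48 mm FOV) for fast unit tests."""
    spec = PhantomSpec(grid_shape=(64, 64, 100), base_spacing=(0.75, 0.75, 0.2),
                       **overrides)
    return spec


def quiet_spec(**overrides) -> PhantomSpec:
    """Small phantom with all noise and spurious specks disabled."""
    spec = small_spec(**overrides)
    spec.noise_sd = {k: 0.0 for k in spec.noise_sd}
    spec.pc_false_positive_rate = 0.0
    return spec


def lesion_in(spec: PhantomSpec, vessel: str, radius: float, peak: float,
              offset=(0.0, 0.0, 0.0)):
    """A CalcificationSpec centered in a vessel territory of the spec."""
    from vncstudy import CalcificationSpec

    geom = PhantomGeometry.from_spec(spec)
    lo, hi = geom.territories[vessel]
    center = tuple(0.5 * (lo[i] + hi[i]) + offset[i] for i in range(3))
    return CalcificationSpec(center=center, radius=radius, peak_hu=peak,
                             vessel=vessel)


@pytest.fixture(scope="session")
def small_quiet_bundle():
    """One noise-free small phantom with a 1.5 mm, 400 HU lesion in the LAD."""
    spec = quiet_spec()
    spec.calcifications = [lesion_in(spec, "LAD", 1.5, 400.0)]
    return generate_phantom(spec, patient_id="P01")


def flat_volume(value=0.0, shape=(8, 8, 4), spacing=(1.0, 1.0, 3.0),
                thickness=None, series_id="TNC"):
    data = np.full(shape, value, dtype=np.float32)
    return CTVolume(data, spacing, thickness or spacing[2], series_id)
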