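import numpy as np
import pytest

from mvphantom import (
    AnnulusModel,
    PBDConfig,
    generate_valve_mesh,
    simulate_closure,
)
from mvphantom.phantom_anatomy import LabelVolume, ThoraxConfig, generate_thorax


@pytest.fixture(scope="session")
def annulus_model():
    return AnnulusModel()


@pytest.fixture(scope="session")
def valve_mesh(annulus_model):
    return generate_valve_mesh(annulus_model)


@pytest.fixture(scope="session")
def closure_sequence(valve_mesh):
    """Full default 180-frame closure (shared; ~8 s once per session)."""
    return simulate_closure(valve_mesh, PBDConfig())


@pytest.fixture(scope="session")
def small_thorax():
    """Reduced-FOV thorax for image tests (valve region fully covered)."""
    return generate_thorax(ThoraxConfig(shape=(80, 80, 80), spacing=(1.5, 1.5, 1.5)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_label_volume(labels, spacing=1.0, label_map=None):
    """Centered isotropic LabelVolume around a given label array."""
    labels = np.asarray(labels)
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * spacing
    affine[:3, 3] = -(np.array(labels.shape) - 1) / 2.0 * spacing
    if label_map is None:
        label_map = {f"label_{i}": int(i) for i in np.unique(labels) if i != 0}
    return LabelVolume(labels=labels, affine=affine, label_map=label_map)
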