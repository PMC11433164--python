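"""Shared fixtures: small phantoms, degraded pairs, and a quickly trained
toy model with perturbation sites (used by the uncertainty tests)."""

import numpy as np
import pytest

from voxsr.degradation import ScaleFactor, make_pair
from voxsr.models import ArchitectureSpec, build_model
from voxsr.nn import init_xavier_uniform
from voxsr.objectives import LossSpec
from voxsr.synthesis import PhantomSpec, generate_phantom
from voxsr.training import TrainConfig, train

TINY_RRDB = dict(
    rrdb_blocks=3, layers_per_block=2, growth_rate=4, initial_features=2,
    rrdb_fusion_width=8, rrdb_preout_width=4,
)
TINY_UNET = dict(unet_depth=2, unet_base_width=4)
TINY_SHUFFLE = dict(shuffle_base_width=8, shuffle_hidden_widths=(8, 16, 32, 64))


@pytest.fixture(scope="session")
def phantom48():
    """One 48^3 phantom with default structural content."""
    return generate_phantom(PhantomSpec(shape=(48, 48, 48), seed=7))


@pytest.fixture(scope="session")
def phantoms48():
    return [
        generate_phantom(PhantomSpec(shape=(48, 48, 48), seed=100 + i))
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def pair_f2(phantom48):
    return make_pair(phantom48, ScaleFactor.isotropic(2))


@pytest.fixture(scope="session")
def toy_trained_rrdb(phantoms48):
    """A tiny RRDB (3 dense blocks, hence 3 perturbation sites) trained for
    two epochs on three 48^3 phantoms — enough structure for the
    uncertainty pipeline to act on."""
    pairs = [make_pair(v, ScaleFactor.isotropic(2)) for v in phantoms48]
    spec = ArchitectureSpec("rrdb", **TINY_RRDB)
    model = init_xavier_uniform(build_model(spec), seed=3)
    cfg = TrainConfig(
        learning_rate=1e-3, epochs=2, effective_batch=4, micro_batch=1,
        patches_per_volume=4, patch_size=32, val_patches_per_volume=1,
        seed=3, loss=LossSpec(kind="l1"), scale_set=(2,),
    )
    train(model, pairs, cfg)
    return model, pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
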