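import numpy as np
import pytest

import anomod as am


@pytest.fixture(scope="session")
def pore3():
    return am.make_pore_model(3, seed=11)


@pytest.fixture(scope="session")
def reference():
    return am.make_reference(400, seed=7)


@pytest.fixture(scope="session")
def unmod_dataset(reference, pore3):
    return am.simulate_reads(
        reference, pore3, None, n_reads=30, read_length=120, seed=21
    )


@pytest.fixture(scope="session")
def cpg_spec():
    return am.ModificationSpec(
        motif="CG",
        offset=0,
        level_shift=2.0,
        per_site_occupancy=1.0,
        site_selection_rate=1.0,
    )


@pytest.fixture(scope="session")
def mod_dataset(reference, pore3, cpg_spec):
    return am.simulate_reads(
        reference, pore3, cpg_spec, n_reads=30, read_length=120, seed=22
    )


@pytest.fixture(scope="session")
def tiny_vae():
    """An untrained small model usable for shape/determinism contracts."""
    from anomod.vae import CnnTransformerVae, VaeConfig

    cfg = VaeConfig(
        token_dim=16, conv_channels=(16, 16), latent_dim=8, n_heads=2, seed=3
    )
    return CnnTransformerVae(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
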