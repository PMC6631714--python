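import numpy as np
import pytest

from gtmdock.contact_fp import CFSchema
from gtmdock.site_prep import select_key_atoms
from gtmdock.synthetic import SyntheticSpec, make_pose_ensemble, make_toy_site


@pytest.fixture(scope="session")
def toy_spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def toy_system(toy_spec):
    """(site-with-keys, ligand, native pose, CF schema) for the toy cavity."""
    site, ligand, native = make_toy_site(toy_spec)
    site = select_key_atoms(site, [ligand.coords])
    return site, ligand, native, CFSchema.from_site(site)


@pytest.fixture(scope="session")
def toy_pool(toy_spec, toy_system):
    _, ligand, native, _ = toy_system
    return make_pose_ensemble(toy_spec, ligand, native, n_poses=120, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
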