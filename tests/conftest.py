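import numpy as np
import pytest

from pepdimer import synthetic as syn
from pepdimer.trajectory import DimerSpec


@pytest.fixture(scope="session")
def dimer_spec() -> DimerSpec:
    return DimerSpec()


@pytest.fixture(scope="session")
def cyclic_template():
    """Disulfide-closed cyclic peptide with the six ladder bonds planted."""
    spec = syn.default_cyclic_template(ring_angle=54.0)
    return syn.build_template(spec)


@pytest.fixture(scope="session")
def linear_hairpin_template():
    spec = syn.ConformerTemplateSpec(
        kind="hairpin",
        sequence=syn.LINEAR_SEQUENCE,
        planted_hbonds=list(syn.LINEAR_LADDER_BONDS),
        ring_angle=40.0,
        first_res_seq=60,
        chain_id="A",
    )
    return syn.build_template(spec)


@pytest.fixture(scope="session")
def small_ensemble():
    """60-frame four-state dimer ensemble with planted labels."""
    recipe = syn.default_dimer_recipe(n_frames=60, noise_sigma=0.3, seed=0)
    traj, labels = syn.generate_ensemble(recipe)
    return traj, labels, recipe


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
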