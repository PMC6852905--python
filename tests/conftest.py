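import numpy as np
import pytest

from chemdiv.core import Dataset, Entry, Molecule, PropertyRecord
from chemdiv.synthetic import EnergyModelSpec, GeneratorSpec, generate_dataset, get_template


def template_molecule(name: str, source_id: str | None = None) -> Molecule:
    """A molecule instance at a template's idealized geometry (no jitter)."""
    t = get_template(name)
    return Molecule(t.elements, t.coords.copy(), source_id=source_id or name)


def entry_from_template(name: str, E: float = -1.0, source_id: str | None = None) -> Entry:
    return Entry(template_molecule(name, source_id), PropertyRecord(E=E))


@pytest.fixture(scope="session")
def energy_spec() -> EnergyModelSpec:
    return EnergyModelSpec()


@pytest.fixture(scope="session")
def small_dataset(energy_spec) -> Dataset:
    """60 jittered template instances with energies, no multiplets."""
    return generate_dataset(
        GeneratorSpec(n_molecules=60, seed=42, multiplet_fraction=0.0), energy_spec
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    from scipy.stats import special_ortho_group

    return special_ortho_group.rvs(3, random_state=np.random.RandomState(rng.integers(2**31 - 1)))
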