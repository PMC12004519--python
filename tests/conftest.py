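import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evbcat import EVBParams, MappingSchedule, ToyDiabaticSystem
from evbcat.embedding import CoulombBackend
from evbcat.synthetic_data import generate_snapshots, make_synthetic_enzyme

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_symmetric() -> ToyDiabaticSystem:
    """Equal-k parabolas, minima 4 Å apart: reorganization energy 16 kcal/mol."""
    return ToyDiabaticSystem(force_constant=2.0, q1=0.0, q2=4.0, dg0=0.0)


@pytest.fixture(scope="session")
def params_uncoupled() -> EVBParams:
    return EVBParams(off_diagonal=0.0, gas_shift=0.0, temperature=300.0)


@pytest.fixture(scope="session")
def schedule() -> MappingSchedule:
    return MappingSchedule.uniform(51)


@pytest.fixture(scope="session")
def backend() -> CoulombBackend:
    return CoulombBackend(state_energies={"R": 0.0, "TS": 30.0})


@pytest.fixture(scope="session")
def planted_enzyme():
    """Small planted enzyme shared across electrostatics tests."""
    return make_synthetic_enzyme(
        n_residues=12, atoms_per_residue=3, planted_effect=-5.0, seed=42
    )


@pytest.fixture(scope="session")
def jitterfree_ensemble(planted_enzyme):
    return generate_snapshots(
        planted_enzyme, "R", 2, thermal_jitter_sigma=0.0, seed=1
    ) + generate_snapshots(planted_enzyme, "TS", 2, thermal_jitter_sigma=0.0, seed=2)


@pytest.fixture(scope="session")
def jittered_ensemble(planted_enzyme):
    return generate_snapshots(
        planted_enzyme, "R", 60, thermal_jitter_sigma=0.1, seed=11
    ) + generate_snapshots(planted_enzyme, "TS", 60, thermal_jitter_sigma=0.1, seed=12)
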