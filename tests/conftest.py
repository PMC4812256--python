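import numpy as np
import pytest

from allocross.core import ProvenanceLabel
from allocross.synth import (
    NoiseModel,
    Placement,
    StateMixture,
    ToyArchitecture,
    ToyStructure,
    simulate_hinge_trajectory,
)


@pytest.fixture(scope="session")
def ca_structure() -> ToyStructure:
    """Cα-only toy chain: 20+20 lobe residues, 8 linker, 30 appended."""
    return ToyStructure.build(ToyArchitecture(20, 20, 8, 30))


@pytest.fixture(scope="session")
def bb_structure() -> ToyStructure:
    """Toy chain with N/CA/C/O backbone atoms."""
    return ToyStructure.build(ToyArchitecture(20, 20, 8, 30, backbone=True))


def static_trajectory(structure: ToyStructure, n_frames: int = 10, seed: int = 0,
                      sigma: float = 0.0, label: ProvenanceLabel | None = None):
    """Single-state trajectory: reference structure plus optional noise."""
    sim = simulate_hinge_trajectory(
        structure,
        StateMixture(states=(Placement(),), weights=(1.0,)),
        NoiseModel(domain_sigma=sigma, linker_sigma=sigma, seed=seed),
        n_frames,
        label=label,
    )
    return sim.trajectory


def two_state_simulation(structure: ToyStructure, weights=(0.7, 0.3),
                         offset_nm: float = 2.0, n_frames: int = 1000,
                         seed: int = 0, domain_sigma: float = 0.02,
                         linker_sigma: float = 0.05,
                         label: ProvenanceLabel | None = None):
    """The reference study condition: two placements ``offset_nm`` apart."""
    mixture = StateMixture(
        states=(Placement(), Placement(translation=(offset_nm, 0.0, 0.0))),
        weights=tuple(weights),
    )
    noise = NoiseModel(domain_sigma=domain_sigma, linker_sigma=linker_sigma, seed=seed)
    return simulate_hinge_trajectory(structure, mixture, noise, n_frames, label=label)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-3.0, 3.0, size=3)
    return Q, t
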