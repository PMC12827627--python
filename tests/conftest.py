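import numpy as np
import pytest

from avidkit import BeadStructure, ToyIgMParams, generate_toy_igm


def make_structure(n: int, seed: int = 0, scale: float = 5.0) -> BeadStructure:
    """Random bead cloud with unique (chain, residue, bead) keys."""
    rng = np.random.default_rng(seed)
    return BeadStructure(
        positions=rng.uniform(-scale, scale, (n, 3)),
        radii=np.full(n, 0.235),
        chain_ids=np.full(n, "A"),
        residue_indices=np.arange(1, n + 1),
        residue_names=np.full(n, "UNK"),
        bead_names=np.full(n, "BB"),
    )


@pytest.fixture(scope="session")
def small_toy():
    """A small mobile-arm toy pentamer ensemble with its domain map."""
    params = ToyIgMParams(n_frames=30, hinge_cone_half_angle=40.0, seed=11)
    return generate_toy_igm(params)


@pytest.fixture(scope="session")
def frozen_toy():
    """Toy pentamer with a zero-width hinge cone: all frames identical."""
    params = ToyIgMParams(n_frames=10, hinge_cone_half_angle=0.0, seed=7)
    return generate_toy_igm(params)
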