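import numpy as np
import pytest

from sig32.synthetic import (
    SimulationDesign,
    planted_signature,
    simulate_expression_cohort,
    simulate_pancancer,
)


@pytest.fixture(scope="session")
def default_design() -> SimulationDesign:
    return SimulationDesign()


@pytest.fixture(scope="session")
def default_cohort(default_design):
    """The 567-sample synthetic cohort with 4 planted subtypes (seed 1)."""
    return simulate_expression_cohort(default_design, seed=1)


@pytest.fixture(scope="session")
def default_pancancer(default_design):
    """Default pan-cancer mutation simulation with 3 planted pathways (seed 1)."""
    return simulate_pancancer(default_design, seed=1)


@pytest.fixture(scope="session")
def signature_genes(default_design):
    return planted_signature(default_design, seed=1)


@pytest.fixture(scope="session")
def small_design() -> SimulationDesign:
    """Scaled-down design for fast unit tests."""
    return SimulationDesign(
        n_types=4,
        n_patients_per_type=25,
        n_genes=150,
        n_pathways=6,
        pathway_sizes=(10, 12, 10, 12, 12, 12),
        n_cohort=160,
        subtype_proportions=(0.25, 0.25, 0.25, 0.25),
    )


def random_trifactor_instance(rng: np.random.Generator, n=30, m=40, k=4, n_types=3):
    """A random binary mutation problem for descent tests."""
    X = (rng.random((n, m)) < 0.15).astype(float)
    labels = rng.integers(0, n_types, size=n)
    labels = np.array([f"t{j}" for j in labels])
    V0 = np.zeros((m, k))
    for j in range(k):
        V0[rng.choice(m, size=5, replace=False), j] = 1.0
    if (V0.sum(axis=0) == 0).any():  # defensive; size=5 choice guarantees non-empty
        V0[0, :] = 1.0
    A = (rng.random((m, m)) < 0.1).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    L = np.diag(A.sum(axis=1)) - A
    return X, labels, V0, L
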