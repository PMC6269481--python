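import numpy as np
import pandas as pd
import pytest

from stemscore.io import DirectionalSignature, ExpressionMatrix
from stemscore.simulate import SimulationConfig, generate


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 features x 3 samples with distinct values in every column."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[10.0, 1.0, 2.0], [5.0, 4.0, 8.0], [1.0, 2.0, 5.0], [7.0, 9.0, 1.0]],
            index=["f1", "f2", "f3", "f4"],
            columns=["s1", "s2", "s3"],
        )
    )


@pytest.fixture
def tiny_signature() -> DirectionalSignature:
    return DirectionalSignature(name="toy", up=frozenset({"f1"}), down=frozenset({"f2"}))


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort, shared across tests (generation is pure)."""
    return generate(SimulationConfig(seed=20260922))


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap cohort for end-to-end plumbing tests."""
    return generate(
        SimulationConfig(
            n_samples=60, n_mirna=80, n_up=10, n_down=8, n_mrna=300,
            n_driver_genes=40, seed=7,
        )
    )


def random_matrix(rng: np.random.Generator, n_features: int, n_samples: int) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            rng.normal(size=(n_features, n_samples)),
            index=[f"g{i}" for i in range(n_features)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
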