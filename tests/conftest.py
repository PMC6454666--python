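import numpy as np
import pytest

from evidfuse import EvidentialEnsembleClassifier, worked_example


@pytest.fixture(scope="session")
def example():
    """The embedded 10-patient worked example bundle."""
    return worked_example()


@pytest.fixture(scope="session")
def example_ensemble(example):
    """Ensemble assembled from the example's published calibration parameters."""
    return EvidentialEnsembleClassifier.from_parameters(
        example.calibrations(), example.weight_vector(), example.decision_threshold
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_decision_table(rng, max_rows=8, max_attrs=4):
    """A small random binary decision table (values array, decision array)."""
    n = int(rng.integers(2, max_rows + 1))
    m = int(rng.integers(1, max_attrs + 1))
    values = rng.integers(0, 2, size=(n, m))
    decision = rng.integers(0, 2, size=n)
    return values, decision


def random_mass(rng):
    """A random valid mass assignment over {pos}, {neg}, Θ."""
    raw = rng.dirichlet(np.ones(3))
    return tuple(float(x) for x in raw)
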