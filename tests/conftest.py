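import pytest

from mcica.phantom import PhantomSpec, generate_phantom
from mcica.pipeline import run_phantom_experiment


@pytest.fixture(scope="session")
def phantom_pair():
    """One default phantom (image + truth), shared across tests."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def experiment():
    """One full end-to-end phantom experiment (trained model, basis, scores)."""
    return run_phantom_experiment(seed=0)
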