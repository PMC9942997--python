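import numpy as np
import pytest

from fungicast import (
    GeneratorConfig,
    generate_linear_benchmark,
    generate_replicates,
    load_substrate_summary,
    make_cv_plan,
)


@pytest.fixture(scope="session")
def summary():
    return load_substrate_summary()


@pytest.fixture(scope="session")
def synth_dataset(summary):
    """The default synthetic study dataset: 16 formulations x 12 bags, seed 42."""
    return generate_replicates(summary, GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def full_plan(synth_dataset):
    """The study's 5-fold x 10-replicate plan for the 192-record dataset."""
    return make_cv_plan(len(synth_dataset), seed=43)


@pytest.fixture(scope="session")
def smooth_benchmark():
    """Noise-free response that is a smooth nonlinear function of the composition."""
    bench = generate_linear_benchmark((0, 0, 0, 0), n_records=150, seed=21)
    X = bench.X
    y = 50.0 + 0.8 * X[:, 0] - 0.5 * X[:, 1] + 20.0 * np.sin(np.pi * X[:, 2] / 100.0)
    frame = bench.frame.copy()
    frame["response"] = y
    bench.frame = frame
    return bench
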