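import numpy as np
import pytest

from tiwd import (
    LifetimeSample,
    TransformedInverseWeibull,
    load_builtin_dataset,
    ml_fit,
)


@pytest.fixture(scope="session")
def metal_fatigue() -> LifetimeSample:
    return load_builtin_dataset("metal_fatigue")


@pytest.fixture(scope="session")
def head_neck_cancer() -> LifetimeSample:
    return load_builtin_dataset("head_neck_cancer")


@pytest.fixture(scope="session")
def metal_fatigue_fit(metal_fatigue):
    return ml_fit(metal_fatigue)


@pytest.fixture(scope="session")
def head_neck_cancer_fit(head_neck_cancer):
    return ml_fit(head_neck_cancer)


@pytest.fixture(scope="session")
def unit_sample_50() -> LifetimeSample:
    """n=50 synthetic sample from TIWD(1, 1), shared across optimizer tests."""
    return TransformedInverseWeibull(1.0, 1.0).rvs(50, seed=42)


@pytest.fixture(scope="session")
def unit_sample_100() -> LifetimeSample:
    return TransformedInverseWeibull(1.0, 1.0).rvs(100, seed=3)
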