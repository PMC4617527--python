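import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plaquecall.pileup_counts import ProportionMatrix
from plaquecall.reference import ReferenceGene
from plaquecall.synthetic import random_gene

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_gene() -> ReferenceGene:
    return random_gene(600, seed=2)


@pytest.fixture(scope="session")
def big_gene() -> ReferenceGene:
    """A lacZ-sized toy gene for full-scale simulations."""
    return random_gene(3096, seed=11)


def make_props(library_id: str, length: int, props: dict, depth: int = 10_000) -> ProportionMatrix:
    """Hand-build a proportion matrix for noise/calling unit tests."""
    return ProportionMatrix(
        library_id=library_id,
        length=length,
        depth=np.full(length, depth, dtype=np.int64),
        props=dict(props),
    )
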