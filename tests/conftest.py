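from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160328)


@pytest.fixture(scope="session")
def v4_region():
    from ccs16s.design import default_regions

    return default_regions()["V4"]


@pytest.fixture(scope="session")
def small_refs():
    """Six mock templates at V4-like length, ~10% mutual divergence."""
    from ccs16s.simulate import make_mock_references

    return make_mock_references(6, length=253, divergence=0.10, seed=11)


@pytest.fixture(scope="session")
def barcode_pairs():
    from ccs16s.simulate import make_barcodes

    return make_barcodes(["S1", "S2"], seed=7)
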