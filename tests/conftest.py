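import pytest
from hypothesis import HealthCheck, settings

from sulciscore import (
    BinaryMask,
    default_reference_specs,
    generate_references,
    load_nomenclature,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return load_nomenclature()


@pytest.fixture(scope="session")
def default_refs():
    return generate_references(default_reference_specs())


@pytest.fixture
def make_mask():
    """Factory for masks on a small shared frame."""

    def _make(pixels, shape=(50, 50), view="superior", hemisphere="left",
              label="S.C", rater="R1"):
        return BinaryMask(view, hemisphere, label, rater, shape,
                          frozenset(tuple(p) for p in pixels))

    return _make
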