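import pytest

from idpcr import PhysicalParams, SequenceSpec
from idpcr.sequences import ek_variant


@pytest.fixture(scope="session")
def polyacid30() -> SequenceSpec:
    """The weak polyacid test chain: 30 E residues with pKA = 4.0, ω = 0."""
    return SequenceSpec.from_string("E" * 30, pka={"E": 4.0})


@pytest.fixture(scope="session")
def polyacid_params():
    """Solution conditions for the polyacid study: λB = 7.1 Å, l = 5.8 Å."""

    def make(pH: float, salt: float = 1e-2, **kw) -> PhysicalParams:
        return PhysicalParams(pH=pH, bjerrum=7.1, kuhn=5.8, salt=salt, **kw)

    return make


@pytest.fixture(scope="session")
def ek_spec():
    """(EK)25 variant as a SequenceSpec under the polyampholyte study
    conditions (uniform ω = 1 stabilizing excluded volume)."""

    def make(n: int) -> SequenceSpec:
        return SequenceSpec.from_string(ek_variant(n), omega=1.0)

    return make


@pytest.fixture(scope="session")
def ek_params():
    """Solution conditions for the (EK)25 study: 0.015 M salt."""

    def make(pH: float) -> PhysicalParams:
        return PhysicalParams(pH=pH, bjerrum=7.1, kuhn=5.8, salt=0.015)

    return make


@pytest.fixture(autouse=True)
def _silence_multiroot_warnings():
    """Multiple-root warnings are expected while iterating collapsed states."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
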