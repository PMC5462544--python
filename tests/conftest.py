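import numpy as np
import pytest

from golgimorph.energetics import ElasticParams, NanodomainField
from golgimorph.geometry import GeometryParams, ShapeFamily, default_rgap_grid


@pytest.fixture(scope="session")
def geom() -> GeometryParams:
    return GeometryParams()


@pytest.fixture(scope="session")
def family(geom) -> ShapeFamily:
    """Shared 200-point shape family for the reference geometry."""
    return ShapeFamily(geom, default_rgap_grid(geom, 200))


@pytest.fixture(scope="session")
def nano02() -> NanodomainField:
    return NanodomainField(Rd=5.0, Phi=0.2)


@pytest.fixture()
def elastic():
    def make(js_rim: float = 0.02, js_mid: float = 0.0, **kw) -> ElasticParams:
        return ElasticParams(Js_rim=js_rim, Js_mid=js_mid, **kw)

    return make


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
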