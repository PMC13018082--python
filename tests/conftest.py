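import pytest
from importlib import resources

from coseg import (CARRIER, GENERAL, CancerType, CbcModel, PenetranceParams,
                   PenetranceSet, load_penetrance_set, read_canrisk)


@pytest.fixture(scope="session")
def demo_text() -> str:
    """Bundled synthetic demonstration family (BRCA1, nine members)."""
    return resources.files("coseg.data").joinpath(
        "demo_family_synthetic.canrisk").read_text()


@pytest.fixture()
def demo_pedigree(demo_text):
    return read_canrisk(demo_text)


@pytest.fixture(scope="session")
def uk_brca1() -> PenetranceSet:
    return load_penetrance_set("UK", "BRCA1")


def make_toy_pset(bc_carrier=(0.6, 55.0, 15.0), bc_general=(0.1, 62.0, 15.0),
                  oc_carrier=(0.4, 58.0, 12.0), oc_general=(0.02, 63.0, 13.0),
                  cbc_carrier=0.02, cbc_general=0.005) -> PenetranceSet:
    """Small hand-specified two-cancer parameter set for exact checks."""
    def curve(tpl, sex="F", **meta):
        return PenetranceParams(*tpl, meta={"sex": sex, **meta})
    return PenetranceSet(
        gene="BRCA1", population="toy",
        curves={
            (CancerType.BC, CARRIER): curve(bc_carrier),
            (CancerType.BC, GENERAL): curve(bc_general),
            (CancerType.OC, CARRIER): curve(oc_carrier),
            (CancerType.OC, GENERAL): curve(oc_general),
        },
        cbc={CARRIER: CbcModel(cbc_carrier), GENERAL: CbcModel(cbc_general)},
    )


@pytest.fixture()
def toy_pset() -> PenetranceSet:
    return make_toy_pset()


@pytest.fixture()
def flat_pset() -> PenetranceSet:
    """Carrier curves identical to population curves: the variant carries no
    phenotype information, so every LR must be 1."""
    p = (0.1, 62.0, 15.0)
    o = (0.02, 63.0, 13.0)
    return make_toy_pset(bc_carrier=p, bc_general=p, oc_carrier=o,
                         oc_general=o, cbc_carrier=0.005, cbc_general=0.005)
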