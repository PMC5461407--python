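import pytest

from corycycle.cycle_core import CellCycleParams, GrowthCondition

# the three study growth conditions: (mu 1/h, td min, measured ratio,
# measured mean origins, inferred C, inferred D)
CONDITIONS = {
    "BHI": dict(mu=0.66, td=63.0, ratio=2.36, mean_oris=5.90, c=78, d=20),
    "BHI+Gluc": dict(mu=0.50, td=83.0, ratio=2.23, mean_oris=5.17, c=96, d=18),
    "MMI": dict(mu=0.32, td=130.0, ratio=1.68, mean_oris=3.85, c=97, d=26),
}


@pytest.fixture
def bhi_params() -> CellCycleParams:
    return CellCycleParams(td=63.0, c=78.0, d=20.0, ploidy=2)


@pytest.fixture
def gluc_params() -> CellCycleParams:
    return CellCycleParams(td=83.0, c=96.0, d=18.0, ploidy=2)


@pytest.fixture
def mmi_params() -> CellCycleParams:
    return CellCycleParams(td=130.0, c=97.0, d=26.0, ploidy=2)


@pytest.fixture
def conditions() -> list[GrowthCondition]:
    return [GrowthCondition(label=k, mu=v["mu"], td=v["td"]) for k, v in CONDITIONS.items()]
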