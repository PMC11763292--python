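import numpy as np
import pytest

from trophicweb import DietMatrix, GroupParams, TrophicLevelTable


@pytest.fixture
def sardine_prey_tls() -> TrophicLevelTable:
    """Prey trophic levels as printed in the model table."""
    return TrophicLevelTable(entries={"zooplankton": 2.05, "phytoplankton": 1.0})


@pytest.fixture
def sardine_diet() -> dict:
    return {"zooplankton": 0.703, "phytoplankton": 0.297}


@pytest.fixture
def chain_web() -> DietMatrix:
    """Producer → herbivore → predator chain (100% diets)."""
    dc = np.zeros((3, 3))
    dc[0, 1] = 1.0  # herbivore eats producer
    dc[1, 2] = 1.0  # predator eats herbivore
    return DietMatrix(
        codes=["P", "H", "C"],
        dc=dc,
        roles={"P": "producer", "H": "consumer", "C": "consumer"},
    )


@pytest.fixture
def two_group_toy() -> tuple[list[GroupParams], DietMatrix]:
    """Producer (B=10, PB=10) fully grazed by a consumer (B=1, QB=5)."""
    dc = np.zeros((2, 2))
    dc[0, 1] = 1.0
    diet = DietMatrix(
        codes=["P", "C"], dc=dc, roles={"P": "producer", "C": "consumer"}
    )
    groups = [
        GroupParams(code="P", role="producer", b=10.0, pb=10.0, ee=None),
        GroupParams(code="C", role="consumer", b=1.0, pb=1.0, qb=5.0, ee=0.0),
    ]
    return groups, diet
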