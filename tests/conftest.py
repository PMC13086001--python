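import numpy as np
import pytest

import plastomics as p


@pytest.fixture(scope="session")
def marker_fixture():
    """The fixed four-taxon marker-gene alignment (426 columns, 10 SNPs,
    one 3-bp indel)."""
    return p.table6_fixture()


@pytest.fixture(scope="session")
def toy_plastome():
    """A 20 kb quadripartite plastome with planted SSRs and a junction gene."""
    spec = p.PlastomeSpec(
        lsc_len=12000, ir_len=3000, ssc_len=2000, seed=42,
        ssrs=[
            p.PlantedSSR("A", 12, "LSC", 500),
            p.PlantedSSR("T", 10, "LSC", 4000),
            p.PlantedSSR("AT", 7, "SSC", 300),
            p.PlantedSSR("TTA", 5, "IRb", 700),
        ],
        genes=[p.PlantedGene("rpl22_like", "LSC/IRb", 357, 66),
               p.PlantedGene("ndhF_like", "IRb/SSC", 120, 80)],
    )
    return p.synth_plastome(spec)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.35) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))
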