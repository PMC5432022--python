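import numpy as np
import pytest

from vipcircuit.ratenet import (
    CellClass,
    ConnectionSpec,
    RateNetworkSpec,
    build_ring,
)


@pytest.fixture(scope="session")
def default_network():
    from vipcircuit.ratenet import default_spec

    return build_ring(default_spec())


def decoupled_spec(n_populations=7, intrinsic=None):
    """A ring with every weight zero (units relax independently)."""
    intrinsic = intrinsic or {c: 1.0 for c in CellClass}
    conns = (ConnectionSpec(CellClass.PYR, CellClass.PYR, "intra", 0.0, 2.0),)
    return RateNetworkSpec(
        n_populations=n_populations, intrinsic_input=intrinsic, connections=conns
    )


def random_two_unit_spec(rng):
    """A randomly weighted 3-population net with a Pyr-SST pair per site."""
    conns = (
        ConnectionSpec(CellClass.PYR, CellClass.PYR, "intra", rng.uniform(0, 20), rng.uniform(2, 10)),
        ConnectionSpec(CellClass.PYR, CellClass.SST, "intra", rng.uniform(0, 30), rng.uniform(2, 10)),
        ConnectionSpec(CellClass.SST, CellClass.PYR, "intra", -rng.uniform(0, 30), rng.uniform(3, 15)),
        ConnectionSpec(
            CellClass.PYR, CellClass.PYR, "inter", rng.uniform(0, 10), rng.uniform(2, 8),
            (1.0,) + (0.0,) * 2,
        ),
    )
    intrinsic = {
        CellClass.PYR: rng.uniform(0.5, 3.0),
        CellClass.PV: 0.0,
        CellClass.SST: rng.uniform(-1.0, 1.0),
        CellClass.VIP: 0.0,
    }
    return RateNetworkSpec(
        n_populations=3, intrinsic_input=intrinsic, connections=conns
    )
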