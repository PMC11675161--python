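import numpy as np
import pytest

from brainnetsim.connectome import Parcellation, StructuralConnectome


@pytest.fixture(scope="session")
def tiny_parcellation():
    return Parcellation(
        region_ids=("L1", "R1", "L2", "R2"),
        region_names=("l1", "r1", "l2", "r2"),
        hemisphere=("L", "R", "L", "R"),
        is_subcortical=(False, False, True, True),
        atlas_name="tiny4",
    )


@pytest.fixture()
def triangle_sc():
    """3-node connectome with counts {w12=2, w13=4, w23=6}."""
    parc = Parcellation(("a", "b", "c"), ("a", "b", "c"), ("L", "R", "L"), (False,) * 3)
    counts = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
    lengths = np.array([[0.0, 10.0, 20.0], [10.0, 0.0, 30.0], [20.0, 30.0, 0.0]])
    return StructuralConnectome(counts, lengths, parc, "triangle")


@pytest.fixture(scope="session")
def two_region_sc():
    parc = Parcellation(("a", "b"), ("a", "b"), ("L", "R"), (False, False))
    counts = np.array([[0.0, 10.0], [10.0, 0.0]])
    lengths = np.array([[0.0, 100.0], [100.0, 0.0]])
    return StructuralConnectome(counts, lengths, parc, "pair")
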