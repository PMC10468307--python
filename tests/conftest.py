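import pandas as pd
import pytest

from paleogene.datasets import synthetic_primate_timetree
from paleogene.timetree import graft_leaf, read_timetree

#: ((A,B),(C,D)) with cherries at 1 MY and the root at 3 MY
BALANCED4 = "((A:1,B:1):2,(C:1,D:1):2);"


@pytest.fixture(scope="session")
def primate_tree():
    """The synthetic 31-species primate timetree (root 74 MYA)."""
    return synthetic_primate_timetree()


@pytest.fixture(scope="session")
def primate_tree_32(primate_tree):
    """With Cebus imitator grafted at its published 1.7 MYA split."""
    return graft_leaf(primate_tree, "Cebus_imitator", "Cebus_capucinus", 1.7)


@pytest.fixture
def balanced4():
    return read_timetree(BALANCED4)


def presence_frame(tree, detections: dict[str, set[str]]) -> pd.DataFrame:
    """Boolean gene × species frame from per-gene detected-taxa sets."""
    species = tree.leaf_names()
    return pd.DataFrame(
        {sp: [sp in detections[g] for g in detections] for sp in species},
        index=list(detections),
        dtype=bool,
    )
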