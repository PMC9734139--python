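import numpy as np
import pytest

from cladescan.phylo import Phylogeny
from cladescan.simulate import DEFAULT_FOCAL_CLADE, default_tree


@pytest.fixture
def four_taxon_tree():
    return Phylogeny.from_newick(
        "((h1:0.1,h2:0.1):0.2,(s1:0.1,s2:0.1):0.2);", focal=["h1", "h2"]
    )


@pytest.fixture
def study_tree():
    """The bundled 13-taxon tree with the four-tip focal clade."""
    return default_tree()


@pytest.fixture
def focal_labels():
    return list(DEFAULT_FOCAL_CLADE)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
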