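import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode


def _read(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick", convert_underscores=False)


@pytest.fixture
def star_tree():
    """Three tips hanging directly off the root, branch length 1 each."""
    return _read("(A:1,B:1,C:1):0;")


@pytest.fixture
def cherry_tree():
    """Balanced 4-tip tree; every root-to-tip path has length 2."""
    return _read("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_counts(rng, n_samples, taxa, low=0, high=20):
    arr = rng.integers(low, high, size=(n_samples, len(taxa)))
    arr[:, 0] += 1  # keep every sample nonempty
    return pd.DataFrame(
        arr, index=[f"s{i}" for i in range(n_samples)], columns=list(taxa)
    )
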