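import math

import pytest

from ouprior import OUParams, read_newick, scale_traits, simulate_traits, simulate_yule


@pytest.fixture(scope="session")
def three_tip_tree():
    return read_newick("((A:0.6,B:0.6):0.4,C:1);")


@pytest.fixture(scope="session")
def ten_tip_tree():
    return simulate_yule(10, math.log(10), seed=11, min_tips_per_root_side=3)


@pytest.fixture(scope="session")
def forty_tip_tree():
    return simulate_yule(40, math.log(40), seed=11, min_tips_per_root_side=10)


@pytest.fixture(scope="session")
def wn_traits_scaled(forty_tip_tree):
    """White-noise-like OU data (alpha=5) on the 40-tip tree, scaled."""
    raw = simulate_traits(forty_tip_tree, OUParams(5.0, 1.0, 1.0, 0.0), seed=21)
    return scale_traits(raw)
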