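import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from paleorange.chronogram import Chronogram
from paleorange.ranges import AreaSet, RangeData, build_state_space


@pytest.fixture
def toy_tree3():
    """3-tip ultrametric tree, height 2."""
    return Chronogram.from_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_tree4():
    """4-tip ultrametric tree, height 3."""
    return Chronogram.from_newick_string("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture
def space2():
    return build_state_space(AreaSet(tuple("AB")), 2)


@pytest.fixture
def space3():
    return build_state_space(AreaSet(tuple("ABC")), 3)


def make_range_data(space, **codings):
    return RangeData(space, {k: space.areas.mask(v) for k, v in codings.items()})
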