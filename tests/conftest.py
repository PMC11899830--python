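import pytest

from conntopo import (MolecularGraph, build_acene, load_bh22,
                      load_coumarin_properties, parse_edge_list)

# Worked-example graph H: a 6-path v1..v6 with a pendant 2-path v7-v8 at v4.
H_EDGES = "v1 v2\nv2 v3\nv3 v4\nv4 v5\nv5 v6\nv4 v7\nv7 v8\n"


@pytest.fixture(scope="session")
def graph_h() -> MolecularGraph:
    return parse_edge_list(H_EDGES, name="H")


@pytest.fixture(scope="session")
def benzene() -> MolecularGraph:
    return build_acene(1)


@pytest.fixture(scope="session")
def bh22_correct():
    return load_bh22(anthanthrene="correct")


@pytest.fixture(scope="session")
def bh22_published():
    return load_bh22(anthanthrene="as-published")


@pytest.fixture(scope="session")
def coumarin25():
    return load_coumarin_properties()
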