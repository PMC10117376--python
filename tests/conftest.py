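import networkx as nx
import pandas as pd
import pytest

from ppikit import fixtures
from ppikit.synth import SynthConfig


@pytest.fixture(scope="session")
def default_cfg() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def call_grid_frame() -> pd.DataFrame:
    rows = [
        {"variant": v, "interactor": i, "call": c}
        for (v, i), c in fixtures.INTERACTION_CALL_GRID.items()
    ]
    return pd.DataFrame(rows)


def labeled(graph: nx.Graph, prefix: str = "N") -> nx.Graph:
    return nx.relabel_nodes(graph, {n: f"{prefix}{n:02d}" for n in graph.nodes})


@pytest.fixture(scope="session")
def small_graph_suite() -> list[nx.Graph]:
    """Graphs of <= 10 nodes for exhaustive-oracle checks."""
    suite = [
        labeled(nx.complete_graph(5)),
        labeled(nx.complete_graph(4)),
        labeled(nx.path_graph(8)),
        labeled(nx.star_graph(6)),
        labeled(nx.cycle_graph(7)),
        labeled(nx.barbell_graph(4, 1)),
        labeled(nx.lollipop_graph(5, 3)),
    ]
    for seed in range(6):
        suite.append(labeled(nx.gnp_random_graph(9, 0.35, seed=seed)))
    return suite
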