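import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def two_cliques() -> nx.Graph:
    """Two 5-cliques joined by a single bridge edge A0-B0 (unweighted)."""
    g = nx.Graph()
    for base in ("A", "B"):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(f"{base}{i}", f"{base}{j}")
    g.add_edge("A0", "B0")
    return g


@pytest.fixture
def bridged_triangles() -> nx.Graph:
    """Two triangles joined by one edge c-x."""
    return nx.Graph(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z"), ("c", "x")]
    )


@pytest.fixture
def triangle_with_tail() -> nx.Graph:
    """A triangle {a,b,c} with one outgoing edge c-d."""
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])


@pytest.fixture
def write_tsv(tmp_path):
    """Write tab-joined rows to a temp file and return its path."""

    def _write(rows, name="data.tsv"):
        path = tmp_path / name
        path.write_text("".join("\t".join(map(str, row)) + "\n" for row in rows))
        return path

    return _write
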