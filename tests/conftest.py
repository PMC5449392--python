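import textwrap

import networkx as nx
import pytest

from netprio import enrichment as en


@pytest.fixture
def path_graph():
    g = nx.path_graph(3)
    return nx.relabel_nodes(g, {0: "a", 1: "b", 2: "c"})


@pytest.fixture
def star_graph():
    g = nx.star_graph(3)
    return nx.relabel_nodes(g, {0: "hub", 1: "x", 2: "y", 3: "z"})


@pytest.fixture
def toy_dag():
    """root -> {a, b}; a -> c (all BP)."""
    terms = {
        "T:root": en.TermInfo("root", "BP", ()),
        "T:a": en.TermInfo("a", "BP", ("T:root",)),
        "T:b": en.TermInfo("b", "BP", ("T:root",)),
        "T:c": en.TermInfo("c", "BP", ("T:a",)),
    }
    return en.OntologyDag(terms)


@pytest.fixture
def tiny_obo(tmp_path):
    content = textwrap.dedent(
        """\
        format-version: 1.2

        [Term]
        id: T:0000001
        name: root
        namespace: biological_process

        [Term]
        id: T:0000002
        name: child one
        namespace: biological_process
        is_a: T:0000001 ! root

        [Term]
        id: T:0000003
        name: grandchild
        namespace: biological_process
        is_a: T:0000002 ! child one

        [Term]
        id: T:0000004
        name: mf root
        namespace: molecular_function
        """
    )
    path = tmp_path / "tiny.obo"
    path.write_text(content)
    return path
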