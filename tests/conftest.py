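"""Shared fixtures: toy networks, a small GO ontology/annotation corpus,
and expression/domain data, all generated programmatically."""

from __future__ import annotations

import textwrap

import pandas as pd
import pytest

from binppi.net_io import DomainData, InteractionNetwork, load_go


def build_network(edges, **edge_kwargs) -> InteractionNetwork:
    net = InteractionNetwork()
    for a, b in edges:
        net.add_edge(a, b, **edge_kwargs)
    return net


@pytest.fixture
def asymmetric_net() -> InteractionNetwork:
    """x and y share neighbors {b, z}; x also has a, y also has c."""
    return build_network([("x", "a"), ("x", "b"), ("x", "z"),
                          ("y", "b"), ("y", "z"), ("y", "c")])


@pytest.fixture
def square_net() -> InteractionNetwork:
    return build_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])


@pytest.fixture
def expression_matrix() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "c1": [1.0, 3.0, 5.0, 2.0],
            "c2": [2.0, 2.0, 5.0, 4.0],
            "c3": [3.0, 1.0, 5.0, 6.0],
        },
        index=["up", "down", "flat", "up2"],
    )


@pytest.fixture
def domain_data() -> DomainData:
    return DomainData(
        annotations={
            "x": frozenset({"d1", "d2"}),
            "y": frozenset({"d1", "d3"}),
            "w": frozenset({"d3"}),
            "h": frozenset({"d1"}),
        },
        ddi={("d1", "d1"), ("d2", "d3"), ("d1", "d2")},
    )


TOY_OBO = textwrap.dedent("""\
    format-version: 1.2
    ontology: toy

    [Term]
    id: GO:0000001
    name: process root
    namespace: biological_process

    [Term]
    id: GO:0000002
    name: process A
    namespace: biological_process
    is_a: GO:0000001 ! process root

    [Term]
    id: GO:0000003
    name: process B
    namespace: biological_process
    is_a: GO:0000001 ! process root

    [Term]
    id: GO:0000004
    name: process C
    namespace: biological_process
    is_a: GO:0000002 ! process A
    is_a: GO:0000003 ! process B

    [Term]
    id: GO:0000005
    name: process D
    namespace: biological_process
    is_a: GO:0000002 ! process A

    [Term]
    id: GO:0000010
    name: component root
    namespace: cellular_component

    [Term]
    id: GO:0000011
    name: nucleus-like
    namespace: cellular_component
    is_a: GO:0000010 ! component root

    [Term]
    id: GO:0000012
    name: membrane-like
    namespace: cellular_component
    is_a: GO:0000010 ! component root
    """)

# protein, term, evidence, aspect
TOY_ANNOTATIONS = [
    ("p1", "GO:0000004", "IDA", "P"),
    ("p2", "GO:0000004", "IDA", "P"),
    ("p2", "GO:0000005", "IMP", "P"),
    ("p3", "GO:0000005", "IEA", "P"),
    ("p4", "GO:0000003", "IDA", "P"),
    ("n1", "GO:0000011", "IDA", "C"),
    ("n2", "GO:0000011", "IEA", "C"),
    ("m1", "GO:0000012", "IDA", "C"),
]


def gaf_line(protein: str, term: str, evidence: str, aspect: str) -> str:
    return "\t".join(
        ["TOY", protein, protein, "", term, "TOY:0001", evidence, "", aspect,
         "", "", "protein", "taxon:4932", "20100101", "TOY", "", ""]
    )


@pytest.fixture(scope="session")
def toy_go_paths(tmp_path_factory):
    root = tmp_path_factory.mktemp("go")
    obo = root / "toy.obo"
    obo.write_text(TOY_OBO)
    gaf = root / "toy.gaf"
    gaf.write_text(
        "!gaf-version: 2.1\n"
        + "\n".join(gaf_line(*row) for row in TOY_ANNOTATIONS)
        + "\n"
    )
    return obo, gaf


@pytest.fixture(scope="session")
def toy_go(toy_go_paths):
    return load_go(*toy_go_paths)
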