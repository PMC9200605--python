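"""Shared fixtures: a hand-checkable 7-term ontology and its tiny corpus.

Toy topology (edges point child -> parent):

    r
    |- a        |- b
    |- c (a)    |- e (b)
    |- d (a)
    |- f (c, d)     # two parents: is_a c, part_of d
"""

import pytest

from subgofa import OntologyDAG, compute_ic


TOY_PARENTS = {
    "r": set(),
    "a": {"r"},
    "b": {"r"},
    "c": {"a"},
    "d": {"a"},
    "e": {"b"},
    "f": {"c", "d"},
}

#: five genes; f's annotation propagates to c, d, a, r
TOY_CORPUS = {
    "g1": {"c"},
    "g2": {"d"},
    "g3": {"e"},
    "g4": {"f"},
    "g5": {"a"},
}

TOY_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: alpha
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: beta
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: gamma
namespace: biological_process
alt_id: GO:0000104
is_a: GO:0000002 ! alpha

[Term]
id: GO:0000005
name: delta
namespace: biological_process
is_a: GO:0000002 ! alpha

[Term]
id: GO:0000006
name: epsilon
namespace: biological_process
is_a: GO:0000003 ! beta

[Term]
id: GO:0000007
name: zeta
namespace: biological_process
is_a: GO:0000004 ! gamma
relationship: part_of GO:0000005 ! delta

[Term]
id: GO:0000008
name: gone
namespace: biological_process
is_obsolete: true
"""


def make_toy_dag() -> OntologyDAG:
    return OntologyDAG(
        terms=set(TOY_PARENTS),
        names={t: t for t in TOY_PARENTS},
        namespace={t: "biological_process" for t in TOY_PARENTS},
        parents={t: set(p) for t, p in TOY_PARENTS.items()},
    )


@pytest.fixture
def toy_dag():
    return make_toy_dag()


@pytest.fixture
def toy_ic(toy_dag):
    return compute_ic(toy_dag, TOY_CORPUS)


@pytest.fixture
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


def brute_ancestors(term, parents):
    """Naive ancestor closure, written independently of the package."""
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents.get(t, ()):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out
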