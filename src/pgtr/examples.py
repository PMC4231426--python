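"""Small worked examples used in documentation and tests."""

from __future__ import annotations

from pgtr.perturbation import PerturbationGraph

#: node order of the five-node demo graph
DEMO_NODES = ["A", "B", "C", "D", "E"]


def demo_graph() -> PerturbationGraph:
    """Cyclic five-node signed PG illustrating order-dependent reduction.

    Edges (signs): A->B, A->C, A->D, B->C, D->B, E->C activating; D-|E and
    C-|B inhibiting.  The three heaviest (least confident) edges A->C (0.9),
    A->B (0.8) and D->B (0.7) each admit a sign-consistent explaining path
    through lighter edges: A->B->C (and A->D->B->C) for A->C, A->D->B for
    A->B, and D-|E->C-|B for D->B.  At confidence factor 0.95 all three are
    potentially removable, but removing all of them would disconnect every
    positive A=>C route, so a reduction that re-checks explainability keeps
    D->B.
    """
    idx = {g: k for k, g in enumerate(DEMO_NODES)}
    spec = {
        ("A", "B", 1): 0.8,
        ("A", "C", 1): 0.9,
        ("A", "D", 1): 0.3,
        ("B", "C", 1): 0.4,
        ("C", "B", -1): 0.5,
        ("D", "B", 1): 0.7,
        ("D", "E", -1): 0.5,
        ("E", "C", 1): 0.4,
    }
    edges = {(idx[s], idx[t]): sign for (s, t, sign) in spec}
    weights = {(idx[s], idx[t]): w for (s, t, sign), w in spec.items()}
    return PerturbationGraph.from_edges(
        DEMO_NODES, edges, weights, method_tag="demo"
    )
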