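"""Signed multi-omic co-association network and sign-coherent loop detection.

Nodes are typed variables (genotype, microbiome, metabolite, BMI); undirected
edges are the significant pairwise associations from the screening stages,
signed by the fitted slope. A *loop* is a simple cycle of three or four nodes
spanning different omic types; it is *meaningful* (directionally coherent)
iff the product of its edge signs is +1 — e.g. a triangle with two negative
links and one positive link is coherent, while a single discordant link
breaks coherence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._utils import substream
from .associations import AssociationEdge

__all__ = ["OmicsNetwork", "Loop", "build_network", "find_loops", "loop_null_count"]


@dataclass
class OmicsNetwork:
    """Typed signed undirected graph with at most one edge per node pair."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[tuple[str, str]]:
        return sorted((n, self.graph.nodes[n]["omic_type"]) for n in self.graph.nodes)

    @property
    def edges(self) -> list[AssociationEdge]:
        return sorted(
            (d["edge"] for _, _, d in self.graph.edges(data=True)),
            key=lambda e: (e.p, e.node_a, e.node_b),
        )

    def sign(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["sign"]

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for n, t in self.nodes:
            g.add_node(n, omic_type=t)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, sign=int(e.sign), beta=float(e.beta),
                       p=float(e.p), stage=str(e.stage), weight=abs(float(e.beta)))
        nx.write_graphml(g, path)


@dataclass
class Loop:
    """A 3- or 4-node cycle with its edge signs and coherence flag."""

    nodes: tuple
    omic_types: tuple
    edges: tuple  # AssociationEdge per consecutive pair (closing edge last)
    sign_product: int
    meaningful: bool

    @property
    def signs(self) -> tuple:
        return tuple(e.sign for e in self.edges)

    def to_record(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "omic_types": list(self.omic_types),
            "signs": [int(s) for s in self.signs],
            "sign_product": int(self.sign_product),
            "meaningful": bool(self.meaningful),
        }


def build_network(edges, merge_snp_groups: bool = False, snp_groups=None) -> OmicsNetwork:
    """Assemble the co-association network from stage edge lists.

    Only cross-omic edges are admissible. Parallel edges for the same node
    pair (e.g. from different stages or ages) are merged keeping the
    smallest-p edge's slope and sign, with the full provenance list retained.
    Optionally, correlated-SNP group members that share all partners can be
    merged into a single node (off by default).
    """
    g = nx.Graph()
    for e in edges:
        if e.type_a == e.type_b:
            raise ValueError(
                f"edge {e.node_a}-{e.node_b} joins two {e.type_a} nodes; "
                "only cross-omic edges are admissible"
            )
        if e.node_a == e.node_b:
            raise ValueError(f"self-edge on {e.node_a}")
        for node, typ in ((e.node_a, e.type_a), (e.node_b, e.type_b)):
            if node in g and g.nodes[node]["omic_type"] != typ:
                raise ValueError(f"node {node} declared with two omic types")
            g.add_node(node, omic_type=typ)
        if g.has_edge(e.node_a, e.node_b):
            d = g.edges[e.node_a, e.node_b]
            d["provenance"].append(e)
            if e.p < d["edge"].p:
                d.update(edge=e, sign=e.sign)
        else:
            g.add_edge(e.node_a, e.node_b, edge=e, sign=e.sign, provenance=[e])

    if merge_snp_groups and snp_groups is not None:
        for group in snp_groups.groups:
            members = [s for s in group if s in g]
            if len(members) < 2:
                continue
            neighborhoods = {m: set(g.neighbors(m)) - set(members) for m in members}
            if len({frozenset(v) for v in neighborhoods.values()}) == 1:
                keep, *rest = sorted(members)
                for m in rest:
                    g = nx.contracted_nodes(g, keep, m, self_loops=False)
    return OmicsNetwork(graph=g)


def _canonical_cycle(nodes: tuple) -> tuple:
    """Rotate/reflect a cycle to its lexicographically smallest node order."""
    k = len(nodes)
    best = None
    for seq in (nodes, nodes[::-1]):
        for r in range(k):
            cand = tuple(seq[(r + i) % k] for i in range(k))
            if best is None or cand < best:
                best = cand
    return best


def _types_admissible(types: tuple, distinct_types_required: bool) -> bool:
    if not distinct_types_required:
        return True
    if len(types) == 3:
        return len(set(types)) == 3
    # 4-node loops: at most one repeated omic type
    return len(set(types)) >= 3


def find_loops(network: OmicsNetwork, sizes=(3, 4), distinct_types_required: bool = True):
    """Enumerate 3-/4-node cycles once each, flagging sign coherence.

    Each simple cycle of a requested size is reported under a canonical
    rotation/reflection (lexicographically smallest node ordering). With
    ``distinct_types_required`` (default) every node of a 3-node loop must
    have a different omic type, and a 4-node loop may repeat at most one
    type. A loop is meaningful iff the product of its edge signs is +1.
    """
    g = network.graph
    sizes = set(int(s) for s in sizes)
    if not sizes <= {3, 4}:
        raise ValueError("loop sizes must be within {3, 4}")
    found = {}
    for cyc in nx.simple_cycles(g, length_bound=max(sizes)):
        if len(cyc) in sizes:
            found[_canonical_cycle(tuple(cyc))] = None
    loops = []
    for cyc in found:
        types = tuple(g.nodes[n]["omic_type"] for n in cyc)
        if not _types_admissible(types, distinct_types_required):
            continue
        cycle_edges = tuple(
            g.edges[cyc[i], cyc[(i + 1) % len(cyc)]]["edge"] for i in range(len(cyc))
        )
        signs = [g.edges[cyc[i], cyc[(i + 1) % len(cyc)]]["sign"] for i in range(len(cyc))]
        prod = int(np.prod(signs))
        loops.append(
            Loop(nodes=cyc, omic_types=types, edges=cycle_edges,
                 sign_product=prod, meaningful=(prod == 1))
        )
    loops.sort(key=lambda lp: (len(lp.nodes), lp.nodes))
    return loops


@dataclass
class LoopNullResult:
    """Permutation distribution of the meaningful-loop count."""

    counts: np.ndarray
    observed: int
    exceedance_p: float
    n_permutations: int


def loop_null_count(
    network: OmicsNetwork,
    n_permutations: int = 1000,
    seed: int = 0,
    sizes=(3, 4),
    distinct_types_required: bool = True,
) -> LoopNullResult:
    """Null distribution of the meaningful-loop count under random edge signs.

    The topology is held fixed while every edge sign is redrawn uniformly
    from {+1, -1}; the empirical exceedance probability of the observed count
    is reported with the add-one correction.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    loops = find_loops(network, sizes=sizes, distinct_types_required=distinct_types_required)
    observed = sum(lp.meaningful for lp in loops)
    if not loops:
        return LoopNullResult(np.zeros(n_permutations, dtype=int), 0, 1.0, n_permutations)

    edge_list = sorted(network.graph.edges, key=lambda uv: tuple(sorted(uv)))
    edge_index = {tuple(sorted(uv)): i for i, uv in enumerate(edge_list)}
    loop_edge_idx = [
        [
            edge_index[tuple(sorted((lp.nodes[i], lp.nodes[(i + 1) % len(lp.nodes)])))]
            for i in range(len(lp.nodes))
        ]
        for lp in loops
    ]
    rng = substream(seed, "loop-null")
    signs = rng.choice((-1, 1), size=(n_permutations, len(edge_list)))
    counts = np.zeros(n_permutations, dtype=int)
    for idx in loop_edge_idx:
        counts += signs[:, idx].prod(axis=1) == 1
    exceed = (1 + int((counts >= observed).sum())) / (n_permutations + 1)
    return LoopNullResult(counts=counts, observed=observed,
                          exceedance_p=float(exceed), n_permutations=n_permutations)


def loops_to_json(loops, path) -> None:
    with open(path, "w") as fh:
        json.dump([lp.to_record() for lp in loops], fh, indent=1, sort_keys=True)
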