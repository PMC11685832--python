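"""Network assembly, loop enumeration and sign-coherence contracts."""

from itertools import combinations, product

import numpy as np
import pytest

from omicloops import build_network, find_loops, loop_null_count
from omicloops.associations import AssociationEdge
from omicloops.network import _canonical_cycle


def edge(a, ta, b, tb, sign=1, p=0.001, stage="mgwas", beta=None):
    beta = beta if beta is not None else float(sign)
    return AssociationEdge(node_a=a, type_a=ta, node_b=b, type_b=tb, age=3.0,
                           beta=beta, se=0.1, p=p, sign=sign, stage=stage)


def triangle(signs, types=("genotype", "metabolite", "bmi")):
    a, b, c = "n1", "n2", "n3"
    return [
        edge(a, types[0], b, types[1], signs[0]),
        edge(b, types[1], c, types[2], signs[1]),
        edge(c, types[2], a, types[0], signs[2]),
    ]


class TestBuildNetwork:
    def test_triangle_has_three_nodes_three_edges(self):
        net = build_network(triangle((1, 1, 1)))
        assert len(net.nodes) == 3
        assert len(net.edges) == 3

    def test_duplicate_pair_merged_keeping_min_p_and_provenance(self):
        e1 = edge("a", "genotype", "b", "bmi", sign=1, p=0.003, stage="persistence")
        e2 = edge("a", "genotype", "b", "bmi", sign=-1, p=0.0004, stage="metabolite")
        net = build_network([e1, e2])
        merged = net.edges[0]
        assert merged.p == 0.0004
        assert net.sign("a", "b") == -1
        assert len(net.graph.edges["a", "b"]["provenance"]) == 2

    def test_same_omic_edge_rejected(self):
        with pytest.raises(ValueError, match="cross-omic"):
            build_network([edge("g1", "microbiome", "g2", "microbiome")])


class TestFindLoops:
    @pytest.mark.parametrize(
        "signs, meaningful",
        [((1, 1, 1), True), ((-1, -1, 1), True), ((-1, 1, 1), False)],
    )
    def test_worked_sign_cases(self, signs, meaningful):
        loops = find_loops(build_network(triangle(signs)))
        assert len(loops) == 1
        assert loops[0].meaningful is meaningful
        assert loops[0].sign_product == int(np.prod(signs))

    @pytest.mark.parametrize("k", [3, 4])
    def test_exhaustive_sign_assignments_match_product_rule(self, k):
        types = ("genotype", "metabolite", "bmi", "microbiome")[:k]
        nodes = [f"n{i}" for i in range(k)]
        for signs in product((1, -1), repeat=k):
            edges = [
                edge(nodes[i], types[i], nodes[(i + 1) % k], types[(i + 1) % k],
                     signs[i])
                for i in range(k)
            ]
            loops = find_loops(build_network(edges))
            assert len(loops) == 1
            assert loops[0].meaningful == (int(np.prod(signs)) == 1)

    def test_four_node_loop_may_repeat_one_type_by_default(self):
        # two metabolites (non-adjacent) in a 4-node loop, as in a SNP -
        # amino acid - genus - amino acid cycle
        types = ("genotype", "metabolite", "microbiome", "metabolite")
        nodes = ["s1", "m1", "g1", "m2"]
        edges = [edge(nodes[i], types[i], nodes[(i + 1) % 4], types[(i + 1) % 4])
                 for i in range(4)]
        assert len(find_loops(build_network(edges))) == 1

    def test_four_node_loop_with_two_repeated_types_needs_relaxed_policy(self):
        types = ("genotype", "metabolite", "genotype", "metabolite")
        nodes = ["s1", "m1", "s2", "m2"]
        edges = [edge(nodes[i], types[i], nodes[(i + 1) % 4], types[(i + 1) % 4])
                 for i in range(4)]
        assert find_loops(build_network(edges)) == []
        assert len(find_loops(build_network(edges), distinct_types_required=False)) == 1

    def test_enumeration_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(17)
        types = ("genotype", "microbiome", "metabolite", "bmi")
        for rep in range(30):
            n = int(rng.integers(5, 13))
            names = [f"v{i}" for i in range(n)]
            node_type = {v: types[rng.integers(0, 4)] for v in names}
            edges = []
            for a, b in combinations(names, 2):
                if node_type[a] != node_type[b] and rng.random() < 0.35:
                    edges.append(edge(a, node_type[a], b, node_type[b],
                                      sign=int(rng.choice((-1, 1))),
                                      p=float(rng.uniform(1e-5, 0.01))))
            net = build_network(edges)
            g = net.graph
            found = {
                (lp.nodes, lp.sign_product)
                for lp in find_loops(net, distinct_types_required=False)
            }
            # independent brute force over all triples and quadruple orderings
            expected = set()
            for u, v, w in combinations(sorted(g.nodes), 3):
                if g.has_edge(u, v) and g.has_edge(v, w) and g.has_edge(w, u):
                    sp = g.edges[u, v]["sign"] * g.edges[v, w]["sign"] * g.edges[w, u]["sign"]
                    expected.add((_canonical_cycle((u, v, w)), sp))
            for quad in combinations(sorted(g.nodes), 4):
                a, b, c, d = quad
                for order in ((a, b, c, d), (a, b, d, c), (a, c, b, d)):
                    if all(g.has_edge(order[i], order[(i + 1) % 4]) for i in range(4)):
                        sp = int(np.prod([g.edges[order[i], order[(i + 1) % 4]]["sign"]
                                          for i in range(4)]))
                        expected.add((_canonical_cycle(order), sp))
            assert found == expected

    def test_invariant_to_relabeling_and_edge_order(self):
        rng = np.random.default_rng(3)
        edges = triangle((1, -1, -1)) + [
            edge("n1", "genotype", "x", "microbiome", -1),
            edge("x", "microbiome", "n2", "metabolite", -1),
        ]
        base = find_loops(build_network(edges))
        shuffled = list(edges)
        rng.shuffle(shuffled)
        assert [lp.nodes for lp in find_loops(build_network(shuffled))] == [
            lp.nodes for lp in base
        ]
        relabel = {"n1": "z9", "n2": "a0", "n3": "m5", "x": "k2"}
        renamed = [
            AssociationEdge(node_a=relabel[e.node_a], type_a=e.type_a,
                            node_b=relabel[e.node_b], type_b=e.type_b, age=e.age,
                            beta=e.beta, se=e.se, p=e.p, sign=e.sign, stage=e.stage)
            for e in edges
        ]
        got = find_loops(build_network(renamed))
        assert len(got) == len(base)
        assert sorted(lp.meaningful for lp in got) == sorted(lp.meaningful for lp in base)

    def test_even_sign_flips_preserve_meaningfulness(self):
        for signs in product((1, -1), repeat=3):
            base = find_loops(build_network(triangle(signs)))[0].meaningful
            for i, j in combinations(range(3), 2):
                flipped = list(signs)
                flipped[i] *= -1
                flipped[j] *= -1
                assert find_loops(build_network(triangle(tuple(flipped))))[0].meaningful == base
            for i in range(3):
                flipped = list(signs)
                flipped[i] *= -1
                assert (
                    find_loops(build_network(triangle(tuple(flipped))))[0].meaningful
                    != base
                )


class TestLoopNull:
    def test_acyclic_network_degenerate_at_zero(self):
        net = build_network([edge("a", "genotype", "b", "bmi")])
        res = loop_null_count(net, n_permutations=50, seed=0)
        assert res.observed == 0
        assert (res.counts == 0).all()

    def test_single_triangle_meaningful_half_the_time(self):
        net = build_network(triangle((1, 1, 1)))
        res = loop_null_count(net, n_permutations=4000, seed=1)
        frac = res.counts.mean()
        assert frac == pytest.approx(0.5, abs=0.04)  # 4 of 8 assignments

    def test_seed_fixes_distribution(self):
        net = build_network(triangle((1, -1, -1)))
        a = loop_null_count(net, n_permutations=200, seed=5)
        b = loop_null_count(net, n_permutations=200, seed=5)
        assert (a.counts == b.counts).all()
        assert a.exceedance_p == b.exceedance_p
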