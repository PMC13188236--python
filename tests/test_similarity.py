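"""Similarity-layer unit tests against independent oracles."""

import numpy as np
import pytest

from mdagraph.similarity import (AssociationTable, DiseaseOntology, GipParams,
                                 SimilarityTable, ancestor_closure,
                                 decay_contributions,
                                 disease_semantic_similarity, gip_kernel,
                                 ic_contributions, integrate_similarity,
                                 mirna_functional_similarity,
                                 pair_semantic_similarity)
from conftest import random_dag


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bfs_ancestors(edges, start):
    """Brute-force reachability over child->parent edges."""
    reached = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for c, p in edges:
                if c == u and p not in reached:
                    reached.add(p)
                    nxt.append(p)
        frontier = nxt
    return reached


def decay_paths_oracle(nodes, edges, term, lam):
    """phi[u] = max over descending paths term..u of lam^len (exhaustive)."""
    children = {}
    for c, p in edges:
        children.setdefault(p, []).append(c)
    phi = {}

    def paths_down(u):
        # enumerate all path lengths from u down to term
        if u == term:
            return [0]
        out = []
        for c in children.get(u, []):
            out.extend(1 + l for l in paths_down(c))
        return out

    for u in nodes:
        ls = paths_down(u)
        phi[u] = max(lam ** l for l in ls) if ls else 0.0
    return phi


# ---------------------------------------------------------------------------
# ancestor closure
# ---------------------------------------------------------------------------

class TestAncestorClosure:
    def test_root_only(self):
        onto = DiseaseOntology(terms={"r"}, edges=[], disease_to_term={"d": "r"})
        v, e = ancestor_closure(onto, "d")
        assert v == {"r"} and e == set()

    def test_chain(self, chain_ontology):
        v, e = ancestor_closure(chain_ontology, "d2")
        assert v == {"a", "b", "c"} and len(e) == 2

    def test_unknown_disease_raises(self, chain_ontology):
        with pytest.raises(KeyError, match="unmapped disease"):
            ancestor_closure(chain_ontology, "nope")

    def test_matches_bfs_oracle_on_random_dag(self):
        rng = np.random.default_rng(3)
        terms, edges = random_dag(rng, 30)
        onto = DiseaseOntology(terms=set(terms), edges=edges,
                               disease_to_term={"d": terms[-1]})
        v, e = ancestor_closure(onto, "d")
        assert v == bfs_ancestors(edges, terms[-1])
        assert e == {(c, p) for c, p in edges if c in v and p in v}


# ---------------------------------------------------------------------------
# semantic contributions
# ---------------------------------------------------------------------------

class TestDecayContributions:
    def test_own_term_contributes_one_and_chain(self):
        dag = ({"a", "b", "c"}, {("c", "b"), ("b", "a")})
        w = decay_contributions(dag, "c", 0.5)
        assert w.phi["c"] == 1.0
        assert w.phi["b"] == 0.5
        assert w.phi["a"] == 0.25
        assert w.sv == pytest.approx(1.75)

    def test_single_step_chain(self):
        w = decay_contributions(({"d", "p"}, {("d", "p")}), "d", 0.5)
        assert w.phi["p"] == 0.5 and w.sv == pytest.approx(1.5)

    def test_diamond_takes_max_path(self):
        # d has two parents p1, p2 sharing grandparent g
        dag = ({"d", "p1", "p2", "g"},
               {("d", "p1"), ("d", "p2"), ("p1", "g"), ("p2", "g")})
        w = decay_contributions(dag, "d", 0.5)
        assert w.phi["g"] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        terms, edges = random_dag(rng, n)
        onto = DiseaseOntology(terms=set(terms), edges=edges,
                               disease_to_term={"d": terms[-1]})
        dag = ancestor_closure(onto, "d")
        w = decay_contributions(dag, terms[-1], 0.5)
        oracle = decay_paths_oracle(dag[0], dag[1], terms[-1], 0.5)
        for u in dag[0]:
            assert w.phi[u] == pytest.approx(oracle[u], abs=1e-10)


class TestIcContributions:
    def test_single_disease_single_node(self):
        onto = DiseaseOntology(terms={"r"}, edges=[], disease_to_term={"d": "r"})
        w = ic_contributions(onto, ancestor_closure(onto, "d"))
        assert w.phi["r"] == pytest.approx(0.0)  # -log(1/1)

    def test_two_disease_frequencies(self):
        # DAGs {a,b} and {a,c}: f(a)=2, |V|=4
        onto = DiseaseOntology(terms={"a", "b", "c"},
                               edges=[("b", "a"), ("c", "a")],
                               disease_to_term={"d1": "b", "d2": "c"})
        w = ic_contributions(onto, ancestor_closure(onto, "d1"))
        assert w.phi["a"] == pytest.approx(-np.log(0.5))
        assert all(v >= 0 for v in w.phi.values())


class TestPairSemantic:
    def test_identical_disease_is_one(self, chain_ontology):
        for d in ("d0", "d1", "d2"):
            dag = ancestor_closure(chain_ontology, d)
            term = chain_ontology.disease_to_term[d]
            for w in (decay_contributions(dag, term),
                      ic_contributions(chain_ontology, dag)):
                assert pair_semantic_similarity(w, w) == pytest.approx(1.0)

    def test_disjoint_dags_are_zero(self):
        onto = DiseaseOntology(terms={"a", "b"}, edges=[],
                               disease_to_term={"d1": "a", "d2": "b"})
        w1 = decay_contributions(ancestor_closure(onto, "d1"), "a")
        w2 = decay_contributions(ancestor_closure(onto, "d2"), "b")
        assert pair_semantic_similarity(w1, w2) == 0.0

    def test_shared_root_chains(self):
        # chains d1 -> a and d2 -> a: (0.5 + 0.5) / (1.5 + 1.5) = 1/3
        onto = DiseaseOntology(terms={"a", "x", "y"},
                               edges=[("x", "a"), ("y", "a")],
                               disease_to_term={"d1": "x", "d2": "y"})
        w1 = decay_contributions(ancestor_closure(onto, "d1"), "x", 0.5)
        w2 = decay_contributions(ancestor_closure(onto, "d2"), "y", 0.5)
        assert pair_semantic_similarity(w1, w2) == pytest.approx(1 / 3)


class TestDiseaseSemanticSimilarity:
    def test_mean_of_two_schemes_and_diagonal(self, chain_ontology):
        table = disease_semantic_similarity(chain_ontology, ["d0", "d1", "d2"])
        assert np.allclose(np.diag(table.values), 1.0)
        assert np.allclose(table.values, table.values.T)

    def test_matches_unmemoized_recomputation(self):
        rng = np.random.default_rng(11)
        from conftest import random_dag as rd
        terms, edges = rd(rng, 30)
        diseases = [f"dz{i}" for i in range(10)]
        mapping = {d: terms[int(rng.integers(0, 30))] for d in diseases}
        onto = DiseaseOntology(terms=set(terms), edges=edges,
                               disease_to_term=mapping)
        table = disease_semantic_similarity(onto, diseases)
        # independent naive recomputation per pair
        for i, di in enumerate(diseases):
            for j, dj in enumerate(diseases):
                dag_i = ancestor_closure(onto, di)
                dag_j = ancestor_closure(onto, dj)
                s1 = pair_semantic_similarity(
                    decay_contributions(dag_i, mapping[di]),
                    decay_contributions(dag_j, mapping[dj]))
                s2 = pair_semantic_similarity(
                    ic_contributions(onto, dag_i),
                    ic_contributions(onto, dag_j))
                assert table.values[i, j] == pytest.approx((s1 + s2) / 2, abs=1e-12)


# ---------------------------------------------------------------------------
# miRNA functional similarity
# ---------------------------------------------------------------------------

class TestFunctionalSimilarity:
    def _sim_table(self, values, labels):
        return SimilarityTable(labels=labels, values=np.asarray(values), kind="S_D")

    def test_identical_singleton_sets(self):
        assoc = AssociationTable(["m0", "m1"], ["d0"], np.array([[1], [1]]))
        sd = self._sim_table([[1.0]], ["d0"])
        fs = mirna_functional_similarity(assoc, sd)
        assert fs.values[0, 1] == pytest.approx(1.0)
        assert fs.values[0, 0] == pytest.approx(1.0)

    def test_zero_cross_similarity(self):
        assoc = AssociationTable(["m0", "m1"], ["d0", "d1"],
                                 np.array([[1, 0], [0, 1]]))
        sd = self._sim_table(np.eye(2), ["d0", "d1"])
        fs = mirna_functional_similarity(assoc, sd)
        assert fs.values[0, 1] == 0.0

    def test_best_match_average_hand_case(self):
        # DM_0={d0}, DM_1={d1,d2}; S(d0,d1)=0.8, S(d0,d2)=0.2
        assoc = AssociationTable(["m0", "m1"], ["d0", "d1", "d2"],
                                 np.array([[1, 0, 0], [0, 1, 1]]))
        sd = self._sim_table([[1.0, 0.8, 0.2],
                              [0.8, 1.0, 0.5],
                              [0.2, 0.5, 1.0]], ["d0", "d1", "d2"])
        fs = mirna_functional_similarity(assoc, sd)
        assert fs.values[0, 1] == pytest.approx((0.8 + 0.8 + 0.2) / 3)

    def test_empty_set_yields_zero(self, small_assoc):
        sd = self._sim_table(np.eye(3), ["d0", "d1", "d2"])
        fs = mirna_functional_similarity(small_assoc, sd)
        assert np.all(fs.values[3] == 0)

    def test_invariant_to_disease_order(self):
        rng = np.random.default_rng(5)
        values = (rng.random((6, 5)) < 0.4).astype(int)
        values[0, 0] = 1  # keep at least one edge
        sd_vals = rng.random((5, 5))
        sd_vals = 0.5 * (sd_vals + sd_vals.T)
        np.fill_diagonal(sd_vals, 1.0)
        labels_d = [f"d{j}" for j in range(5)]
        assoc = AssociationTable([f"m{i}" for i in range(6)], labels_d, values)
        fs1 = mirna_functional_similarity(assoc, self._sim_table(sd_vals, labels_d))
        perm = rng.permutation(5)
        assoc2 = AssociationTable([f"m{i}" for i in range(6)],
                                  [labels_d[p] for p in perm], values[:, perm])
        fs2 = mirna_functional_similarity(
            assoc2, self._sim_table(sd_vals[np.ix_(perm, perm)],
                                    [labels_d[p] for p in perm]))
        assert np.allclose(fs1.values, fs2.values)


# ---------------------------------------------------------------------------
# GIP kernel
# ---------------------------------------------------------------------------

class TestGipKernel:
    def test_hand_case_two_profiles(self):
        k = gip_kernel(np.array([[1, 0], [0, 1]]), ["a", "b"], GipParams(1.0))
        # eta = 1 / mean(1, 1) = 1; ||diff||^2 = 2
        assert k.values[0, 1] == pytest.approx(np.exp(-2))
        assert np.all(np.diag(k.values) == 1.0)

    def test_identical_profiles(self):
        k = gip_kernel(np.array([[1, 1, 0], [1, 1, 0]]), ["a", "b"])
        assert np.allclose(k.values, 1.0)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(0)
        profiles = (rng.random((20, 15)) < 0.3).astype(float)
        profiles[0, 0] = 1
        k = gip_kernel(profiles, [f"x{i}" for i in range(20)])
        assert np.all(k.values > 0) and np.all(k.values <= 1)
        assert np.allclose(k.values, k.values.T, atol=1e-12)

    def test_all_zero_profiles_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            gip_kernel(np.zeros((3, 4)), ["a", "b", "c"])


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

class TestIntegration:
    def _t(self, v, kind="S_D"):
        n = len(v)
        return SimilarityTable([f"x{i}" for i in range(n)], np.asarray(v, float), kind)

    def test_primary_everywhere(self):
        p = self._t([[1, 0.5], [0.5, 1]])
        b = self._t([[1, 0.9], [0.9, 1]], "GIP_d")
        assert np.allclose(integrate_similarity(p, b).values, p.values)

    def test_backfill_everywhere(self):
        p = self._t(np.zeros((2, 2)))
        b = self._t([[1, 0.9], [0.9, 1]], "GIP_d")
        assert np.allclose(integrate_similarity(p, b).values, b.values)

    def test_elementwise_branch_oracle_and_idempotence(self):
        rng = np.random.default_rng(2)
        pv = rng.random((4, 4)) * (rng.random((4, 4)) < 0.5)
        pv = 0.5 * (pv + pv.T)
        bv = 0.5 * (lambda x: x + x.T)(rng.random((4, 4)))
        p, b = self._t(pv), self._t(bv, "GIP_d")
        out = integrate_similarity(p, b)
        for i in range(4):
            for j in range(4):
                expect = pv[i, j] if pv[i, j] > 0 else bv[i, j]
                assert out.values[i, j] == expect
        again = integrate_similarity(out, b)
        assert np.allclose(again.values, out.values)

    def test_label_mismatch_raises(self):
        p = self._t([[1.0]])
        b = SimilarityTable(["other"], np.array([[1.0]]), "GIP_d")
        with pytest.raises(ValueError, match="label mismatch"):
            integrate_similarity(p, b)
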