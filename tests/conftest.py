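import numpy as np
import pytest

from mdagraph.similarity import AssociationTable, DiseaseOntology
from mdagraph.synthetic import SyntheticSpec, make_association, make_ontology


@pytest.fixture
def small_assoc() -> AssociationTable:
    """Hand-sized association table (4 miRNAs x 3 diseases)."""
    values = np.array([[1, 0, 1],
                       [0, 1, 0],
                       [1, 1, 0],
                       [0, 0, 0]])
    return AssociationTable(mirna_labels=[f"m{i}" for i in range(4)],
                            disease_labels=[f"d{j}" for j in range(3)],
                            values=values)


@pytest.fixture
def chain_ontology() -> DiseaseOntology:
    """c -> b -> a chain with one disease at each node."""
    return DiseaseOntology(terms={"a", "b", "c"},
                           edges=[("c", "b"), ("b", "a")],
                           disease_to_term={"d0": "a", "d1": "b", "d2": "c"})


@pytest.fixture
def tiny_spec() -> SyntheticSpec:
    """Small end-to-end spec for fast pipeline tests."""
    return SyntheticSpec(n_mirna=40, n_disease=25, latent_rank=3,
                         density=0.15, noise=0.0, seed=7,
                         n_image_classes=2, image_size=64)


@pytest.fixture
def tiny_dataset(tiny_spec):
    assoc, probs = make_association(tiny_spec)
    onto = make_ontology(tiny_spec)
    return assoc, probs, onto


def random_dag(rng: np.random.Generator, n_nodes: int):
    """Random single-rooted DAG as (terms, child->parent edges)."""
    terms = [f"t{i}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        n_par = int(rng.integers(1, min(3, i) + 1))
        for p in rng.choice(i, size=n_par, replace=False):
            edges.append((terms[i], terms[int(p)]))
    return terms, edges
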