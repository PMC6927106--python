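import numpy as np
import pytest

from hpofactor.containers import EntityIndex
from hpofactor.ontology import (
    AnnotationSet,
    OntologyDAG,
    compute_term_stats,
    propagate_true_path,
)


@pytest.fixture
def chain_dag():
    """R -> A -> C plus a sibling B under R."""
    return OntologyDAG.from_parent_map(
        {"R": set(), "A": {"R"}, "B": {"R"}, "C": {"A"}}
    )


@pytest.fixture
def diamond_dag():
    """C has two parents A and B, both under R."""
    return OntologyDAG.from_parent_map(
        {"R": set(), "A": {"R"}, "B": {"R"}, "C": {"A", "B"}}
    )


@pytest.fixture
def toy_annotations(chain_dag):
    """4 proteins; closed annotations giving count(R)=4, count(A)=2,
    count(C)=1, count(B)=1."""
    raw = AnnotationSet.from_pairs(
        [("p1", "C"), ("p2", "A"), ("p3", "B"), ("p4", "R")]
    )
    return propagate_true_path(raw, chain_dag)


@pytest.fixture
def toy_stats(toy_annotations, chain_dag):
    return compute_term_stats(toy_annotations, chain_dag)


def random_dag_parent_map(n_terms: int, rng: np.random.Generator, max_parents=3):
    """Independent brute-force toy DAG builder for oracle tests."""
    ids = [f"X{i:03d}" for i in range(n_terms)]
    pm = {ids[0]: set()}
    for i in range(1, n_terms):
        k = min(int(rng.integers(1, max_parents + 1)), i)
        pm[ids[i]] = {ids[int(j)] for j in rng.choice(i, size=k, replace=False)}
    return pm
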