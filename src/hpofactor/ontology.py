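"""Ontology handling: is-a DAG, true-path propagation, information content
and pairwise semantic similarity.

The phenotype ontology is a rooted DAG of terms connected by is-a edges.
Annotating a protein with a term implies every ancestor of that term (the
"true-path rule"), so annotation counts are computed after ancestor closure.
The information content of a term ``s`` annotated by ``count(s)`` of ``N_p``
proteins is ``I(s) = -ln(count(s) / N_p)``: rare (specific) terms carry high
information, a term annotated to every protein carries none.  The semantic
similarity of two terms is the Lin-style ratio

    sim(s, t) = 2 * I(mca(s, t)) / (I(s) + I(t))

where ``mca`` is the most informative common ancestor (the common ancestor
with minimal annotation probability).  The all-pairs similarity matrix is the
term network used as a graph regularizer downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property
from typing import IO, Iterable, Mapping

import networkx as nx
import numpy as np
import obonet

from .containers import EntityIndex, SimilarityNetwork

__all__ = [
    "OntologyDAG",
    "AnnotationSet",
    "TermStats",
    "parse_obo",
    "propagate_true_path",
    "compute_term_stats",
    "most_informative_common_ancestor",
    "semantic_similarity",
    "build_nhpo",
    "descendants",
]

GLOBAL_ROOT = "GLOBAL:ROOT"


class OntologyError(ValueError):
    """Raised for structural problems in an ontology (cycles, dangling ids)."""


@dataclass(frozen=True)
class OntologyDAG:
    """Rooted is-a DAG over ontology terms.

    ``parent_map`` maps each term to its set of is-a parents; the root has
    none.  Multi-rooted ontologies are represented as one DAG by linking the
    per-sub-ontology roots under a synthetic global root, so that every pair
    of terms has at least one common ancestor.
    """

    terms: frozenset[str]
    parent_map: Mapping[str, frozenset[str]]
    root: str
    sub_roots: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.root not in self.terms:
            raise OntologyError(f"root {self.root!r} not among terms")
        for term, parents in self.parent_map.items():
            for p in parents:
                if p not in self.terms:
                    raise OntologyError(
                        f"dangling is_a target {p!r} (parent of {term!r})"
                    )
        # cycle check via DFS coloring
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term, parents in self.parent_map.items():
            for p in parents:
                graph.add_edge(term, p)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise OntologyError(f"cycle detected through edge {cycle[0][:2]}")
        object.__setattr__(self, "_graph", graph)
        for term in self.terms:
            if term != self.root and not self.parent_map.get(term):
                raise OntologyError(f"term {term!r} cannot reach the root")

    @classmethod
    def from_parent_map(
        cls, parent_map: Mapping[str, Iterable[str]], root: str | None = None
    ) -> "OntologyDAG":
        terms = set(parent_map)
        for parents in parent_map.values():
            terms.update(parents)
        roots = [t for t in sorted(terms) if not parent_map.get(t)]
        if root is None:
            if len(roots) != 1:
                raise OntologyError(f"expected a single root, found {roots}")
            root = roots[0]
        return cls(
            terms=frozenset(terms),
            parent_map={t: frozenset(parent_map.get(t, ())) for t in terms},
            root=root,
        )

    @cached_property
    def children_map(self) -> dict[str, frozenset[str]]:
        kids: dict[str, set[str]] = {t: set() for t in self.terms}
        for term, parents in self.parent_map.items():
            for p in parents:
                kids[p].add(term)
        return {t: frozenset(k) for t, k in kids.items()}

    @cached_property
    def leaves(self) -> frozenset[str]:
        return frozenset(t for t, k in self.children_map.items() if not k)

    @cached_property
    def _ancestor_sets(self) -> dict[str, frozenset[str]]:
        """Reflexive ancestor sets (every term is its own ancestor)."""
        memo: dict[str, frozenset[str]] = {}
        order = list(nx.topological_sort(self._graph))  # children before parents
        for term in reversed(order):  # parents first
            acc: set[str] = {term}
            for p in self.parent_map.get(term, ()):
                acc |= memo[p]
            memo[term] = frozenset(acc)
        return memo

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        anc = self._ancestor_sets[term]
        return anc if include_self else anc - {term}

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class AnnotationSet:
    """A set of (protein id, term id) pairs."""

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationSet":
        return cls(pairs=frozenset((str(p), str(t)) for p, t in pairs))

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(p for p, _ in self.pairs)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass(frozen=True)
class TermStats:
    """Per-term annotation counts, probabilities and information content.

    Only terms with at least one annotated protein are retained.  ``prob`` is
    count(s)/N_p and ``ic`` is the information content -ln prob, in nats.
    """

    count: Mapping[str, int]
    n_proteins: int

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("need at least one annotated protein")
        if any(c < 1 for c in self.count.values()):
            raise ValueError("retained terms must have count >= 1")
        prob = {t: c / self.n_proteins for t, c in self.count.items()}
        object.__setattr__(self, "prob", prob)
        object.__setattr__(
            self, "ic", {t: (-np.log(p)) + 0.0 for t, p in prob.items()}
        )

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.count)

    def __contains__(self, term: str) -> bool:
        return term in self.count


def parse_obo(source: str | IO[str], unify_roots: bool = True) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into an :class:`OntologyDAG`.

    Only is-a edges are kept (part-of and other typedefs are dropped) and
    obsolete terms are excluded.  A multi-rooted file is unified under a
    synthetic global root when ``unify_roots`` is true; otherwise it is an
    error.  Cycles and is-a references to unknown terms are hard errors.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    graph = obonet.read_obo(source, ignore_obsolete=True)

    parent_map: dict[str, set[str]] = {t: set() for t in graph.nodes}
    stanza_terms = {t for t, data in graph.nodes(data=True) if data}
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in stanza_terms:
            raise OntologyError(
                f"dangling is_a target {parent!r} referenced by {child!r}"
            )
        parent_map.setdefault(child, set()).add(parent)
    parent_map = {t: parent_map.get(t, set()) for t in stanza_terms}

    roots = sorted(t for t, parents in parent_map.items() if not parents)
    if not roots:
        raise OntologyError("no root term found (all terms have parents)")
    if len(roots) == 1:
        root, sub_roots = roots[0], ()
    elif unify_roots:
        root, sub_roots = GLOBAL_ROOT, tuple(roots)
        parent_map[GLOBAL_ROOT] = set()
        for r in roots:
            parent_map[r] = {GLOBAL_ROOT}
    else:
        raise OntologyError(f"multiple roots found: {roots}")

    terms = frozenset(parent_map)
    return OntologyDAG(
        terms=terms,
        parent_map={t: frozenset(p) for t, p in parent_map.items()},
        root=root,
        sub_roots=sub_roots,
    )


def propagate_true_path(
    raw: AnnotationSet, dag: OntologyDAG, on_unknown: str = "error"
) -> AnnotationSet:
    """Close an annotation set under ancestors (the true-path rule).

    Idempotent; output always contains the input.  ``on_unknown`` controls
    annotations to terms absent from the DAG: "error" (default) or "skip".
    """
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    closed: set[tuple[str, str]] = set()
    for protein, term in raw.pairs:
        if term not in dag:
            if on_unknown == "error":
                raise OntologyError(f"annotation to unknown term {term!r}")
            continue
        for anc in dag.ancestors(term):
            closed.add((protein, anc))
    return AnnotationSet(pairs=frozenset(closed))


def compute_term_stats(ann: AnnotationSet, dag: OntologyDAG) -> TermStats:
    """Count annotated proteins per term over a propagated annotation set.

    Terms never annotated (count 0 after propagation) are dropped; the
    remaining counts define p(s) and I(s) = -ln p(s).
    """
    if not ann.pairs:
        raise ValueError("empty annotation set")
    count: dict[str, int] = {}
    for _, term in ann.pairs:
        count[term] = count.get(term, 0) + 1
    return TermStats(count=count, n_proteins=len(ann.proteins))


def most_informative_common_ancestor(
    s: str, t: str, dag: OntologyDAG, stats: TermStats
) -> str:
    """Common ancestor of ``s`` and ``t`` with minimal annotation probability.

    Ancestor sets are reflexive, so mca(s, s) = s.  Ties on probability are
    broken by lexicographically smallest term id (the similarity score only
    depends on the probability, so tie-breaking never changes it).
    """
    common = dag.ancestors(s) & dag.ancestors(t)
    common = [k for k in common if k in stats]
    if not common:
        raise OntologyError(f"no annotated common ancestor for {s!r}, {t!r}")
    return min(common, key=lambda k: (stats.prob[k], k))


def semantic_similarity(
    s: str, t: str, stats: TermStats, dag: OntologyDAG
) -> float:
    """Lin-style similarity 2*I(mca)/(I(s)+I(t)), in [0, 1].

    Defined as 0 when I(s)+I(t) = 0 (both terms annotated to every protein:
    nothing is shared beyond the trivial root).
    """
    denom = stats.ic[s] + stats.ic[t]
    if denom <= 0.0:
        return 0.0
    mca = most_informative_common_ancestor(s, t, dag, stats)
    return float(2.0 * stats.ic[mca] / denom) + 0.0


def build_nhpo(stats: TermStats, dag: OntologyDAG) -> SimilarityNetwork:
    """All-pairs semantic-similarity network over the retained terms.

    The edge weight between two terms is exactly their similarity score; the
    diagonal is forced to zero (self-loops are excluded from the graph before
    Laplacian construction).
    """
    index = EntityIndex.from_ids(stats.terms)
    n = len(index)
    ic = np.array([stats.ic[t] for t in index.ids])
    # boolean reflexive-ancestor incidence restricted to retained terms
    pos = {t: i for i, t in enumerate(index.ids)}
    anc = np.zeros((n, n), dtype=bool)
    for i, term in enumerate(index.ids):
        for a in dag.ancestors(term):
            j = pos.get(a)
            if j is not None:
                anc[i, j] = True
    weights = np.zeros((n, n))
    neg = np.full(n, -np.inf)
    for i in range(n):
        shared = anc & anc[i]  # (n, n) common-ancestor mask against term i
        ic_mca = np.where(shared, ic, neg).max(axis=1)
        denom = ic + ic[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(denom > 0, 2.0 * ic_mca / denom, 0.0)
        weights[i] = np.maximum(row, 0.0)
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2.0  # exact symmetry against fp noise
    return SimilarityNetwork(weights=weights, index=index, kind="term")


def descendants(term: str, dag: OntologyDAG) -> frozenset[str]:
    """All terms reachable downward from ``term``, excluding ``term``."""
    if term not in dag:
        raise OntologyError(f"unknown term {term!r}")
    seen: set[str] = set()
    stack = [term]
    while stack:
        node = stack.pop()
        for child in dag.children_map[node]:
            if child not in seen:
                seen.add(child)
                stack.append(child)
    return frozenset(seen)
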