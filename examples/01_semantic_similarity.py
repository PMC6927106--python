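"""Build a tiny is-a ontology, propagate annotations by the true-path rule,
and compute information-content-based term similarities.

The similarity of two terms is 2*I(mca)/(I(s)+I(t)) where I(s) = -ln of the
fraction of proteins annotated to s and mca is the common ancestor with the
smallest annotation probability.  A score near 1 means the terms share
almost all of their information; 0 means they share only the trivial root.
"""

from hpofactor.ontology import (
    AnnotationSet,
    OntologyDAG,
    build_nhpo,
    compute_term_stats,
    propagate_true_path,
    semantic_similarity,
)

# root R; A and B below it; C below A
dag = OntologyDAG.from_parent_map(
    {"R": set(), "A": {"R"}, "B": {"R"}, "C": {"A"}}
)

raw = AnnotationSet.from_pairs(
    [("p1", "C"), ("p2", "A"), ("p3", "B"), ("p4", "R")]
)
ann = propagate_true_path(raw, dag)
print(f"{len(raw)} raw pairs -> {len(ann)} after ancestor closure")

stats = compute_term_stats(ann, dag)
for term in sorted(stats.terms):
    print(f"  count({term}) = {stats.count[term]}, I({term}) = {stats.ic[term]:.4f} nats")

print(f"sim(A, C) = {semantic_similarity('A', 'C', stats, dag):.4f}"
      "  (parent/child: high, they share A's information)")
print(f"sim(A, B) = {semantic_similarity('A', 'B', stats, dag):.4f}"
      "  (siblings whose only common ancestor is the root: zero)")

net = build_nhpo(stats, dag)
print(f"term network: {net.n_nodes} terms, {net.n_edges} weighted edges")
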