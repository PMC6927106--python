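"""Synthetic data generation with the statistical structure the model
assumes: a rooted is-a DAG, hierarchy-closed annotations sampled from
planted non-negative low-rank factors, and protein networks correlated with
the planted protein factors.

This is a test harness, not a model of real annotation corpora: it
reproduces the low-rank + hierarchy-closure + network-smoothness structure
at desk scale, but not, e.g., the heavy-tailed term-frequency distribution
of a real ontology corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AnnotationMatrix, EntityIndex, SimilarityNetwork
from .ontology import OntologyDAG

__all__ = [
    "SyntheticScenario",
    "make_toy_dag",
    "plant_factors",
    "sample_annotations",
    "make_ppn_from_factors",
    "generate_scenario",
    "holdout_positives",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study condition."""

    n_proteins: int = 300
    n_terms: int = 200
    true_rank: int = 10
    density: float = 0.05
    noise: float = 0.05
    edge_density: float = 0.05
    ppn_coverage: float = 0.7
    max_parents: int = 3
    seed: int = 0


def make_toy_dag(
    n_terms: int, max_parents: int = 3, seed: int = 0
) -> OntologyDAG:
    """Random single-rooted DAG; each non-root term gets 1..max_parents
    parents among earlier terms, so term ids are a topological order."""
    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_terms)))
    ids = [f"T{i:0{width}d}" for i in range(n_terms)]
    parent_map: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        k = min(k, i)
        parents = rng.choice(i, size=k, replace=False)
        parent_map[ids[i]] = {ids[int(p)] for p in parents}
    return OntologyDAG(
        terms=frozenset(ids),
        parent_map={t: frozenset(p) for t, p in parent_map.items()},
        root=ids[0],
    )


def plant_factors(
    n_proteins: int,
    n_terms: int,
    true_rank: int,
    seed: int = 0,
    zero_fraction: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative ground-truth factors with Exponential(1) entries, a
    fraction of which is zeroed for sparsity."""
    rng = np.random.default_rng(seed)
    U = rng.exponential(1.0, size=(n_proteins, true_rank))
    V = rng.exponential(1.0, size=(n_terms, true_rank))
    U *= rng.random(U.shape) >= zero_fraction
    V *= rng.random(V.shape) >= zero_fraction
    return U, V


def _ancestor_incidence(dag: OntologyDAG, index: EntityIndex) -> np.ndarray:
    """A[j, a] = 1 iff term a is a (reflexive) ancestor of term j."""
    n = len(index)
    A = np.zeros((n, n), dtype=bool)
    for j, term in enumerate(index.ids):
        for a in dag.ancestors(term):
            if a in index:
                A[j, index.position(a)] = True
    return A


def sample_annotations(
    U_true: np.ndarray,
    V_true: np.ndarray,
    dag: OntologyDAG,
    density: float,
    seed: int = 0,
    offset: float = 6.0,
) -> AnnotationMatrix:
    """Sample a hierarchy-closed binary annotation matrix from planted
    factors.

    Cell probabilities are logistic in the planted signal,
    p_ij = sigma(c * m_ij - offset) with m = U* V*^T, so cells with no signal
    keep a small baseline probability sigma(-offset).  The gain c is
    calibrated by bisection so the realized density AFTER ancestor closure
    hits the target (closure only adds positives, so calibration targets the
    post-closure density; the draw's uniforms are frozen, making realized
    density monotone in c).
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    n_p, n_h = U_true.shape[0], V_true.shape[0]
    if len(dag) != n_h:
        raise ValueError("V_true rows must match the number of DAG terms")
    index = EntityIndex.from_ids(dag.terms)
    anc = _ancestor_incidence(dag, index)
    rng = np.random.default_rng(seed)
    uniforms = rng.random((n_p, n_h))
    M = U_true @ V_true.T

    def realize(c: float) -> np.ndarray:
        prob = 1.0 / (1.0 + np.exp(-(c * M - offset)))
        raw = uniforms < prob
        return (raw @ anc) > 0  # ancestor closure

    lo, hi = 0.0, 1.0
    while realize(hi).mean() < density and hi < 1e6:
        hi *= 2.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if realize(mid).mean() < density:
            lo = mid
        else:
            hi = mid
    Y = realize(hi).astype(float)
    width = max(4, len(str(n_p)))
    proteins = EntityIndex.from_ids(f"P{i:0{width}d}" for i in range(n_p))
    return AnnotationMatrix(values=Y, row_index=proteins, col_index=index)


def make_ppn_from_factors(
    U_true: np.ndarray,
    noise: float = 0.0,
    edge_density: float = 0.05,
    seed: int = 0,
    index: EntityIndex | None = None,
    coverage: float = 1.0,
) -> SimilarityNetwork:
    """Protein network whose edges track cosine similarity of the planted
    protein factors, perturbed by Gaussian noise and thresholded to a target
    edge density.

    ``coverage`` < 1 restricts the network to a random protein subset
    (zero rows/columns elsewhere), emulating real network sources that each
    connect only part of the annotated proteome.
    """
    n = U_true.shape[0]
    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(U_true, axis=1, keepdims=True)
    unit = U_true / np.maximum(norms, 1e-12)
    sim = unit @ unit.T
    if noise > 0:
        pert = rng.normal(0.0, noise, size=(n, n))
        sim = sim + (pert + pert.T) / 2.0
    np.fill_diagonal(sim, 0.0)
    sim = np.clip(sim, 0.0, None)
    iu = np.triu_indices(n, k=1)
    vals = sim[iu]
    keep = max(1, int(round(edge_density * len(vals))))
    if keep < len(vals):
        cutoff = np.partition(vals, len(vals) - keep)[len(vals) - keep]
        sim[sim < max(cutoff, 1e-12)] = 0.0
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 0.0)
    if coverage < 1.0:
        covered = rng.choice(n, size=max(2, int(round(coverage * n))), replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[covered] = True
        sim[~mask, :] = 0.0
        sim[:, ~mask] = 0.0
    if index is None:
        width = max(4, len(str(n)))
        index = EntityIndex.from_ids(f"P{i:0{width}d}" for i in range(n))
    return SimilarityNetwork(weights=sim, index=index, kind="protein")


def generate_scenario(scenario: SyntheticScenario) -> dict:
    """Generate one complete study condition.

    Returns a dict with the DAG, planted factors, the hierarchy-closed
    annotation matrix and two protein networks (one at the scenario noise,
    one noisier) correlated with the planted protein factors.
    """
    rng = np.random.default_rng(scenario.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    dag = make_toy_dag(scenario.n_terms, scenario.max_parents, int(seeds[0]))
    U_true, V_true = plant_factors(
        scenario.n_proteins, scenario.n_terms, scenario.true_rank, int(seeds[1])
    )
    Y = sample_annotations(
        U_true, V_true, dag, scenario.density, int(seeds[2])
    )
    # two comparably informative sources with independent noise, each
    # covering only part of the proteome (as real network databases do)
    ppn_a = make_ppn_from_factors(
        U_true,
        noise=scenario.noise,
        edge_density=scenario.edge_density,
        seed=int(seeds[3]),
        index=Y.row_index,
        coverage=scenario.ppn_coverage,
    )
    ppn_b = make_ppn_from_factors(
        U_true,
        noise=scenario.noise,
        edge_density=scenario.edge_density,
        seed=int(seeds[3]) // 2 + 1,
        index=Y.row_index,
        coverage=scenario.ppn_coverage,
    )
    return {
        "dag": dag,
        "U_true": U_true,
        "V_true": V_true,
        "Y": Y,
        "ppns": [ppn_a, ppn_b],
    }


def holdout_positives(
    Y: AnnotationMatrix | np.ndarray, fraction: float, seed: int = 0
) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Randomly hide a fraction of the positive cells from the loss.

    Returns the training mask W (0 at hidden positives) and the hidden cell
    set, for held-out evaluation.
    """
    Ym = Y.values if isinstance(Y, AnnotationMatrix) else np.asarray(Y)
    pos = np.argwhere(Ym == 1)
    rng = np.random.default_rng(seed)
    n_hide = int(round(fraction * len(pos)))
    chosen = rng.choice(len(pos), size=n_hide, replace=False)
    W = np.ones_like(Ym, dtype=float)
    hidden = set()
    for k in chosen:
        i, j = int(pos[k, 0]), int(pos[k, 1])
        W[i, j] = 0.0
        hidden.add((i, j))
    return W, hidden
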