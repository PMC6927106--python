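"""End-to-end convenience pipelines used by the CLI, the examples and the
test harness: build the term network from an annotation matrix, run one
hierarchy-aware CV fold for each model variant, and run the planted-factor
recovery experiment.
"""

from __future__ import annotations

import numpy as np

from . import data_io, evaluation, factorization, synthetic
from .containers import AnnotationMatrix, SimilarityNetwork
from .factorization import Hyperparams
from .ontology import (
    AnnotationSet,
    OntologyDAG,
    build_nhpo,
    compute_term_stats,
)

__all__ = [
    "nhpo_from_matrix",
    "default_hyperparams",
    "run_recovery",
    "run_variant_comparison",
]

#: defaults selected once by internal validation on synthetic scenarios
DEFAULT_LAM = 0.5
DEFAULT_ALPHA = 0.5
DEFAULT_BETA = 2.0**-7


def nhpo_from_matrix(
    Y: AnnotationMatrix, dag: OntologyDAG, train_mask: np.ndarray | None = None
) -> SimilarityNetwork:
    """Term-similarity network from the (training part of an) annotation
    matrix, aligned to the matrix's term columns.

    Held-out cells must not inform the similarity, so a training mask can
    restrict which positives are counted.
    """
    values = Y.values if train_mask is None else Y.values * train_mask
    pairs = [
        (Y.row_index.ids[i], Y.col_index.ids[j])
        for i, j in np.argwhere(values == 1)
    ]
    stats = compute_term_stats(AnnotationSet.from_pairs(pairs), dag)
    net = build_nhpo(stats, dag)
    return data_io.align_to_index(net, Y.col_index)


def default_hyperparams(K: int, seed: int, **overrides) -> Hyperparams:
    params = dict(
        K=K,
        lam=DEFAULT_LAM,
        alpha=DEFAULT_ALPHA,
        beta=DEFAULT_BETA,
        max_iter=300,
        tol=1e-6,
        seed=seed,
    )
    params.update(overrides)
    return Hyperparams(**params)


def run_recovery(
    scenario: synthetic.SyntheticScenario, holdout_fraction: float = 0.2
) -> dict:
    """Hide a random fraction of positives, fit the full model, and score
    the hidden cells.

    Returns the held-out annotation-centric AUC/AUPR plus the fitted model.
    """
    data = synthetic.generate_scenario(scenario)
    Y = data["Y"]
    W, hidden = synthetic.holdout_positives(Y, holdout_fraction, seed=scenario.seed)
    Sh = nhpo_from_matrix(Y, data["dag"], train_mask=W)
    hyper = default_hyperparams(K=scenario.true_rank, seed=scenario.seed)
    model = factorization.fit(Y, W, Sh, data["ppns"], hyper)
    scores = factorization.predict(model)
    test_pos = np.zeros(Y.values.shape, dtype=bool)
    for i, j in hidden:
        test_pos[i, j] = True
    exclude = (Y.values == 1) & ~test_pos
    auc, aupr = evaluation.annotation_centric(scores, test_pos, exclude)
    return {"auc": auc, "aupr": aupr, "model": model, "data": data}


def run_variant_comparison(
    scenario: synthetic.SyntheticScenario,
    variants: tuple[str, ...] = ("NMF", "NMF-PPN", "NMF-NHPO", "HPOAnnotator"),
) -> dict[str, dict[str, float]]:
    """One hierarchy-aware CV fold (20% of positives held out with
    descendant removal), fit per variant, scored on the held-out cells.

    Returns {variant: {"auc": ..., "aupr": ...}}.
    """
    data = synthetic.generate_scenario(scenario)
    Y = data["Y"]
    plan = evaluation.make_cv_splits(
        Y, data["dag"], Y.col_index, repeats=1, folds=5, seed=scenario.seed
    )
    fold = plan.repeats[0][0]
    W = fold.train_mask(Y.values)
    test_pos, exclude = fold.matrices(Y.values)
    Sh = nhpo_from_matrix(Y, data["dag"], train_mask=W)
    out: dict[str, dict[str, float]] = {}
    for name in variants:
        hyper = default_hyperparams(K=scenario.true_rank, seed=scenario.seed)
        if name == "NMF":
            hyper, Sh_used, ppns = (
                factorization.variant_config(name, hyper, 0, False),
                None,
                [],
            )
        elif name == "NMF-PPN":
            hyper = factorization.variant_config(name, hyper, 1, False)
            Sh_used, ppns = None, [data["ppns"][0]]
        elif name == "NMF-NHPO":
            hyper = factorization.variant_config(name, hyper, 0, True)
            Sh_used, ppns = Sh, []
        elif name == "AiPA":
            hyper = factorization.variant_config(name, hyper, 1, True)
            Sh_used, ppns = Sh, [data["ppns"][0]]
        else:  # HPOAnnotator
            hyper = factorization.variant_config(
                name, hyper, len(data["ppns"]), True
            )
            Sh_used, ppns = Sh, data["ppns"]
        model = factorization.fit(Y, W, Sh_used, ppns, hyper)
        auc, aupr = evaluation.annotation_centric(
            factorization.predict(model), test_pos, exclude
        )
        out[name] = {"auc": auc, "aupr": aupr}
    return out
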