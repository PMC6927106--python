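"""Evaluation protocol: ranking metrics, hierarchy-aware cross-validation
and release-over-release independent testing.

Eight criteria are reported: annotation-centric AUC/AUPR over all evaluable
protein-term cells pooled together; per-protein averages ("micro-AUC/AUPR"
in this package's reports, each protein's ranking of its own terms); and
per-term averages ("macro-AUC/AUPR"), with leaf-AUC/AUPR the same restricted
to ontology leaves.  NOTE: the micro/macro naming here follows the reports
this package mirrors — both are macro-style averages (per-protein and
per-term respectively), not the usual pooled "micro" of the ML literature.

Cross-validation splits the known (protein, term) pairs into folds.  Because
annotations are ancestor-closed, a held-out pair (p, h) leaks through any
retained training pair (p, d) with d a descendant of h (d implies h); such
pairs are removed from training and excluded from scoring, being known
positives hidden from the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .containers import AnnotationMatrix, EntityIndex
from .ontology import OntologyDAG, descendants

__all__ = [
    "EvaluationReport",
    "CVFold",
    "SplitPlan",
    "GROUP_BINS",
    "roc_auc",
    "pr_auc",
    "annotation_centric",
    "protein_centric",
    "term_centric",
    "group_metrics",
    "make_cv_splits",
    "independent_split",
    "evaluate_predictions",
    "similarity_diagnostics",
]

# Term bins by number of annotated proteins: [1-10], [11-30], [31-100],
# [101-300], [>=301].
GROUP_BINS: tuple[tuple[int, float], ...] = (
    (1, 10),
    (11, 30),
    (31, 100),
    (101, 300),
    (301, float("inf")),
)


def _bin_label(lo: int, hi: float) -> str:
    return f"[{lo}-{int(hi)}]" if np.isfinite(hi) else f"[>={lo}]"


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Rank-based AUC with average-rank tie handling; None if single-class."""
    labels = np.asarray(labels)
    if labels.min(initial=1) == labels.max(initial=0):
        return None
    return float(roc_auc_score(labels, scores))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Average precision (step-wise AUPR, no interpolation); None if no
    positives."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        return None
    return float(average_precision_score(labels, scores))


def annotation_centric(
    scores: np.ndarray, test_pos: np.ndarray, exclude: np.ndarray
) -> tuple[float | None, float | None]:
    """Pool all evaluable cells into one vector pair and score it.

    ``test_pos`` marks held-out positives (label 1); every other cell not in
    ``exclude`` is a negative.  ``exclude`` marks training positives and
    hidden (removed-descendant) pairs, which are neither positives nor
    negatives here.
    """
    mask = ~np.asarray(exclude, bool)
    y = np.asarray(test_pos, bool)[mask].ravel()
    s = np.asarray(scores, float)[mask].ravel()
    return roc_auc(s, y), pr_auc(s, y)


def _averaged(
    scores: np.ndarray,
    test_pos: np.ndarray,
    exclude: np.ndarray,
    axis_indices: Iterable[int],
    axis: int,
) -> tuple[float | None, float | None, int]:
    """Per-row (axis=0) or per-column (axis=1) AUC/AUPR, averaged over
    entities with defined curves; returns (mean_auc, mean_aupr, n_skipped)."""
    aucs, auprs = [], []
    skipped = 0
    test_pos = np.asarray(test_pos, bool)
    exclude = np.asarray(exclude, bool)
    for i in axis_indices:
        sl = (i, slice(None)) if axis == 0 else (slice(None), i)
        mask = ~exclude[sl]
        y = test_pos[sl][mask]
        s = scores[sl][mask]
        a = roc_auc(s, y)
        p = pr_auc(s, y)
        if a is None or p is None:
            skipped += 1
            continue
        aucs.append(a)
        auprs.append(p)
    if not aucs:
        return None, None, skipped
    return float(np.mean(aucs)), float(np.mean(auprs)), skipped


def protein_centric(
    scores: np.ndarray, test_pos: np.ndarray, exclude: np.ndarray
) -> tuple[float | None, float | None, int]:
    """Per-protein AUC/AUPR averaged over proteins with defined curves."""
    return _averaged(scores, test_pos, exclude, range(scores.shape[0]), axis=0)


def term_centric(
    scores: np.ndarray,
    test_pos: np.ndarray,
    exclude: np.ndarray,
    term_index: EntityIndex | None = None,
    dag: OntologyDAG | None = None,
) -> tuple[float | None, float | None, float | None, float | None, int, int]:
    """Per-term averages, plus the same restricted to ontology leaves.

    Returns (macro_auc, macro_aupr, leaf_auc, leaf_aupr, skipped_terms,
    skipped_leaves).  Leaf metrics require ``term_index`` and ``dag``.
    """
    macro_auc, macro_aupr, skipped = _averaged(
        scores, test_pos, exclude, range(scores.shape[1]), axis=1
    )
    leaf_auc = leaf_aupr = None
    skipped_leaves = 0
    if term_index is not None and dag is not None:
        leaf_cols = [
            j for j, t in enumerate(term_index.ids) if t in dag.leaves
        ]
        if leaf_cols:
            leaf_auc, leaf_aupr, skipped_leaves = _averaged(
                scores, test_pos, exclude, leaf_cols, axis=1
            )
    return macro_auc, macro_aupr, leaf_auc, leaf_aupr, skipped, skipped_leaves


def group_metrics(
    scores: np.ndarray,
    test_pos: np.ndarray,
    exclude: np.ndarray,
    train_counts: np.ndarray,
) -> dict[str, dict[str, float | int]]:
    """Per-term macro AUC/AUPR within annotation-count bins.

    ``train_counts[j]`` is the number of training annotations of term j;
    terms with zero training annotations fall outside every bin.  Empty bins
    are absent from the result.
    """
    out: dict[str, dict[str, float | int]] = {}
    train_counts = np.asarray(train_counts)
    for lo, hi in GROUP_BINS:
        cols = np.nonzero((train_counts >= lo) & (train_counts <= hi))[0]
        if len(cols) == 0:
            continue
        auc, aupr, skipped = _averaged(scores, test_pos, exclude, cols, axis=1)
        if auc is None:
            continue
        out[_bin_label(lo, hi)] = {
            "macro_auc": auc,
            "macro_aupr": aupr,
            "n_terms": int(len(cols)),
            "n_skipped": skipped,
        }
    return out


@dataclass
class EvaluationReport:
    """The eight ranking criteria plus the five-bin per-term breakdown."""

    auc: float | None
    aupr: float | None
    micro_auc: float | None
    micro_aupr: float | None
    macro_auc: float | None
    macro_aupr: float | None
    leaf_auc: float | None
    leaf_aupr: float | None
    group_macro: dict[str, dict[str, float | int]] = field(default_factory=dict)
    skipped_proteins: int = 0
    skipped_terms: int = 0
    skipped_leaves: int = 0

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "micro_auc": self.micro_auc,
            "micro_aupr": self.micro_aupr,
            "macro_auc": self.macro_auc,
            "macro_aupr": self.macro_aupr,
            "leaf_auc": self.leaf_auc,
            "leaf_aupr": self.leaf_aupr,
            "group_macro": self.group_macro,
            "skipped": {
                "proteins": self.skipped_proteins,
                "terms": self.skipped_terms,
                "leaves": self.skipped_leaves,
            },
        }


def evaluate_predictions(
    scores: np.ndarray,
    test_pos: np.ndarray,
    exclude: np.ndarray,
    train_counts: np.ndarray | None = None,
    term_index: EntityIndex | None = None,
    dag: OntologyDAG | None = None,
) -> EvaluationReport:
    """Compute the full eight-criterion report for one prediction matrix."""
    auc, aupr = annotation_centric(scores, test_pos, exclude)
    mi_auc, mi_aupr, sk_p = protein_centric(scores, test_pos, exclude)
    ma_auc, ma_aupr, lf_auc, lf_aupr, sk_t, sk_l = term_centric(
        scores, test_pos, exclude, term_index, dag
    )
    groups = (
        group_metrics(scores, test_pos, exclude, train_counts)
        if train_counts is not None
        else {}
    )
    return EvaluationReport(
        auc=auc,
        aupr=aupr,
        micro_auc=mi_auc,
        micro_aupr=mi_aupr,
        macro_auc=ma_auc,
        macro_aupr=ma_aupr,
        leaf_auc=lf_auc,
        leaf_aupr=lf_aupr,
        group_macro=groups,
        skipped_proteins=sk_p,
        skipped_terms=sk_t,
        skipped_leaves=sk_l,
    )


# --- splitting --------------------------------------------------------------


@dataclass(frozen=True)
class CVFold:
    """One fold: held-out test pairs plus the training pairs additionally
    removed because they are descendants of a test pair for the same
    protein."""

    test_pairs: frozenset[tuple[int, int]]
    removed_pairs: frozenset[tuple[int, int]]

    def train_mask(self, Y: np.ndarray) -> np.ndarray:
        """Loss mask: 1 everywhere except test and removed-descendant cells."""
        W = np.ones_like(np.asarray(Y, float))
        for i, j in self.test_pairs | self.removed_pairs:
            W[i, j] = 0.0
        return W

    def matrices(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(test_pos, exclude) boolean matrices for scoring this fold."""
        Y = np.asarray(Y)
        test_pos = np.zeros(Y.shape, dtype=bool)
        for i, j in self.test_pairs:
            test_pos[i, j] = True
        removed = np.zeros(Y.shape, dtype=bool)
        for i, j in self.removed_pairs:
            removed[i, j] = True
        train_pos = (Y == 1) & ~test_pos & ~removed
        return test_pos, train_pos | removed


@dataclass(frozen=True)
class SplitPlan:
    """repeats x folds cross-validation plan over the positive cells."""

    repeats: tuple[tuple[CVFold, ...], ...]
    seed: int


def make_cv_splits(
    Y: np.ndarray | AnnotationMatrix,
    dag: OntologyDAG,
    term_index: EntityIndex,
    repeats: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Random fold partition of the known annotations, with hierarchy-aware
    descendant removal.

    Per repeat, the (p, h) positive cells are partitioned into ``folds``
    equal folds.  For every test pair (p, h), every training pair (p, d)
    with d a descendant of h is removed from training (the descendant would
    imply the held-out annotation).  Deterministic given ``seed``.
    """
    Ym = Y.values if isinstance(Y, AnnotationMatrix) else np.asarray(Y)
    pos = np.argwhere(Ym == 1)
    if len(pos) < folds:
        raise ValueError("more folds than known annotations")
    desc_cols: dict[int, np.ndarray] = {}
    for j, term in enumerate(term_index.ids):
        desc = descendants(term, dag)
        desc_cols[j] = np.array(
            sorted(term_index.position(d) for d in desc if d in term_index),
            dtype=int,
        )
    rng = np.random.default_rng(seed)
    all_repeats = []
    pos_set = {(int(i), int(j)) for i, j in pos}
    for _ in range(repeats):
        perm = rng.permutation(len(pos))
        fold_of = np.empty(len(pos), dtype=int)
        fold_of[perm] = np.arange(len(pos)) % folds
        fold_list = []
        for f in range(folds):
            test = {(int(i), int(j)) for i, j in pos[fold_of == f]}
            removed: set[tuple[int, int]] = set()
            for i, j in test:
                for d in desc_cols[j]:
                    cell = (i, int(d))
                    if cell in pos_set and cell not in test:
                        removed.add(cell)
            fold_list.append(
                CVFold(
                    test_pairs=frozenset(test),
                    removed_pairs=frozenset(removed),
                )
            )
        all_repeats.append(tuple(fold_list))
    return SplitPlan(repeats=tuple(all_repeats), seed=seed)


def independent_split(
    old: AnnotationMatrix, new: AnnotationMatrix
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Train-on-old / test-on-newly-added split across two releases.

    Training uses every old positive (mask all ones).  Test positives are
    pairs present in the new release but not the old, restricted to the old
    release's protein/term universe; pairs involving entities the model has
    no row/column for are dropped and counted.  Evaluable negatives are
    cells zero in both releases.  Returns (test_pos, exclude, stats).
    """
    test_pos = np.zeros(old.values.shape, dtype=bool)
    n_outside = 0
    old_pairs = old.pairs()
    for protein, term in new.pairs():
        if protein not in old.row_index or term not in old.col_index:
            n_outside += 1
            continue
        if (protein, term) in old_pairs:
            continue
        i = old.row_index.position(protein)
        j = old.col_index.position(term)
        test_pos[i, j] = True
    exclude = old.values == 1
    stats = {
        "n_test_positives": int(test_pos.sum()),
        "n_outside_universe": n_outside,
    }
    return test_pos, exclude, stats


# --- diagnostics ------------------------------------------------------------


def similarity_diagnostics(
    Y: np.ndarray | AnnotationMatrix,
    Sh: np.ndarray | None = None,
    Sp: np.ndarray | None = None,
) -> dict:
    """Average network similarity grouped by co-annotation counts.

    Table A: term pairs grouped by the number of proteins they share (M);
    mean term-network similarity per group with a linear trend fit.  Table B:
    protein pairs grouped by the number of terms they share (K); mean
    protein-network similarity per group with a cubic trend fit.  Empty
    groups are omitted.  Trend fits are weighted by sqrt(group size): the
    grouped means have variance inversely proportional to the number of
    pairs, so sparse extreme groups should not dominate the fit.
    """
    Ym = Y.values if isinstance(Y, AnnotationMatrix) else np.asarray(Y, float)

    def grouped(shared: np.ndarray, sims: np.ndarray, degree: int) -> dict:
        groups, counts = {}, {}
        for m in np.unique(shared):
            sel = shared == m
            groups[int(m)] = float(sims[sel].mean())
            counts[int(m)] = int(sel.sum())
        xs = np.array(sorted(groups))
        ys = np.array([groups[int(m)] for m in xs])
        w = np.sqrt([counts[int(m)] for m in xs])
        deg = min(degree, len(xs) - 1)
        coef = np.polyfit(xs, ys, deg, w=w) if deg >= 1 else np.array([ys[0]])
        return {"groups": groups, "counts": counts, "coef": coef.tolist()}

    out: dict = {}
    if Sh is not None:
        Sh = Sh.weights if hasattr(Sh, "weights") else np.asarray(Sh, float)
        shared = (Ym.T @ Ym).astype(int)
        iu = np.triu_indices_from(shared, k=1)
        table = grouped(shared[iu], Sh[iu], degree=1)
        table["linear_coef"] = table.pop("coef")
        out["term_pairs"] = table
    if Sp is not None:
        Sp = Sp.weights if hasattr(Sp, "weights") else np.asarray(Sp, float)
        shared = (Ym @ Ym.T).astype(int)
        iu = np.triu_indices_from(shared, k=1)
        table = grouped(shared[iu], Sp[iu], degree=3)
        table["cubic_coef"] = table.pop("coef")
        out["protein_pairs"] = table
    return out
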