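"""Masked non-negative matrix factorization with dual graph regularization.

The model approximates the binary protein x term annotation matrix Y by a
product of two non-negative low-rank factors, Y ~ U V^T, with U (proteins x K)
and V (terms x K).  The objective is

    J(U, V) = || W . (Y - U V^T) ||_F^2
              + lambda (||U||_F^2 + ||V||_F^2)
              + alpha * sum_k tr(U^T L^{p_k} U)
              + beta  * tr(V^T L^h V)

where W is a binary loss mask (0 = cell excluded, e.g. held out for
validation), L^{p_k} = D - S^{p_k} are the unnormalized Laplacians of the
protein networks and L^h that of the term-similarity network.  The Laplacian
traces penalize factor rows that differ across strong edges, pulling
network-adjacent proteins (terms) toward nearby latent positions.

J is biconvex in U and V; it is minimized by alternating multiplicative
updates derived from the KKT complementarity conditions.  With each Laplacian
split into non-negative parts L = L+ - L- (L+ = (|L|+L)/2), the V update is

    V <- V . sqrt( [(W.Y)^T U + beta L^{h-} V]
                 / [(W.(U V^T))^T U + lambda V + beta L^{h+} V] )

and the U update is symmetric with alpha and the protein Laplacians summed.
Both preserve non-negativity and never increase J.  Predicted annotation
scores are the entries of U V^T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import AnnotationMatrix, EntityIndex, MaskMatrix, SimilarityNetwork

__all__ = [
    "Hyperparams",
    "FactorModel",
    "LaplacianPair",
    "VARIANTS",
    "graph_laplacian",
    "split_laplacian",
    "objective",
    "update_U",
    "update_V",
    "fit",
    "predict",
    "variant_config",
    "grid_search",
]

logger = logging.getLogger(__name__)

EPS = 1e-12  # denominator guard; multiplicative ratios are undefined at 0


class ConfigurationError(ValueError):
    """Raised for inconsistent hyperparameter / network combinations."""


@dataclass(frozen=True)
class Hyperparams:
    """Model hyperparameters.

    K is the latent rank; lam the Tikhonov (l2) coefficient; alpha weighs the
    summed protein-network Laplacians, beta the term-network Laplacian.
    """

    K: int
    lam: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    max_iter: int = 500
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")
        if min(self.lam, self.alpha, self.beta) < 0:
            raise ConfigurationError("lam, alpha, beta must be >= 0")
        if self.tol <= 0 or self.max_iter < 1:
            raise ConfigurationError("tol must be > 0 and max_iter >= 1")


@dataclass
class FactorModel:
    """Fitted non-negative factors plus the objective trace."""

    U: np.ndarray
    V: np.ndarray
    hyper: Hyperparams
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=np.float64)
        self.V = np.asarray(self.V, dtype=np.float64)
        if (self.U < 0).any() or (self.V < 0).any():
            raise ValueError("factors must be non-negative")
        if self.U.shape[1] != self.V.shape[1]:
            raise ValueError("U and V must share the latent dimension")


@dataclass(frozen=True)
class LaplacianPair:
    """Split L = plus - minus with both parts elementwise non-negative."""

    plus: np.ndarray
    minus: np.ndarray


def graph_laplacian(net: SimilarityNetwork | np.ndarray) -> np.ndarray:
    """Unnormalized Laplacian L = D - S, D = diag(row sums); rows sum to 0."""
    S = net.weights if isinstance(net, SimilarityNetwork) else np.asarray(net)
    return np.diag(S.sum(axis=1)) - S


def split_laplacian(L: np.ndarray) -> LaplacianPair:
    """L+ = (|L|+L)/2, L- = (|L|-L)/2; plus - minus reconstructs L exactly.

    For L = D - S with S >= 0 and zero diagonal this yields L+ = D, L- = S.
    """
    L = np.asarray(L, dtype=np.float64)
    absL = np.abs(L)
    return LaplacianPair(plus=(absL + L) / 2.0, minus=(absL - L) / 2.0)


def _as_array(x) -> np.ndarray:
    if isinstance(x, AnnotationMatrix):
        return x.values
    if isinstance(x, MaskMatrix):
        return x.values
    return np.asarray(x, dtype=np.float64)


def objective(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray | None,
    Lh: np.ndarray | None,
    Lps: list[np.ndarray],
    hyper: Hyperparams,
) -> float:
    """Evaluate the regularized masked reconstruction objective J(U, V)."""
    Y = _as_array(Y)
    U, V = np.asarray(U, float), np.asarray(V, float)
    if U.shape[0] != Y.shape[0] or V.shape[0] != Y.shape[1]:
        raise ValueError("factor shapes do not conform to Y")
    resid = Y - U @ V.T
    if W is not None:
        resid = _as_array(W) * resid
    J = float((resid**2).sum())
    J += hyper.lam * float((U**2).sum() + (V**2).sum())
    for Lp in Lps:
        J += hyper.alpha * float(np.trace(U.T @ Lp @ U))
    if Lh is not None:
        J += hyper.beta * float(np.trace(V.T @ Lh @ V))
    return J


def _check_finite(arr: np.ndarray, what: str, iteration: int | None = None) -> None:
    if not np.isfinite(arr).all():
        at = f" at iteration {iteration}" if iteration is not None else ""
        raise FloatingPointError(f"non-finite values in {what}{at}")


def update_V(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray | None,
    Lh_pair: LaplacianPair | None,
    hyper: Hyperparams,
    iteration: int | None = None,
) -> np.ndarray:
    """One multiplicative update of the term factors V (U held fixed)."""
    WY = Y if W is None else W * Y
    WUVt = U @ V.T if W is None else W * (U @ V.T)
    num = WY.T @ U
    den = WUVt.T @ U + hyper.lam * V
    if Lh_pair is not None and hyper.beta > 0:
        num = num + hyper.beta * (Lh_pair.minus @ V)
        den = den + hyper.beta * (Lh_pair.plus @ V)
    V_new = V * np.sqrt(num / (den + EPS))
    _check_finite(V_new, "V update", iteration)
    return V_new


def update_U(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray | None,
    Lp_pairs: list[LaplacianPair],
    hyper: Hyperparams,
    iteration: int | None = None,
) -> np.ndarray:
    """One multiplicative update of the protein factors U (V held fixed)."""
    WY = Y if W is None else W * Y
    WUVt = U @ V.T if W is None else W * (U @ V.T)
    num = WY @ V
    den = WUVt @ V + hyper.lam * U
    if Lp_pairs and hyper.alpha > 0:
        for pair in Lp_pairs:
            num = num + hyper.alpha * (pair.minus @ U)
            den = den + hyper.alpha * (pair.plus @ U)
    U_new = U * np.sqrt(num / (den + EPS))
    _check_finite(U_new, "U update", iteration)
    return U_new


def kkt_residual(
    U: np.ndarray,
    V: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray | None,
    Lh: np.ndarray | None,
    Lps: list[np.ndarray],
    hyper: Hyperparams,
) -> float:
    """Max abs of elementwise min(X, dJ/dX) over both factors.

    Zero at a KKT point: either a factor entry is 0 (and its gradient is
    >= 0) or the gradient vanishes.
    """
    Y = _as_array(Y)
    Wm = None if W is None else _as_array(W)
    WY = Y if Wm is None else Wm * Y
    WUVt = U @ V.T if Wm is None else Wm * (U @ V.T)
    grad_U = 2.0 * (WUVt @ V - WY @ V + hyper.lam * U)
    for Lp in Lps:
        grad_U += 2.0 * hyper.alpha * (Lp @ U)
    grad_V = 2.0 * (WUVt.T @ U - WY.T @ U + hyper.lam * V)
    if Lh is not None:
        grad_V += 2.0 * hyper.beta * (Lh @ V)
    res_U = np.abs(np.minimum(U, grad_U)).max(initial=0.0)
    res_V = np.abs(np.minimum(V, grad_V)).max(initial=0.0)
    return float(max(res_U, res_V))


def _init_factors(
    shape: tuple[int, int], hyper: Hyperparams, mean_y: float
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform(0,1) scaled so that U V^T starts at Y's magnitude."""
    rng = np.random.default_rng(hyper.seed)
    scale = np.sqrt(max(mean_y, EPS) / hyper.K)
    n_p, n_h = shape
    U = rng.uniform(0.0, 1.0, size=(n_p, hyper.K)) * scale
    V = rng.uniform(0.0, 1.0, size=(n_h, hyper.K)) * scale
    return U, V


def fit(
    Y: np.ndarray | AnnotationMatrix,
    W: np.ndarray | MaskMatrix | None,
    Sh: SimilarityNetwork | None,
    Sps: list[SimilarityNetwork],
    hyper: Hyperparams,
) -> FactorModel:
    """Fit the model by alternating multiplicative updates.

    Stops when the relative objective change drops below ``hyper.tol`` or
    after ``hyper.max_iter`` iterations.  Networks must already be aligned to
    Y's protein/term indexes.
    """
    Ym = _as_array(Y)
    if Ym.size == 0:
        raise ValueError("empty annotation matrix")
    Wm = None if W is None else _as_array(W)
    if Wm is not None and Wm.shape != Ym.shape:
        raise ValueError("mask shape does not match Y")
    if hyper.beta > 0 and Sh is None:
        raise ConfigurationError("beta > 0 requires a term network")
    if hyper.alpha > 0 and not Sps:
        raise ConfigurationError("alpha > 0 requires at least one protein network")

    Lh = graph_laplacian(Sh) if (Sh is not None and hyper.beta > 0) else None
    Lps = [graph_laplacian(s) for s in Sps] if hyper.alpha > 0 else []
    if hyper.alpha > 0:
        for s in Sps:
            if s.weights.shape[0] != Ym.shape[0]:
                raise ValueError("protein network not aligned to Y's rows")
    if Lh is not None and Lh.shape[0] != Ym.shape[1]:
        raise ValueError("term network not aligned to Y's columns")

    Lh_pair = split_laplacian(Lh) if Lh is not None else None
    Lp_pairs = [split_laplacian(L) for L in Lps]

    U, V = _init_factors(Ym.shape, hyper, float(Ym.mean()))
    trace = [objective(U, V, Ym, Wm, Lh, Lps, hyper)]
    for it in range(1, hyper.max_iter + 1):
        U = update_U(U, V, Ym, Wm, Lp_pairs, hyper, iteration=it)
        V = update_V(U, V, Ym, Wm, Lh_pair, hyper, iteration=it)
        J = objective(U, V, Ym, Wm, Lh, Lps, hyper)
        if not np.isfinite(J):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        trace.append(J)
        logger.debug("iter %d objective %.6g", it, J)
        prev = trace[-2]
        if prev > 0 and abs(prev - J) / prev < hyper.tol:
            break
    return FactorModel(U=U, V=V, hyper=hyper, objective_trace=trace)


def predict(model: FactorModel) -> np.ndarray:
    """Annotation scores Y_hat = U V^T; larger = more likely annotation."""
    return model.U @ model.V.T


# --- variants ---------------------------------------------------------------

VARIANTS = ("NMF", "NMF-PPN", "NMF-NHPO", "AiPA", "HPOAnnotator")


def variant_config(
    name: str, hyper: Hyperparams, n_ppns: int, has_term_network: bool
) -> Hyperparams:
    """Validate and normalize hyperparameters for a named model variant.

    NMF: alpha = beta = 0 (no networks).  NMF-PPN: beta = 0, exactly one
    protein network.  NMF-NHPO: alpha = 0, term network only.  AiPA:
    alpha, beta > 0 with exactly one protein network.  HPOAnnotator:
    alpha, beta > 0 with all provided protein networks.
    """
    if name not in VARIANTS:
        raise ConfigurationError(f"unknown variant {name!r}; choose from {VARIANTS}")
    if name == "NMF":
        return replace(hyper, alpha=0.0, beta=0.0)
    if name == "NMF-PPN":
        if n_ppns != 1:
            raise ConfigurationError("NMF-PPN uses exactly one protein network")
        if hyper.alpha <= 0:
            raise ConfigurationError("NMF-PPN requires alpha > 0")
        return replace(hyper, beta=0.0)
    if name == "NMF-NHPO":
        if not has_term_network:
            raise ConfigurationError("NMF-NHPO requires a term network")
        if hyper.beta <= 0:
            raise ConfigurationError("NMF-NHPO requires beta > 0")
        return replace(hyper, alpha=0.0)
    # AiPA / HPOAnnotator: both regularizers active
    if hyper.alpha <= 0 or hyper.beta <= 0:
        raise ConfigurationError(f"{name} requires alpha > 0 and beta > 0")
    if not has_term_network:
        raise ConfigurationError(f"{name} requires a term network")
    if name == "AiPA" and n_ppns != 1:
        raise ConfigurationError("AiPA uses exactly one protein network")
    if name == "HPOAnnotator" and n_ppns < 1:
        raise ConfigurationError("HPOAnnotator requires protein networks")
    return hyper


# --- hyperparameter search --------------------------------------------------


def grid_search(
    Y: np.ndarray | AnnotationMatrix,
    W: np.ndarray | MaskMatrix | None,
    Sh: SimilarityNetwork | None,
    Sps: list[SimilarityNetwork],
    grid: list[Hyperparams],
    folds: int = 5,
    seed: int = 0,
) -> Hyperparams:
    """Select hyperparameters by internal k-fold cross-validation.

    The observed positives are split into ``folds`` random folds; each grid
    point is fit with one fold's positives masked out and scored by
    annotation-centric AUPR on that fold (validation positives vs. cells that
    are zero in Y).  Returns the grid point with the best mean validation
    AUPR.  Deterministic given ``seed``.
    """
    from .evaluation import annotation_centric

    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    Ym = _as_array(Y)
    Wm = np.ones_like(Ym) if W is None else _as_array(W)
    pos = np.argwhere((Ym == 1) & (Wm == 1))
    if len(pos) < folds:
        raise ConfigurationError("fewer observed positives than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pos))
    fold_of = np.empty(len(pos), dtype=int)
    fold_of[perm] = np.arange(len(pos)) % folds

    best: tuple[float, int] | None = None
    for gi, hyper in enumerate(grid):
        scores = []
        for f in range(folds):
            val = pos[fold_of == f]
            W_train = Wm.copy()
            W_train[val[:, 0], val[:, 1]] = 0.0
            model = fit(Ym, W_train, Sh, Sps, hyper)
            pred = predict(model)
            test_pos = np.zeros_like(Ym, dtype=bool)
            test_pos[val[:, 0], val[:, 1]] = True
            exclude = (Ym == 1) & ~test_pos  # training positives
            _, aupr = annotation_centric(pred, test_pos, exclude)
            scores.append(aupr)
        mean_aupr = float(np.mean(scores))
        logger.info("grid point %d: validation AUPR %.4f", gi, mean_aupr)
        if best is None or mean_aupr > best[0]:
            best = (mean_aupr, gi)
    return grid[best[1]]
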