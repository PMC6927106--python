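"""Bi-random-walk (BiRW) baseline.

BiRW propagates known annotations over both the protein network and the
term network simultaneously via the fixed-point iteration

    Y_t = decay * P Y_{t-1} G + (1 - decay) * Y0

where P and G are the symmetrically normalized protein and term networks
(D^{-1/2} S D^{-1/2}) and Y0 the initial annotation matrix.  With spectral
norms of P and G at most 1 and decay < 1 the map is a contraction, so the
iteration converges geometrically to a unique fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SimilarityNetwork

__all__ = ["BiRWConfig", "normalize_network", "birw"]

_DIVERGENCE_FACTOR = 1e6


@dataclass(frozen=True)
class BiRWConfig:
    """decay in (0, 1) trades propagated against initial annotations."""

    decay: float = 0.5
    max_iter: int = 1000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")


def normalize_network(net: SimilarityNetwork | np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} S D^{-1/2}.

    Rows/columns of isolated nodes (zero degree) are left zero rather than
    producing NaN.
    """
    S = net.weights if isinstance(net, SimilarityNetwork) else np.asarray(net, float)
    deg = S.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    return (inv_sqrt[:, None] * S) * inv_sqrt[None, :]


def birw(
    P: np.ndarray, G: np.ndarray, Y0: np.ndarray, cfg: BiRWConfig
) -> np.ndarray:
    """Iterate the bi-random walk to its fixed point and return the scores."""
    P = np.asarray(P, float)
    G = np.asarray(G, float)
    Y0 = np.asarray(Y0, float)
    if P.shape != (Y0.shape[0], Y0.shape[0]) or G.shape != (
        Y0.shape[1],
        Y0.shape[1],
    ):
        raise ValueError("P/G shapes do not conform to Y0")
    limit = max(np.abs(Y0).max(), 1.0) * _DIVERGENCE_FACTOR
    Y = Y0.copy()
    for _ in range(cfg.max_iter):
        Y_next = cfg.decay * (P @ Y @ G) + (1.0 - cfg.decay) * Y0
        delta = np.abs(Y_next - Y).max()
        Y = Y_next
        if np.abs(Y).max() > limit or not np.isfinite(Y).all():
            raise FloatingPointError("bi-random walk diverged")
        if delta < cfg.tol:
            break
    return Y
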