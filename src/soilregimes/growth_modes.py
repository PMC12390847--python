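"""Rank-2 NMF of the phylum x condition growth-fold matrix.

The clipped log growth folds form a non-negative matrix G (phyla x conditions,
40 x 130 at the study's scale).  Non-negative matrix factorization G = W x H
with two factors extracts two growth modes: in the study one mode loads on
Bacillota (basic perturbations), the other on Pseudomonadota and Bacteroidota
(moderate pH), retaining ~93% of the matrix variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

__all__ = ["GrowthMatrix", "NMFResult", "build_growth_matrix", "nmf_decompose", "variance_retained"]


@dataclass
class GrowthMatrix:
    """Non-negative phyla x condition growth folds with stable labels."""

    G: pd.DataFrame

    def __post_init__(self) -> None:
        if self.G.size == 0:
            raise ValueError("empty growth matrix")
        if (self.G.values < 0).any():
            raise ValueError("growth folds must be non-negative")


@dataclass
class NMFResult:
    W: pd.DataFrame  # phyla x rank weights
    H: pd.DataFrame  # rank x conditions modes
    variance_retained: float

    def dominant_mode(self) -> pd.Series:
        """Per-phylum index (0-based) of the mode with the largest weight."""
        return pd.Series(np.argmax(self.W.values, axis=1), index=self.W.index)


def build_growth_matrix(folds_g: pd.DataFrame) -> GrowthMatrix:
    """Assemble the growth matrix from phylum-level clipped folds."""
    if folds_g is None or folds_g.size == 0:
        raise ValueError("empty fold table")
    G = folds_g.sort_index(axis=0).sort_index(axis=1)
    return GrowthMatrix(G=G)


def variance_retained(G, W, H) -> float:
    """Frobenius fraction 1 - ||G - WH||_F^2 / ||G||_F^2, clipped to [0, 1]."""
    G = np.asarray(G, float)
    WH = np.asarray(W, float) @ np.asarray(H, float)
    denom = np.sum(G**2)
    if denom == 0:
        raise ValueError("variance undefined for an all-zero matrix")
    return float(np.clip(1.0 - np.sum((G - WH) ** 2) / denom, 0.0, 1.0))


def nmf_decompose(G: GrowthMatrix | pd.DataFrame, rank: int = 2, seed: int = 0,
                  n_restarts: int = 10, max_iter: int = 2000) -> NMFResult:
    """Best-of-restarts coordinate-descent NMF.

    NMF is non-convex; ``n_restarts`` random initializations (seeds derived
    deterministically from ``seed``) are run and the factorization with the
    smallest Frobenius reconstruction error is returned.
    """
    Gdf = G.G if isinstance(G, GrowthMatrix) else pd.DataFrame(G)
    X = Gdf.to_numpy(float)
    if not np.any(X > 0):
        raise ValueError("all-zero growth matrix: NMF degenerate")
    rng = np.random.default_rng(seed)
    best = None
    for s in rng.integers(0, 2**31 - 1, size=max(1, n_restarts)):
        model = NMF(n_components=rank, init="random", random_state=int(s),
                    max_iter=max_iter, tol=1e-8)
        W = model.fit_transform(X)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, W, model.components_)
    _, W, H = best
    # order modes by total contribution for stable reporting
    order = np.argsort(-(W.sum(axis=0) * H.sum(axis=1)))
    W, H = W[:, order], H[order]
    return NMFResult(
        W=pd.DataFrame(W, index=Gdf.index, columns=[f"mode{i+1}" for i in range(rank)]),
        H=pd.DataFrame(H, index=[f"mode{i+1}" for i in range(rank)], columns=Gdf.columns),
        variance_retained=variance_retained(X, W, H),
    )
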