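"""Correlation-matrix PCA of an environmental stack.

Fits the eigendecomposition of the Pearson correlation matrix over masked
cells, selects how many axes to keep by either the Kaiser-Guttman latent
root criterion or a fixed 95% cumulative-variance criterion, and projects
per-cell scores back into raster layers that can serve as an uncorrelated
predictor set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import Layer, RasterStack

__all__ = ["PCAModel", "fit_pca", "select_axes", "project_scores", "pca_report"]


@dataclass
class PCAModel:
    """Eigendecomposition of a correlation matrix, with the standardization
    (per-layer means/SDs) needed to score new cells."""

    layer_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray  # non-increasing
    eigenvectors: np.ndarray  # (V, V), column k = loading vector of axis k

    @property
    def n_vars(self) -> int:
        return len(self.layer_names)

    @property
    def proportion(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.proportion)


def fit_pca(stack: RasterStack) -> PCAModel:
    """PCA of the Pearson correlation matrix over masked cells.

    Sign convention: each eigenvector's largest-magnitude loading is made
    positive, so scores are reproducible across linear-algebra backends.
    """
    if stack.n_layers < 2:
        raise ValueError("PCA requires at least 2 layers")
    X = stack.env_matrix()
    if X.shape[0] < stack.n_layers:
        raise ValueError("fewer masked cells than layers")
    sds = X.std(axis=0, ddof=1)
    for name, s in zip(stack.names, sds):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"layer {name!r} has zero variance over masked cells")
    means = X.mean(axis=0)
    Z = (X - means) / sds
    R = (Z.T @ Z) / (X.shape[0] - 1)
    w, U = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, U = np.maximum(w[order], 0.0), U[:, order]
    for k in range(U.shape[1]):
        if U[np.argmax(np.abs(U[:, k])), k] < 0:
            U[:, k] = -U[:, k]
    return PCAModel(list(stack.names), means, sds, w, U)


def select_axes(model: PCAModel, criterion: str) -> int:
    """Number of axes to retain.

    ``kaiser``: count of eigenvalues strictly greater than one.
    ``cumulative95``: smallest k whose cumulative proportion reaches 0.95.
    """
    if criterion == "kaiser":
        return int(np.sum(model.eigenvalues > 1.0))
    if criterion == "cumulative95":
        return int(np.searchsorted(model.cumulative, 0.95 - 1e-12) + 1)
    raise ValueError(f"unknown criterion: {criterion}")


def project_scores(model: PCAModel, stack: RasterStack, k: int) -> RasterStack:
    """Score the stack on the first ``k`` axes, as layers PC1..PCk."""
    if k < 1 or k > model.n_vars:
        raise ValueError("k out of range")
    if list(stack.names) != model.layer_names:
        raise ValueError("stack layer names/order do not match the fitted model")
    X = stack.env_matrix()
    Z = (X - model.means) / model.sds
    scores = Z @ model.eigenvectors[:, :k]
    mask = stack.mask
    layers = []
    for j in range(k):
        vals = np.full(stack.grid.shape, np.nan)
        vals[mask] = scores[:, j]
        layers.append(Layer(stack.grid, vals, mask.copy()))
    return RasterStack(stack.grid, layers, [f"PC{j + 1}" for j in range(k)])


def pca_report(model: PCAModel) -> pd.DataFrame:
    """Eigenvalue table: axis, eigenvalue, proportion (%), cumulative (%)."""
    return pd.DataFrame(
        {
            "axis": [f"PC{i + 1}" for i in range(model.n_vars)],
            "eigenvalue": model.eigenvalues,
            "proportion_pct": 100 * model.proportion,
            "cumulative_pct": 100 * model.cumulative,
        }
    )
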