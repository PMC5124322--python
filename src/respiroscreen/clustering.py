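"""Shared clustering machinery: a deterministic batch SOM and a K-means wrapper.

The self-organizing map here is a batch SOM on a small rectangular grid with a
Gaussian neighbourhood whose width decays linearly across epochs.  The codebook
is initialised on the plane spanned by the first two principal components
(sign-fixed), so that — unlike an online SOM — fitting is fully deterministic
and invariant to the order of the input samples.  Commercial tools used for
phenotype-profile clustering do not document their defaults; cluster identity
is therefore validated by recovery properties, never by label equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ValidationError


@dataclass
class ClusterResult:
    """Cluster labels (1..k) with per-cluster summary profiles.

    ``medians`` holds one row per cluster index (NaN rows for empty clusters);
    ``flags`` optionally annotates clusters (e.g. P-like / A-like deficiency
    calls for screen profiles).
    """

    labels: pd.Series
    k: int
    algorithm: str
    seed: int | None
    grid_shape: tuple[int, int] | None = None
    medians: pd.DataFrame | None = None
    flags: dict[int, str] = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(range(1, self.k + 1), fill_value=0)

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def empty_clusters(self) -> list[int]:
        return [c for c, n in self.sizes.items() if n == 0]


class BatchSOM:
    """Batch self-organizing map on a rectangular grid.

    Parameters
    ----------
    grid : (rows, cols) of the unit lattice; k = rows * cols.
    n_epochs : number of batch updates.
    sigma0, sigma_final : Gaussian neighbourhood width, decayed linearly
        from ``sigma0`` (default half the larger grid dimension) to
        ``sigma_final`` (in grid units).
    """

    def __init__(self, grid: tuple[int, int] = (3, 4), n_epochs: int = 50,
                 sigma0: float | None = None, sigma_final: float = 0.5):
        self.grid = tuple(grid)
        self.n_epochs = int(n_epochs)
        self.sigma0 = float(sigma0) if sigma0 is not None else max(self.grid) / 2.0
        self.sigma_final = float(sigma_final)
        self.weights_: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1]

    def _grid_coords(self) -> np.ndarray:
        gy, gx = np.meshgrid(np.arange(self.grid[0]), np.arange(self.grid[1]),
                             indexing="ij")
        return np.column_stack([gy.ravel(), gx.ravel()]).astype(float)

    def _init_weights(self, X: np.ndarray) -> np.ndarray:
        n, f = X.shape
        mean = X.mean(axis=0)
        Xc = X - mean
        # PCA plane, deterministic signs: largest-magnitude loading positive
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        coords = self._grid_coords()
        w = np.tile(mean, (self.n_units, 1))
        for axis in range(min(2, vt.shape[0])):
            v = vt[axis]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            extent = coords[:, axis] - coords[:, axis].mean()
            span = extent.max() - extent.min()
            if span == 0:
                continue
            scale = 2.0 * s[axis] / np.sqrt(max(n - 1, 1))
            w += np.outer(extent / span * scale, v)
        return w

    def fit(self, X: np.ndarray) -> "BatchSOM":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 1:
            raise ValidationError("SOM input must be a non-empty 2-D array")
        coords = self._grid_coords()
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        w = self._init_weights(X)
        for epoch in range(self.n_epochs):
            frac = epoch / max(self.n_epochs - 1, 1)
            sigma = self.sigma0 + frac * (self.sigma_final - self.sigma0)
            bmu = self._bmu(X, w)
            h = np.exp(-d2 / (2.0 * sigma ** 2))  # (units, units)
            hb = h[:, bmu]                        # (units, n)
            num = hb @ X
            den = hb.sum(axis=1)
            ok = den > 0
            w[ok] = num[ok] / den[ok, None]
        self.weights_ = w
        return self

    @staticmethod
    def _bmu(X: np.ndarray, w: np.ndarray) -> np.ndarray:
        # argmin of squared distance; ties broken by lowest unit index
        d = ((X[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise ValidationError("SOM not fitted")
        return self._bmu(np.asarray(X, dtype=float), self.weights_)


def cluster_matrix(values: pd.DataFrame, algorithm: str = "som", k: int = 12,
                   grid: tuple[int, int] | None = None, seed: int | None = 0,
                   n_epochs: int = 50) -> ClusterResult:
    """Cluster the rows of ``values`` into k groups.

    ``algorithm="som"`` uses :class:`BatchSOM` (grid defaults to the most
    square factorisation of k); ``algorithm="kmeans"`` uses scikit-learn
    K-means with ``n_init=10`` restarts at the given seed.
    """
    if values.isna().any().any():
        raise ValidationError("clustering requires a complete matrix (no NaN)")
    n = len(values)
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of rows ({n})")
    X = values.to_numpy(dtype=float)
    if algorithm == "som":
        if grid is None:
            grid = _default_grid(k)
        if grid[0] * grid[1] != k:
            raise ValidationError(f"grid {grid} incompatible with k={k}")
        som = BatchSOM(grid=grid, n_epochs=n_epochs).fit(X)
        labels = som.predict(X) + 1
        result = ClusterResult(labels=pd.Series(labels, index=values.index), k=k,
                               algorithm="som", seed=seed, grid_shape=grid)
    elif algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X) + 1
        result = ClusterResult(labels=pd.Series(labels, index=values.index), k=k,
                               algorithm="kmeans", seed=seed)
    else:
        raise ValidationError(f"unknown clustering algorithm {algorithm!r}")
    med = values.groupby(result.labels).median()
    result.medians = med.reindex(range(1, k + 1))
    return result


def _default_grid(k: int) -> tuple[int, int]:
    best = (1, k)
    for r in range(1, int(np.sqrt(k)) + 1):
        if k % r == 0:
            best = (r, k // r)
    return best
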