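"""Ordination: PCA on macro-haplogroup frequencies and classical (Torgerson)
metric MDS on population distance matrices.

Both are implemented as explicit eigendecompositions so the conventions are
fully specified: PCA centres columns without variance scaling (frequencies
already share a unit); MDS double-centres the squared distance matrix. Axis
signs are arbitrary in both methods, so a deterministic rule is imposed: the
largest-magnitude loading (PCA) or coordinate (MDS) on each axis is made
positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # rows = populations, columns = axis1..k
    explained: np.ndarray  # per-axis variance / eigenvalue fraction
    method: str


def build_frequency_matrix(
    classifications: pd.DataFrame,
    min_n: int = 30,
    macro_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Population x macro-haplogroup relative-frequency matrix.

    *classifications* needs columns ``population`` and ``macro``. Populations
    with fewer than *min_n* samples are excluded (logged).
    """
    sizes = classifications.groupby("population").size()
    keep = sizes[sizes >= min_n].index
    for pop in sizes.index.difference(keep):
        logger.warning("excluding population %r (n=%d < %d)", pop, sizes[pop], min_n)
    if len(keep) == 0:
        raise ValueError("no population meets the minimum size")
    sub = classifications[classifications["population"].isin(keep)]
    counts = sub.groupby(["population", "macro"]).size().unstack(fill_value=0)
    if macro_labels is not None:
        counts = counts.reindex(columns=macro_labels, fill_value=0)
    freq = counts.div(counts.sum(axis=1), axis=0)
    return freq


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    flip = np.sign(vectors[np.abs(vectors).argmax(axis=0), np.arange(vectors.shape[1])])
    flip[flip == 0] = 1.0
    return vectors * flip


def pca(freq: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Column-centred (unscaled) PCA of a frequency matrix."""
    X = freq.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    if n_axes > min(n - 1, p):
        raise ValueError(f"n_axes={n_axes} exceeds min(rows-1, cols)")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0, None)
    total = eigvals.sum()
    eigvecs = _fix_signs(eigvecs[:, :n_axes])
    scores = Xc @ eigvecs
    explained = (eigvals[:n_axes] / total) if total > 0 else np.zeros(n_axes)
    coords = pd.DataFrame(
        scores,
        index=freq.index,
        columns=[f"axis{i+1}" for i in range(n_axes)],
    )
    return OrdinationResult(coords, explained, "pca")


def classical_mds(dist: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Torgerson metric MDS: eigendecomposition of -1/2 J D^2 J."""
    D = dist.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12
    if not pos.any():
        raise ValueError("distance matrix has no positive eigenvalue")
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        logger.warning(
            "requested %d axes but only %d positive eigenvalues; truncating",
            n_axes,
            n_pos,
        )
        n_axes = n_pos
    coords_arr = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    coords_arr = _fix_signs(coords_arr)
    explained = eigvals[:n_axes] / eigvals[:n_pos].sum()
    coords = pd.DataFrame(
        coords_arr,
        index=dist.labels,
        columns=[f"axis{i+1}" for i in range(n_axes)],
    )
    return OrdinationResult(coords, explained, "mds")
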