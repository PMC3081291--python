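"""Spatial segmentation of MSI feature matrices.

The segmentation recipe: mean-center the pixels x bins matrix, project onto
the leading principal components, cluster the scores agglomeratively (Ward
linkage on Euclidean distances by default), cut the dendrogram into k
branches, and paint each pixel of each section with its branch. The
dendrogram bookkeeping (per-branch spectrum counts and branch distances)
mirrors how such trees are annotated in imaging-MS reports.

The number of components kept defaults to the smallest k explaining >= 70%
of the variance, capped at 20; linkage and metric are configurable because
the upstream convention fixes neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .preprocess import FeatureMatrix

__all__ = [
    "PCAResult",
    "Dendrogram",
    "SegmentationMap",
    "pca",
    "n_components_for_variance",
    "hcluster",
    "cut_tree",
    "segmentation_image",
    "section_heatmap",
    "PALETTE",
]

#: fixed branch palette (RGB, 0-1): red, green, blue, orange, purple, teal...
PALETTE = (
    (0.839, 0.153, 0.157),
    (0.173, 0.627, 0.173),
    (0.122, 0.467, 0.706),
    (1.000, 0.498, 0.055),
    (0.580, 0.404, 0.741),
    (0.090, 0.745, 0.812),
    (0.737, 0.741, 0.133),
    (0.550, 0.337, 0.294),
)


@dataclass
class PCAResult:
    """Scores, loadings and variance bookkeeping of a PCA.

    ``scores @ loadings.T + mean`` reconstructs the input when k is the full
    rank. ``rank_truncated`` flags a request for more components than the
    data's rank.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    total_variance: float
    mean: np.ndarray
    rank_truncated: bool = False


def pca(matrix: FeatureMatrix | np.ndarray, k: int) -> PCAResult:
    """PCA by SVD of the column-mean-centered matrix.

    Deterministic sign convention: each loading column is flipped so its
    largest-magnitude element is positive. A ``k`` beyond the numerical rank
    is truncated at the rank with ``rank_truncated=True``.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix must be finite")
    n, p = X.shape
    if k < 1 or k > min(n, p):
        raise ValueError(f"k must lie in [1, {min(n, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max(initial=0.0) * max(n, p) * np.finfo(float).eps
    rank = int(np.sum(S > tol))
    truncated = k > rank
    k_eff = min(k, max(rank, 1))
    U, S, Vt = U[:, :k_eff], S[:k_eff], Vt[:k_eff]
    # sign convention: largest-|loading| element positive per component
    flip = np.sign(Vt[np.arange(k_eff), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    denom = max(n - 1, 1)
    return PCAResult(
        scores=U * S,
        loadings=Vt.T,
        explained_variance=S**2 / denom,
        total_variance=float(np.sum(Xc**2) / denom),
        mean=mean,
        rank_truncated=truncated,
    )


def n_components_for_variance(
    result_or_matrix, threshold: float = 0.7, cap: int = 20
) -> int:
    """Smallest k whose cumulative explained variance reaches ``threshold``."""
    if isinstance(result_or_matrix, PCAResult):
        ev, total = result_or_matrix.explained_variance, result_or_matrix.total_variance
    else:
        X = (
            result_or_matrix.values
            if isinstance(result_or_matrix, FeatureMatrix)
            else np.asarray(result_or_matrix, float)
        )
        full = pca(X, min(X.shape))
        ev, total = full.explained_variance, full.total_variance
    if total == 0:
        return 1
    frac = np.cumsum(ev) / total
    k = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    return int(min(max(k, 1), cap, len(ev)))


@dataclass
class Dendrogram:
    """Agglomerative merge tree over n observations.

    ``merges`` is the (n-1, 4) scipy-style linkage array: row i merges nodes
    ``a``, ``b`` (leaves are 0..n-1, internal nodes n+i) at ``distance`` into
    a branch of ``new_size`` spectra.
    """

    merges: np.ndarray
    n_leaves: int
    linkage: str = "ward"

    @property
    def branch_counts(self) -> np.ndarray:
        return self.merges[:, 3].astype(int)

    @property
    def branch_distances(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> np.ndarray:
        return hierarchy.leaves_list(self.merges)

    def to_newick(self) -> str:
        """Nested-parenthesis serialization with branch distances."""
        n = self.n_leaves
        nodes: dict[int, str] = {i: str(i) for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for i, (a, b, d, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(0.0, d - heights[a])
            lb = max(0.0, d - heights[b])
            nodes[n + i] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
            heights[n + i] = d
        return nodes[n + len(self.merges) - 1] + ";"


def hcluster(
    scores: np.ndarray, linkage: str = "ward", metric: str = "euclidean"
) -> Dendrogram:
    """Agglomerative clustering of PCA scores (or any observation matrix)."""
    X = np.asarray(scores, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations to cluster")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError("linkage must be 'ward', 'average' or 'complete'")
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage)
    return Dendrogram(merges=Z, n_leaves=X.shape[0], linkage=linkage)


def cut_tree(
    dendrogram: Dendrogram,
    k_clusters: int | None = None,
    distance_threshold: float | None = None,
) -> np.ndarray:
    """Flat labels from the dendrogram, by undoing the last k-1 merges (or
    cutting at a distance). Labels are renumbered deterministically in order
    of each cluster's first leaf index, starting at 0."""
    if (k_clusters is None) == (distance_threshold is None):
        raise ValueError("give exactly one of k_clusters or distance_threshold")
    n = dendrogram.n_leaves
    if k_clusters is not None:
        if not 1 <= k_clusters <= n:
            raise ValueError(f"k_clusters must lie in [1, {n}]")
        raw = hierarchy.fcluster(dendrogram.merges, t=k_clusters, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(dendrogram.merges, t=distance_threshold, criterion="distance")
    labels = np.asarray(raw)
    remap: dict[int, int] = {}
    for lab in labels:  # first-leaf order
        if lab not in remap:
            remap[lab] = len(remap)
    return np.array([remap[lab] for lab in labels], dtype=int)


@dataclass
class SegmentationMap:
    """Per-section cluster-label images; excluded pixels are -1.

    ``images`` maps section index -> (height, width) int array; ``palette``
    maps cluster id -> RGB.
    """

    images: dict[int, np.ndarray]
    n_clusters: int
    palette: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    def included_counts(self) -> dict[int, int]:
        return {sec: int((img >= 0).sum()) for sec, img in self.images.items()}


def segmentation_image(
    labels: np.ndarray,
    row_index: list[tuple[int, int, int]],
    width: int,
    height: int,
) -> SegmentationMap:
    """Paint cluster labels back onto the per-section pixel grids.

    Pixels absent from ``row_index`` (background, or spectra excluded during
    normalization — sections may carry different included-pixel counts) are
    marked -1.
    """
    if len(labels) != len(row_index):
        raise ValueError("labels and row_index must align")
    images: dict[int, np.ndarray] = {}
    for lab, (sec, x, y) in zip(labels, row_index):
        if not (0 <= x < width and 0 <= y < height):
            raise ValueError(f"pixel ({x}, {y}) outside the {width}x{height} grid")
        img = images.setdefault(sec, np.full((height, width), -1, dtype=int))
        img[y, x] = int(lab)
    k = int(labels.max()) + 1 if len(labels) else 0
    palette = {i: PALETTE[i % len(PALETTE)] for i in range(k)}
    return SegmentationMap(images=images, n_clusters=k, palette=palette)


def section_heatmap(matrix: FeatureMatrix) -> tuple[np.ndarray, list[int]]:
    """Stacked-spectra display: rows grouped in per-section bands, scaled 0-100.

    Returns the display matrix (rows ordered by section, values as percent of
    the global maximum so the color scale reads 0% black to 100% white) and
    the list of band boundary rows (the first row of each section after the
    first).
    """
    sections = [r[0] for r in matrix.row_index]
    order = np.argsort(np.array(sections), kind="stable")
    vals = matrix.values[order]
    top = vals.max()
    display = vals * (100.0 / top) if top > 0 else vals.copy()
    boundaries = []
    sorted_secs = [sections[i] for i in order]
    for i in range(1, len(sorted_secs)):
        if sorted_secs[i] != sorted_secs[i - 1]:
            boundaries.append(i)
    return display, boundaries
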