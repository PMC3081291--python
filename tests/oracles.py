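"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive (quadratic/cubic loops, explicit
formulas) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def classify_pixels(spec) -> dict[str, int]:
    """Per-region pixel counts by looping over every pixel individually."""
    from leechmsi.phantom import RegionLabel

    counts = {r.name: 0 for r in RegionLabel}
    cx, cy = spec.disc_center
    for y in range(spec.height):
        for x in range(spec.width):
            r = ((x - cx) ** 2 + (y - cy) ** 2) ** 0.5
            label = RegionLabel.BACKGROUND
            if r <= spec.disc_radius:
                label = (
                    RegionLabel.GANGLION_ANTERIOR if y < cy else RegionLabel.GANGLION_POSTERIOR
                )
            if spec.neuropil_radius and r <= spec.neuropil_radius:
                label = RegionLabel.NEUROPIL
            if spec.annulus_inner is not None and spec.annulus_inner <= r <= spec.annulus_outer:
                label = RegionLabel.SINUS_ANNULUS
            counts[label.name] += 1
    return counts


def agglomerate(X: np.ndarray, linkage: str) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomerative clustering recomputing every cluster pair each
    step from the raw points. Returns the merge sequence as
    (leafset_a, leafset_b, distance) with the lowest-index pair chosen on
    ties. Linkage distances use the textbook definitions: complete = max
    pairwise Euclidean distance, average = mean pairwise distance, ward =
    sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||."""
    X = np.asarray(X, float)
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                pts_a, pts_b = X[sorted(a)], X[sorted(b)]
                if linkage == "complete":
                    d = max(
                        float(np.linalg.norm(p - q)) for p in pts_a for q in pts_b
                    )
                elif linkage == "average":
                    d = float(
                        np.mean([np.linalg.norm(p - q) for p in pts_a for q in pts_b])
                    )
                elif linkage == "ward":
                    na, nb = len(a), len(b)
                    d = float(
                        np.sqrt(2.0 * na * nb / (na + nb))
                        * np.linalg.norm(pts_a.mean(0) - pts_b.mean(0))
                    )
                else:
                    raise ValueError(linkage)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] | clusters[j]
        ]
    return merges


def linkage_to_leafsets(Z: np.ndarray, n: int) -> list[tuple[frozenset, frozenset, float]]:
    """Convert a scipy-style linkage array to the oracle's merge format."""
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, d, _) in enumerate(Z):
        fa, fb = sets[int(a)], sets[int(b)]
        out.append((fa, fb, float(d)))
        sets[n + k] = fa | fb
    return out


def covariance_pca(X: np.ndarray):
    """PCA via explicit covariance matrix + eigendecomposition.

    Returns (explained variances descending, loadings columns) with the same
    sign convention as the implementation (largest-|element| positive).
    """
    X = np.asarray(X, float)
    Xc = X - X.mean(axis=0)
    C = (Xc.T @ Xc) / max(len(X) - 1, 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    return w, V
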