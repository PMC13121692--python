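"""Independent brute-force oracles used to validate the analysis code.

These deliberately avoid the implementation paths they check: the
superposition oracle scans rotations on an Euler-angle grid instead of
solving the least-squares problem, and the clustering oracle is a direct
textbook DBSCAN (neighbourhood graph + BFS over core points).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation


def grid_rmsd_oracle(
    mobile: np.ndarray,
    reference: np.ndarray,
    coarse_deg: float = 4.0,
    fine_deg: float = 1.0,
) -> float:
    """Best superposition RMSD by exhaustive Euler-angle grid search.

    A coarse global zyz grid locates the basin; a fine local grid
    (resolution ``fine_deg``, default 1 degree) refines it.  Translation
    is handled exactly by centroid removal, so only rotations are
    searched.  The returned value is an upper bound on the true optimum,
    tight to the grid resolution.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def best_on(grid: np.ndarray) -> tuple[float, np.ndarray]:
        rots = Rotation.from_euler("zyz", grid, degrees=True).as_matrix()
        moved = np.einsum("rij,nj->rni", rots, mob)
        rms = np.sqrt(((moved - ref) ** 2).sum(axis=2).mean(axis=1))
        k = int(np.argmin(rms))
        return float(rms[k]), grid[k]

    a = np.arange(0.0, 360.0, coarse_deg)
    b = np.arange(0.0, 180.0 + coarse_deg, coarse_deg)
    grid = np.array(np.meshgrid(a, b, a)).reshape(3, -1).T
    best, ang = best_on(grid)
    loc = [np.arange(x - coarse_deg, x + coarse_deg + 1e-9, fine_deg) for x in ang]
    grid = np.array(np.meshgrid(*loc)).reshape(3, -1).T
    best_fine, _ = best_on(grid)
    return min(best, best_fine)


def dbscan_oracle(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Textbook DBSCAN labelling (-1 = noise).

    A point is core when its eps-neighbourhood (including itself) holds
    at least ``min_samples`` points; clusters are connected components of
    core points under eps-adjacency; border points join the first cluster
    (in scan order) with a core neighbour.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    current = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        # BFS over core connectivity
        labels[i] = current
        stack = [i]
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = current
                    if core[k]:
                        stack.append(k)
        current += 1
    return labels


def core_mask(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return (d <= eps).sum(axis=1) >= min_samples


def partitions_equal(labels_a: np.ndarray, labels_b: np.ndarray,
                     restrict: np.ndarray | None = None) -> bool:
    """True when two labelings induce the same partition (up to renaming)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if restrict is not None:
        a, b = a[restrict], b[restrict]
    if not np.array_equal(a == -1, b == -1):
        return False
    sets_a = {frozenset(np.flatnonzero(a == lab)) for lab in set(a) - {-1}}
    sets_b = {frozenset(np.flatnonzero(b == lab)) for lab in set(b) - {-1}}
    return sets_a == sets_b


def ar1(rng: np.random.Generator, n: int, phi: float, sigma: float = 1.0) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation sigma."""
    innov = rng.standard_normal(n)
    return lfilter([sigma * np.sqrt(1.0 - phi**2)], [1.0, -phi], innov)
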