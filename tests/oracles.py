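"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorized/convolution/KD-tree code paths of
the package: densities are per-cube neighborhood sums, the membrane is a
hand-rolled BFS, and DisTP is a full distance enumeration.
"""

from collections import deque

import numpy as np


def knn_mean_distance(coords: np.ndarray, k: int) -> float:
    """Mean distance to the k-th nearest other particle, all-pairs O(n^2)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    total = 0.0
    for i in range(n):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        d = np.sort(np.delete(d, i))
        total += d[k - 1]
    return total / n


def _ball_offsets(radius: int) -> np.ndarray:
    offs = []
    for dz in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                if dz * dz + dy * dy + dx * dx <= radius * radius:
                    offs.append((dz, dy, dx))
    return np.asarray(offs)


def density_oracle(counts: np.ndarray, smooth_range: int) -> np.ndarray:
    """Per-cube exhaustive evaluation of the smoothed-density sum."""
    counts = np.asarray(counts, dtype=float)
    shape = counts.shape
    offs = _ball_offsets(smooth_range)
    weights = 1.0 / np.maximum(np.sqrt((offs**2).sum(axis=1)), 1.0)
    out = np.zeros(shape)
    for i in np.ndindex(shape):
        j = offs + np.asarray(i)
        inside = (
            (j[:, 0] >= 0) & (j[:, 0] < shape[0])
            & (j[:, 1] >= 0) & (j[:, 1] < shape[1])
            & (j[:, 2] >= 0) & (j[:, 2] < shape[2])
        )
        jj = j[inside]
        out[i] = (counts[jj[:, 0], jj[:, 1], jj[:, 2]] * weights[inside]).sum() / inside.sum()
    return out


def membrane_oracle(
    counts: np.ndarray, min_particles: int = 3, window: int = 5
) -> np.ndarray:
    """Flood fill over the 1-cube-padded grid, by explicit BFS.

    Traversable iff the window^3 Chebyshev-neighborhood particle total is
    below min_particles; fill is face-adjacent and starts from every
    traversable pad cube.
    """
    padded = np.pad(np.asarray(counts), 1)
    shape = padded.shape
    r = (window - 1) // 2

    def window_total(i):
        z0, y0, x0 = (max(c - r, 0) for c in i)
        z1, y1, x1 = (min(c + r + 1, s) for c, s in zip(i, shape))
        return padded[z0:z1, y0:y1, x0:x1].sum()

    traversable = np.zeros(shape, dtype=bool)
    for i in np.ndindex(shape):
        traversable[i] = window_total(i) < min_particles

    membrane = np.zeros(shape, dtype=bool)
    queue: deque = deque()
    for i in np.ndindex(shape):
        on_border = any(c == 0 or c == s - 1 for c, s in zip(i, shape))
        if on_border and traversable[i] and not membrane[i]:
            membrane[i] = True
            queue.append(i)
    faces = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in faces:
            n = (z + dz, y + dy, x + dx)
            if all(0 <= c < s for c, s in zip(n, shape)):
                if traversable[n] and not membrane[n]:
                    membrane[n] = True
                    queue.append(n)
    return membrane


def distp_oracle(
    counts: np.ndarray, membrane_padded: np.ndarray, top_k: int = 10
) -> np.ndarray:
    """Mean of the top_k smallest distances to membrane cubes, by full
    enumeration over every membrane cube."""
    counts = np.asarray(counts)
    mem = np.argwhere(membrane_padded).astype(float)
    out = np.full(counts.shape, np.nan)
    core = membrane_padded[1:-1, 1:-1, 1:-1]
    for i in np.ndindex(counts.shape):
        if counts[i] <= 0 or core[i]:
            continue
        p = np.asarray(i, dtype=float) + 1.0  # padded coordinates
        d = np.sqrt(((mem - p) ** 2).sum(axis=1))
        d.sort()
        out[i] = d[:top_k].mean()
    return out


def ward_merge_sequence(points: np.ndarray) -> list[frozenset]:
    """Greedy Ward agglomeration by exhaustive evaluation of the
    within-cluster sum-of-squares increase at every step."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        best_cost = np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = points[list(clusters[a])]
                cb = points[list(clusters[b])]
                na, nb = len(ca), len(cb)
                delta = (
                    na * nb / (na + nb)
                    * ((ca.mean(axis=0) - cb.mean(axis=0)) ** 2).sum()
                )
                if delta < best_cost:
                    best_cost = delta
                    best = (a, b)
        a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def scipy_merge_sequence(Z: np.ndarray, n: int) -> list[frozenset]:
    """Merge sets in order from a scipy linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append(merged)
    return merges


def weighted_variance(values: np.ndarray, weights: np.ndarray) -> float:
    m = float((weights * values).sum() / weights.sum())
    return float((weights * (values - m) ** 2).sum() / weights.sum())


def sort_quantile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile computed directly from the sorted array."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)
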