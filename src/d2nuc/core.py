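"""Geometric core: mesh segmentation, smoothed density, membrane detection,
and distance-to-periphery (DisTP).

All cube-level distances are Euclidean distances between integer cube
indices (cube centers) and are reported in cube-length units; nothing is
rescaled back to the reconstruction's physical unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from d2nuc.structures import D2_COLUMNS, GenomeStructure

logger = logging.getLogger(__name__)

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class ScoreParams:
    """Tunables of the per-cell geometry pipeline (defaults as published)."""

    knn: int = 7
    smooth_range: int = 3
    membrane_min_particles: int = 3
    membrane_window: int = 5
    distp_k: int = 10


@dataclass
class CubeGrid:
    """Voxelization of one cell.

    ``counts`` has ``shape``; ``membrane`` lives on a 1-cube-padded grid
    (``shape + 2``); ``density`` and ``distp`` are per-cube fields on the
    unpadded grid (``distp`` is NaN outside filled, non-membrane cubes).
    """

    origin: np.ndarray
    cube_length: float
    shape: tuple[int, int, int]
    counts: np.ndarray = field(repr=False)
    density: np.ndarray | None = field(default=None, repr=False)
    membrane: np.ndarray | None = field(default=None, repr=False)
    distp: np.ndarray | None = field(default=None, repr=False)

    @property
    def membrane_core(self) -> np.ndarray:
        """Membrane mask restricted to the unpadded grid."""
        if self.membrane is None:
            raise ValueError("membrane not computed")
        return self.membrane[1:-1, 1:-1, 1:-1]

    def particle_cubes(self, coords: np.ndarray) -> np.ndarray:
        """(n, 3) integer cube index per coordinate row."""
        return np.floor((coords - self.origin) / self.cube_length).astype(np.int64)


def compute_cube_length(structure: GenomeStructure | np.ndarray, k: int = 7) -> float:
    """Cell-specific cube length: mean distance from every particle to its
    k-th nearest other particle."""
    coords = structure.coords if isinstance(structure, GenomeStructure) else np.asarray(structure, dtype=float)
    n = len(coords)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} particles for k={k}, got {n}")
    tree = cKDTree(coords)
    # +1 because the query point itself is returned at distance 0
    dists, _ = tree.query(coords, k=k + 1)
    return float(dists[:, k].mean())


def build_mesh(structure: GenomeStructure | np.ndarray, cube_length: float) -> CubeGrid:
    """Partition particles into equally shaped cubes of side ``cube_length``.

    The origin is the per-axis minimum coordinate, so a particle exactly at
    the origin falls in cube (0, 0, 0).
    """
    if cube_length <= 0:
        raise ValueError(f"cube_length must be positive, got {cube_length}")
    coords = structure.coords if isinstance(structure, GenomeStructure) else np.asarray(structure, dtype=float)
    origin = coords.min(axis=0)
    idx = np.floor((coords - origin) / cube_length).astype(np.int64)
    shape = tuple(int(s) for s in idx.max(axis=0) + 1)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return CubeGrid(origin=origin, cube_length=float(cube_length), shape=shape, counts=counts)


def _ball_offsets(radius: int) -> np.ndarray:
    """Integer offsets with Euclidean norm <= radius (the smoothing set S)."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([dz.ravel(), dy.ravel(), dx.ravel()], axis=1)
    keep = (offs**2).sum(axis=1) <= radius**2
    return offs[keep]


def _ball_kernel(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """(weight kernel, membership kernel) for the smoothing neighborhood."""
    r = int(radius)
    size = 2 * r + 1
    weights = np.zeros((size, size, size))
    member = np.zeros((size, size, size))
    for off in _ball_offsets(radius):
        d = float(np.linalg.norm(off))
        weights[tuple(off + r)] = 1.0 / max(d, 1.0)
        member[tuple(off + r)] = 1.0
    return weights, member


def compute_density(grid: CubeGrid, smooth_range: int = 3) -> np.ndarray:
    """Smoothed DNA density per cube.

    D_i = (sum over in-grid cubes j with ||i-j|| <= smooth_range of
    C_j / max(||i-j||, 1)) / num(S), where num(S) counts all in-grid cubes
    of the neighborhood, empty ones included.  The self term (j = i) uses
    weight 1 instead of the singular 1/0.
    """
    if smooth_range < 0:
        raise ValueError(f"smooth_range must be >= 0, got {smooth_range}")
    weights, member = _ball_kernel(smooth_range)
    counts = grid.counts.astype(float)
    numerator = ndimage.convolve(counts, weights, mode="constant", cval=0.0)
    in_grid = np.ones_like(counts)
    n_s = ndimage.convolve(in_grid, member, mode="constant", cval=0.0)
    grid.density = numerator / n_s
    return grid.density


def detect_membrane(
    grid: CubeGrid, min_particles: int = 3, window: int = 5
) -> np.ndarray:
    """Label membrane cubes by flood fill over the 1-cube-padded grid.

    A cube is traversable iff the particle total over its window^3 Chebyshev
    neighborhood is below ``min_particles``; the membrane is the traversable
    region connected (face adjacency) to the outside padding, so faraway
    cubes holding only one or two outlier particles become membrane while
    enclosed cavities never do.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    padded = np.pad(grid.counts, 1).astype(float)
    kernel = np.ones((window, window, window))
    local_total = ndimage.convolve(padded, kernel, mode="constant", cval=0.0)
    traversable = local_total < min_particles

    labels, _ = ndimage.label(traversable, structure=_FACE_STRUCTURE)
    border = np.zeros_like(traversable)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    outside = np.unique(labels[border & traversable])
    outside = outside[outside != 0]
    grid.membrane = np.isin(labels, outside)
    return grid.membrane


def compute_distp(grid: CubeGrid, top_k: int = 10) -> np.ndarray:
    """DisTP per filled non-membrane cube: mean of the ``top_k`` smallest
    Euclidean index-distances to membrane cubes (cube-length units)."""
    if grid.membrane is None:
        raise ValueError("membrane not computed")
    membrane_idx = np.argwhere(grid.membrane)
    if len(membrane_idx) < top_k:
        raise ValueError(
            f"need at least {top_k} membrane cubes, found {len(membrane_idx)}"
        )
    filled = (grid.counts > 0) & ~grid.membrane_core
    distp = np.full(grid.shape, np.nan)
    targets = np.argwhere(filled)
    if len(targets):
        tree = cKDTree(membrane_idx.astype(float))
        # +1 moves unpadded indices into padded-grid coordinates
        dists, _ = tree.query(targets.astype(float) + 1.0, k=top_k)
        dists = np.atleast_2d(dists)
        distp[tuple(targets.T)] = dists.mean(axis=1)
    grid.distp = distp
    return distp


def score_cell(
    structure: GenomeStructure, params: ScoreParams | None = None
) -> pd.DataFrame:
    """Run the full per-cell geometry pipeline and return the D2 table.

    Each particle inherits the smoothed density and DisTP of its cube;
    particles landing in membrane cubes (dissociative outliers) are dropped
    and counted in ``table.attrs['n_dropped']``.
    """
    params = params or ScoreParams()
    cube_length = compute_cube_length(structure, k=params.knn)
    grid = build_mesh(structure, cube_length)
    compute_density(grid, smooth_range=params.smooth_range)
    detect_membrane(
        grid,
        min_particles=params.membrane_min_particles,
        window=params.membrane_window,
    )
    compute_distp(grid, top_k=params.distp_k)

    idx = grid.particle_cubes(structure.coords)
    cube = (idx[:, 0], idx[:, 1], idx[:, 2])
    keep = ~grid.membrane_core[cube]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d outlier particle(s) in membrane cubes",
            structure.cell_id,
            n_dropped,
        )
    df = structure.df.loc[keep].reset_index(drop=True)
    kept_cube = tuple(c[keep] for c in cube)
    table = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "hap": df["hap"],
            "start": df["pos"].astype(np.int64),
            "end": (df["pos"] + structure.resolution).astype(np.int64),
            "density": grid.density[kept_cube],
            "distp": grid.distp[kept_cube],
        }
    )[D2_COLUMNS]
    table.attrs["cell_id"] = structure.cell_id
    table.attrs["resolution"] = structure.resolution
    table.attrs["cube_length"] = cube_length
    table.attrs["n_dropped"] = n_dropped
    return table


def score_ensemble(
    structures: list[GenomeStructure], params: ScoreParams | None = None
) -> list[pd.DataFrame]:
    """Score every cell of an ensemble with shared parameters."""
    return [score_cell(s, params) for s in structures]
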