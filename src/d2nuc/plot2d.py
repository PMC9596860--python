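"""The D2 plot: axis bounds, the 15x15 state grid, and occupancy P_ga.

A physical state is one (density-bin, DisTP-bin) pair; its flat index is
``density_bin * nbins + distp_bin``.  States occupied by fewer than
``min_segments`` (segment, cell) occurrences are flagged empty and excluded
from every downstream statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

SEGMENT_KEY = ["chrom", "hap", "bin"]


class _Outlier:
    """Sentinel for values falling outside the axis bounds."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "OUTLIER"


OUTLIER = _Outlier()


@dataclass(frozen=True)
class AxisBounds:
    """Axis ranges of the D2 plot (density x DisTP)."""

    density_lo: float
    density_hi: float
    distp_lo: float
    distp_hi: float
    source: str = "standard"

    def __post_init__(self) -> None:
        if not (self.density_lo < self.density_hi and self.distp_lo < self.distp_hi):
            raise ValueError(f"degenerate axis bounds: {self}")


def standard_diploid_bounds() -> AxisBounds:
    """The fixed range shared by all diploid cell types."""
    return AxisBounds(1.0, 3.2, 1.21, 16.0, source="standard")


def fit_bounds(cell_tables: list[pd.DataFrame]) -> AxisBounds:
    """Fit axis bounds from pooled per-particle values.

    Density keeps the central 95% (mean +/- 1.96 SD); DisTP keeps everything
    from the periphery up to the 95th percentile.
    """
    density = np.concatenate([t["density"].to_numpy() for t in cell_tables])
    distp = np.concatenate([t["distp"].to_numpy() for t in cell_tables])
    if density.size == 0:
        raise ValueError("no pooled values")
    sd = float(density.std())
    if sd == 0.0:
        raise ValueError("zero density variance; cannot fit bounds")
    mu = float(density.mean())
    return AxisBounds(
        density_lo=mu - 1.96 * sd,
        density_hi=mu + 1.96 * sd,
        distp_lo=float(distp.min()),
        distp_hi=float(np.quantile(distp, 0.95)),
        source="fitted",
    )


def _axis_bin(values: np.ndarray, lo: float, hi: float, nbins: int) -> np.ndarray:
    """Left-closed right-open binning with a closed top edge; -1 = outlier."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite value passed to state assignment")
    b = np.floor(nbins * (values - lo) / (hi - lo)).astype(np.int64)
    b[values == hi] = nbins - 1
    b[(values < lo) | (values > hi)] = -1
    return b


def assign_states(
    density: np.ndarray,
    distp: np.ndarray,
    bounds: AxisBounds,
    nbins: int = 15,
) -> np.ndarray:
    """Vectorized state assignment: flat state index per row, -1 for outliers."""
    di = _axis_bin(density, bounds.density_lo, bounds.density_hi, nbins)
    pj = _axis_bin(distp, bounds.distp_lo, bounds.distp_hi, nbins)
    flat = di * nbins + pj
    flat[(di < 0) | (pj < 0)] = -1
    return flat


def assign_state(
    density: float, distp: float, bounds: AxisBounds, nbins: int = 15
):
    """State index (density_bin, distp_bin) for one observation, or OUTLIER."""
    flat = assign_states(np.array([density]), np.array([distp]), bounds, nbins)[0]
    if flat < 0:
        return OUTLIER
    return (int(flat) // nbins, int(flat) % nbins)


@dataclass
class D2Plot:
    """The state grid with per-state occurrence counts and the empty mask."""

    bounds: AxisBounds
    nbins: int
    state_counts: np.ndarray = field(repr=False)  # (nbins**2,) occurrences
    min_segments: int = 200

    @property
    def n_states(self) -> int:
        return self.nbins**2

    @property
    def empty(self) -> np.ndarray:
        """States excluded from downstream statistics."""
        return self.state_counts < self.min_segments

    @property
    def nonempty_states(self) -> np.ndarray:
        return np.flatnonzero(~self.empty)

    def state_coords(self, states: np.ndarray | None = None) -> pd.DataFrame:
        """Bin indices and bin-center values for the given flat state ids."""
        if states is None:
            states = np.arange(self.n_states)
        states = np.asarray(states)
        di, pj = states // self.nbins, states % self.nbins
        b = self.bounds
        dw = (b.density_hi - b.density_lo) / self.nbins
        pw = (b.distp_hi - b.distp_lo) / self.nbins
        return pd.DataFrame(
            {
                "state": states,
                "density_bin": di,
                "distp_bin": pj,
                "density_center": b.density_lo + (di + 0.5) * dw,
                "distp_center": b.distp_lo + (pj + 0.5) * pw,
            }
        )

    def counts_grid(self) -> np.ndarray:
        return self.state_counts.reshape(self.nbins, self.nbins)


@dataclass
class OccupancyMatrix:
    """P_ga over segments x states: the fraction of cells in which segment g
    was observed at state a (denominator = total cell count)."""

    segments: pd.DataFrame = field(repr=False)  # columns chrom, hap, bin
    P: sparse.csr_matrix = field(repr=False)
    n_cells: int = 0
    resolution: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def row_index(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.segments[SEGMENT_KEY])


def _table_resolution(table: pd.DataFrame) -> int:
    res = table.attrs.get("resolution")
    if res:
        return int(res)
    return int((table["end"] - table["start"]).iloc[0])


def build_occupancy(
    cell_tables: list[pd.DataFrame],
    bounds: AxisBounds,
    nbins: int = 15,
    min_segments: int = 200,
) -> tuple[D2Plot, OccupancyMatrix]:
    """Assemble the D2 plot and occupancy matrix from per-cell tables.

    Out-of-bounds observations are dropped (outliers); states with fewer
    than ``min_segments`` (segment, cell) occurrences are flagged empty and
    their P columns zeroed for downstream use (raw counts are kept in the
    plot for audit).
    """
    if not cell_tables:
        raise ValueError("need at least one cell table")
    resolutions = {_table_resolution(t) for t in cell_tables}
    if len(resolutions) != 1:
        raise ValueError(f"inconsistent resolutions across cells: {sorted(resolutions)}")
    resolution = resolutions.pop()
    n_cells = len(cell_tables)

    frames = []
    for ci, t in enumerate(cell_tables):
        states = assign_states(
            t["density"].to_numpy(), t["distp"].to_numpy(), bounds, nbins
        )
        keep = states >= 0
        frames.append(
            pd.DataFrame(
                {
                    "chrom": t["chrom"].to_numpy()[keep],
                    "hap": t["hap"].to_numpy()[keep],
                    "bin": t["start"].to_numpy()[keep] // resolution,
                    "state": states[keep],
                }
            )
        )
    obs = pd.concat(frames, ignore_index=True)

    seg_codes, seg_index = pd.factorize(
        pd.MultiIndex.from_frame(obs[SEGMENT_KEY]), sort=True
    )
    counts = sparse.coo_matrix(
        (np.ones(len(obs)), (seg_codes, obs["state"].to_numpy())),
        shape=(len(seg_index), nbins**2),
    ).tocsr()

    state_counts = np.asarray(counts.sum(axis=0)).ravel()
    plot = D2Plot(
        bounds=bounds, nbins=nbins, state_counts=state_counts, min_segments=min_segments
    )

    P = counts.multiply(1.0 / n_cells).tocsr()
    if plot.empty.any():
        mask = sparse.diags((~plot.empty).astype(float))
        P = (P @ mask).tocsr()
    segments = pd.DataFrame(seg_index.to_list(), columns=SEGMENT_KEY)
    occ = OccupancyMatrix(
        segments=segments, P=P, n_cells=n_cells, resolution=resolution
    )
    return plot, occ


def save_occupancy(
    plot: D2Plot, occ: OccupancyMatrix, path: str | Path
) -> None:
    """Write occupancy as a TSV triplet table plus a JSON metadata sidecar."""
    path = Path(path)
    coo = occ.P.tocoo()
    seg = occ.segments.iloc[coo.row].reset_index(drop=True)
    pd.DataFrame(
        {
            "chrom": seg["chrom"],
            "hap": seg["hap"],
            "bin": seg["bin"],
            "state": coo.col,
            "p": coo.data,
        }
    ).to_csv(path, sep="\t", index=False)
    meta = {
        "nbins": plot.nbins,
        "min_segments": plot.min_segments,
        "n_cells": occ.n_cells,
        "resolution": occ.resolution,
        "bounds": {
            "density_lo": plot.bounds.density_lo,
            "density_hi": plot.bounds.density_hi,
            "distp_lo": plot.bounds.distp_lo,
            "distp_hi": plot.bounds.distp_hi,
            "source": plot.bounds.source,
        },
        "state_counts": plot.state_counts.tolist(),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_occupancy(path: str | Path) -> tuple[D2Plot, OccupancyMatrix]:
    """Read back artifacts written by :func:`save_occupancy`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    b = meta["bounds"]
    bounds = AxisBounds(
        b["density_lo"], b["density_hi"], b["distp_lo"], b["distp_hi"], b["source"]
    )
    plot = D2Plot(
        bounds=bounds,
        nbins=meta["nbins"],
        state_counts=np.asarray(meta["state_counts"], dtype=float),
        min_segments=meta["min_segments"],
    )
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    seg_codes, seg_index = pd.factorize(
        pd.MultiIndex.from_frame(df[SEGMENT_KEY]), sort=True
    )
    P = sparse.coo_matrix(
        (df["p"].to_numpy(), (seg_codes, df["state"].to_numpy())),
        shape=(len(seg_index), plot.n_states),
    ).tocsr()
    segments = pd.DataFrame(seg_index.to_list(), columns=SEGMENT_KEY)
    occ = OccupancyMatrix(
        segments=segments,
        P=P,
        n_cells=meta["n_cells"],
        resolution=meta["resolution"],
    )
    return plot, occ
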