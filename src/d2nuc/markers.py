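"""Genomic marker tracks indexed onto fixed-size bins, and their enrichment
over D2-plot physical states.

Raw track values are reduced to one value per genomic bin, z-scored
genome-wide into NV_g, and then weighted by the occupancy matrix P_ga:

    E_a  = sum_g P_ga * NV_g / sum_g P_ga            (per-state enrichment)
    E'_a = mean of NV_g over segments whose cross-cell mean density/DisTP
           lands in state a                           (mean-based variant)
    SD_a = sqrt(sum_g P_ga * (NV_g - E_a)^2 / sum_g P_ga)

Unphased tracks are duplicated onto both haplotypes at lookup time.
Segments with missing NV are excluded from numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from d2nuc.plot2d import D2Plot, OccupancyMatrix, assign_states

BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]


class MarkerTrack:
    """A marker reduced to one raw value per genomic bin.

    ``values`` holds columns chrom, [hap,] bin, value.  ``nv`` (the z-scored
    normalized value) is computed lazily so constant single-bin tracks are
    representable; using a constant track for enrichment raises.
    """

    def __init__(
        self,
        name: str,
        kind: str,  # signal | coverage_fraction | point_median
        values: pd.DataFrame,
        phased: bool = False,
        nv: pd.Series | None = None,
    ) -> None:
        self.name = name
        self.kind = kind
        self.values = values
        self.phased = phased
        self._nv = nv

    @property
    def nv(self) -> pd.Series:
        if self._nv is None:
            v = self.values["value"].to_numpy(dtype=float)
            finite = v[np.isfinite(v)]
            if finite.size == 0:
                self._nv = pd.Series(np.empty(0), dtype=float)
            else:
                sd = finite.std()
                if sd == 0.0:
                    raise ValueError(
                        f"track {self.name!r} is constant; z-scored NV undefined"
                    )
                self._nv = (self.values["value"] - finite.mean()) / sd
        return self._nv

    def nv_for(self, segments: pd.DataFrame) -> np.ndarray:
        """NV aligned to a (chrom, hap, bin) segment table; NaN = missing.

        Unphased tracks match on (chrom, bin) only, i.e. the same value is
        copied to both haplotypes.
        """
        keys = ["chrom", "hap", "bin"] if self.phased else ["chrom", "bin"]
        lut = self.values[[c for c in keys if c in self.values.columns]].copy()
        lut["nv"] = self.nv.to_numpy()
        merged = segments.reset_index(drop=True).merge(lut, on=keys, how="left")
        return merged["nv"].to_numpy(dtype=float)


def _read_intervals(source, columns: list[str]) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        df = pd.read_csv(
            source, sep="\t", header=None, comment="#", names=columns,
            usecols=range(len(columns)),
        )
    else:
        df = source.copy()
    df["chrom"] = df["chrom"].astype(str)
    return df


def _split_to_bins(intervals: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Explode intervals into (chrom, bin, overlap_len[, value]) rows."""
    start = intervals["start"].to_numpy(dtype=np.int64)
    end = intervals["end"].to_numpy(dtype=np.int64)
    if (start < 0).any():
        raise ValueError("negative interval coordinates")
    if (end <= start).any():
        raise ValueError("intervals must satisfy start < end")
    b0 = start // resolution
    b1 = (end - 1) // resolution
    reps = (b1 - b0 + 1).astype(np.int64)
    row = np.repeat(np.arange(len(intervals)), reps)
    offset = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    bins = b0[row] + offset
    bin_start = bins * resolution
    ov = np.minimum(end[row], bin_start + resolution) - np.maximum(
        start[row], bin_start
    )
    out = pd.DataFrame(
        {
            "chrom": intervals["chrom"].to_numpy()[row],
            "bin": bins,
            "overlap": ov,
        }
    )
    if "value" in intervals.columns:
        out["value"] = intervals["value"].to_numpy(dtype=float)[row]
    return out


def index_signal(intervals, resolution: int, name: str = "signal") -> MarkerTrack:
    """Weight-average a bedGraph-style signal into fixed-size bins.

    Bin value = sum(overlap_len * value) / sum(overlap_len); bins with no
    covered length are missing.
    """
    df = _read_intervals(intervals, BEDGRAPH_COLUMNS)
    if len(df) == 0:
        values = pd.DataFrame({"chrom": [], "bin": [], "value": []})
        return MarkerTrack(name=name, kind="signal", values=values)
    pieces = _split_to_bins(df, resolution)
    pieces["wv"] = pieces["overlap"] * pieces["value"]
    agg = pieces.groupby(["chrom", "bin"], as_index=False).agg(
        wv=("wv", "sum"), w=("overlap", "sum")
    )
    agg["value"] = agg["wv"] / agg["w"]
    return MarkerTrack(
        name=name, kind="signal", values=agg[["chrom", "bin", "value"]]
    )


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    out = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom"):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        new_group = starts > np.maximum.accumulate(
            np.concatenate([[-1], ends[:-1]])
        )
        gid = np.cumsum(new_group) - 1
        ms = pd.DataFrame({"gid": gid, "start": starts, "end": ends}).groupby("gid")
        merged = pd.DataFrame(
            {"start": ms["start"].min(), "end": ms["end"].max()}
        )
        merged["chrom"] = chrom
        out.append(merged)
    return pd.concat(out, ignore_index=True)[["chrom", "start", "end"]]


def index_coverage(
    intervals,
    resolution: int,
    name: str = "coverage",
    universe: pd.DataFrame | None = None,
) -> MarkerTrack:
    """Fraction of each bin covered by the union of an interval set.

    Overlapping intervals are merged first so covered bases are never double
    counted.  Only touched bins get a value unless a ``universe`` of
    (chrom, bin) rows is supplied, in which case untouched bins get 0.
    """
    df = _read_intervals(intervals, ["chrom", "start", "end"])
    if len(df):
        merged = _merge_intervals(df)
        pieces = _split_to_bins(merged, resolution)
        agg = pieces.groupby(["chrom", "bin"], as_index=False)["overlap"].sum()
        agg["value"] = agg["overlap"] / resolution
        values = agg[["chrom", "bin", "value"]]
    else:
        values = pd.DataFrame({"chrom": [], "bin": [], "value": []})
    if universe is not None:
        uni = universe[["chrom", "bin"]].drop_duplicates().copy()
        uni["chrom"] = uni["chrom"].astype(str)
        values = uni.merge(values, on=["chrom", "bin"], how="left")
        values["value"] = values["value"].fillna(0.0)
    return MarkerTrack(name=name, kind="coverage_fraction", values=values)


def filter_repeats(
    catalog: pd.DataFrame, min_occurrences: int = 20_000
) -> pd.DataFrame:
    """Keep only repeat families with strictly more than ``min_occurrences``
    genomic occurrences (low-count families are too sparse at bin scale)."""
    if len(catalog) == 0:
        return catalog.copy()
    counts = catalog["family"].value_counts()
    keep = counts.index[counts > min_occurrences]
    return catalog[catalog["family"].isin(keep)].reset_index(drop=True)


def index_point_median(
    sites, resolution: int, name: str = "cpg"
) -> MarkerTrack:
    """Per-bin median of per-site percentages; zero-read sites are dropped."""
    df = _read_intervals(sites, ["chrom", "pos", "reads", "percent"])
    df = df[df["reads"] > 0]
    if len(df) == 0:
        values = pd.DataFrame({"chrom": [], "bin": [], "value": []})
        return MarkerTrack(name=name, kind="point_median", values=values)
    df = df.assign(bin=df["pos"].to_numpy(dtype=np.int64) // resolution)
    agg = df.groupby(["chrom", "bin"], as_index=False)["percent"].median()
    agg = agg.rename(columns={"percent": "value"})
    return MarkerTrack(name=name, kind="point_median", values=agg)


@dataclass
class EnrichmentMap:
    """Per-state enrichment of one marker over the non-empty states."""

    name: str
    states: np.ndarray  # flat state ids (non-empty)
    e_raw: np.ndarray
    e: np.ndarray  # z-scored across states
    sd: np.ndarray | None = None

    def as_series(self, which: str = "e") -> pd.Series:
        return pd.Series(getattr(self, which), index=self.states, name=self.name)


def _zscore_states(values: np.ndarray, name: str) -> np.ndarray:
    sd = values.std()
    if sd == 0.0:
        warnings.warn(
            f"enrichment of {name!r} identical across states; z-scores set to 0",
            stacklevel=3,
        )
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def _weighted_state_scores(
    track: MarkerTrack, occ: OccupancyMatrix, plot: D2Plot
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(states, E_raw, weights, per-state weighted mean square) over
    non-empty states, excluding segments with missing NV."""
    seg = occ.segments.copy()
    nv = track.nv_for(seg)
    have = np.isfinite(nv)
    states = plot.nonempty_states
    P = occ.P[np.flatnonzero(have)][:, states]
    nv = nv[have]
    w = np.asarray(P.sum(axis=0)).ravel()
    if (w == 0).any():
        bad = states[w == 0]
        raise ValueError(
            f"non-empty state(s) {bad.tolist()} carry zero occupancy for "
            f"track {track.name!r}"
        )
    num = P.T @ nv
    e_raw = num / w
    m2 = (P.T @ (nv**2)) / w
    return states, e_raw, w, m2


def enrichment(
    track: MarkerTrack, occ: OccupancyMatrix, plot: D2Plot
) -> EnrichmentMap:
    """Occupancy-weighted marker enrichment per state, z-scored across the
    non-empty states."""
    states, e_raw, _, _ = _weighted_state_scores(track, occ, plot)
    return EnrichmentMap(
        name=track.name,
        states=states,
        e_raw=e_raw,
        e=_zscore_states(e_raw, track.name),
    )


def enrichment_sd(track: MarkerTrack, occ: OccupancyMatrix, plot: D2Plot) -> pd.Series:
    """Occupancy-weighted SD of NV around the raw enrichment, per state."""
    states, e_raw, _, m2 = _weighted_state_scores(track, occ, plot)
    var = np.maximum(m2 - e_raw**2, 0.0)
    return pd.Series(np.sqrt(var), index=states, name=f"{track.name}_sd")


def segment_means(cell_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cross-cell mean density and DisTP per (chrom, hap, bin) segment."""
    frames = []
    for t in cell_tables:
        res = t.attrs.get("resolution") or int((t["end"] - t["start"]).iloc[0])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": t["chrom"],
                    "hap": t["hap"],
                    "bin": t["start"] // res,
                    "density": t["density"],
                    "distp": t["distp"],
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    return pooled.groupby(["chrom", "hap", "bin"], as_index=False).agg(
        density=("density", "mean"), distp=("distp", "mean"), n_cells=("density", "size")
    )


def enrichment_mean_based(
    track: MarkerTrack, cell_tables: list[pd.DataFrame], plot: D2Plot
) -> EnrichmentMap:
    """Alternative enrichment: place each segment at the state of its
    cross-cell mean density/DisTP and average NV within states."""
    means = segment_means(cell_tables)
    state = assign_states(
        means["density"].to_numpy(), means["distp"].to_numpy(), plot.bounds, plot.nbins
    )
    nv = track.nv_for(means[["chrom", "hap", "bin"]])
    ok = (state >= 0) & np.isfinite(nv) & ~plot.empty[np.clip(state, 0, None)]
    grouped = (
        pd.DataFrame({"state": state[ok], "nv": nv[ok]})
        .groupby("state")["nv"]
        .mean()
    )
    states = grouped.index.to_numpy()
    e_raw = grouped.to_numpy()
    return EnrichmentMap(
        name=track.name,
        states=states,
        e_raw=e_raw,
        e=_zscore_states(e_raw, track.name),
    )


def gene_set_enrichment(
    bin_set: pd.DataFrame, occ: OccupancyMatrix, plot: D2Plot
) -> pd.Series:
    """Per-state occupancy ratio of a bin set over the all-segments background.

    Both distributions are normalized over the non-empty states; states with
    zero background are missing.
    """
    if len(bin_set) == 0:
        raise ValueError("empty bin set")
    keys = ["chrom", "hap", "bin"] if "hap" in bin_set.columns else ["chrom", "bin"]
    sel = bin_set[keys].drop_duplicates().copy()
    sel["chrom"] = sel["chrom"].astype(str)
    sel["_in"] = True
    merged = occ.segments.merge(sel, on=keys, how="left")
    member = merged["_in"].notna().to_numpy()
    if not member.any():
        raise ValueError("bin set shares no segments with the occupancy matrix")

    states = plot.nonempty_states
    fg = np.asarray(occ.P[np.flatnonzero(member)][:, states].sum(axis=0)).ravel()
    bg = np.asarray(occ.P[:, states].sum(axis=0)).ravel()
    fg_dist = fg / fg.sum()
    bg_dist = bg / bg.sum()
    ratio = np.divide(
        fg_dist, bg_dist, out=np.full_like(fg_dist, np.nan), where=bg_dist > 0
    )
    return pd.Series(ratio, index=states, name="ratio")


def enrichment_matrix(maps: list[EnrichmentMap], which: str = "e") -> pd.DataFrame:
    """States x markers matrix of (z-scored) enrichment scores."""
    return pd.concat([m.as_series(which) for m in maps], axis=1)
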