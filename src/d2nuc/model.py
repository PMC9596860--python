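"""Transcriptional-activation model over D2-plot states.

Ward clustering of the marker-enrichment matrix partitions the non-empty
states into four areas (active / intermediate / repress_histone /
repress_repeat); the per-segment activation index is the occupancy mass on
the active and intermediate areas; trajectory modes (CA / RA / CR) are
called from stage-wise activation-index quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import linregress, pearsonr

from d2nuc.plot2d import D2Plot, OccupancyMatrix

AREA_LABELS = ("active", "intermediate", "repress_histone", "repress_repeat")

#: transcription-marker panel used for state clustering (one panel entry of
#: the published 16 is unnamed in the text; the panel is user-configurable).
DEFAULT_MARKER_PANEL = [
    "Txn-St", "Txn-W", "Pr-Ac", "Pr-W", "En-St", "En-W",
    "H3K27ac", "H3K36me3", "H3K4me3", "H3K4me2", "Alu",
    "H3K9me3", "H3K27me3", "L1", "Ht-L",
]
DEFAULT_ACTIVE_MARKERS = ["Txn-St", "Pr-Ac", "En-St", "H3K27ac", "H3K4me3"]
DEFAULT_HISTONE_MARKERS = ["H3K9me3", "H3K27me3"]
DEFAULT_REPEAT_MARKERS = ["L1", "Ht-L"]


@dataclass
class AreaModel:
    """Cluster assignment and area label per non-empty state."""

    states: np.ndarray  # flat state ids
    cluster: np.ndarray  # 1..k
    labels: np.ndarray = field(repr=False)  # area label per state
    leaf_order: np.ndarray = field(default=None, repr=False)
    linkage: np.ndarray = field(default=None, repr=False)

    def states_of(self, *labels: str) -> np.ndarray:
        return self.states[np.isin(self.labels, labels)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"state": self.states, "cluster": self.cluster, "area": self.labels}
        )


def cluster_states(
    e_matrix: pd.DataFrame,
    k: int = 4,
    active_markers: list[str] | None = None,
    histone_markers: list[str] | None = None,
    repeat_markers: list[str] | None = None,
) -> AreaModel:
    """Ward-cluster states (rows) in marker-enrichment space and label areas.

    Clusters are ranked by their mean enrichment over the active-marker
    subset: top rank -> active, second -> intermediate; of the remaining two,
    the one whose repressive-histone mean exceeds its repeat mean (relative
    to the other cluster) -> repress_histone, the other -> repress_repeat.
    With k != 4, generic rank labels ``rank_1`` (most active) .. ``rank_k``
    are used instead.
    """
    if len(e_matrix) < k:
        raise ValueError(f"cannot cut {len(e_matrix)} states into {k} clusters")
    X = e_matrix.to_numpy(dtype=float)
    states = e_matrix.index.to_numpy()
    if k == 1:
        return AreaModel(
            states=states,
            cluster=np.ones(len(states), dtype=int),
            labels=np.array(["rank_1"] * len(states)),
        )
    Z = hierarchy.linkage(X, method="ward", optimal_ordering=True)
    cluster = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    leaf_order = hierarchy.leaves_list(Z)

    cols = list(e_matrix.columns)
    active = [m for m in (active_markers or DEFAULT_ACTIVE_MARKERS) if m in cols]
    if not active:
        active = cols
    act_score = {
        c: float(e_matrix.loc[cluster == c, active].to_numpy().mean())
        for c in np.unique(cluster)
    }
    ranked = sorted(act_score, key=act_score.get, reverse=True)

    labels = np.empty(len(states), dtype=object)
    if k == 4:
        histone = [m for m in (histone_markers or DEFAULT_HISTONE_MARKERS) if m in cols]
        repeat = [m for m in (repeat_markers or DEFAULT_REPEAT_MARKERS) if m in cols]
        labels[cluster == ranked[0]] = "active"
        labels[cluster == ranked[1]] = "intermediate"
        lo1, lo2 = ranked[2], ranked[3]

        def _pref(c: int) -> float:
            h = float(e_matrix.loc[cluster == c, histone].to_numpy().mean()) if histone else 0.0
            r = float(e_matrix.loc[cluster == c, repeat].to_numpy().mean()) if repeat else 0.0
            return h - r

        if _pref(lo1) >= _pref(lo2):
            histone_c, repeat_c = lo1, lo2
        else:
            histone_c, repeat_c = lo2, lo1
        labels[cluster == histone_c] = "repress_histone"
        labels[cluster == repeat_c] = "repress_repeat"
    else:
        for rank, c in enumerate(ranked, start=1):
            labels[cluster == c] = f"rank_{rank}"

    return AreaModel(
        states=states,
        cluster=cluster,
        labels=labels.astype(str),
        leaf_order=leaf_order,
        linkage=Z,
    )


def property_strength(
    e_matrix: pd.DataFrame,
    plot: D2Plot,
    active_markers: list[str] | None = None,
) -> pd.DataFrame:
    """Per-DisTP-row slopes of mean active-marker enrichment.

    For the density property, x is the density-bin centers of the non-empty
    states in the row; for the DisTP property, x is the DisTP-bin centers of
    the row and its two neighbors.  Slopes are ordinary least squares; rows
    with fewer than 2 distinct x values are NaN.
    """
    cols = list(e_matrix.columns)
    active = [m for m in (active_markers or DEFAULT_ACTIVE_MARKERS) if m in cols]
    if not active:
        active = cols
    y_all = e_matrix[active].mean(axis=1)
    coords = plot.state_coords(e_matrix.index.to_numpy()).set_index("state")

    def _slope(x: np.ndarray, y: np.ndarray) -> float:
        if len(np.unique(x)) < 2:
            return np.nan
        return float(linregress(x, y).slope)

    rows = []
    for d in range(plot.nbins):
        in_row = coords["distp_bin"] == d
        s_density = _slope(
            coords.loc[in_row, "density_center"].to_numpy(),
            y_all[in_row.to_numpy()].to_numpy(),
        )
        near = coords["distp_bin"].isin(
            [r for r in (d - 1, d, d + 1) if 0 <= r < plot.nbins]
        )
        s_distp = _slope(
            coords.loc[near, "distp_center"].to_numpy(),
            y_all[near.to_numpy()].to_numpy(),
        )
        rows.append({"distp_bin": d, "density": s_density, "distp": s_distp})
    return pd.DataFrame(rows).set_index("distp_bin")


def activation_index(occ: OccupancyMatrix, areas: AreaModel) -> pd.Series:
    """AI_g: occupancy probability mass on the active + intermediate areas."""
    target = areas.states_of("active", "intermediate")
    if target.size and target.max() >= occ.P.shape[1]:
        raise ValueError("area model state grid does not match occupancy matrix")
    ai = np.asarray(occ.P[:, target].sum(axis=1)).ravel()
    return pd.Series(ai, index=occ.row_index(), name="ai")


def classify_modes(
    ai_by_stage: pd.DataFrame, q: float = 0.10
) -> pd.DataFrame:
    """Call CA / RA / CR trajectory modes from stage-ordered AI columns.

    Per stage, segments at or above the (1-q) quantile are active, at or
    below the q quantile repressed, else medium.  CA = active everywhere;
    CR = repressed everywhere; RA = not active at the first stage but active
    at the last; everything else is unclassified.
    """
    if ai_by_stage.shape[1] < 2:
        raise ValueError("need at least two stages")
    classes = pd.DataFrame(index=ai_by_stage.index)
    for stage in ai_by_stage.columns:
        v = ai_by_stage[stage]
        hi = v.quantile(1 - q)
        lo = v.quantile(q)
        cls = np.where(v >= hi, "active", np.where(v <= lo, "repressed", "medium"))
        classes[stage] = cls
    arr = classes.to_numpy()
    all_active = (arr == "active").all(axis=1)
    all_repressed = (arr == "repressed").all(axis=1)
    ra = (arr[:, 0] != "active") & (arr[:, -1] == "active")
    mode = np.full(len(arr), "unclassified", dtype=object)
    mode[ra] = "RA"
    mode[all_repressed] = "CR"
    mode[all_active] = "CA"
    out = classes.copy()
    out["mode"] = mode
    return out


def per_bin_stochasticity(
    cell_tables: list[pd.DataFrame],
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Cross-cell mean and population SD of density and DisTP per segment.

    Returns the per-segment table plus the Pearson (r, p) between density
    mean and density SD, the cell-type-specificity statistic.  Segments seen
    in fewer than 2 cells get NaN SDs.
    """
    if len(cell_tables) < 2:
        raise ValueError("need at least two cells")
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
    g = pooled.groupby(["chrom", "hap", "bin"])
    out = g.agg(
        n_cells=("density", "size"),
        density_mean=("density", "mean"),
        density_sd=("density", lambda v: v.std(ddof=0)),
        distp_mean=("distp", "mean"),
        distp_sd=("distp", lambda v: v.std(ddof=0)),
    ).reset_index()
    few = out["n_cells"] < 2
    out.loc[few, ["density_sd", "distp_sd"]] = np.nan
    ok = out["density_sd"].notna()
    x = out.loc[ok, "density_mean"].to_numpy()
    y = out.loc[ok, "density_sd"].to_numpy()
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return out, (np.nan, np.nan)
    r, p = pearsonr(x, y)
    return out, (float(r), float(p))


def periphery_lad_correlation(
    cell_tables: list[pd.DataFrame],
    lad_track,
    distp_cut: float = 2.0,
    agg_bp: int = 2_000_000,
    resolution: int | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation between periphery probability and LAD coverage.

    Periphery probability per segment = fraction of all cells whose DisTP is
    below ``distp_cut``; probability and LAD coverage are averaged over
    consecutive ``agg_bp`` windows and 3-sigma outliers on either variable
    are dropped before the two-sided Pearson correlation.
    """
    n_cells = len(cell_tables)
    frames = []
    for t in cell_tables:
        res = t.attrs.get("resolution") or int((t["end"] - t["start"]).iloc[0])
        if resolution is None:
            resolution = res
        frames.append(
            pd.DataFrame(
                {
                    "chrom": t["chrom"],
                    "hap": t["hap"],
                    "bin": t["start"] // res,
                    "below": (t["distp"] < distp_cut).astype(float),
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    per_seg = pooled.groupby(["chrom", "hap", "bin"], as_index=False)["below"].sum()
    per_seg["prob"] = per_seg["below"] / n_cells

    lad = lad_track.values[["chrom", "bin", "value"]].copy()
    keys = ["chrom", "hap", "bin"] if getattr(lad_track, "phased", False) else ["chrom", "bin"]
    if lad_track.phased:
        lad = lad_track.values[["chrom", "hap", "bin", "value"]].copy()
    merged = per_seg.merge(lad, on=keys, how="inner")
    if len(merged) == 0:
        raise ValueError("LAD track shares no bins with the structures")

    bins_per_window = max(int(agg_bp // resolution), 1)
    merged["window"] = merged["bin"] // bins_per_window
    agg = merged.groupby(["chrom", "hap", "window"], as_index=False).agg(
        prob=("prob", "mean"), value=("value", "mean")
    )

    x = agg["prob"].to_numpy()
    y = agg["value"].to_numpy()
    keep = (np.abs(x - x.mean()) <= 3 * x.std()) & (np.abs(y - y.mean()) <= 3 * y.std())
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"only {len(x)} windows survive trimming; need >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance after trimming; correlation undefined")
    r, p = pearsonr(x, y)
    return float(r), float(p), int(len(x))


def high_density_profile(
    cell_tables: list[pd.DataFrame], top_frac: float = 0.05
) -> pd.DataFrame:
    """Fraction of observations above the pooled (1 - top_frac) density
    quantile, per integer DisTP bin."""
    density = np.concatenate([t["density"].to_numpy() for t in cell_tables])
    distp = np.concatenate([t["distp"].to_numpy() for t in cell_tables])
    threshold = float(np.quantile(density, 1 - top_frac))
    dbin = np.floor(distp).astype(int)
    df = pd.DataFrame({"distp_bin": dbin, "high": density > threshold})
    out = df.groupby("distp_bin", as_index=False)["high"].agg(["mean", "size"])
    out = out.rename(columns={"mean": "fraction", "size": "n"})
    out.attrs["threshold"] = threshold
    return out
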