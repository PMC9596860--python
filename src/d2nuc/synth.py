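"""Synthetic nuclear ensembles with known ground truth.

Cells are confined random-walk polymers inside a spherical (optionally
ellipsoidal) nucleus.  Contiguous segment blocks carry class labels
(active-like / repressed-like / chromocenter) with controllable radial bias
and local-density structure, so density / DisTP / enrichment machinery can
be validated against planted signal without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from d2nuc.markers import MarkerTrack
from d2nuc.structures import GenomeStructure

CLASS_ACTIVE = "active-like"
CLASS_REPRESSED = "repressed-like"
CLASS_CHROMOCENTER = "chromocenter"

_MAX_STEP_RETRIES = 200


@dataclass
class SynthConfig:
    n_cells: int = 20
    n_chroms: int = 4
    particles_per_chrom: int = 500
    resolution: int = 100_000
    #: None = derive from particle count so the chains actually fill the
    #: nucleus like a polymer melt (sparse chains would let the membrane
    #: flood fill thread between them and destroy the radial DisTP signal)
    nucleus_radius: float | None = None
    #: target packing when the radius is derived; smaller = denser nucleus
    packing: float = 0.75
    step_length: float = 1.0
    #: soft self-avoidance: reject steps closer than this fraction of the
    #: step length to any of the 25 most recent particles
    min_separation_factor: float = 0.3
    #: per-class radial bias in [-1, 1]; positive pushes toward the periphery
    #: (target radius fraction (1 + b) / 2)
    radial_bias: dict = field(
        default_factory=lambda: {CLASS_ACTIVE: -0.5, CLASS_REPRESSED: 0.6}
    )
    chromocenter_fraction: float = 0.10
    active_fraction: float = 0.45
    block_length: int = 25
    bias_strength: float = 0.7
    axis_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    inverted: bool = False
    seed: int = 0
    #: optional explicit class -> probability map (overrides the default
    #: chromocenter / active / repressed split); only 'chromocenter' gets
    #: blob treatment, any other label may appear in radial_bias
    class_fractions: dict | None = None
    #: segment-class labels are drawn from this seed so different ensembles
    #: (e.g. differentiation stages) can share one genome annotation
    class_seed: int | None = None

    def __post_init__(self) -> None:
        if self.nucleus_radius is not None and self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        if self.step_length >= self.effective_radius():
            raise ValueError("step_length must be smaller than nucleus_radius")
        for name, frac in (
            ("chromocenter_fraction", self.chromocenter_fraction),
            ("active_fraction", self.active_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for cls, b in self.radial_bias.items():
            if not -1.0 <= b <= 1.0:
                raise ValueError(f"radial_bias[{cls!r}] must be in [-1, 1]")

    def effective_radius(self) -> float:
        """Explicit radius, or one derived so mean particle spacing tracks
        the step length (melt-like filling)."""
        if self.nucleus_radius is not None:
            return self.nucleus_radius
        n = self.n_chroms * self.particles_per_chrom
        return self.packing * self.step_length * (3 * n / (4 * np.pi)) ** (1 / 3)


@dataclass
class GroundTruth:
    """Per-segment class labels plus recorded marker loadings."""

    segments: pd.DataFrame = field(repr=False)  # chrom, hap, bin, class
    loadings: dict = field(default_factory=dict)  # name -> dict(alpha, beta, noise_sd)

    def class_of(self) -> pd.Series:
        return self.segments.set_index(["chrom", "hap", "bin"])["class"]


class PackingError(RuntimeError):
    pass


def _assign_classes(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Contiguous blocks of segments get one class each (shared by all cells)."""
    if config.class_fractions is not None:
        names = list(config.class_fractions)
        probs = np.asarray([config.class_fractions[n] for n in names], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("class_fractions must sum to 1")
    else:
        p_c = config.chromocenter_fraction
        p_a = config.active_fraction * (1 - p_c)
        names = [CLASS_CHROMOCENTER, CLASS_ACTIVE, CLASS_REPRESSED]
        probs = np.asarray([p_c, p_a, 1.0 - p_c - p_a])
    rows = []
    for ci in range(config.n_chroms):
        chrom = str(ci + 1)
        n = config.particles_per_chrom
        start = 0
        while start < n:
            length = min(config.block_length, n - start)
            cls = rng.choice(names, p=probs)
            for i in range(start, start + length):
                rows.append((chrom, "none", i, cls))
            start += length
    return pd.DataFrame(rows, columns=["chrom", "hap", "bin", "class"])


def _confined_walk(
    n: int,
    radius: float,
    step: float,
    rng: np.random.Generator,
    min_sep_factor: float = 0.3,
) -> np.ndarray:
    """Self-avoiding-ish random walk confined to the sphere of ``radius``."""
    pts = np.empty((n, 3))
    pts[0] = _random_in_ball(rng, 0.8 * radius)
    min_sep = min_sep_factor * step
    for i in range(1, n):
        for _ in range(_MAX_STEP_RETRIES):
            cand = pts[i - 1] + step * _random_unit(rng)
            if cand @ cand > radius * radius:
                continue
            recent = pts[max(0, i - 25) : i]
            if len(recent) and (
                ((recent - cand) ** 2).sum(axis=1).min() < min_sep * min_sep
            ):
                continue
            pts[i] = cand
            break
        else:
            raise PackingError(
                "confined walk failed to place a particle; "
                "increase nucleus_radius or decrease step_length"
            )
    return pts


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    return _random_unit(rng) * radius * rng.random() ** (1 / 3)


def _generate_cell(
    config: SynthConfig, classes: pd.DataFrame, cell_index: int
) -> GenomeStructure:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, cell_index]))
    R = config.effective_radius()
    all_coords = []
    frames = []
    for ci in range(config.n_chroms):
        chrom = str(ci + 1)
        n = config.particles_per_chrom
        pts = _confined_walk(
            n, R, config.step_length, rng, config.min_separation_factor
        )
        cls = classes.loc[classes["chrom"] == chrom, "class"].to_numpy()

        # radial bias: pull class members toward their target radius shell
        for label, b in config.radial_bias.items():
            b_eff = -b if config.inverted else b
            sel = cls == label
            if not sel.any() or b_eff == 0.0:
                continue
            target_r = (1.0 + b_eff) / 2.0 * R
            p = pts[sel]
            r = np.linalg.norm(p, axis=1)
            r_safe = np.where(r > 0, r, 1.0)
            new_r = r + config.bias_strength * (target_r - r)
            pts[sel] = p * (new_r / r_safe)[:, None]

        # chromocenters: collapse contiguous runs into dense interior blobs
        is_cc = cls == CLASS_CHROMOCENTER
        if is_cc.any():
            run_id = np.cumsum(np.diff(is_cc.astype(int), prepend=0) == 1)
            for rid in np.unique(run_id[is_cc]):
                sel = is_cc & (run_id == rid)
                center = _random_in_ball(rng, 0.45 * R)
                pts[sel] = center + rng.normal(
                    scale=0.35 * config.step_length, size=(int(sel.sum()), 3)
                )

        all_coords.append(pts)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "hap": "none",
                    "pos": np.arange(n, dtype=np.int64) * config.resolution,
                }
            )
        )
    coords = np.vstack(all_coords) * np.asarray(config.axis_scale)
    df = pd.concat(frames, ignore_index=True)
    df[["x", "y", "z"]] = coords
    return GenomeStructure(
        cell_id=f"synthcell_{cell_index:03d}", resolution=config.resolution, df=df
    )


def generate_ensemble(
    config: SynthConfig,
) -> tuple[list[GenomeStructure], GroundTruth]:
    """Generate a reproducible multi-cell ensemble plus its ground truth.

    Segment classes are drawn once from the ensemble seed and shared by all
    cells; each cell then gets its own RNG stream derived from
    (seed, cell index), so ensembles are order-independent.
    """
    class_seed = config.seed if config.class_seed is None else config.class_seed
    class_rng = np.random.default_rng(np.random.SeedSequence([class_seed]))
    classes = _assign_classes(config, class_rng)
    structures = [
        _generate_cell(config, classes, i) for i in range(config.n_cells)
    ]
    return structures, GroundTruth(segments=classes)


def generate_marker_track(
    segment_stats: pd.DataFrame,
    alpha: float,
    beta: float,
    noise_sd: float,
    seed: int,
    name: str = "synthetic",
    ground_truth: GroundTruth | None = None,
) -> MarkerTrack:
    """Synthesize a marker with known loadings on mean density and DisTP.

    value_g = alpha * z(mean density_g) + beta * z(mean DisTP_g) + N(0, sd).
    ``segment_stats`` must carry chrom/hap/bin and per-segment mean
    ``density`` and ``distp`` columns (see ``markers.segment_means``).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    zd = _z(segment_stats["density"].to_numpy(dtype=float))
    zp = _z(segment_stats["distp"].to_numpy(dtype=float))
    value = alpha * zd + beta * zp
    if noise_sd > 0:
        value = value + rng.normal(scale=noise_sd, size=len(value))
    values = segment_stats[["chrom", "hap", "bin"]].copy()
    values["value"] = value
    # degenerate all-zero loadings: keep the track constructible (NV := 0)
    nv = pd.Series(np.zeros(len(values))) if value.std() == 0 else None
    track = MarkerTrack(name=name, kind="signal", values=values, phased=True, nv=nv)
    if ground_truth is not None:
        ground_truth.loadings[name] = {
            "alpha": alpha, "beta": beta, "noise_sd": noise_sd,
        }
    return track
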