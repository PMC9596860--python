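import numpy as np
import pandas as pd
import pytest

from d2nuc import core, markers, plot2d, synth


@pytest.fixture(scope="session")
def small_ensemble():
    cfg = synth.SynthConfig(
        n_cells=10, n_chroms=2, particles_per_chrom=600, seed=3
    )
    cells, truth = synth.generate_ensemble(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def small_tables(small_ensemble):
    _, cells, _ = small_ensemble
    return core.score_ensemble(cells)


@pytest.fixture(scope="session")
def small_plot_occ(small_tables):
    bounds = plot2d.fit_bounds(small_tables)
    return plot2d.build_occupancy(small_tables, bounds, min_segments=5)


@pytest.fixture(scope="session")
def small_stats(small_tables):
    return markers.segment_means(small_tables)


def random_grid(rng: np.random.Generator) -> np.ndarray:
    """A random sparse counts grid with a dense blob plus stray particles."""
    shape = tuple(rng.integers(4, 13, size=3))
    counts = np.zeros(shape, dtype=np.int64)
    n_blob = int(rng.integers(5, 40))
    center = np.array([s // 2 for s in shape])
    spread = max(min(shape) // 3, 1)
    blob = center + rng.integers(-spread, spread + 1, size=(n_blob, 3))
    blob = np.clip(blob, 0, np.array(shape) - 1)
    np.add.at(counts, (blob[:, 0], blob[:, 1], blob[:, 2]), 1)
    n_stray = int(rng.integers(0, 6))
    stray = np.stack([rng.integers(0, s, size=n_stray) for s in shape], axis=1)
    if n_stray:
        np.add.at(counts, (stray[:, 0], stray[:, 1], stray[:, 2]), 1)
    return counts


def toy_structure_df(coords: np.ndarray, resolution: int = 20_000) -> pd.DataFrame:
    n = len(coords)
    df = pd.DataFrame(
        {
            "chrom": ["1"] * n,
            "hap": ["none"] * n,
            "pos": np.arange(n, dtype=np.int64) * resolution,
        }
    )
    df[["x", "y", "z"]] = np.asarray(coords, dtype=float)
    return df
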