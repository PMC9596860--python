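"""Readers and writers for particle tables and per-cell D2 tables.

Genomic coordinates are 0-based half-open everywhere; ``.3dg`` positions are
taken verbatim as bin starts.  Haplotype labels are ``pat``, ``mat`` or
``none`` (unphased / haploid).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

HAP_NONE = "none"
_VALID_HAPS = ("pat", "mat", HAP_NONE)

#: chromosome token with an optional trailing haplotype suffix, e.g. ``1(pat)``
_CHROM_RE = re.compile(r"^([^()\s]+)(?:\((\w+)\))?$")

MIN_PARTICLES = 8  # k-NN with the default k=7 must be computable


class StructureParseError(ValueError):
    """Raised for malformed or inconsistent particle tables."""


@dataclass(frozen=True)
class Particle:
    """One genomic bin placed in 3D space."""

    chrom: str
    hap: str
    pos: int
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative genomic position: {self.pos}")
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates: {self.xyz}")
        if self.hap not in _VALID_HAPS:
            raise ValueError(f"invalid haplotype label: {self.hap!r}")


@dataclass
class GenomeStructure:
    """One cell's reconstructed particle cloud.

    ``df`` holds columns ``chrom`` (str), ``hap`` (str), ``pos`` (int),
    ``x``, ``y``, ``z`` (float) in input order.
    """

    cell_id: str
    resolution: int
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.df) < MIN_PARTICLES:
            raise StructureParseError(
                f"too few particles: {len(self.df)} < {MIN_PARTICLES}"
            )
        if self.resolution <= 0:
            raise StructureParseError(f"invalid resolution: {self.resolution}")
        dup = self.df.duplicated(subset=["chrom", "hap", "pos"])
        if dup.any():
            row = self.df[dup].iloc[0]
            raise StructureParseError(
                f"duplicate particle at {row.chrom}({row.hap}):{row.pos}"
            )
        if (self.df["pos"] < 0).any():
            raise StructureParseError("negative genomic position")
        if not np.isfinite(self.df[["x", "y", "z"]].to_numpy()).all():
            raise StructureParseError("non-finite coordinate")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) float array of particle coordinates."""
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def bin_index(self) -> np.ndarray:
        """Integer genomic bin index ``pos // resolution`` per particle."""
        return (self.df["pos"].to_numpy() // self.resolution).astype(np.int64)

    def particles(self) -> Iterator[Particle]:
        for row in self.df.itertuples(index=False):
            yield Particle(row.chrom, row.hap, int(row.pos), (row.x, row.y, row.z))


def _parse_chrom_token(token: str, lineno: int) -> tuple[str, str]:
    m = _CHROM_RE.match(token)
    if m is None:
        raise StructureParseError(f"line {lineno}: malformed chromosome field {token!r}")
    chrom, hap = m.group(1), m.group(2)
    if hap is None:
        return chrom, HAP_NONE
    if hap not in ("pat", "mat"):
        raise StructureParseError(
            f"line {lineno}: unknown haplotype suffix ({hap}) in {token!r}"
        )
    return chrom, hap


def infer_resolution(positions: np.ndarray) -> int:
    """Infer bp-per-bin as the GCD of the spacings between sorted positions."""
    uniq = np.unique(positions.astype(np.int64))
    diffs = np.diff(uniq)
    diffs = diffs[diffs > 0]
    if diffs.size == 0:
        raise StructureParseError("cannot infer resolution from a single position")
    return int(np.gcd.reduce(diffs))


def read_structure(
    path: str | Path,
    dialect: str = "3dg",
    resolution: int | None = None,
    cell_id: str | None = None,
) -> GenomeStructure:
    """Read a whitespace-separated particle table.

    ``3dg`` lines are ``chrom[(hap)] pos x y z``; ``tsv`` expects a header
    ``chrom hap pos x y z``.  Resolution is inferred from position spacings
    unless given.
    """
    path = Path(path)
    if dialect not in ("3dg", "tsv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if cell_id is None:
        cell_id = path.stem.removesuffix(".3dg")

    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "hap", "pos", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise StructureParseError(f"tsv missing columns {required - set(df.columns)}")
        df = df[["chrom", "hap", "pos", "x", "y", "z"]]
        df["chrom"] = df["chrom"].astype(str)
    else:
        chroms: list[str] = []
        haps: list[str] = []
        poss: list[int] = []
        coords: list[tuple[float, float, float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 5:
                    raise StructureParseError(
                        f"line {lineno}: expected 5 fields, got {len(fields)}"
                    )
                chrom, hap = _parse_chrom_token(fields[0], lineno)
                try:
                    pos = int(fields[1])
                    xyz = (float(fields[2]), float(fields[3]), float(fields[4]))
                except ValueError as exc:
                    raise StructureParseError(f"line {lineno}: {exc}") from exc
                chroms.append(chrom)
                haps.append(hap)
                poss.append(pos)
                coords.append(xyz)
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "hap": haps,
                "pos": np.asarray(poss, dtype=np.int64),
            }
        )
        df[["x", "y", "z"]] = np.asarray(coords, dtype=float).reshape(-1, 3)

    if len(df) < MIN_PARTICLES:
        raise StructureParseError(f"too few particles: {len(df)} < {MIN_PARTICLES}")
    if resolution is None:
        resolution = infer_resolution(df["pos"].to_numpy())
    return GenomeStructure(cell_id=cell_id, resolution=int(resolution), df=df)


def write_structure(structure: GenomeStructure, path: str | Path) -> None:
    """Write a structure back out as ``.3dg`` text."""
    with open(path, "w") as fh:
        for row in structure.df.itertuples(index=False):
            token = row.chrom if row.hap == HAP_NONE else f"{row.chrom}({row.hap})"
            fh.write(f"{token}\t{int(row.pos)}\t{row.x!r}\t{row.y!r}\t{row.z!r}\n")


D2_COLUMNS = ["chrom", "hap", "start", "end", "density", "distp"]


def write_cell_d2(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell D2 table (``chrom hap start end density distp`` TSV)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty D2 table")
    missing = set(D2_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"D2 table missing columns {missing}")
    table[D2_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cell_d2(path: str | Path) -> pd.DataFrame:
    """Read a per-cell D2 table written by :func:`write_cell_d2`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(D2_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"D2 table missing columns {missing}")
    df["chrom"] = df["chrom"].astype(str)
    return df[D2_COLUMNS]
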