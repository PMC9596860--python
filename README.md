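# d2nuc

Physical-state analysis of reconstructed single-cell 3D genome structures.

`d2nuc` takes particle-table reconstructions (Dip-C `.3dg`-style text, one
row per genomic bin with x/y/z coordinates) and computes, per cell:

1. a **cell-specific cube mesh** whose cube length is the mean distance to
   the 7th-nearest particle (normalizes nuclear size across cells);
2. **smoothed DNA density** per cube, averaging neighboring cube counts
   weighted by inverse index-distance over a radius-3 ball;
3. the **nuclear membrane** by flood fill of effectively-empty cubes from
   the outside (a cube is traversable when its 5x5x5 window holds fewer
   than 3 particles, so stray outlier particles become membrane territory
   while enclosed cavities never do);
4. **DisTP** (distance to periphery) per filled cube: the mean of the 10
   smallest distances to membrane cubes, in cube-length units.

Across cells, per-particle (density, DisTP) pairs populate a 15x15 state
grid (the "D2 plot"; standard diploid range 1-3.2 x 1.21-16, or fitted
bounds at mean +/- 1.96 SD density / 95th-percentile DisTP). The occupancy
matrix P_ga (fraction of cells in which segment g sits at state a) then
drives:

- **marker enrichment** per state (occupancy-weighted mean of z-scored
  track values), its mean-based variant, its per-state SD, and gene-set
  occupancy ratios;
- a **4-area transcriptional model** (Ward clustering of states in marker
  space: active / intermediate / repress_histone / repress_repeat) with
  per-DisTP-row property-strength slopes;
- **activation indexes** (occupancy mass on active + intermediate areas)
  and **CA / RA / CR trajectory modes** across ordered cell stages
  (top/bottom-decile calls per stage);
- validation statistics: periphery-probability vs LAD-coverage Pearson
  correlation (2 Mb aggregation, 3-sigma trimming), the top-5% high-density
  DisTP profile, and per-bin cross-cell mean/SD stochasticity.

A first-class synthetic module generates confined polymer-like nuclei with
planted radial classes, chromocenters, inverted architectures, and marker
tracks with known density/DisTP loadings, so the whole pipeline is testable
offline with ground truth.

## CLI

All commands log their configuration to stderr.

```sh
# synthetic ensemble: one .3dg per cell + ground_truth.tsv
d2 synth --out-dir ens/ --n-cells 20 --seed 1

# per-cell density/DisTP table
d2 compute --structure ens/synthcell_000.3dg --out cell0.d2.tsv \
    --knn 7 --smooth-range 3 --membrane-min-particles 3 \
    --membrane-window 5 --distp-k 10

# D2 plot + occupancy matrix (TSV triplets + JSON metadata sidecar)
d2 plot-states --cells cell0.d2.tsv --cells cell1.d2.tsv \
    --bounds standard --nbins 15 --min-segments 200 --out occupancy.tsv

# marker enrichment from a bedGraph / BED / site table
d2 enrich --occupancy occupancy.tsv --track h3k4me3.bedgraph \
    --kind signal --resolution 20000 --out h3k4me3.enrich.tsv

# 4-area model from a directory of *.enrich.tsv files
d2 cluster --enrich-dir enrich/ --k 4 --out areas.tsv

# trajectory modes across stage-ordered occupancy matrices
d2 trajectory --occupancy s1.tsv --occupancy s2.tsv --occupancy s3.tsv \
    --areas areas.tsv --q 0.10 --out modes.bed

# LAD validation
d2 validate-lad --cells cell0.d2.tsv --lad lads.bed \
    --resolution 100000 --out lad_corr.tsv

# one-shot synthetic end-to-end run
d2 demo --out-dir demo/ --seed 0
```

`d2 synth` also accepts a flat `key = value` config file via `--config`
(flags override the file, both override defaults).

## Layout

| module | contents |
| --- | --- |
| `d2nuc.structures` | `.3dg` / TSV readers and writers, `GenomeStructure` |
| `d2nuc.core` | cube mesh, smoothed density, membrane flood fill, DisTP |
| `d2nuc.plot2d` | axis bounds, state grid, occupancy matrix |
| `d2nuc.markers` | track indexing (signal / coverage / point-median), enrichment statistics |
| `d2nuc.model` | Ward areas, property strength, activation index, trajectory modes, validation stats |
| `d2nuc.synth` | synthetic ensembles and marker tracks with ground truth |
| `d2nuc.cli` | the `d2` command group |
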