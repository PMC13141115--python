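# mifprep

Preprocessing and imaging cytometry for **sequential multiplex
immunofluorescence (cyclic mIF)** microscopy.

In cyclic mIF one specimen (an FFPE tissue section, a primary-cell culture,
or an organ-on-a-chip membrane) is stained, imaged and antibody-stripped
over many cycles. Each cycle delivers a grid of 16-bit tile images per
channel: a nuclear (DAPI) reference plus one or more marker channels.
Before any quantitative analysis those acquisitions must be corrected for
illumination, stitched, background-subtracted, aligned across cycles and
assembled into one multichannel image — and single cells must be called
from it. `mifprep` implements that pipeline as a tested Python library with
a CLI:

1. **Shading correction** — divide each tile by a mean-normalized
   shading-reference field (flat-field division); brightfield snapshots are
   flattened by Gaussian division (`image / G_σ(image) · mean`).
2. **Stitching** — nominal grid placement, pairwise translation refinement
   by masked cross-correlation on overlap strips with subpixel phase
   refinement, maximum-correlation spanning-tree placement, feathered
   blending.
3. **Rolling-ball background subtraction** — the background is the
   grayscale opening of the image with a spherical cap of radius *r*
   (the upper envelope of a ball rolled beneath the intensity surface);
   large radii use the classical shrink/roll/expand strategy, with an exact
   mode retained.
4. **Registration** — every cycle is aligned to the reference cycle by
   phase cross-correlation of the DAPI channels; the per-cycle translation
   is applied to all channels of that cycle. Retention QC reports per-cycle
   Dice overlap and Pearson correlation of the nuclear signal.
5. **Autofluorescence subtraction** — an acquired autofluorescence channel
   is subtracted from affected marker channels, with an auto-estimated
   scale from signal-poor pixels.
6. **Z-projection** — chip acquisitions arrive as z-stacks and are
   collapsed by a plain or local-contrast-weighted mean.
7. **Phenotyping** — nuclei are segmented from DAPI (Otsu +
   distance-transform watershed) or imported from an external segmenter's
   label map; a cell is assigned marker identity *m* when at least **60%**
   of its nuclear pixels fall inside marker *m*'s binarized mask
   (fraction ≥ 0.60), with conflicts resolved by the largest fraction and
   near-ties reported rather than guessed. The rule exists because
   membrane markers of adjacent cell types overlap spatially, and naive
   per-pixel calls invent biphenotypic cells.

A fully seeded synthetic-acquisition generator (`mifprep.synthetic`)
produces ground-truthed multi-cycle tile scans — known shading fields,
stage jitter, cycle drift, stripping losses, haze, autofluorescent debris,
chip pores — so every stage is testable without real data.

## Worked example

Generate a 6-cycle, 400-cell, two-class acquisition and run the full
pipeline:

```bash
mifprep simulate --n-cells 400 --cycles 6 --seed 17 --out acq
cat > run.yaml <<'YAML'
input_dir: acq
output_dir: out
grid: {rows: 2, cols: 2, tile_height: 288, tile_width: 288, overlap_fraction: 0.125}
phenotyping: {identity_markers: [memA, memB]}
YAML
mifprep run run.yaml
mifprep qc out/hyperstack.tif
```

The run prints its stage timings and artifacts:

```
{
 "hyperstack": "out/hyperstack.tif",
 "cell_table": "out/cell_table.csv",
 "n_cells": 400,
 "provenance": "out/provenance.json"
}
```

and the QC command reports how well the nuclear signal is retained and
re-aligned across the six cycles (Dice of Otsu-binarized DAPI vs cycle 1,
Pearson over the union support):

```
cycle 1: dice=1.000 pearson=1.000
cycle 2: dice=0.990 pearson=0.994
cycle 3: dice=0.989 pearson=0.993
...
```

`out/cell_table.csv` holds one row per segmented nucleus — centroid, area,
per-marker nuclear-overlap fraction and mean intensity, a validity flag for
intensities of markers foreign to the assigned identity, and the identity
itself:

```
cell_id,centroid_row,centroid_col,area_px,frac_memA,mean_memA,valid_memA,...,assigned_identity,tie_flag
1,28.92,299.0,179,1.0,1902.01,True,...,memA,False
2,37.96,28.69,194,0.0,26.28,False,...,memB,False
```

Here cell 1 has 100% of its nucleus inside the `memA` membrane mask and 0%
inside `memB`, so it is called `memA`; all 400 simulated cells recover
their generating class on this fixture.

Every stage is also available standalone (`mifprep stitch`,
`subtract-bg`, `subtract-af`, `register`, `phenotype`, ...) and as plain
library functions.

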