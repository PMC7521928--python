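# enspatial

Monte Carlo spatial-proximity analysis for pulse-chase cell-coordinate data
from the zebrafish enteric nervous system (ENS).

## The problem

In EdU pulse-chase experiments on the adult zebrafish gut, EdU marks cells
that divided during the pulse. If EdU⁺ enteric glia (*her4.3*:EGFP⁺) and
EdU⁺ newborn neurons (HuC/D⁺) descend from common proliferating
progenitors, the two daughter cells should sit close together — much closer
than lineally unrelated cells mixed at random through the myenteric plexus.
`enspatial` turns that intuition into a test on annotated confocal fields:
tables of cell coordinates and phenotype labels (CellCounter-style exports,
in μm) from 450 × 450 μm images.

## The statistic

For every *center* cell (e.g. each GFP⁺EdU⁺ glial cell) and each radius
*r* in the grid {20, 30, …, 100, 150, …, 500} μm, the edge-corrected
density of *target* cells (e.g. HuC/D⁺EdU⁺ neurons) is

  ρ(r) = N(r) / A(r),

where N(r) counts targets within distance r and A(r) is the area of the
circle that lies inside the image — exactly π·r² for interior circles, and
the closed-form circle–rectangle intersection near edges (a Monte Carlo
area estimator is available as a cross-check). The observed statistic per
radius is the grand mean of ρ(r) over all center cells pooled across a
group's images.

The null model keeps each image's per-phenotype counts but redraws every
position uniformly. Each of 50 reshuffles per image contributes one null
sample (that image's mean density per radius); samples pool across images
(41 images × 50 reshuffles = 2050 samples), a gamma distribution is fitted
per radius, and the equal-tailed 90% interval is taken from its quantiles.
An observed mean **above** the interval at a radius flags clustering beyond
chance at that scale; **below** flags dispersion; **inside** is consistent
with uniform mixing.

The package also ships:

* a synthetic point-pattern generator — uniform fields at the published
  ENS phenotype mixture and EdU labelling fractions (t0/t4/t11 presets),
  or fields seeded with short-separation division doublets of chosen
  glia/glia, glia/neuron, neuron/neuron composition;
* replicate-level counting statistics — per-fish proportions, two-sided
  Mann-Whitney tests (exact for small tie-free samples), Benjamini–Hochberg
  correction, and graded significance labels (ns / * / ** / ***).

## Worked example

Simulate ten fields at the t0 labelling preset, each carrying 15
heterotypic glia/neuron EdU⁺ doublets (separation ≤ 20 μm) on a realistic
uniform background, then run the analysis:

```sh
enspatial simulate --preset t0 --frames 10 --doublets 15 \
    --p-gg 0 --p-gn 1 --p-nn 0 --seed 7 --out cells.csv
enspatial analyze --input cells.csv --out-dir results \
    --pair "GFP+EdU+:HuC/D+EdU+" --seed 7
```

Selected rows of `results/results.csv`:

```
 radius_um  observed_mean_density     ci_lo     ci_hi   call
        20              6.635e-04 1.235e-05 1.817e-04  above
        40              2.244e-04 3.423e-05 1.291e-04  above
        60              1.417e-04 4.829e-05 1.093e-04  above
       150              8.950e-05 6.311e-05 9.128e-05 inside
       500              7.627e-05 7.080e-05 8.140e-05 inside
```

At 20–60 μm the observed density of EdU⁺ neurons around EdU⁺ glia is
several-fold above the null interval — the doublets are detected — while
at 150 μm and beyond the pattern is indistinguishable from uniform mixing:
clustering is confined to the spatial scale of a cell division, as expected
for sibling pairs. Densities are in cells/μm²; the null mean approaches
n_targets/(450·450) ≈ 7.4 × 10⁻⁵ at large radii.

The calibration command quantifies the false-positive behaviour of the
interval on uniform data:

```sh
$ enspatial calibrate --replicates 50 --seed 3
coverage at r=40 μm over 50 uniform replicates: 92.0% inside the 90% interval (8.0% outside)
```

`enspatial compare` runs the replicate-level group statistics and
`enspatial report` extracts band-plot data (radius, observed, lo, hi) from
a results table.

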