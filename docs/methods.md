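# Methods

## Model and procedure

The analysis treats each annotated confocal field as a realisation of a
marked planar point process on a W × H rectangle (default 450 × 450 μm,
origin at the lower-left corner, coordinates in continuous μm). The
myenteric plexus is thin enough to be treated as two-dimensional, so only
X and Y enter the analysis. Marks are phenotype labels from an explicit,
configurable vocabulary; the default covers the EdU pulse-chase
classification (GFP⁺EdU⁺ glia, HuC/D⁺EdU⁺ neurons, their EdU⁻ counterparts,
and "other" ENS cells).

**Observed statistic.** For a (center, target) phenotype pair and radius r,
each center cell contributes the edge-corrected density
count(targets within r) / clipped-area(r). The per-radius statistic is the
unweighted grand mean over all center cells pooled across the group's
frames — cells, not frames, are the measured units, so frames with more
center cells weigh proportionally more. Distances are boundary-inclusive
(d ≤ r counts as inside): ties are measure-zero for continuous data and the
convention makes synthetic fixtures deterministic. In homotypic queries the
center cell is excluded from its own count by default; counting it would
add a constant 1/area inflation at every radius.

**Edge correction.** The density denominator is the area of the sampling
circle that lies inside the frame. The default is the exact closed form for
circle–rectangle intersection, computed by inclusion–exclusion over the
rectangle's corners of the quadrant area I(x, y) — the circle's area within
{X ≤ x, Y ≤ y} — itself a three-branch piecewise antiderivative of the
y-clipped chord. A Monte Carlo estimator (uniform points inside the circle,
π·r² scaled by the fraction landing in the frame; binomial SE
π·r²·√(p(1−p)/n)) is retained behind `area_mode="monte_carlo"` for
cross-validation; it agrees with the closed form at the 3-SE scale and is
never needed for production runs, where exactness is available.

**Null model.** The null hypothesis is spatial uniformity given the
marginal composition: per-phenotype counts of each frame are kept and every
position is redrawn i.i.d. uniform on the rectangle (all phenotypes move,
including the centers). Each frame is reshuffled 50 times; each reshuffle
yields one null sample per radius — the reshuffled frame's mean density
over its center cells — and samples pool across the group's frames before
fitting. A group of 41 frames therefore accumulates 2050 samples per
radius. Taking the per-frame mean as the sample unit keeps the per-image
simulation count (50) and the per-dataset pooled total (>2000) consistent;
pooling across frames before the fit is this package's choice, as is
comparing the pooled grand mean (rather than per-frame means) against the
interval.

**Interval and call.** A gamma distribution (location 0) is fitted per
radius to the pooled samples: maximum likelihood when all samples are
positive (the MLE pins shape·scale to the sample mean), method of moments
(k = m²/s², θ = s²/m, unbiased variance) when zeros occur, since the gamma
log-likelihood is undefined at zero. The decision interval is the
equal-tailed pair of gamma quantiles at (1−level)/2 and 1−(1−level)/2,
level 0.90 by default. Per radius the call is `above` / `below` /
`inside`, with the boundary counting as inside; both tails count as
non-chance events even though clustering (above) is the direction of
interest. Radii whose null samples are all zero (or constant) are flagged
degenerate, reported with a point-mass interval, and always called
`inside` — absence of any target cell is not evidence of structure.

**Seeding.** One user seed fans out through `numpy.random.SeedSequence.spawn`
into independent child streams per pair, per frame, per reshuffle, per
replicate. Identical seeds give bit-identical results end to end, including
written CSV/JSON outputs (manifests carry no timestamps).

## Synthetic data

The generator emulates the pulse-chase study's composition, not its
biology. Compartment proportions among ENS cells default to the published
adult means — 65.49% neurons, 24.20% glia, 12.93% double-negative —
renormalised to sum to 1 (the published means come from different
quantifications and sum to ≈1.026). EdU⁺ fractions per compartment come
from the timepoint presets: t0 8.0% of glia and 0.068% of neurons, t4
3.6% / 0.71%, t11 3.9% / 0.70%. Per-frame counts are multinomial in the
mixture and binomial in the preset fractions, emulating replicate
variance; exact counts can be pinned via `fixed_counts`.

Absolute cell density per field is not a published quantity. The default of
400 ENS cells per 450 μm square is a model choice: it yields ≈8 EdU⁺ glia
per frame at t0, consistent with 8.0% of ≈95 glia, at a biologically
plausible packing for the myenteric plexus.

**Doublets.** The clustering alternative places division doublets: a parent
position uniform in the frame, a partner at distance uniform on (0, d_max]
(default 20 μm, under the 20–60 μm scale at which clustering is expected
to surface) and uniform angle, resampled until inside the frame.
Composition (glia/glia, glia/neuron, neuron/neuron) is drawn per doublet
from configurable probabilities. With sampled backgrounds the doublet
members are EdU⁺ cells *added on top of* the mixture/preset draw: they
model recent divisions that the marginal labelling fractions do not
resolve, and the unpaired background EdU⁺ cells keep the pattern uniform
at large radii — a doublet-only EdU⁺ population would carry a genuine
+1/area excess around every center at all radii below full frame coverage
and would register as (weak) clustering even at 150 μm and beyond. With
`fixed_counts` the doublets consume the configured counts instead, and
excess demand is a configuration error. Members keep a shared `pair_id`
(−1 for background) through file round-trips for recovery tests; the
analysis ignores it.

**What the generator does not emulate.** Real fields have inhomogeneous
cell density (ganglionated networks, gut-region gradients), soft-core
repulsion between nuclei, segmentation and annotation errors, and lineage
dynamics (quiescent → activated glia → neuroblast → neuron). Passing tests
therefore demonstrate calibration and detection under the stated point
process, not robustness to those features; on real data, density
inhomogeneity shared by all phenotypes inflates cross-phenotype densities
relative to a uniform null at the inhomogeneity's own scale.

## Numerical choices

* Gamma MLE via `scipy.stats.gamma.fit` with location fixed at 0,
  initialised from method-of-moments; fitted mean agrees with the sample
  mean to well under 1%.
* Degenerate samples (zero mean or zero variance) raise in `fit_gamma` and
  are flagged, not fitted, in `build_null`.
* Mann-Whitney: exact-distribution p for combined n ≤ 20 without ties,
  tie-corrected continuity-corrected normal approximation otherwise
  (`scipy.stats.mannwhitneyu` supplies both routes). Exact and asymptotic
  p agree within 0.02 at n ≈ 18 on tie-free data.
* Benjamini–Hochberg via `statsmodels` `multipletests(fdr_bh)`; note the
  step-up adjustment is order-invariant but *not* idempotent
  ([1.0, 0.25] → [1.0, 0.5] → [1.0, 1.0]).
* Significance grades: ns (p > 0.05), * (p ≤ 0.05), ** (p ≤ 0.01),
  *** (p ≤ 0.001), boundaries inclusive.
* Cell tables are read with `float_precision="round_trip"` and written via
  `repr`, so coordinates survive file round-trips bit-exactly.

## Problem sizes

The calibration experiment uses 300 independent single-frame replicates
(100 center + 100 target cells, 50 reshuffles each) at r = 40 μm — about
15 000 full density evaluations, a few minutes on one CPU. The detection
experiment uses 50 runs of 10 doublet frames (15 heterotypic pairs each,
t0 background) across the full 17-radius grid. Both sizes give binomial
standard errors of 1–2 percentage points on the reported rates while
keeping a laptop-scale runtime; the statistic and null construction are
identical at any scale.

## Known limitations

* The gamma interval is estimated from 50 samples per frame group;
  its quantile noise costs roughly one percentage point of coverage
  (≈88–89% empirical vs 90% nominal at the calibration scale).
* Comparing a grand mean pooled over many frames against an interval for
  per-frame means is conservative for large groups: the grand mean's
  sampling variance shrinks with the number of frames while the interval
  does not.
* The uniform null ignores density inhomogeneity; see above.
* Doublet separation law and absolute density are model choices, exposed
  as configuration, with no claim of anatomical fidelity.
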