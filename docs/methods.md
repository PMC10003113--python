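# Methods

This note documents the models, conventions and design choices behind each
stage; it is the reference for what the synthetic benchmarks do and do not
demonstrate about real data.

## Skeleton graphs and network metrics

A filament mask is thinned to an 8-connected, one-pixel-wide skeleton
(topology-preserving, so connected-component counts survive). Pixels are
classified by their 8-neighbour count: 0 → isolated node, 1 → endpoint,
2 → branch interior, ≥ 3 → junction pixel. Adjacent junction pixels are
merged into a single junction node; without this merge a T-crossing, whose
thinned form is typically a 2–4 pixel cluster, would count as several
junctions and inflate branch counts. Branches are traced as maximal pixel
paths between nodes; two parallel branches between the same pair of
junctions (a closed cycle through two junctions) are kept as distinct
branches, and a connected component with no node at all (a pure ring) is
recorded as a single closed branch with no nodes.

Length convention: consecutive path pixels contribute 1·`pixel_size`
(axial) or √2·`pixel_size` (diagonal); steps *internal* to a junction
cluster contribute nothing. A straight N-pixel axial segment therefore
measures exactly (N−1)·`pixel_size` and a perfect diagonal
(N−1)·√2·`pixel_size`. Sum of branch lengths = tree length; sum of tree
lengths = network total length (asserted to 1e−9 relative in the tests).
An empty network reports total length 0 and *missing* (NaN) ratio fields,
never 0 — a cell with no detectable network must not drag per-well density
means toward zero.

Tiny trees (including single isolated pixels, zero-length trees) are kept
and counted: heavily stressed networks are dominated by specks, and
discarding them would bias trees-per-length downward exactly where the
phenotype lives. No spur pruning is applied by default.

The whole decomposition is cross-checked against an independent
brute-force oracle (neighbour-count convolution + component labelling +
adjacency-pair enumeration) that must agree exactly on every fixture
raster and on skeletons of random blob sets.

### Segmentation default

The default threshold is a robust half-maximum: midway between the median
(background, since filaments occupy a few percent of the field) and the
99.9th percentile (filament peak). Class-balancing thresholds such as Otsu
place the cut far down the filament profile when background dominates,
swelling the mask from ~3 px to ~5 px width; the swollen mask costs ~0.35
Jaccard against the true filament support and, after thinning, erodes
every fragment tip. Otsu remains available (`method="otsu"`), and a fixed
threshold can be passed explicitly. No extra pre-blur is applied by
default — the images already carry the optical blur of the microscope.

## Synthetic mitochondrial networks

A cell is drawn as `n_trees` disjoint trees sharing a fixed total length
budget (default 450 µm, the scale of an unstressed fibroblast network at
0.3 µm/px, a plausible 40× high-content pixel pitch). The fragmentation
parameter `f ∈ [0, 1]` maps linearly onto the tree count, from one
connected network (`f = 0`) to `n_trees_max = 30` fragments (`f = 1`).
`f` is an ordinal phenotype index: the benchmark uses its direction and
monotonicity, not an absolute fragment density.

Each tree is a branching self-avoiding walk whose segments follow the 8
compass directions, so every drawn step is exactly axial or diagonal and
the ground-truth length is exact on the raster. Two design constraints
make the truth recoverable by the analysis chain rather than merely
nominal:

- **Block isolation.** Trees are confined to disjoint blocks of a shuffled
  grid partition (3 px margin), so distinct ground-truth trees can never
  merge in the rendering; the detected tree count equals the true count
  exactly in practice.
- **Clearance.** Within a tree, new segments must keep a 4 px Chebyshev
  clearance from already-drawn filament (the first pixels after a branch
  anchor are exempt), so the dilated/blurred rendering never fuses
  parallel passes into blobs that would thin to something shorter.

Rendering: the polyline raster is dilated to ~3 px, blurred with a
σ = 1 px Gaussian, scaled to photon counts (background 20, filament 600),
and corrupted with Poisson shot noise plus σ = 3 Gaussian read noise
(`apply_noise=False` gives the clean rendering). Thinning retreats about
one pixel per fragment tip and junction clusters absorb a few internal
steps, so detected total length sits a few percent below truth (mean
within 10% across the fragmentation range); tree counts are exact. Segment
lengths are 12–28 px and side branches start with probability 0.10 per
segment, keeping junction density low enough that these losses stay small.

What the benchmark does *not* emulate: curved filaments, 3-D stacks,
intensity variation along filaments, touching cells, or realistic PSFs.
Passing recovery tests shows the measurement chain is faithful to its own
conventions, not that it segments arbitrary real micrographs.

## Micropattern spreading

Patterns (the equilateral-triangle envelope of an extra-large Y motif,
default side 90 µm at 1.0 µm/px) sit on a grid whose pitch exceeds any
cell's extent, so neighbours cannot touch. One cell per pattern is drawn
as a filled equilateral triangle; the scale factor is calibrated by
bisection so the rasterized pixel count matches the target area, and the
truth records the rendered footprint exactly. True areas are normal
(default mean 2000, SD 250 µm², truncated at 600), bracketing the 1800 µm²
spreading threshold the way healthy fibroblast populations do.

Analysis thresholds (Otsu), fills holes (spreading area is the footprint,
not the stained skeleton), labels components, drops sub-25 px debris, and
assigns each component to its nearest pattern center; patterns with zero
or multiple cells are excluded with the reason logged. The spread flag
uses strict `area > 1800 µm²` — "exceeding" — so a boundary cell does not
count. Percentages are reported over the analyzed cells of a field; with
several fields, per-well percentages and the pooled percentage generally
differ and both can be computed from the per-cell table.

## Stain color index

The generator paints an exact count `round(f · ROI)` of ROI pixels in the
stain hue band (magenta-pink, hue 0.82–0.96 of the hue circle, saturation
0.45–0.85) over a pale low-saturation background, then quantizes to 8-bit
RGB; `f` is exact by construction. The quantification selects pixels by
hue band + minimum saturation (0.15), histograms hues into 255 equal
categories — making the histogram a pure color measure independent of
brightness — sums the stain peak and divides by the ROI area. The ROI is
always a supplied mask; there is no automatic dermis segmentation. The
band and saturation floor are echoed into every result for provenance.
Recovered indices are affine in `f` with unit slope to within the 8-bit
hue quantization.

## Melatonin cycling

Schedule: 24 h cycles of 8 h day + 16 h night; sampling 30 min before
night onset and +2/+5/+8 h after it. The clean signal is a constant day
baseline (default 20 assay units — ELISA units are treated as arbitrary,
no absolute calibration) plus a raised-cosine night bump scaled by
`(1 − s)`, `s` the blue-light suppression. The bump is normalized so that
mean(night samples) − baseline equals `amplitude · (1 − s)` *exactly* at
zero noise: the within-replicate induction statistic is unbiased by
construction, and `ŝ = 1 − induction/amplitude` recovers `s` (±0.1 at the
default 5-unit noise with 200 replicates; the estimator error shrinks as
1/√n). Day 1 is the default analysis window, the day on which the
untreated/stressed contrast is established; comparisons use the
non-parametric unpaired route, matching small-replicate release data.

## Conversion kinetics and dose arithmetic

Crocin stays at its initial concentration through a lag (default 66 h),
then declines along a logistic tail `c₀ · 2/(1 + exp(rate·(t − lag)))`
(default rate 0.04 h⁻¹, giving completion — crocin < 1% of initial —
near 200 h inside a 240 h observation window); crocetin is `c₀ − crocin`,
so the 1:1 molar balance is an identity before noise. The default
`c₀ = 1.79 mM` is the crocin molarity of a 10% dose of a 50 g/L extract
solution at 35% w/w crocin. Optional multiplicative noise (CV) is applied
independently to both series, after which the balance holds only in
expectation. Molar contents use a mass basis (mmol/kg); g/L inputs are
treated as kg-equivalent at density 1.0 kg/L unless stated. The
completion tolerance (1%) and the crocetin plateau criterion (< 2%
relative variation over the final quarter of the window) are configurable.
Spectrum summaries integrate by the trapezoid rule with band edges
interpolated onto the grid; the blue band is fixed at 400–490 nm.

## Statistics ladder

Shapiro–Wilk at α = 0.05 on *every* group gates the route; groups with
n < 3 or zero variance are rejected as degenerate rather than silently
routed. Parametric: unpaired t-test for two groups, one-way ANOVA followed
by Dunnett's test against the reference (single pooled variance, exact
multivariate-t implementation) for more. Non-parametric: Kruskal–Wallis
followed by pairwise two-sided Mann–Whitney U vs the reference (unpaired),
or Wilcoxon signed-rank (paired). Comparing a group with an identical copy
of itself returns p = 1 rather than an error. Percent effects are
100·(treated − reference)/reference, rounded half away from zero — the
rounding that reproduces the worked percent annotations from their printed
means; the three annotations that do not round consistently from their own
printed means are documented test exclusions, not chased. `#` (p < 0.1) is
reported as a trend flag, `ns` at p ≥ 0.1. Under the global null the
Dunnett route's family-wise error calibrates to 0.05 (within [0.03, 0.07]
over 1000 simulations), the Mann–Whitney rejection rate to 0.05 ± 0.02,
and the triple Shapiro gate passes ≈ 0.95³ of normal triplets.

## Pipeline

`pipeline.run_experiment` materializes defaults into the config, refuses
to start without an explicit seed, derives every per-cell seed from the
root seed, and writes per-cell CSVs, rendered report tables, and a
manifest with the full config plus SHA-256 checksums of every output —
identical config + seed reproduce identical checksums. Report cells are
written at full float precision so the rendered tables parse back exactly.

## Problem sizes

Defaults are chosen so a full test run and the acceptance script each
complete in about a minute on one CPU: 320×320 px cells, 25–50 seeds per
fragmentation level, 30 cells per demo condition, 200 melatonin
replicates, and 1000 simulations per calibration estimate. All sizes are
parameters; nothing in the methods depends on them beyond Monte-Carlo
resolution.

## Known limitations

- Junction-cluster internal steps carry no length, so branch-dense
  networks under-measure total length by a few percent relative to the
  generating polylines; the bias is shared by any convention that merges
  junction clusters.
- The fragmentation axis controls fragment *count* at fixed budget;
  stressed conditions in real data also lose total network length, which
  the demo reproduces by lowering the budget per condition rather than
  coupling it to `f`.
- Stain quantification assumes a single chromogen; no color deconvolution
  of mixed stains.
- The melatonin model has no circadian drift, desynchronization, or
  day-to-day amplitude change; it tests the induction/suppression
  estimator, not circadian biology.
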