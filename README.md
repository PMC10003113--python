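# photoskin

Quantification of blue-light ("digital stress") damage and protection in
skin models. Chronic exposure to the 400–490 nm blue band of device screens
fragments the mitochondrial network of dermal fibroblasts, contracts cell
spreading on adhesive micropatterns, raises oxidized-protein immunostaining
in skin sections, and suppresses the night-phase rise of melatonin in
cyclized co-cultures. This package implements the measurement side of such a
study — every quantification, plus synthetic data generators with known
ground truth so each stage can be validated end to end — for image-analysis
and in-vitro scientists who need these readouts to be testable.

## What it computes

**Mitochondrial network morphology** (`photoskin.mito`). A fluorescence
image is thresholded, skeletonized to a one-pixel medial line, and
decomposed into a graph: nodes are *junctions* (skeleton pixels with ≥ 3
neighbours, 8-adjacent junction pixels merged into one node) and
*endpoints* (1 neighbour); *branches* are the filament segments between
nodes; *trees* are the connected components. On the raster an axial step
counts 1·`pixel_size` and a diagonal step √2·`pixel_size`. Per cell:

- network total length `L = Σ branch lengths` (µm),
- trees per length `N_t / L` (µm⁻¹) and average tree length `L / N_t`,
- branches per length `N_b / L` and average/maximum branch length.

Fragmentation (the stress phenotype) raises the densities and shortens the
averages. Per-well values are unweighted means over single cells.

**Micropattern spreading** (`photoskin.spread`). Per-cell area = foreground
pixels × `pixel_size`²; a cell is *correctly spread* when its area strictly
exceeds 1800 µm². Reported per condition: mean area and % spread cells.

**Stain color index** (`photoskin.stain`). Stain-colored pixels (a hue band
with minimum saturation) are selected inside a region of interest,
histogrammed into 255 hue categories, and the peak counts are summed:
`color index = sum count / ROI area ∈ [0, 1]`, expressed as % of the
stressed control.

**Melatonin cycling** (`photoskin.melatonin`). Series sampled 30 min before
each night onset and +2/+5/+8 h into the night are phase-aligned; the
*night induction* of a replicate is mean(night) − baseline, and condition
comparisons run through the statistics ladder.

**Dose & conversion arithmetic** (`photoskin.dose`). Cumulative dose
(J/cm²), molar content (`w/w × 10⁶ / M` mmol/kg; crocin M = 976.97 g/mol,
crocetin M = 328.41 g/mol), 1:1 molar balance checking of
crocin→crocetin conversion curves, and absorption-spectrum summaries
(λ_max, share of absorbance in the 400–490 nm blue band).

**Statistics ladder** (`photoskin.stats`). Shapiro–Wilk on every group
gates parametric vs non-parametric; then unpaired t-test (2 groups) or
one-way ANOVA + Dunnett vs the control (parametric), Kruskal–Wallis +
pairwise Mann–Whitney U (non-parametric unpaired), or Wilcoxon signed-rank
(paired). Effects are percent change vs the reference mean, flagged
`#`/`*`/`**`/`***` at p < 0.1/0.05/0.01/0.001.

All synthetic generators live in `photoskin.synth` and are deterministic
under a seed; their ground truth satisfies exact conservation laws (length,
area, stained fraction, molar balance) before noise.

## Worked example

```python
from photoskin import mito, stats
from photoskin.synth import gen_mito_image

image, truth = gen_mito_image(fragmentation=0.8, total_length=260.0, seed=1)
metrics, graph = mito.analyze_cell(image)
print(truth.n_trees, metrics.n_trees)                  # 24 24
print(round(metrics.avg_tree_length, 2))               # 9.75  (µm)
print(stats.percent_change(259.69, 454.06))            # (-42.807..., -43)
```

The generator placed 24 filament fragments with a 260 µm total length
budget; the analysis recovers the tree count exactly and the per-tree
length to within a few percent. The last line reproduces a stressed-vs-
untreated network-length annotation (−43%) from the two per-well means.

The numbered scripts under `analysis/` run each study stage and write
tables under `results/`:

```
python analysis/02_mito_network.py --seed 1     # fragmentation sweep
python analysis/08_run_demo.py --seed 1         # full three-condition demo
```

`analysis/08_run_demo.py` prints network and spreading tables in which each
cell carries its percent change and significance flag vs the blue-light
control, e.g. `2257.77 (+18% *** vs. blue light control)`.

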