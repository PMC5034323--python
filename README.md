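# isletquant

Unbiased whole-section quantification of pancreatic endocrine cell mass from
multi-channel fluorescence images, with islet morphometry, nucleus-based cell
typing, and simulations of the sampling designs it replaces.

## The problem

Endocrine cell mass — the fraction of pancreas tissue occupied by
hormone-positive cells — is the central readout in studies of diabetes,
islet development and beta-cell regeneration. It is usually *estimated* by
sampling: counting grid vertices on a few microscope fields, or measuring a
handful of islet-rich regions per section. Because islets are sparse,
clustered, and span four orders of magnitude in size (from single cells to
structures of thousands of cells), such sampling is easily biased several
fold. Measuring the *entire* section removes the sampling step: every
hormone-positive pixel is counted and normalized to a manually contoured
pancreas area.

`isletquant` implements that whole-section pipeline as a Python library with
a thin CLI:

* **raster and contour IO** — calibrated multi-page TIFF channels (one
  nuclei channel, 1–3 hormone channels), pancreas/exclusion contours as
  GeoJSON or ImageJ `.roi` polygons;
* **preprocessing** — rolling-ball background subtraction, tissue-mask
  construction (pancreas outline minus every exclusion region occupying
  >0.05 % of the outline), manual or Otsu thresholds;
* **islet segmentation** — morphological closing + hole filling groups
  stained pixels into islet structures with identification numbers;
  per-islet stained area, filled area, centroid, perimeter,
  circularity `4πA/P²` and Feret diameter (rotating calipers);
* **cell typing** — distance-transform watershed of the nuclei mask; each
  nucleus perimeter is expanded by 1 px and the most prevalent hormone
  signal in that perinuclear ring assigns the cell type;
* **stereology simulations** — point-counting grids (default 25 µm
  spacing), islet-rich panel-selection curves, every-nth-section designs,
  head/body/tail block-selection schemes, largest-N-islet cell ratios;
* **analytics** — log-binned size distributions in cell-equivalents
  (area / 178 µm²), composition-by-size curves, area-fraction curves,
  density-coded size/shape scatter;
* **synthetic data** — a seeded generator that renders sections with full
  ground truth, so every stage is testable without any specimen.

## Worked example

```python
from isletquant import (RunConfig, SynthParams, generate_section,
                        quantify_section, truth_summary)

section, contours, gt = generate_section(
    SynthParams(frame_um=(1200.0, 1200.0), n_islets=15, seed=3))
cfg = RunConfig(pixel_size=1.0,
                thresholds={r: 100.0 for r in section.channels})
result = quantify_section(section, contours, cfg)
print(result.summary.islet_count, truth_summary(gt).islet_count)
print(result.summary.percent_endocrine_area)
```

Running `python examples/02_quantify_section.py` (this scenario) prints:

```
                        pipeline       truth
islet count                   15          15
percent endocrine area     3.484       3.484
pancreas area (um^2)     1440000     1440000
n glucagon                    76          76
n insulin                    185         185
n somatostatin                22          22
```

All 15 planted islets are recovered, the percent endocrine area (total
hormone-positive area over pancreas area, ×100) matches the generator's
truth, and every one of the 283 cells is typed correctly from its
perinuclear ring. `examples/03…05` demonstrate point counting (unbiased
when averaged over grid offsets, coarse on single panels), the
sampling-bias simulations (islet-rich panel selection overestimated the
endocrine mass 4.7-fold on a clustered section; the top-100-largest-islet
beta/alpha ratio came out 0.90-fold of the all-islet ratio), and the size
distribution analytics (the few large islets carry most of the islet area).

The same pipeline runs from the shell: `isletquant synth`, `isletquant
quantify --config cfg.yaml`, `isletquant point-count`, `isletquant
panel-bias`, `isletquant block-sim`, `isletquant top-n-ratios`.

## Documentation

`docs/methods.md` describes the model and procedure, every tunable
parameter with its default and units, what the synthetic generator does and
does not emulate, and the package's numerical choices and limitations.
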