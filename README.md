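# nucloc

Quantify how strongly a fluorescently tagged protein — typically a
transcription factor — is concentrated in the nucleus of a single cell,
from segmented microscopy images.

Nuclear translocation of factors such as Msn2, Dot6 or Mig1 in budding
yeast is a standard readout of signalling dynamics: cells are imaged in
time lapse, segmented, and each cell at each timepoint is reduced to one
number describing how nuclear the factor is.  When a second fluorophore
marks the nucleus (e.g. Nhp6a-mCherry), that number has a natural
definition, the **nuclear localization**

```
ℓ = ⟨I_nuc⟩ / ⟨I_cell⟩
```

the ratio of mean fluorescence over the nuclear pixels to the mean over
all cell pixels (nucleus included).  ℓ = 1 means uniformly distributed,
ℓ > 1.65 marks predominantly nuclear cells, 1.15 < ℓ < 1.65 predominantly
cytoplasmic ones, and ℓ ≤ 1.15 usually indicates a poorly segmented cell.
Multiplying ℓ by ⟨I_cell⟩ recovers the nuclear concentration ⟨I_nuc⟩.

Without a nuclear marker, practitioners fall back on ad-hoc
spatial-inhomogeneity statistics.  This package implements the whole
comparison toolkit:

* **Ground truth** — ℓ from a nuclear-marker channel, with the nucleus
  segmented by Otsu, Kapur, Johannsen, Bernsen or Contrast thresholding
  after a Gaussian blur (`nucleus_segmentation`).
* **Seven published proxies** — brightest-20% mean, coefficient of
  variation, top-3/rest and top-5/rest ratios, smoothed disc-median
  ratio, top-5 minus rest difference, and the first Hu invariant moment
  η₁ (`localization_metrics`).
* **A convolutional regressor** — a compact three-conv-layer network
  mapping a 64×64 single-cell crop (fluorescence + optional bright-field)
  straight to ℓ, trained with MSE/Adam under a linear learning-rate
  schedule, with random hyperparameter search (`cnn_localizer`).  The
  network and its training are implemented directly in NumPy.
* **A synthetic-cell generator** — single cells and glucose-switch time
  series with *known* ℓ, PSF blur, shot and read noise
  (`synthetic_cells`).
* **Evaluation machinery** — centred log₂-ratio error distributions,
  min-max-normalized time-series overlays, per-timepoint/per-cell RMSE,
  Pearson correlation and Kraskov–Stögbauer–Grassberger mutual
  information (`evaluation`).

## Worked example

```python
import numpy as np
from nucloc import (
    SceneParams, make_scene, SegmentationConfig, segment_nucleus,
    NucleusMask, ground_truth_localization, quantify_all, classify_cells,
)

# a synthetic cell constructed to have localization 2.0
scene = make_scene(SceneParams(target_loc=2.0, seed=7))

# segment the nucleus from the marker channel, then measure ℓ
nuc = segment_nucleus(scene.image, SegmentationConfig(method="otsu", blur_sigma=0.5))
loc = ground_truth_localization(scene.image, nuc)
print(f"measured ℓ = {loc.value:.3f}  (constructed: {scene.true_loc:.3f})")
print("class:", classify_cells([loc.value])[0])

# the marker-free proxy statistics
values, _ = quantify_all(scene.image)
for tag, v in values.items():
    print(f"{tag:>9s}: {v.value:.3f}")
```

prints

```
measured ℓ = 1.790  (constructed: 1.867)
class: nuclear
 petrenko: 158.088
 sunnaker: 0.337
     logg: 2.350
 granados: 2.381
  bodvard: 1.847
   caihao: 129.828
      hu1: 0.001
```

The PSF blur dilutes the constructed 2.0 to a realized 1.867, and shot
noise plus the segmentation's own blur account for the remaining gap to
the measured 1.790.  Each proxy reports its own scale, which is why the
evaluation module compares methods through scale-free error summaries.

A command-line interface mirrors the library:
`nucloc simulate`, `nucloc segment`, `nucloc quantify`, `nucloc train`,
`nucloc predict`, `nucloc evaluate` (see `nucloc --help`).

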