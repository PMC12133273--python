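# Methods

## The localization statistic and its bands

For a segmented cell with a known set of nuclear pixels, nuclear
localization is defined as ℓ = ⟨I_nuc⟩/⟨I_cell⟩, the mean fluorescence
over nuclear pixels divided by the mean over all cell pixels (nucleus
included).  ℓ is scale-free in the fluorescence units, equals 1 for a
uniformly distributed protein, and multiplying by ⟨I_cell⟩ recovers the
nuclear concentration.  Cells are classified by two bands: values at or
below 1.15 are treated as segmentation artifacts (the lowest mode of the
empirical ℓ distribution comes from poorly segmented or dividing cells),
values in (1.15, 1.65] as predominantly cytoplasmic, and values above
1.65 as predominantly nuclear.  Boundary values sit with the lower class;
the underlying inequalities are strict on one side only and a convention
had to be fixed.

## Nucleus segmentation

The nucleus is found by thresholding the nuclear-marker channel inside
the cell mask, after a Gaussian blur (default sigma 1.0 px).  Global
methods (Otsu, Kapur maximum-entropy, Johannsen minimum-entropy) build a
256-bin equal-width histogram spanning the in-mask intensity range —
the classical convention for these estimators — and return a threshold
at a bin edge; a pixel is nuclear iff strictly above the threshold, so
a pure-background degenerate image yields an empty (flagged) mask rather
than a spurious nucleus.  Local methods (Bernsen, Contrast) classify each
pixel against its window (default 15 px): Bernsen thresholds at the
window mid-grey with a low-contrast fallback to the global-mean class;
Contrast assigns a pixel to whichever of the window extremes it is
closer to.  Johannsen candidates are restricted to populated histogram
bins that split off two non-empty classes, the standard guard, and the
criterion is minimized.  Bimodality of the marker histogram is assumed,
not enforced; a dip statistic is logged as a diagnostic
(`bimodality_diagnostic`) because on real data this property is
guaranteed by the experimental design (a constitutively bright nuclear
marker), not by computation.

Otsu thresholds on blurred small nuclei are systematically dilated by
the blur halo (intermediate-intensity ring pixels): with both the
rendering PSF and the preprocessing blur at 1 px, a 3-px-radius nucleus
is recovered at IoU ≈ 0.75; with moderate optics (PSF 0.5 px) recovery
is essentially exact.  Kapur's maximum-entropy criterion sits lower in
the histogram valley and admits background-tail pixels when the nucleus
occupies less than ~10% of the cell; the classical observation that the
global methods behave alike holds for well-resolved bright markers, and
the corresponding test uses that regime (4.5-px nucleus, SNR ≈ 10,
sharp marker).

## The proxy statistics

All seven statistics operate on in-mask pixels only; "remaining pixels"
means in-mask pixels outside the selected bright set.  Top-k selection
sorts by intensity descending with row-major pixel index as the
tie-break, so results are reproducible; ties are measure-zero on real
data.  The brightest-20% count is ⌈0.2 N⌉ so one-pixel cells are legal.
The coefficient of variation uses the population standard deviation
(ddof 0) by default; both choices are configurable.  The disc-median
statistic smooths the in-mask image with a mask-normalized Gaussian
(sigma 1.0 px) so pixels outside the cell do not dilute the smoothing,
centres a disc (radius 3 px) on the brightest smoothed pixel, and takes
the ratio of disc median to remaining median; the published description
is ambiguous between this reading and fitting a 2-D Gaussian profile,
and the smoothing-then-disc-median reading was implemented (the
alternative would be a separate estimator, not a parameter change).

The first Hu invariant moment is computed from intensity-weighted
central moments, treating fluorescence as mass: η₁ = η₂₀ + η₀₂ with
η_pq = μ_pq/μ₀₀^(1+(p+q)/2).  This normalization is invariant to
translation, rotation and spatial scale of the masked image, but scales
as 1/k when all intensities are multiplied by k — an intrinsic property
of the classical definition, asserted as such in the tests.

## The convolutional regressor

The network maps a fixed 64×64 single-cell crop to one continuous value
interpretable on the ℓ scale.  Architecture: `n_conv_layers` blocks of
3×3 same-padding convolutions + ReLU (channel count doubling from
`base_channels`), 2×2 max pooling after every block except the last,
flatten, then a fully connected head (hidden width 64) ending in a
single linear unit.  Defaults: 3 conv blocks, base 8 channels, 1
convolution per block, 2 fully connected layers, 2 input channels
(fluorescence + bright-field).  Inputs are cropped to the cell bounding
box, zeroed outside the mask, centred in the frame (cells larger than
the frame are down-scaled and flagged; yeast at 60× rarely exceeds
64 px), and each channel is divided by its in-mask median intensity so
arbitrary fluorescence units cancel.

Inputs are normalized per channel by the in-mask *median* intensity —
the typical cytosolic level — so that the normalized nuclear amplitude
is independent of the nucleus-to-cell pixel fraction.  (Normalizing by
a high percentile was tried first and rejected: the 99th percentile
falls inside the nuclear intensity range at a position that depends on
cell size, which couples the normalized amplitude to geometry and
induced a measurable size-dependent prediction bias.)

Training minimizes mean squared error against ground-truth
localizations (marker-derived on real data, the generator's known truth
on synthetic data) with Adam (default) or SGD, batch 64, learning rate
1e-3 decaying linearly to 0.5× over 50 epochs and constant after, 10%
random validation split.  Labels below 1.15 are excluded by default because
that mode reflects segmentation artifacts, not biology (a flag restores
them).  Random hyperparameter search samples batch size 16–256, epochs
20–200, learning rate log-uniform 1e-5–1e-1, scheduler epochs 20–100,
optimizer ∈ {adam, sgd}, base channels 4–32, and 1–3 conv layers /
convolutions per layer / fully connected layers, ranking candidates by
validation accuracy at the 1.65 band.

The network, its gradients (im2col/GEMM convolutions in a channels-last
layout), and both optimizers are implemented directly in NumPy in
float32.  This keeps the package dependency-light and bit-reproducible
on a single CPU thread: the same seed and data give identical weights.
Max-pooling backward routes gradient through an equality mask; positive
ties are vanishingly rare in float32 and zero ties are annihilated by
the preceding ReLU's gradient mask.

## The synthetic-cell generator

Scenes emulate trapped budding yeast imaged at 60× (0.18 µm/px): an
axis-aligned elliptical cell (default semi-axes 12 × 9 px; populations
jitter 9–17 × 7–13, spanning newborn through grown/old cells so that
the sizes a multi-hour time-lapse produces are represented), a disc
nucleus (default radius 3 px, jittered 2.5–3.8), uniform cytoplasm at
100 photons/px with a lognormal inter-cell expression spread (sigma
0.25 in log space — protein abundance varies severalfold between
cells), and a nucleus level solved in closed form so the noise-free
field realizes a requested ℓ* exactly
(n* = ℓ*c(N_cell−N_nuc)/(N_cell−ℓ*N_nuc)).  Rendering applies a
Gaussian PSF (sigma 1 px; optionally five defocused planes
max-projected, since the analysis only ever sees maximum projections),
then Poisson shot noise and Gaussian read noise (SD 5) — a plausible
sCMOS regime; no measured values exist for these constants and they are
configurable.
The marker channel is a bright nucleus (5× contrast) on a dim cell,
bimodal by construction; the bright-field channel is a dark cell-edge
ring with faint nucleus shading.  The realized localization of the
noise-free (post-blur) field is recorded as the truth before noise;
blur spreads nuclear signal into the cytoplasm, so the realized ℓ sits
up to ~12% below a strong target, and all parameter-recovery statements
are made against the realized value.

Time series follow a glucose-switch profile: a pre-switch baseline,
exponential relaxation to the post-switch level (rate 0.5/frame by
default), and optional telegraph bursts — a two-state process with
per-frame entry rate and mean dwell, initialized at its stationary
occupancy — that transiently move pre-switch frames to the stimulated
level, emulating the spontaneous nuclear entry/exit of stress factors in
unstressed cells.  Exit-type factors swap the high/low roles.  Three
slow acquisition processes are superimposed, because multi-hour
time-lapse intensities are never static: lognormal frame-to-frame
expression fluctuation (CV 0.10), exponential photobleaching
(0.3%/frame), and cell growth (0.5%/frame on the axes, capped at the
frame).  The localization truth is intensity-scale free, but statistics
that track raw brightness are exposed to these drifts, as on real data.
Each frame is rendered independently with a seed derived from the
master seed.

What the generator does *not* emulate: irregular cell shapes, budding
and division, nucleus movement within a frame, autofluorescence
gradients, flat-field inhomogeneity, or segmentation errors in the cell
mask itself.  Passing tests therefore demonstrate correctness of the
estimators and the learnability of the mapping under controlled
conditions, not performance on real microscopy.

## Evaluation

Methods live on incommensurate scales, so comparisons are scale-free.
Centred log₂ ratios (log₂ of prediction over truth, minus the mean over
cells) remove each method's multiplicative bias; their standard
deviation and adjusted Fisher–Pearson skewness summarize spread and
asymmetry.  Statistics that can be non-positive receive an additive
shift before logs (the disc-median ratio: +1); statistics that run
opposite to localization are negated before min-max normalization, with
the inversion decided by the sign of their correlation with ground truth
on a calibration set rather than hard-coded per dataset.  Time-series
RMSE (per timepoint across cells, and per cell across timepoints) is
computed on per-cell min-max-normalized series for all methods including
ground truth, because raw-scale RMSE would be dominated by scale rather
than shape; a raw mode is provided, and series without dynamics
(constant) fall back to raw scales.  Mutual information uses the
Kraskov–Stögbauer–Grassberger k-nearest-neighbour estimator (algorithm
1, max-norm, k = 3, natural log), clipped at zero.

## Problem sizes

The benchmark network is trained on 4200 synthetic cells (ℓ* uniform in
[1.0, 2.6], default geometry, noise and expression spread) for 30
epochs and evaluated on 800 held-out cells — the package's desk-scale
stand-in for the ~180 000-image populations a real experiment produces.
At these sizes training takes about five minutes on one CPU core,
held-out classification accuracy at the 1.65 band is ~96%, and the
correlation with the true localization is ~0.98.  The time-series
benchmark uses 100 cells × 60 frames with the switch at frame 30,
alternating entry- and exit-type dynamics with light bursting and
per-cell geometry jitter.

## Known limitations

* The NumPy network trains at desk scale only; it is deliberately small
  and has no GPU path, data augmentation, or regularization beyond the
  learning-rate schedule.
* The generator's piecewise-constant intensity model makes the spatial
  proxy statistics better behaved than on real images.  This matters for
  the time-series ranking: under this model the order-statistic and
  median-based proxies are near-optimal estimators of the realized
  localization (the top-k/rest ratios have almost no systematic error,
  and the disc-median ratio's default 3-px disc is effectively a matched
  filter for the synthetic disc nucleus), so at desk scale the network
  outperforms the intensity-tracking statistics (brightest-20% mean,
  bright-minus-rest difference, CV, η₁) but does not overtake the best
  ratio statistics — the corresponding benchmark test asserts the full
  ordering and documents this gap when it fails.  Real images contain
  irregular nuclei, vacuoles, puncta and focus drift, which defeat
  peak- and median-based statistics; the generator deliberately does not
  model intracellular structure.
* Bernsen/Contrast local thresholding parameters (window, contrast
  floor) are classical defaults, not tuned to any dataset.
* The Johannsen variant implemented is the standard minimization of the
  Johannsen–Bille criterion; sources differ on the variant used by
  published comparisons.
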