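# Methods

## The measurement model

The object of study is a *density profile*: the mean fluorescence intensity of a
channel as a function of signed distance from the epithelial boundary, averaged
along the epithelium. Distance is Euclidean, in micrometres, measured to the
boundary *pixel chain* (positive luminal, negative in tissue, zero on the chain
itself). Bins are uniform and half-open `[lo, hi)` — each pixel contributes to
exactly one bin via its centre distance — with pixel counts recorded per bin and
empty bins carried as missing values, never as zeros. Pixels under the debris
mask are excluded from both numerator and denominator, so masked regions cannot
bias bin means.

Profiles are z-normalized per image over the full profiling range
(mean-subtracted, divided by the sample SD over non-missing bins), then averaged
bin-wise per animal, windowed (default 0–20 µm), and compared across groups.

### Why "per image, full range" normalization

The z-transform is stated by the quantification convention this package
follows; its *scope* is a design choice here. Normalizing each image over the
full 0–100 µm range before any aggregation (a) makes fields comparable across
staining efficiency and detector gain, and (b) fixes the reference frame
against which a genotype's mucus peak is "high". Per-animal or per-group
normalization is a one-line change (`normalize_profile` after
`aggregate_by_animal`) and is deliberately not the default.

An important consequence: z-normalization is invariant to affine rescaling of a
profile. A pure amplitude effect on an isolated signal component is therefore
*invisible* after normalization; group differences are only observable because
real profiles contain structured components that do not scale with the signal
(see the generator, below).

## Boundary detection

Chain: Gaussian smoothing (σ = 2 µm default) → Sobel gradient magnitude → Otsu
threshold → morphological closing (3 µm) → hole filling → largest connected
component → edge refinement → lumen-facing edge extraction → orientation.

Two refinements matter in practice:

- **Solidification.** The lumen is taken as the largest connected component of
  the mask complement; smaller complement pockets (holes open to the image
  frame) are absorbed into tissue, so exactly one lumen-facing edge exists.
- **Half-max refinement.** Thresholding a gradient band keeps the band's outer
  envelope, which sits roughly one smoothing σ luminal of the true edge (~3 px
  bias at defaults). The mask is therefore re-thresholded at the midpoint
  between the lumen level and the *inter-nuclear tissue floor*, the standard
  unbiased localisation of a blurred step. Both levels are estimated from the
  raw image (medians / 20th percentile well inside each side of the initial
  mask): the smoothed image blends bright nuclei into the floor estimate and
  biases the edge tissue-ward. A gradient-ridge snap was evaluated and
  rejected — nuclear texture gradients dominate the tissue-edge gradient and
  drag the ridge into the tissue.

On synthetic scenes this yields a mean absolute boundary error of ~0.7 px at
default noise, monotone in noise level. Orientation calls the dim DAPI side
(within 20 µm of the edge) the lumen and raises an explicit ambiguity error at
< 5 % relative difference, prompting the manual mode: a CSV polyline spanning
the frame, rasterized to an 8-connected chain, with the luminal side named by
the user.

## Debris classification

Luminal supra-threshold objects are segmented on a caller-chosen channel subset
— by default DAPI plus the FISH channels, *excluding* the diffuse mucus channel,
whose entire band would otherwise segment as one object. Per-channel thresholds
are Otsu over luminal pixels, floored at background mean + 4 SD so pure-noise
channels produce ~no objects. An object is debris iff any of:

1. **broadband** — threshold-normalised mean intensity > 1 in ≥ 2 spectrally
   distinct channels with second-brightest/brightest ratio ≥ 0.5
   (autofluorescence is spectrally flat; FISH and mucus signals are not);
2. **oversize** — area > 20 µm² (bacteria render at ~1–7 µm²);
3. **luminal tissue fragment** — DAPI-positive while detached from the tissue
   (shed epithelial cells carry nuclei; bacteria show no DAPI at tissue-scale
   imaging settings).

Every object's per-channel intensities, area, call and reason are persisted for
audit. Subtraction replaces masked pixels with the background estimate (0) and
is idempotent; since binning excludes masked pixels by count, the choice of
fill value cannot bias profiles. Thresholds are deliberately generous margins
around the synthetic object sizes and are per-dataset parameters, not
constants of the method.

## Statistics

The experimental unit is the animal (per-animal bin-wise mean profiles). The
primary test is a classical fixed-effects two-way ANOVA, `value ~ group *
distance_bin`, both factors categorical, fitted via OLS (Type II sums of
squares; identical to the textbook decomposition for the balanced designs the
pipeline produces). Distance bins are repeated measures within an animal, which
classical ANOVA ignores; two mitigations are built in rather than assumed away:

- a **group-label permutation test** on the same F statistic (animals as
  exchangeable units) reported next to the parametric p in every report — with
  5 animals/group its resolution floor is 1/126;
- per-image z-normalization, which removes most animal-level intercept
  variation before the window is taken.

Under an iid null the group-effect rejection rate at α = 0.05 calibrates to
0.03–0.05 in simulation; at the pipeline level (full scenes, ratio-1 groups)
the empirical false-positive rate at p < 0.01 stays within a few percent —
mildly anticonservative, which is why the permutation p is printed alongside.
Pointwise contrasts default to Welch's t (small n, no variance-equality
assumption) and are reported as group mean ± SD with p; requested distances
snap to the containing bin. No multiple-testing correction is applied across
channels by default, mirroring per-channel reporting conventions.

## The synthetic scene generator

Each scene renders, at 0.5 µm/pixel over 512×512 by default:

- **Tissue + DAPI**: tissue below a sinusoidal boundary (amplitude 10 µm,
  period 100 µm), cytoplasmic background 30, nuclei as disks (radius 2–4 µm,
  intensity 150–220, 0.03 µm⁻²) kept ≥ 1.5 µm below the surface — columnar
  epithelial nuclei are basal, and the DAPI-dark apical band is what makes the
  gradient edge clean in real sections too.
- **Mucus (MUC2)**: Gaussian peak at 11 µm (SD 4 µm), amplitude 20, plus an
  *unscaled* luminal digesta-autofluorescence haze rising sigmoidally to a
  plateau (amplitude 20) beyond ~25 µm. The haze is the structured, non-scaling
  component that keeps amplitude effects observable after z-normalization; with
  these defaults the wild-type normalized peak lands near 0.9 and a 3× group
  near 3.7, the signal-to-background regime the method is designed for.
- **Bacteria**: punctate channels drawn from an inhomogeneous Poisson process
  with distance-dependent rate (default EUB338: exponential decay, 20 µm scale,
  0.08 µm⁻² at the epithelium), stamped as Gaussian blobs (σ 0.75 µm, peak
  120), plus the same broadband haze (amplitude 15). Library rate shapes cover
  near-epithelium enrichment, depletion, and a ~10 µm crossover. Puncta are
  never placed under debris (supports disjoint at generation).
- **Debris**: disks (radius 2–5 µm) added to *every* channel with correlated
  intensity (~100 ± jitter) — the broadband signature the classifier keys on.
- **Noise**: Poisson shot noise (gain 2 intensity units/count) plus Gaussian
  read noise (SD 6), independently per channel.

Group experiments scale signal-channel amplitudes of one group by an effect
ratio (default 3), never the backgrounds; per-animal seeds derive from one
master seed, and identical config + seed reproduces every byte.

What the generator does **not** emulate: optical PSF and z-sectioning, villus/
crypt topology, bacterial morphology and chaining, spectral bleed-through,
per-animal biological shape variability, staining gradients. Passing tests
therefore demonstrate correctness of the measurement chain and calibration of
the statistics under a controlled forward model — not robustness to every
failure mode of real histology. The boundary detector's accuracy in particular
is measured against scenes with a single smooth boundary.

## Numerical choices

- Coordinates are 0-based (row, col); boundary chains 8-connected; bins
  half-open; distance assigned per pixel centre; sample (n−1) SD everywhere.
- Distance is measured to the discrete boundary chain (exactly the brute-force
  min-over-boundary-pixels value, asserted in tests). Half-pixel quantization
  of that definition times a steep intensity slope bounds profile accuracy in
  Gaussian tails; at 0.5 µm/px the binned profile is within 2 % of the analytic
  curve in the mucus-layer core and within 2 % of peak amplitude everywhere.
- Peak ties break toward the smaller distance; all-missing profiles, constant
  profiles (SD = 0), empty design cells and zero residual variance raise typed
  errors rather than returning NaN.
- Simulation studies (power/calibration loops) use a narrow 160×48 µm field
  with the same channel models, and the closed-form balanced ANOVA; its
  equality with the OLS route is itself a test.

## Reporting

Every run persists all intermediates (masks as TIFF, tables as CSV, report as
JSON with config hash, seed and version) so any stage can be rerun in isolation
and two runs of one config are byte-identical. Figures (group mean ± SEM curves
per channel) are regenerated from the persisted CSVs, not from images.
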