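# mucoprofiler

Epithelium-referenced spatial profiling of fluorescence in intestinal
cross-sections.

Histology of the gut mucus layer and its microbiota asks a spatial question:
how much mucus (MUC2 immunofluorescence) and how many bacteria (16S rRNA FISH
probes such as EUB338, BAC303, LGC354, MUC1437) sit at each distance from the
epithelial surface, and does a genotype or treatment shift that distribution?
`mucoprofiler` answers it as a reproducible pipeline for multichannel confocal
images of tissue sections:

1. **Boundary** — the lumen-facing epithelial edge is detected from the spatial
   gradient of the DAPI (nuclear) channel: Gaussian smoothing, Sobel gradient
   magnitude, Otsu threshold, morphological cleanup, then refinement of the mask
   edge to the half-maximum crossing of the smoothed intensity. A manual
   polyline mode covers sections the detector gets wrong.
2. **Debris** — autofluorescent luminal objects (plant material, shed epithelial
   cells) are segmented and classified by three auditable rules — broadband
   fluorescence across spectrally distinct channels, oversize area, or
   DAPI-positive detached fragment — and excluded from all signal channels.
3. **Profile** — every pixel gets a signed Euclidean distance to the boundary
   chain (positive into the lumen, micrometres); channel intensity is averaged
   along the epithelium into 1 µm distance bins, z-normalized per image
   (mean-subtracted, divided by the sample SD), and aggregated per animal.
4. **Stats** — per-animal windowed profiles (default 0–20 µm) enter a
   fixed-effects two-way ANOVA with group and distance bin as crossed
   categorical factors plus interaction; a group-label permutation test on the
   same F statistic is reported alongside (bins are repeated measures within an
   animal), and named distances get Welch two-sample contrasts reported as
   group mean ± SD with p.

A first-class **synthetic scene generator** renders confocal-like fields with
known ground truth — nucleated tissue band with a sinusoidal boundary, a
diffuse mucus channel peaking ~11 µm into the lumen over an unscaled luminal
autofluorescence background, punctate bacteria as an inhomogeneous Poisson
process in distance, broadband debris, mixed Poisson–Gaussian noise — so every
stage is tested end-to-end without microscope data.

## Worked example

The reference in-silico experiment mirrors a two-genotype comparison: 5 animals
per group, one 512×512 field per animal at 0.5 µm/pixel, the variant group
carrying 3× mucus and bacterial amplitude over an identical background.

```bash
python analysis/01_simulate_experiment.py
python analysis/02_detect_boundaries.py
python analysis/03_classify_debris.py
python analysis/04_density_profiles.py
python analysis/05_group_statistics.py
```

The last two scripts print (abridged):

```
MUC2:
  R451C: peak normalized density 3.76 at 10.5 um from the epithelium
  WT: peak normalized density 0.94 at 11.5 um from the epithelium

MUC2 (window 0-20 um):
  group effect:       F = 89903.6, p = 5.82e-222 (permutation p = 0.0078)
  at 11 um (mean ± SD): R451C: 3.67 ± 0.02, WT: 0.94 ± 0.05, Welch p = 6.95e-11

EUB338 (window 0-20 um):
  group effect:       F = 17.9, p = 3.82e-05 (permutation p = 0.0078)
```

Read: both groups place the mucus density maximum ~11 µm luminal of the
epithelium; the variant group's normalized peak is ~4× the wild-type value, the
0–20 µm window differs overwhelmingly by group, and total bacterial density
near the epithelium is shifted as well. The permutation p of 0.0078 is the
resolution floor of a 5-vs-5 label permutation (126 distinct splits), i.e. the
strongest evidence that design can state without distributional assumptions.
Boundary detection lands within ~0.6 px of the true edge and the debris
classifier recovers the planted objects at ≥0.99 precision/recall (scripts 02
and 03 print the per-field tables).

The same pipeline runs from one YAML config — `mucoprofiler run --config
run.yaml` — with stage subcommands (`simulate`, `boundary`, `debris`,
`profile`, `stats`) to rerun any step from its persisted inputs, on synthetic
or real TIFF inputs alike.

## Layout

- `src/mucoprofiler/` — library: `scene` (generator), `boundary`, `debris`,
  `profiles`, `stats`, `experiment` (in-memory runner), `pipeline` (staged
  orchestration + persistence), `config`, `cli`.
- `analysis/` — numbered drivers for the reference experiment.
- `tests/` — unit/property tests per module plus `test_acceptance.py`, the
  quantitative guarantees of the whole pipeline.
- `docs/methods.md` — model and design notes: what the generator emulates,
  parameter meanings and defaults, numerical choices, known limitations.
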