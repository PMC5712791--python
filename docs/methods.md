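# Methods

## Model and assumptions

The package measures the concentration of enzyme-labeled nanoparticles by
digital counting. Its assumptions, in order of appearance in the pipeline:

- **Scene**: monodisperse spherical water-in-oil droplets (~30 µm diameter)
  imaged in a single fluorescence channel at fixed magnification, appearing
  as round spots of similar radius that frequently touch but do not merge.
  Empty droplets are weakly luminescent (stray enzyme), occupied droplets
  are bright, and small bright speckles/vesicles may be present.
- **Noise**: photon shot noise (Poisson) plus detector read noise
  (Gaussian). At the photon counts of interest the mixture is treated as
  approximately Gaussian for denoising purposes.
- **Occupancy**: nanoparticles arrive at the droplet generator at random,
  so the count per droplet is Poisson(λ) and a droplet is fluorescent iff
  it holds ≥ 1 particle. Hence `p = 1 − e^(−λ)` and `λ = −ln(1 − p)` with
  `p` estimated as the fluorescent fraction of the detected droplets.
- **Volume**: a single average droplet volume `V = (4/3)π(d/2)³` with
  d = 30 µm converts λ to molarity; per-droplet measured radii are *not*
  used (the assay is calibrated to the nominal droplet size, and apparent
  image radii include segmentation dilation).

## Pipeline parameters

| parameter | default | units | role / rationale |
|---|---|---|---|
| `gaussian_sigma` | 1.0 | px | denoising bandwidth; small vs. the 16 px minimum droplet radius, so shape is preserved |
| `clahe_tiles` | 8 | — | tiles per image side; at full frames (1080×1920) a 135×240 px block holds several droplets, which the method needs (see Limitations) |
| `clahe_clip` | 0.05 | fraction of block pixels | clip limit of the 256-bin block histogram; limits noise over-amplification in flat background blocks |
| `opening_radius` | 5 | px | disk structuring element; deletes 2–4 px speckles, far below droplet scale |
| `radius_min`, `radius_max` | 16, 32 | px | Hough search band bracketing the apparent droplet radii |
| `hough_sensitivity` | 0.33 | fraction of perimeter | minimum vote support; one third of a circle suffices, so partially occluded droplets are kept |
| `droplet_diameter_um` | 30 | µm | nominal droplet size for the volume conversion |
| `avogadro` | 6.02×10²³ | mol⁻¹ | see below |
| `threshold_slope`, `threshold_intercept` | 1.3717, 0.0126 | — | the fitted mean-adaptive fluorescent threshold `D(m)` |

**The Avogadro constant is deliberately truncated.** The validation-series
reference concentrations are reproduced to all printed digits only with
N_A = 6.02×10²³ mol⁻¹ and d = 30 µm exactly (the full-precision
6.022×10²³ misses them by ~4×10⁻⁴ relative). The default therefore pins
the truncated value so stored tallies and concentrations stay mutually
consistent; override `avogadro` for full-precision work.

**The fluorescent threshold lives on the unit intensity scale.** Images
are normalized to [0, 1] on read (by 255 or 65535), and `D(m)`'s intercept
0.0126 only makes sense there. `m` is computed on the *denoised* image I:
a normalized Gaussian filter leaves the mean essentially unchanged while
making it insensitive to shot noise; the enhanced image J would distort
the mean nonlinearly. The fit behind the two coefficients is taken as
given — its training pairs (manual thresholds vs. image means) are not
available, so refitting is out of scope.

## Numerical and algorithmic decisions

- **CLAHE conventions**: 256 histogram bins regardless of source bit
  depth; clip value = `clip × block pixel count`; clipped excess is
  redistributed uniformly over all 256 bins and re-clipped iteratively
  until the residual excess is below one count (mass is conserved
  throughout); the block mapping is the normalized cumulative histogram
  (so `tiles=1, clip=1` is exactly global histogram equalization); output
  pixels bilinearly interpolate the four nearest block-center mappings,
  clamping to the nearest block outside the center lattice. Edge blocks
  absorb the division remainder.
- **Otsu**: exhaustive maximization of `ω₀ω₁(μ₀−μ₁)²` over all 255
  interior edges of a 256-bin histogram; ties take the smallest
  threshold; binarization is strict (`value > t`, ties to background).
- **Edge map**: inner morphological boundary with 4-connectivity (a true
  pixel with a false 4-neighbor). This thin boundary's pixel count tracks
  the ideal perimeter 2πr of a disk; the 8-connected variant is ~25%
  thicker and dilutes perimeter-normalized scores. Outside the frame
  counts as foreground, so regions flush with the border contribute no
  artificial straight edge.
- **Hough vote locus**: for radius r, the integer offsets whose rounded
  Euclidean length equals r — a width-1 annulus holding ≈ 2πr pixels, the
  exact discrete dual of the circle equation. Votes are accumulated by
  FFT convolution of the 0/1 edge image with the 0/1 annulus stamp and
  rounded back to exact integers (verified against a naive triple-loop
  reference in the tests).
- **Peak scoring**: a rasterized circle's boundary pixels straddle exactly
  two adjacent integer radii, so `find_circles` pools votes over adjacent
  radius-plane *pairs*, normalized by the pair midline perimeter
  2π(r+½); an ideal circle then scores ≈ 0.91–1.0 while interstitial
  ghost arcs between packed droplets stay far below (≈ 0.2–0.3, under the
  0.33 sensitivity floor). The pooled support map is smoothed spatially
  (σ = 1 px) for localization; candidate peaks are accepted greedily by
  descending score with non-maximum suppression at distance `radius_min`
  (the monodispersity assumption: two droplet centers cannot be closer
  than one minimum radius), ties broken by (row, col). Reported radii are
  pair midlines, so they carry a ±0.5 px discretization — the tool counts
  droplets, it does not do metrology.
- **Degenerate inputs**: constant images are rejected by Otsu (no two
  classes); a saturated readout (every droplet fluorescent) raises rather
  than returning an infinite λ — the assay is outside its dynamic range;
  zero fluorescent droplets give λ = 0 and 0 fM exactly; SNR with a
  noise-free background returns `inf` as a documented sentinel.

## The simulator

`dropcount.simulate.generate_fmi` emulates: rejection-sampled droplet
packing in which circles may touch (center distance ≥ rᵢ + rⱼ −
`max_overlap`, default 2 px) but never merge or engulf; truth radii
drawn uniformly from 18–28 px — near-monodisperse around the ~24 px
nominal radius, leaving margin inside the 16–32 px search band for the
~1 px apparent dilation that soft edges, denoising and thresholding add;
per-droplet Poisson(λ) occupancy (fluorescent iff k ≥ 1, default
λ = 0.14, matching the validation series' occupancy scale); intensity
levels background 0.05, empty 0.09, fluorescent 0.7 with a 1.5 px soft
radial edge; bright speckle distractors (radius 2–4 px, level 0.8);
Poisson shot noise at `photon_scale` = 500 photons per unit intensity
followed by additive Gaussian noise (σ = 0.02) and clipping to [0, 1].

The empty-droplet level 0.09 is chosen for internal consistency with the
fluorescent threshold model: at realistic fill fractions (~18% droplet
area) the image mean is ≈ 0.07–0.08, so `D(m)` ≈ 0.11 — empty droplets
must sit below that with a noise margin while staying well above
background, which is exactly the "weakly luminescent" regime the
enhancement stage exists for. An empty level at or above ~0.12 would make
every empty droplet cross `D(m)` and saturate the readout.

Not emulated: optical point-spread blur beyond the soft edge, droplet
polydispersity beyond the radius range, shrinkage/coalescence over time,
vignetting or illumination gradients, multi-frame or multi-channel data.
Passing tests therefore demonstrate correct behavior under the modeled
degradations (packing, weak empties, speckles, Poisson–Gaussian noise),
not robustness to optical artifacts absent from the model.

## Problem sizes in the test suite

Detection-quality checks run on 20 full-size frames (1080×1920, 200
droplets, λ = 0.14) at the generator defaults; occupancy-parameter
recovery pools 50 frames at 540×960 with 60 droplets each (3000 droplets,
so 3 binomial standard errors on λ̂ ≈ 0.018 at λ* = 0.10); unit tests use
540×960 scenes. All randomness is seeded; frame generation is
bit-reproducible for a given parameter set.

## Known limitations

- **CLAHE block size must exceed the droplet diameter.** With 8×8 tiles
  the method assumes blocks several times the droplet size (true for full
  frames). On frames below roughly 500 px a side, blocks approach droplet
  scale, block statistics become droplet-dominated, and segmentation of
  weak empties degrades. Reduce `clahe_tiles` for small crops.
- **Otsu assumes a two-class histogram.** When the realized fluorescent
  fraction is high (≳ 25%), the enhanced histogram turns trimodal
  (background / empty / bright) and the threshold can jump above the
  empty-droplet level, dropping weak droplets. The assay's intended
  operating range (λ ≈ 0.1–0.15, ~10–14% fluorescent) is safely inside
  the two-class regime.
- **Dynamic range.** The Poisson inversion loses precision as p → 1; a
  fully fluorescent frame is rejected outright. Dilution is the remedy,
  not extrapolation.
- **Counting, not localization.** Centers are good to ~1–2 px and radii
  to ~1 px, sufficient for counting; no sub-pixel refinement is done.
- **A single average volume** converts λ to molarity; droplet-to-droplet
  volume variation propagates directly into concentration error and is
  not modeled.
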