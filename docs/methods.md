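# Methods

This note records the models, conventions and design decisions behind
`fibis`, in enough detail to audit or reimplement any stage.

## Phasor model and conventions

A TCSPC pixel holds a histogram `h_k` of photon arrival times in `T`
uniform bins covering one laser period `P = 1/f_rep` (12.5 ns at 80 MHz).
The first-harmonic phasor is

    g = Σ h_k cos(ω t_k) / Σ h_k,   s = Σ h_k sin(ω t_k) / Σ h_k,

with `t_k` the **bin centers** (halves the discretization bias relative
to bin edges) and `ω = 2π f_rep` — the standard phasor convention; the
universal-semicircle identities and the 0.4 / 3.4 ns NADH trajectory
endpoints only hold with the 2π factor. Only the first harmonic is used.

Closed forms used throughout: a mono-exponential decay of lifetime τ sits
at `g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)`; the phase lifetime is
`τ_φ = (s/g)/ω` and the modulation lifetime `τ_M = (1/ω)√(1/(g²+s²) − 1)`.
For multi-exponential decays `τ_M > τ_φ` (tested property). Because the
generator folds decays over previous pulse periods, a binned synthetic
decay has *exactly* the closed-form phasor up to midpoint-rule error
(≪ 0.01 for T ≥ 64), so the generator and the transform validate each
other without shared code.

**Calibration** is a single global complex factor
`c = z_expected / z_measured` obtained from a reference fluorophore of
known mono-exponential lifetime (default 2.5 ns, the Coumarin-6 value of
the workflow this package mirrors); every pixel phasor `z = g + is` is
multiplied by `c`. This corrects a global phase offset and modulation
scale (instrument response) but deliberately not per-pixel IRF
variations — matching the single-reference workflow. Self-calibration of
the reference maps its mean phasor onto the expected point exactly, and
the operation is invertible to machine precision.

Pixel convention everywhere: 0-based, row-major, origin top-left, y
increasing downward. Pixels with zero photons have undefined (NaN)
phasors and are excluded from all aggregations.

## FIBIS segmentation

Stage order: normalize → detect scan noise → FFT denoise → threshold →
size-gate/erode. Identical inputs give bit-identical masks; each run
attaches a structured log (threshold, peaks removed, objects deleted or
eroded).

**Normalization.** Each of the `F` frames is independently z-scored
(zero-variance frames map to zeros), the standardized frames averaged,
and the average min–max rescaled to [0, 1]. Standardizing before
averaging gives faint frames the same weight as bright ones — the reason
the method can "highlight" signal that single bright frames would
otherwise compress.

**Scan-noise detection.** Stripe noise from line scanning is a gain that
varies along x, so its energy concentrates on the horizontal axis through
DC of the centered 2-D Fourier magnitude. Each axis component (outside a
3-px DC guard) is flagged when it exceeds `median + k·MAD` of all
components at the same integer radius, with `k = 6` and the
normal-consistent scaled MAD (1.4826 × raw MAD). Two implementation
details matter:

* the image is mean-subtracted and tapered with a **radially symmetric**
  Hann window before the transform. Without the taper, boundary
  discontinuities leak a spectral cross along both axes; with a
  *separable* taper, the window's own sidelobes do the same. Either
  artifact makes smooth blob images appear striped.
* components below `10⁻⁶ ×` the spectral maximum are ignored: for
  spectrally concentrated images the annulus statistics are computed over
  round-off dust, where "6 MADs above the median" is meaningless.

With these choices, smooth scenes and pure white noise are flagged in
≤ 5% of seeded trials, while 0.3-amplitude stripes are always found at
their true frequency.

**Denoising** multiplies the (unwindowed) spectrum by Gaussian notches
`1 − exp(−d²/2σ²)` (σ = 2 px) at every flagged peak and its conjugate,
inverse-transforms, and clips to ≥ 0. Unflagged images pass through
bit-identical. On striped fixtures the stripe Fourier coefficient drops
by ≥ 10× while total blob mass changes ≤ 5%, and the intensity
histogram's excess kurtosis decreases (the "more normal histogram"
effect).

**Thresholding.** Otsu's method (exhaustive between-class-variance
maximization over a 256-bin histogram) applied to the nonzero-pixel
intensities **winsorized to the interquartile band of their intensity
range**, `[min + 0.25·R, min + 0.75·R]` with `R = max − min`; the
resulting threshold is applied to the full image. The interquartile
restriction exists because rare very bright pixels stretch the intensity
range of an accumulated scan and drag the cutoff; clipping the histogram
(never the mask) makes the threshold invariant to how far that tail
reaches while keeping the brightest pixels in the foreground. We
deliberately interpret "interquartile" on the intensity *range*, not on
pixel percentiles: in any image where diffuse background pixels
outnumber object pixels, both pixel-percentile quartiles fall inside the
background mode, Otsu then splits the background against itself, about
half the background passes the threshold, and (8-connected site
percolation threshold ≈ 0.41) the speckle percolates into one giant
component that the erosion stage shatters into hundreds of spurious
in-range fragments. The range-based reading avoids this failure and is
verified against the intended behaviors (two-level images split exactly;
a blob over a 40%-intensity diffuse background separates ≥ 95%/≤ 5%).

**Size gating and erosion.** 8-connected components (8-connectivity
keeps thin diagonal mitochondria intact) are measured in µm using the
equivalent-area diameter `2√(area/π)·pixel_size`; components below
0.5 µm are deleted as noise. A component is *oversized* when its
equivalent diameter **or its major-axis length** exceeds 7 µm — the
major-axis criterion is needed because mitochondria are elongated: a
9-µm dumbbell of two bridged organelles has an equivalent diameter of
only ~2 µm. Oversized components are iteratively eroded along the
intensity gradient: at each step the boundary pixels with intensity
below the component's median are removed (if none qualify the whole
boundary is removed, so progress is guaranteed), the piece is relabeled
and re-measured, and derived pieces that fit the range are accepted with
their erosion count recorded. After `max_erosion_iters` (default 10)
leftover oversized pieces are deleted. Final labels are ordered by
centroid for determinism.

**Baseline.** The comparison method divides the accumulated raw
intensity by its 0.9-quantile (over photon-bearing pixels), clips to
[0, 1], applies plain Otsu and labels components — no noise handling, no
size gate, no erosion. On degraded scenes this baseline floods the
diffuse cytosol region into large unresolved blobs and keeps stripe
pixels; both failure modes are exercised in tests.

## Metabolic index

Each object's phasor is the intensity-weighted mean over its valid
pixels. The bound-NADH fraction is the scalar projection of that point
onto the chord between the pure free (0.4 ns) and bound (3.4 ns)
phasors, normalized by the chord's squared length and clamped to [0, 1];
off-chord points are orthogonally projected first (the standard
two-component phasor decomposition — the trajectory analysis is
one-dimensional). The reported value is the *bound* fraction (higher =
more OXPHOS-like); CSV outputs also carry the free fraction. The
projection treats photon counts as the mixture weights; no correction
for a quantum-yield difference between free and bound NADH is applied
(the generator's `relative_yield_bound` parameter exists to explore that
assumption; with yield ≠ 1 the recovered fraction is photon-weighted,
not concentration-weighted).

Outliers are rejected per acquisition group with a Mahalanobis ellipse:
points whose squared distance from the cloud mean (2×2 sample
covariance) exceeds the chi-square quantile at 95% confidence (2 d.o.f.)
are flagged and excluded from group statistics. On Gaussian clouds the
exclusion rate converges to 5% as n grows (tested). Groups are compared
with the two-sample Kolmogorov–Smirnov test (exact statistic, asymptotic
p-value — the regime of hundreds of organelles per condition).

Pseudocolor maps paint each object by its fraction through a monotone
256-entry colormap (viridis); colors decode back to fractions within
1/256.

## Image-quality metrics

MSE is `(1/MN) ΣΣ (R−F)²`; PSNR is `10·log₁₀(L²/MSE)` with `L = 255`
(masks are compared as 0/255 images so L is meaningful for binary
content; identical images report +inf). SSIM uses a uniform 7×7 window,
biased (moment) estimates of the local statistics, stabilizers
`C1 = (0.01·L)²`, `C2 = (0.03·L)²`, averaged over all full windows; the
implementation exposes the luminance and contrast-structure terms
separately because multi-scale SSIM needs the latter alone at fine
scales. MS-SSIM accumulates contrast-structure at each 2×2
average-pooled dyadic scale and luminance only at the coarsest, with the
canonical five-scale exponent weights (0.0448, 0.2856, 0.3001, 0.2363,
0.1333, renormalized when fewer scales fit the image); negative terms
are clamped at zero. All three metrics agree with definitional
double-loop implementations to 1e-9 on ≤16×16 fixtures; `scales=1`
reduces MS-SSIM to SSIM exactly.

The benchmark harness segments each synthetic acquisition with both
FIBIS and the baseline, scores each mask against the ground-truth mask
on the 0/255 scale, and reports per-trial rows plus means ± s.e.m. and
relative improvement percentages (sign-oriented so positive = FIBIS
better; undefined cases such as infinite PSNR are flagged NaN).

## Synthetic acquisitions

The generator emulates the acquisition the analysis targets: 256×256 px
at 0.2 µm/px (a 63× two-photon field), 15 accumulated frames, 80 MHz
repetition, 256 decay bins.

* **Objects**: 8–12 ellipses/capsules of 0.8–4 µm length and 0.4–0.9 µm
  width per scene, random orientation, placed with rejection sampling to
  stay separated. Peak emission is a shared surface brightness (±30%
  per-object variation) — NADH concentration, not organelle size, sets
  brightness — with a floor guaranteeing ≥ 10⁴ photons per object.
* **Decay physics**: each object has a true bound fraction; its decay is
  the photon-weighted mixture of the two pure folded exponentials.
  Because every photon is either free-origin or bound-origin, per-frame
  counts are drawn as two Poisson fields and the accumulated totals are
  distributed over time bins by two vectorized multinomials with the
  pure-lifetime pmfs. Frame/decay photon conservation is exact by
  construction, and folding removes the truncation bias a 3.4 ns decay
  would otherwise have in a 12.5 ns window.
* **Optics**: a Gaussian blur of σ = 0.7 px (0.33 µm FWHM, the
  two-photon diffraction scale) stands in for the PSF; ≥ 95% of a static
  object's photons fall inside its 1-px-dilated true mask.
* **Background**: diffuse cytosolic NADH as a smooth soft-edged
  cell-interior ellipse at 0.4× the median object peak rate (bound
  fraction 0.2). The cell deliberately does not fill the frame: the
  dark surround / diffuse cytosol / mitochondria three-population
  structure is what makes naive global thresholding fail in the way the
  baseline illustrates.
* **Degradations**: per-object linear drift totalling 3–8 px over the
  15 frames (motion blur in the accumulated image) and multiplicative
  stripe gain `1 + 0.3·sin(2πx/8)`.
* **Determinism**: the scene seed fixes geometry; rendering uses a
  spawned child stream, so stacks are bit-identical across runs.
  `benchmark_set` derives trial seeds as `seed + index` and renders
  intensity only by default (the segmentation benchmark does not read
  the decay).

What the generator does **not** model: photobleaching, detector
afterpulsing or IRF width, depth-dependent aberrations, the FAD channel,
and realistic mitochondrial texture (objects are flat-topped). Passing
tests therefore demonstrate the algorithmic claims — noise rejection,
blur correction, fraction recovery — under controlled conditions, not
performance on any particular microscope's data.

## Known limitations

* Under the benchmark degradation (up to 8 px drift, 0.4× diffuse
  background), thin (~0.5 µm) fast-moving objects smear to at or below
  the cytosol intensity; no global threshold can recover them, and FIBIS
  typically loses 0–2 such objects per scene (object counts within ±1 of
  truth on most scenes, within ±4 always in our characterization). This
  is a property of intensity thresholding on accumulated frames, not of
  the implementation.
* A signal-free but noisy field (background only) yields speckle above
  any data-driven threshold; the pipeline returns an empty mask only for
  genuinely constant images.
* Otsu with a dominant background population places the cutoff
  conservatively (deep into the signal tail), so very dim structures
  near the background level are under-segmented rather than
  over-segmented.
* The free/bound fraction assumes equal photon yield of the two NADH
  states (see above) and a fixed 0.4/3.4 ns trajectory; both are
  configurable.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `rep_rate_hz` | 80e6 | laser repetition rate (sets ω and the 12.5 ns window) |
| `tau_free_ns` / `tau_bound_ns` | 0.4 / 3.4 | NADH trajectory endpoints |
| reference lifetime | 2.5 ns | calibration fluorophore |
| `pixel_size_um` | 0.2 (synthetic) | must be supplied for real data |
| `size_range_um` | (0.5, 7.0) | accepted organelle size |
| `noise_detect_k` | 6 | MAD multiplier for spectral peaks |
| `notch_sigma_px` | 2 | Gaussian notch width |
| `max_erosion_iters` | 10 | erosion cap per component |
| `baseline_quantile` | 0.9 | baseline normalization quantile |
| ellipse confidence | 0.95 | chi-square outlier gate |
| SSIM window / k1 / k2 / L | 7 / 0.01 / 0.03 / 255 | similarity metrics |

Problem sizes used by the shipped tests and the acceptance script —
256×256 scenes, 34 benchmark trials, 1024-bin lifetime round trips —
match the conditions described above and complete in about a minute.
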