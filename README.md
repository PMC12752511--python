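# fibis

Phasor-FLIM analysis and intensity-based segmentation of single
mitochondria from NADH autofluorescence.

## What problem this solves

Cellular energy metabolism can be read out label-free from the intrinsic
fluorescence of NADH: the co-factor's lifetime is short when free
(~0.4 ns, glycolysis-associated) and long when protein-bound (~3.4 ns,
OXPHOS-associated). Fluorescence-lifetime imaging (FLIM) with
time-correlated single-photon counting records a photon arrival-time
histogram per pixel, and the fit-free *phasor* transform turns each
histogram into a point

```
g = Σ h(t) cos(ωt) / Σ h(t),    s = Σ h(t) sin(ωt) / Σ h(t),    ω = 2π f_rep
```

Mono-exponential decays of lifetime τ fall on the universal semicircle at
`g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)`; mixtures fall inside, on the chord
between their components. The position of a pixel (or an organelle) along
the chord between the pure free-NADH and bound-NADH phasors is a direct
metabolic index.

Getting that index **per mitochondrion** in live cells is hard: frames
are accumulated (15 scans) to collect enough photons, so moving
mitochondria smear into blurred tracks, periodic laser-scan stripe noise
is amplified by normalization, and diffuse cytosolic NADH hides dim
organelles. `fibis` implements FIBIS — FLIM intensity-based image
segmentation — which addresses exactly these failure modes:

1. **normalize** — each frame z-scored, frames averaged, average rescaled
   to [0, 1] (faint frames contribute equally, bright frames cannot
   compress the histogram);
2. **detect scan noise** — robust (median + k·MAD) peak detection along
   the stripe axis of the centered 2-D Fourier magnitude;
3. **denoise** — Gaussian notches over each flagged peak and its
   conjugate;
4. **threshold** — Otsu's method on the histogram winsorized to the
   interquartile band of the intensity range, which keeps rare very
   bright pixels from dragging the cutoff;
5. **size-gate + erode** — 8-connected components outside the plausible
   mitochondrion range (0.5–7 µm) are removed (specks) or iteratively
   eroded along the intensity gradient (blurred/merged blobs) until they
   resolve into single organelles.

The labeled objects are then mapped into phasor space
(intensity-weighted means), projected onto the free→bound trajectory to
get per-mitochondrion bound-NADH fractions, gated with a Mahalanobis
chi-square ellipse to reject outliers, and compared across conditions
with a two-sample Kolmogorov–Smirnov test. Segmentation quality is
quantified against reference masks with MSE, peak SNR, SSIM and
multi-scale SSIM.

Because no microscope data ships with the package, `fibis.synth`
generates complete synthetic TCSPC acquisitions with known ground truth
(objects with per-object bound fractions and drift, Poisson photon
statistics, folded-exponential decay sampling at 80 MHz, stripe noise,
diffuse cytosolic background) — every claim the package makes is tested
against that generator.

## Worked example

```python
import numpy as np
from fibis import synth, segment, phasor, metabolic

scene = synth.make_scene("paper_benchmark", seed=7)   # 12 objects, blur + stripes
stack, truth = synth.render_stack(scene)

cfg = segment.FibisConfig(pixel_size_um=0.2)
mask = segment.fibis_pipeline(stack, cfg)

bundle = phasor.field_phasor(stack)
traj = metabolic.TrajectoryConfig(rep_rate_hz=stack.rep_rate_hz)
records = metabolic.build_records(mask, bundle, traj, group="demo")

print(f"true objects: {truth.mask.max()}, segmented: {mask.n_objects}")
print(f"scan-noise peaks removed: {mask.log['n_noise_peaks']}, "
      f"threshold: {mask.log['threshold']:.3f}")
fracs = np.array([r.fb_fraction for r in records if not r.outlier_flag])
print(f"bound-NADH fraction: median {np.median(fracs):.3f}, "
      f"IQR [{np.percentile(fracs,25):.3f}, {np.percentile(fracs,75):.3f}]")
```

prints

```
true objects: 12, segmented: 10
scan-noise peaks removed: 6, threshold: 0.359
bound-NADH fraction: median 0.354, IQR [0.254, 0.478]
```

Twelve mitochondria were simulated with random bound fractions; ten are
recovered (two thin fast-moving ones smear below the cytosol level — see
`docs/methods.md` for this limitation), the stripe noise was found and
notched out, and each object carries its own metabolic index.

The same chain is available from the shell:

```bash
fibis simulate --preset paper_benchmark --n 2 --seed 3 --decay --out sim/
fibis phasor   sim/trial_000.tif --out bundle.h5
fibis segment  sim/trial_000.tif --pixel-size-um 0.2 --out mask.tif --table objects.csv
fibis fraction mask.tif bundle.h5 --out fractions.csv --png pseudocolor.png
fibis compare  fractions_a.csv fractions_b.csv --column fb_fraction
fibis benchmark --n-trials 34 --seed 7 --out bench.csv
```

Every subcommand writes a JSON provenance record next to its outputs.

## File formats

* **TCSPC stacks** — multipage TIFF (`F` intensity frames followed by
  `T` decay planes, 16-bit) with a JSON sidecar (`rep_rate_hz`,
  `pixel_size_um`, `F`, `T`), or a single HDF5 container
  (`/frames`, `/decay` + attributes).
* **Phasor bundles** — HDF5 with `/g`, `/s`, `/intensity` and metadata
  attributes. This is an open stand-in for the proprietary SimFCS R64
  format: it carries the referenced phasor arrays the pipeline needs,
  with no attempt at byte-level R64 compatibility.
* **Object tables** — CSV with fixed columns `id, group, area_px,
  size_um, centroid_y, centroid_x, g_mean, s_mean, fb_fraction,
  outlier_flag, free_fraction`.

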