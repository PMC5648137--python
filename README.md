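# wims — wavelet imaging on multiple scales

`wims` analyses fluorescence time-lapse movies of migrating cells with
continuous 2-D wavelet transforms applied across spatial scales at once.
It is written for cell biologists and biophysicists working with
TIRF/widefield movies of adhesion proteins (paxillin, vinculin) and
actomyosin markers, where the quantities of interest live on three very
different scales:

* **whole cell** — the cell outline, and where and how fast its front
  protrudes or retracts;
* **focal adhesions** — elongated, oriented complexes a few hundred
  nanometres to a few micrometres long, to be detected, sized, oriented
  and tracked frame to frame;
* **inside each adhesion** — protein sub-populations that appear, move
  along the adhesion axis at ~0.04–1 µm/min, collide and switch
  direction.

## The method in brief

The forward transform of a frame `I` at scale `a` and position `b` is

    T(a, b) = (1/a) ∫ I(r) ψ*((r − b)/a) dr

with `ψ` the Mexican-hat (Ricker) wavelet, or its anisotropic
"stretched" variant `ψ_{ξ,θ}` whose axis ratio `ξ` and orientation `θ`
match elongated adhesions.  Coefficients are computed at every pixel
(translation-invariant oversampling), with the sum truncated to a
`±4a` box around `b` and evaluated by FFT.  The image is recovered over
a chosen scale band by

    I(r) = (1/C) Σ_b Σ_n Δb Δa a_n⁻⁴ T(a_n, b) ψ((r − b)/a_n),

so a coarse band (`a = 20..200`) yields the smooth cell body whose
threshold contour is the boundary, while local maxima of the stretched
coefficients over `(a, ξ, θ, b)` — kept if at least 10% of the strongest
maximum and placed greedily so footprint ellipses never overlap — are
the adhesions.  A fixed 1-D cross-section through each adhesion, fitted
per frame with a constrained two-Gaussian mixture

    φ(x) = A₀ + A₁′ exp(−(x−β₁)²/2α₁²) + A₂′ exp(−(x−β₂)²/2α₂²),

gives sub-population trajectories `β(t)`, their velocities (positive =
away from the cell boundary) and a ten-category taxonomy of internal
dynamics.  For two-channel actomyosin bundles, a three-method consensus
peak detector (prominence, second derivative with Mexican-hat fits, and
a long-tailed Lorentzian-pair template) tracks the protein populations
at the bundle poles and reports per-channel pole velocities and their
same-side difference Δv.

Details, parameter defaults and numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

No imaging data ships with the package; the built-in generator renders
ground-truthed scenes for every analysis stage:

```python
import numpy as np
from wims import detect, morphology
from wims.synthdata import detection_scene, scenario_library, simulate_movie

# detect oriented adhesions in a synthetic TIRF-like frame (SNR 10)
cfg = detection_scene(n_adhesions=8, shape=(128, 128), snr=10.0, seed=42)
series, truth = simulate_movie(cfg)
adhesions = detect.detect_adhesions(
    series.frame(0), scales=range(4, 21), xis=(0.5, 1.0, 1.5), thetas=180
)
print(f"{len(adhesions)} adhesions detected")
for ad in adhesions[:3]:
    print(f"  x={ad.x:5.1f} y={ad.y:5.1f} a={ad.a:g}px xi={ad.xi:g} "
          f"theta={ad.theta:6.2f} deg  T={ad.coefficient:.0f}")

# track the advancing front of a growing cell
lib = scenario_library(seed=42)
series, _ = simulate_movie(lib["growing_disk"])
masks = []
for t in range(series.n_frames):
    _, m, _ = morphology.extract_boundary(series.frame(t), scales=range(10, 41, 4))
    masks.append(m)
decs = [morphology.decompose_regions(masks[i], masks[i + 1], i, i + 1)
        for i in range(len(masks) - 1)]
fm = morphology.front_metrics(decs, series.pixel_size, series.frame_interval)
print(f"front velocity: {fm['front_velocity_um_per_min']:.2f} "
      f"+/- {fm['velocity_stderr']:.2f} um/min")
```

Output:

```
8 adhesions detected
  x= 89.0 y= 58.0 a=4px xi=1.5 theta=105.54 deg  T=774
  x= 36.0 y= 18.0 a=4px xi=1.5 theta= 37.00 deg  T=690
  x= 30.0 y= 59.0 a=4px xi=1.5 theta= 25.41 deg  T=673
front velocity: 1.25 +/- 0.00 um/min
```

All eight scripted adhesions are found (none spurious); each line gives
the detected center, the best-matching wavelet scale `a` and axis ratio
`ξ`, the refined orientation and the wavelet coefficient `T` at the
maximum.  The growing-disk scene scripts its boundary to advance one
pixel per 5-s frame — exactly 1.26 µm/min at 0.105 µm/pixel — and the
front tracker recovers 1.25 µm/min.

A command line mirrors the library (`wims simulate | transform |
detect | boundary | run`); real input is TIFF stacks with pixel size
and frame interval supplied via a TOML/YAML config.

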