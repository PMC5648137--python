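# Methods

`wims` analyses fluorescence time-lapse movies of migrating cells with
continuous wavelet transforms applied at several spatial scales at once:
coarse scales carry the cell outline, intermediate scales the focal
adhesions, and fixed 1-D cross-sections through each adhesion carry the
motion of protein sub-populations inside it.  This note records the
model, the numerical choices, and what the synthetic benchmarks do and
do not establish.

## Wavelet families and transforms

The isotropic analysing function is the Mexican-hat (Ricker) wavelet

    psi(u) = (2 - |u|^2) exp(-|u|^2 / 2),

applied at scale `a` through `T(a, b) = (1/a) ∫ I(r) psi((r - b)/a) dr`.
The anisotropic ("stretched") variant divides the displacement component
perpendicular to the wavelet frame by an axis ratio `xi` before applying
the same profile, and is rotated by an orientation `theta` in
`[0, 180)` degrees (the shape has two-fold rotational symmetry).  With
`xi = 1` it reduces exactly to the Mexican hat.  A 1-D Lorentzian-pair
wavelet — a unit-area Lorentzian of width `gamma` minus a half-amplitude
Lorentzian of width `2 gamma` — serves as a long-tailed fitting template
for 1-D profile peaks; its two lobes carry equal area, so it integrates
to zero, and its slow tails keep the negative side-lobes shallow.

**Admissibility and reconstruction constants.** The admissibility
constant of the stretched family is reported in closed form as
`pi (1 + xi^2) / (2 xi)` (`pi` for the Mexican hat).  The package also
evaluates the defining integral numerically
(`admissibility_constant_numeric`): the potential-convolution
`g = psi ⊛ 1/|r|` is computed by quadrature with the `1/|r|` kernel
cell-averaged at the origin, and `c = ∫|g|^2 / (2 pi)^2`, the
normalisation under which the Mexican hat gives exactly `pi`.  The two
agree to better than 1% at `xi = 1`.  For anisotropic members the
literal integral of the printed wavelet scales as `pi xi^2`; the closed
form's `(xi + 1/xi)/2` shape corresponds to an L2-normalised,
axis-symmetrised dilation convention that the evaluated wavelet does not
use.  Both numbers are exposed; nothing downstream depends on the
anisotropic admissibility value.

What inversion actually requires is the resolution-of-identity constant
of the discrete transform pair used here.  Deriving it in Fourier space
for our `1/a` forward normalisation and `da/a^4` inverse measure gives

    C = 2 pi^2 xi^2,

independent of direction even for a single-orientation anisotropic
transform (the scale integral of `|psi_hat(a k)|^2 da/a` absorbs the
angular factor); summing orientation-resolved coefficients over
`[0, 180)` multiplies it by `pi`.  `inverse_transform` uses `C`; the
round-trip test (band `a = 2..64`, step 1) reconstructs a band-limited
image to ~1.3% relative L2 error.

## Discrete numerics

* **Truncation.**  Kernels are evaluated on a box of half-width
  `truncation * a * max(1, xi)` (default `truncation = 4.0`).  A 3a box
  is commonly quoted as "where the wavelet is nearly zero", but the
  wavelet still carries ~3% of its positive lobe beyond 3a and that mass
  couples to image noise at the ~1.5% level relative to a full-image
  sum; at 4a the residual is below 0.4% for every (a, xi) tested.  The
  box size is a config key.
* **Zero-sum correction.**  Each sampled, truncated kernel has its mean
  subtracted so it sums to zero exactly.  A uniform image then
  transforms to exactly zero and integer-pixel shifts of the input shift
  the coefficients exactly — the two defining invariances — at the cost
  of a sub-percent offset relative to the untruncated sum, verified
  against a brute-force oracle.
* **Mesh regimes.**  Scales below `refine_below` (default 4 px) run on a
  4x pixel-replicated mesh (no interpolation), scales above
  `coarsen_above` (default 16 px) on a 2x block-mean mesh zero-padded by
  the kernel half-width, the rest on the native grid.  The mesh cell
  area (1/16, 1 or 4 px^2) enters the quadrature weight, keeping
  coefficient values continuous across regimes.  At `a >= 4` the native
  mesh already samples the Gaussian envelope densely enough that
  refinement changes coefficients by < 1e-3 relative, which is why the
  refinement cutoff sits at 4 rather than a more conservative 8; both
  cutoffs are config keys.  Zero intensity is assumed outside the frame.
* **Evaluation.**  The truncated sum is a correlation with an even
  kernel and is evaluated by FFT (exact up to floating point).  Large
  orientation fans are processed one scale at a time with the image FFT
  reused across the fan and kernels transformed in batches; results are
  bit-identical regardless of the chunk size, and memory stays bounded
  (three scale-slabs at once during maxima finding).
* **Coordinates.**  Pixel centers at integer coordinates, origin
  top-left, arrays row-major (y, x); orientations in degrees from the +x
  axis, converted to radians in exactly one place.  All outputs are in
  original full-resolution pixel coordinates.

## Adhesion detection

Candidates are strict local maxima of the stretched-wavelet
coefficients over position (8-neighbourhood), orientation (±1 step,
wrapped mod 180°) and the scale/axis-ratio grid (±1 step) where several
are present, thresholded at 10% of the strongest surviving maximum
(config).  Two practical guards:

* the frame median is subtracted before transforming — interior
  coefficients are unchanged (zero-sum kernels), but the camera
  background otherwise registers against the implicit zero beyond the
  frame edge and produces dominant large-scale "detections" in the
  corners;
* candidates within one footprint extent (`a * max(1, xi)`) of the
  border are discarded as border-contaminated.

The isotropic grid member `xi = 1` responds identically at every
orientation; its orientation axis is collapsed before maxima finding,
and a candidate there must beat its anisotropic neighbours at every
orientation (all of which are grid-adjacent to the degenerate
coordinate).

Accepted detections come from a greedy sweep in descending coefficient
order; a candidate is accepted iff its footprint ellipse — semi-axes
`(a, a xi)` along the wavelet frame under the default `scaled`
convention; a `literal` convention with axes `a` and `xi` is also
available — is disjoint from every previously accepted one.
Disjointness uses the characteristic cubic of the conic pencil (two
distinct positive roots ⇔ separated), an exact algebraic test validated
against dense polygonal oracles; raster tests would be
resolution-dependent.  Ties in coefficient break by lower y, then lower
x, making placement deterministic.

**Orientation refinement.**  The grid argmax over theta is noisy: at the
small scales where adhesions register best, the orientation response is
a shallow lobe on a large isotropic baseline, and a single grid sample
jitters by 5–20° at realistic noise.  Detected orientations are
therefore refined by the doubled-angle circular mean of
baseline-subtracted thin-wavelet (`xi = 0.2`) responses over a 1° fan at
scales 6–12 px, windowed ±25° around the lobe maximum.  This is still a
wavelet-response estimator — it averages the same information the grid
samples — and brings the mean orientation error at peak SNR 10 to
~1.2–1.5°, close to the Cramér–Rao bound (~1–2° per detection for the
smallest adhesions), which is why accuracy statements are made about
the *mean* over detections rather than a per-detection maximum.  The
refinement can be disabled (`refine=False`).

## Cell boundary and front kinematics

The boundary is the sub-pixel marching-squares contour of the
coarse-scale band reconstruction (default band `a = 20..200`, step 4),
thresholded by Otsu's rule by default (the threshold is the one genuinely
free parameter of this stage; a fractional override is provided).  Only
the largest connected component is kept.  Accuracy is bounded by the
smallest band scale; on rasterised disks the recovered radius is within
a pixel.

Between two frames the plane splits exactly into protruded
(`mask1 & ~mask0`), retracted (`mask0 & ~mask1`) and stable
(`mask0 & mask1`) regions; contour runs adjacent (within a 2-px
dilation) to changed pixels are labelled protruding/retracting.  Front
advance is the nearest-point distance from the labelled front vertices
of one contour to the previous contour, averaged along the front; the
front velocity is the least-squares slope of cumulative advance versus
time.  The nearest-point correspondence is a package choice — any
normal-direction estimator would do for smooth fronts; it degrades on
strongly concave or fast-folding boundaries.

Adhesion-boundary geometry: distance is point-to-polyline (segment
projections, not just vertices); the local tangent is the principal
direction of the contour vertices within ±5 vertices of the nearest
point, and adhesion-to-tangent angles are folded into `[0, 90]` because
orientations are axial.  Regions are assigned as: central at ≥ 4 um from
any boundary; otherwise the label of the nearest labelled front, with
near-equidistant protruding/retracting fronts (±2 px) classed as
intersecting.

## Frame-to-frame linking

An adhesion in frame t claims the highest-coefficient unclaimed
detection of frame t+1 inside its own footprint ellipse with axial
orientation difference ≤ 10°, brighter adhesions choosing first; ties
between equal-coefficient candidates go to the nearest center, then
index order.  The search ellipse uses the frame-t parameters.  There is
no gap closing by default (a track ends the first unmatched frame); a
one-frame tolerance sits behind a flag.  On 30 drifting synthetic
adhesions with truth identities, ≥ 95% of consecutive links are correct.

## Intra-adhesion dynamics

Each analysed adhesion defines a fixed axis through its center along its
orientation, reaching the reference-frame boundary on one side and an
equal length opposite (clipped and flagged if the far side leaves the
frame).  Intensity is sampled at 1-px steps with bilinear interpolation
over the reference frame ± 20 frames.  Per frame, samples above the mean
of the profile's extremes are fitted with a constrained two-Gaussian
mixture on the profile-minimum baseline, both amplitudes bounded below
by zero.  Guard rails around the raw fit, each of which addresses a
failure mode observed on noisy profiles:

* fits with fewer than 8 samples above the cutoff are marked skipped;
* coincident centers (< 2.5 px apart) collapse to a single population;
* two Gaussians are retained only when they beat a single Gaussian by a
  nested F-test at the 1% level, with residuals evaluated on the *full*
  profile — the evidence for two populations (the valley, the flanks)
  lies mostly below the fitting cutoff, and a noisy single peak is
  otherwise routinely over-split;
* an amplitude below 5% of its partner counts as a single peak.

Peaks are linked across frames by nearest center against the
extrapolated recent drift (slope from ≥ 4 points, clipped to ±1
px/frame — the physical speed range), with up to 4 missing frames
tolerated; frames whose effective peak count flips against two agreeing
neighbours are flagged stray and excluded from velocity fits.  A
stitching pass joins temporally disjoint fragments whose end positions
line up, and merges "zipper" duplicates (two trajectories alternately
claiming one peak).  Two peaks wider than their closing distance stop
being separable around 3 widths apart, so collisions are detected three
ways: resolved separation dropping below the collision distance
(default 2 px) while approaching; a merge (both trajectories end
together with a successor starting between their last positions); or an
absorption (one trajectory vanishes near the survivor after the
separation collapsed below ~4 mean widths and under 60% of its maximum).

Velocities are least-squares slopes of retained centers versus time,
reported in um/min with 95% CIs, **positive away from the cell
boundary** — that convention is applied uniformly and stated in outputs.
Direction switches use a two-segment fit with the RSS-optimal
breakpoint, accepted only when the slopes change sign.  The taxonomy
classifier maps trajectory counts, stationary/away/toward statuses
(|v| < 0.05 um/min is stationary, config) and collision/switch events
onto ten categories: colliding pairs (A), one/two/three translating away
(B–D), stationary-plus-away (E), stationary-plus-toward (F), one/two
stationary (G–H), collision-then-switch with both away (I), and
stationary with two translating away (J).  Post-collision motion is
judged from 5 frames after the event on trajectories with ≥ 6 retained
samples.  Three-peak patterns are realised as successions: the
two-Gaussian window resolves at most two concurrent populations, so
scripted category D/J scenes nucleate each new cluster near the boundary
after its predecessor fades — matching how such patterns present in the
fits.

## 1-D consensus peak detection and pole tracking

Three detectors run on every bundle profile: (1) smoothed local extrema
ordered by prominence (the larger drop to the flanking minima), each
minima-bounded interval fitted with a Gaussian; (2) the second
derivative of the smoothed profile, its negative lobes fitted with 1-D
Mexican hats whose analytic double integral recovers the original peak
(height `B s^2`, area `B s^3 sqrt(2 pi)`); (3) least-squares
Lorentzian-pair template fits with a free baseline (the positive-lobe
area is `0.2164 *` amplitude, independent of width).  Sizes are unified
as integrated intensity above baseline so the methods are comparable.
Each method discards peaks whose amplitude is below 4x the profile's
robust noise level (MAD of first differences): the three methods share
the smoothed profile, so without an absolute significance floor they
*agree* on noise bumps and consensus would not suppress them.  With it,
the consensus false-positive rate on pure noise is ~0.01 peaks/profile.
A peak is kept iff all three methods report one within 2 px.

Pole tracking samples both channels along the bundle's long axis (the
`r_perp` direction of the detected ellipse when `xi > 1`).  Poles are
the outermost substantial (≥ 25% of the largest size) consensus peaks on
each side of the midpoint, followed frame-to-frame by proximity (gate
3 px — poles drift far less than a pixel per frame), and localised
sub-pixel by the baseline-subtracted intensity centroid in a window of
±1.5 peak widths.  Velocities are line fits of position versus time,
positive toward the bundle center; same-side poles of the two channels
are partnered and `delta_v = v_vinculin - v_myosin` reported per pair,
with 0.03 um/min histogram bins.  Scripted converging poles at 0.02 and
0.065/0.13 um/min are recovered within a few percent over 61 frames at
SNR 10.

## Synthetic data: what it emulates and what it does not

The generator renders: a smooth cell (disk plus low-order radial modes)
whose boundary advances at prescribed sector velocities; adhesions as
oriented anisotropic Gaussian blobs (lengths ~10–20 px, widths ~2–3 px
after blur) — deliberately *not* the wavelet shape, so detection always
runs under model mismatch, as with real data; intra-adhesion clusters as
1-D Gaussians moving along the axis with optional scripted switches and
births/deaths; two-channel bundles with pole populations; a sigma = 1 px
Gaussian blur (the diffraction limit at 0.105 um/px); and
Poisson-then-Gaussian camera noise.  Scene SNR means post-blur peak
amplitude over the *total* rms noise at that pixel (shot plus read).
Fixed seeds give bit-identical movies.

Default calibration is 0.105 um/pixel and 5 s/frame; front velocities
0.3–2 um/min, intra-adhesion cluster speeds 0.04–1.1 um/min and pole
speeds 0.02–0.13 um/min span the regimes the analyses must resolve.

Passing these benchmarks shows the pipeline recovers scripted geometry
and kinematics under realistic shot/read noise and a mismatched
photometric model.  It does not establish performance on real
micrographs with structured background (cytoplasmic texture, uneven
illumination), adhesion shapes beyond anisotropic Gaussians, merging or
splitting adhesions, or boundaries with sharp concavities, where the
smooth-contour assumptions of the front tracking degrade.

## Known limitations

* Orientation precision is noise-limited near the information bound for
  the smallest adhesions; per-detection guarantees tighter than ~2° at
  peak SNR 10 are not achievable by any estimator.
* The two-Gaussian window resolves at most two concurrent
  sub-populations; separations below ~3 peak widths appear as one.
* Greedy placement and linking are order-dependent by design (brightest
  first); no global assignment or merge/split modelling is attempted.
* The inverse transform is quantitative only for bands well inside the
  computed scale range; band-edge features lose amplitude.
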