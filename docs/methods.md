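# Methods

This note records the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic phantoms do and do
not establish about real data.

## Coordinate and unit conventions

Internal lengths are µm, times are hours post inoculation, densities are
CFU·mL⁻¹. Arrays are indexed `(z, y, x)` with z the detection axis
through the thin dimension of the chamber, y the long vertical axis and
x the short horizontal axis; indices are 0-based with half-open extents.
Voxel *centres* sit at `(i + 0.5)·voxel_size`.

## Scan geometry and the shear model

The sample is translated along an axis at angle θ (nominally 45°) to the
illumination/detection axes, so successive camera frames are sheared
relative to the sample. With stage step Δs along the tilted axis, the
deskewed axial spacing is `Δs·cosθ` and the in-frame lateral displacement
per slice is `Δs·sinθ` (both `Δs/√2` at 45°). `shear_correct` inverts
this with a nearest-neighbour single-axis shear, exactly invertible in
floating point; voxels with no source pixel carry NaN. Phantom scans
default to `Δs = voxel·√2` so the deskewed grid coincides with the truth
grid and the shear is exactly one pixel per slice — the instrument's
50 µm steps are equally valid configuration.

With the instrument defaults (200 slices of 50 µm at 45°, footprint
60 × 20 mm clipped to the 3 mm chamber) the geometry model reproduces
the printed 4,290 mm³ chamber volume and 3,600 mm³ imaged volume.

## Forward model (phantom renderer)

Truth channels — root scattering, grain fluorescence, GFP intensity
mapped from density through the linear calibration — are blurred once
with the anisotropic Gaussian light-sheet PSF (sheet FWHM, default
50 µm, along detection z; lateral FWHM in-plane) and then sampled on the
sheared planes with linear interpolation (`grid-constant` boundary, so
edge-straddling samples blend with a zero background). Blurring in truth
space before sampling is equivalent to convolving the sampled planes for
a shift-invariant Gaussian, and keeps the renderer separable. Vignetting
is a separable cosine fall-off field (default corner minimum 0.6),
followed by an offset and Gaussian read noise seeded per (tile, channel)
from a `SeedSequence`. The sheet thickness is treated as constant across
the field of view; beam divergence over the Rayleigh range is ignored
(reported Rayleigh figures for such instruments vary by where they are
measured, and a constant sheet is the conservative phantom).

Mass consistency: with noise off and vignetting ≡ 1 the rendered,
overlap-corrected total intensity equals the blurred-truth total within
1% (tested).

### Particle packing

Random sequential addition of non-overlapping spheres with diameters
uniform in 0.25–1.25 mm (sandy-soil grain sizes), largest first, fully
inside the chamber. Insertion stops when porosity reaches the target
(without overshooting, tolerance 0.02); jamming raises an error naming
the achieved porosity. Voxelized porosity agrees with the analytic
sphere-volume porosity within 2% at 10 µm voxels (tested). RSA does not
reproduce the contact network or coordination statistics of a poured
bed; for optical phantoms only the pore geometry scale matters.

### Root

A straight capsule (sphere-swept polyline) with a tapered tip; arc
length `initial + rate·t` with `initial = 2 mm` (seedling length) and a
default elongation rate of 200 µm·h⁻¹. Roots leaving the chamber are
clipped and flagged. No branching or root hairs.

### Bacterial density field

Per voxel, on the pore liquid (zero inside grains and root):

    c(x, t) = bias(x) · [ B·g(t; t_bulk, σ_b)
                        + R·g(t; t_root, σ_r)·exp(−d_root(x)/λ)
                        + H·Σ_k 1[pulse_k(t)]·exp(−‖x − h_k‖²/2σ_h²) ]

with `bias(x) = s ≥ 1` where the local pore size is below the threshold
(defaults s = 3, 400 µm), `g` a Gaussian envelope of unit peak (constant
when no peak time is set), `d_root` the Euclidean distance from the root
surface, λ the near-root accumulation scale, and hotspots at seeded
Poisson-disc centres pulsing when `(t − φ_k) mod period < duration`
(default period 4 h, duration 2 h, phases 0). Hotspots are immobile by
construction, matching the diagonal-stripe signature their tip-relative
position produces under root growth.

## Reconstruction

**Flat field.** Packed soil is a textured material: grains repeat across
the field, so the per-pixel histogram *mode* of intensity over many
frames (9-px neighbourhood, bins of 1/256 of the dynamic range,
parabolic sub-bin refinement) estimates the illumination/detection
profile; the weight matrix is reference mode / local mode, clipped to
[0.2, 5] and smoothed at the neighbourhood scale (the profile is smooth
by nature). The pipeline estimates weights on the particle channel —
where the texture assumption holds — and applies them to all channels,
since vignetting is channel-independent; estimating on the GFP channel
would divide out genuine near-root signal. Application decomposes each
frame into a Laplacian pyramid and scales each band, expanded to frame
resolution, by the weight matrix (optionally with per-level gains);
with uniform gains this is exactly per-pixel multiplication, and the
structure allows high-frequency bands to be attenuated separately.
Correction is applied to raw frames, before deskew, where the vignetting
physically lives.

**Deconvolution.** Standard Richardson–Lucy multiplicative updates
(Poisson maximum likelihood), initialized with the data, FFT convolution
with reflective padding, default 10 iterations, no regularization.
Non-negativity, total-intensity conservation within 1% and a
non-decreasing Poisson likelihood are tested invariants, and the result
cross-checks against scikit-image's independent implementation.

**Stitching.** Tiles carry nominal stage origins; integer-voxel
corrections come from phase correlation in overlap zones (search radius
±5 voxels; sub-voxel refinement out of scope), anchored at the
first tile and propagated across the adjacency graph. In multi-channel
runs the corrections are estimated once on the particle channel and
applied to every channel so all channels stay on one grid. Fusion is a
multiband Laplacian-pyramid blend per z-slice: tiles are embedded in the
canvas with edge replication (zero-padding would ring at tile borders),
feathered weights span the measured overlap, pyramid depth is
`⌊log₂(min overlap)⌋ − 1` (≥ 1). Stitching is order-independent (tiles
are sorted internally) and a 10% inter-tile intensity mismatch leaves a
seam below 2% of the dynamic range (tested).

## Segmentation

The root is a seeded flood fill of the scattering channel at a fixed
global threshold (Otsu default; 26-connectivity default for robustness
to single-voxel diagonal gaps), keeping seed-connected components,
closed with a 1-voxel ball. Seeds default to the brightest scatter voxel
and propagate from the previous time point's mask centroid. Whether the
original interactive workflow used a fixed or adaptive homogeneity
criterion is unknown; fixed-threshold is the reproducible choice.

Pores: the particle stain is superficial, so the particle channel is
min–max normalized and averaged with the inverted normalized GFP signal
(grain cores are dark in both); grains are the composite above a manual
or Otsu threshold, closed with radius 1; pores are the complement minus
the root. A constant GFP channel degrades gracefully to particle-only
segmentation.

Pore size is the local thickness: twice the largest `dt(c)` over centres
c with `‖v − c‖ < dt(c)`, dt the Euclidean distance transform — i.e. the
diameter of the largest inscribed sphere containing the voxel. It is
computed exactly by sweeping candidate radii in descending order; at
radius r the voxels covered by an inscribed sphere of radius ≥ r are
those within r of `{dt ≥ r}`, one distance transform per distinct
radius. A quantized sweep (`resolution_um`) trades accuracy for speed on
large volumes: it never overestimates, with median error below
2·resolution (occasional deeper dips in a pore's outer shell). Exact
mode is the default and matches exhaustive brute force exactly on ≤ 32³
grids (tested on 50 random masks).

## Quantification

Distance from the root surface is an anisotropy-aware Euclidean distance
transform (exactly equal to brute force, tested). The centerline is the
longest geodesic path through the 3-D skeleton (26-connected graph,
physical edge weights, double Dijkstra sweep); the path is smoothed
(window 5) against the discrete staircase, and endpoints are walked
along their local tangents to the mask boundary because thinning
retracts tube ends by about one radius — the tip is thus the visible tip
of the root. A perfectly even-symmetric tube can be deleted outright by
the thinning algorithm (a synthetic-raster pathology; real masks are
never symmetric), in which case the mask is thickened by one voxel to
break the symmetry at a half-voxel bias. Every soil voxel receives the
arc-length-from-tip of its nearest centerline node.

Calibration chains two regressions from the 12-point dilution design
spanning OD₆₀₀ 1.2×10⁻³–3.0: least-squares `intensity = a·OD + b` and
through-origin `CFU = c·OD`; density is `c·(I − b)/a` clipped at zero.
Degenerate designs (constant intensity, < 1 decade of OD) are rejected.
Suspension-based calibration may underestimate density in biofilms; no
correction is attempted.

Classification uses half-open bins `[lo, hi)` (boundary values fall
upward): rhizosphere < 0.2 mm from the root surface, bulk beyond; base
of the root > 2 mm from the tip; radial profiles restricted to a
3 mm-diameter cylinder around the centerline; pore-size bins of 100 µm
by default. `D(R_k, t)` is the mean calibrated density over the group's
soil voxels, optionally divided by the segmented root volume at t
("per unit volume of root", flag on by default). `⟨D⟩` in `D/⟨D⟩` is the
spatial mean over the scheme's groups at fixed time — the normalization
exists to compare patterns independently of colonization magnitude — with
a temporal-mean alternative behind a flag; the variance indicator is the
temporal variance of `D/⟨D⟩` per group with the first five time points
discarded (too little soil in the mature root region early on). Empty
groups emit flagged rows rather than failing.

Kinematics diagrams bin mean density by (distance-from-tip, time);
stripe slopes are fitted to per-time argmax positions, and pulse periods
come from the first autocorrelation peak of a series, after removing a
centred moving-average trend when pulsation rides on a colonization
envelope.

## Benchmark protocols and problem sizes

`rhizolight.protocols` freezes the study conditions the test suite and
`scripts/acceptance.py` run:

* *Reconstruction fidelity*: 3 × 3 × 1.5 mm chamber at 25 µm, 2 × 2
  tiles with 20% overlap at 45°, noise off. The full chain scores
  voxelwise Pearson r ≥ 0.98 against truth on every channel, with
  per-grain centroid errors well below one voxel.
* *Indicator recovery*: 5 × 8 × 2 mm chamber at 50 µm, 23 hourly time
  points (20–42 h post inoculation), programmed with a bulk envelope
  peaking at 26 h (σ = 2.5 h), a near-root envelope peaking at 32 h
  (σ = 5 h, λ = 300 µm), 4-h/2-h hotspot pulses (σ = 150 µm, ≥ 1.2 mm
  from the root trajectory) and the 3× small-pore bias; the root
  elongates at 120 µm·h⁻¹ so it stays inside the phantom chamber.
  Envelope widths, hotspot size and λ are set so the *ground-truth*
  volume-averaged curves actually peak at the programmed times: in an
  80 mm³ desk-scale chamber, hotspots or near-root accumulation occupying
  an unrealistically large volume fraction would dominate the bulk mean,
  an artifact the real 4,290 mm³ chamber does not have. Recovery is
  judged by running segmentation + quantification with no access to the
  truth; recovered values match the programmed ones (bias ratio within
  15%, pulse period within ±1 h, peak times within ±1 time step).
* *Kinematics stripe*: a single always-on, lab-frame-fixed hotspot
  beside a root elongating at 200 µm·h⁻¹ over 11 hourly points; the
  fitted stripe slope recovers the rate within 10%.

These sizes were chosen as the smallest mesocosms in which the programmed
effects are unambiguous; nothing in the pipeline depends on them.

## What the phantoms do not show

The phantoms demonstrate correctness of the computational chain, not
instrument performance: they contain no refractive-index mismatch,
scattering, depth-dependent PSF or sheet divergence, no root movement
between time points other than tip elongation, no biofilm optics
(calibration is suspension-based), spherical grains rather than fractured
shards, and square-wave rather than biologically irregular pulses.
Passing tests therefore establish that *if* the optical corrections
assumed here hold, the programmed biology is recovered quantitatively —
they cannot certify segmentation thresholds or calibration validity on
real acquisitions, which remain operator-checked choices.
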