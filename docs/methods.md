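# Methods

`octd` quantifies optical coherence tomography dacryography (OCTD) of the
lacrimal canaliculus (LC): cube scans of the medial eyelid acquired every
minute after instillation of a light-scattering contrast agent (2%
rebamipide suspension). The pipeline has five analysis stages — refractive
axial correction, conjunctival surface detection, lumen segmentation,
centerline tracing with curved reslicing, and morphometry/washout
measurement — plus a synthetic phantom generator that provides ground truth
for all of them. This note records the models, conventions and numerical
choices, and what the phantom does and does not emulate.

## Coordinate and measurement conventions

* Voxel grids are indexed `(axial, slow, fast)`; physical coordinates are
  `index × spacing` (µm) at voxel centers.
* Extent convention: a run of *k* voxels spans *k* × spacing (voxel as
  cell); a single voxel has extent equal to one spacing. Areas are pixel
  count × pixel area, reported in mm².
* Interpolation is trilinear (nearest-neighbour for label/mask volumes, so
  labels never mix). Sample coordinates within 10⁻⁶ of a lattice point are
  snapped to it, which makes axis-aligned reslices bit-identical to direct
  slicing.

## Refractive axial correction

OCT measures optical path length along the beam. Dividing the axial length
scale by the tissue refractive index *n* = 1.42 converts it to geometric
length: `dz → dz / n`, voxel values untouched (no interpolation loss). The
correction is applied uniformly over the whole axial range, including any
air above the conjunctiva; a resampling variant (values interpolated onto a
grid that keeps the original spacing) exists behind a flag. Correcting an
already-corrected volume is an error — the `medium` flag on every volume
makes double division impossible. The axial resolution bookkeeping follows
the same rule (13 µm in air → 13/1.42 ≈ 9 µm in tissue).

## Phantom forward model

The phantom renders the raw (optical-scale) acquisition, so the standard
correction restores physical sizes: a structure of physical depth *d* below
the surface spans *n·d* of raw axial scale. Ground-truth label volumes
therefore carry the corrected spacing — the grid all analysis runs on.

Geometry (all defaults are the healthy-cohort mean morphometry):

* A flat conjunctival surface 300 µm (optical) below the volume top, air
  above.
* A vertical segment modelled as a flask: a solid of revolution under the
  punctum whose axial extent equals the vertical anteroposterior (AP)
  lumen length (356 µm) and whose en-face radius swells from a 50 µm
  punctal neck to 300 µm mid-depth (`r(u) = r_neck + (R − r_neck)·sin πu`).
* A horizontal segment modelled as a ribbon with elliptic cross-section —
  AP height 143 µm × transverse width 2900 µm — centred 250 µm below the
  surface, running along the fast axis. The ellipse makes the true
  cross-sectional area π·a·b/4 ≈ 0.326 mm², matching the published area for
  the published axes.
* An epithelial shell (Euclidean distance ≤ 89 µm from the lumen) and a
  muscle cuff (next 150 µm) — the orbicularis/Horner's muscle layer.
* Obstruction modes: `punctal` closes the punctum and buries the lumen so
  its shallowest point sits `blind_extremity_depth` (default 259 µm) below
  the conjunctiva; `canalicular` ends the horizontal lumen mid-course with
  a 600 µm taper.

Intensities are arbitrary grayscale units on a nominal [0, 255] scale: air
10, tissue 90, epithelium 60, muscle 75. The pre-contrast lumen sits at the
air level (tears are optically transparent), which also puts the
background-subtracted baseline at zero — the regime in which the
threshold-crossing washout statistic tracks the true half-life. Lumen
intensity over time rises linearly from baseline to the peak (220) at
1 minute, then decays as `base + A·2^(−(t−1)/T)` with true half-life `T`
(default 6 min). The linear rise is a modelling choice; only the peak time
is anatomically anchored.

Speckle is multiplicative unit-mean gamma noise (shape 4 by default,
σ/µ = 0.5; shape ∞ = noiseless), drawn i.i.d. per voxel; air gets additive
Gaussian noise (σ = 2) only. The long-run ROI mean over any tissue class
equals that class's mean intensity, which the normalization step relies on.

Grid: the instrument's 1024 × 400 A-scan cube over 7 × 7 mm (5 mm depth) is
rendered at 512 × 200 × 256 voxels with the physical field of view
preserved (spacing ≈ 9.77 × 35 × 27.3 µm raw; 6.88 µm axial after
correction). Full instrument sampling adds nothing to algorithm validation
and quadruples memory. Kinetics cohorts use a compact en-face crop
(512 × 48 × 64, same spacing, shortened ribbon) because only ROI time
courses matter there. An acquisition is 11 frames at minutes 0–10, with
per-frame RNG streams spawned from one seed (bit-reproducible).

What the phantom does *not* emulate: OCT physics (no attenuation,
shadowing, rolloff, or depth-dependent speckle statistics), eyelid eversion
deformation, motion between frames, curved or rough conjunctival surfaces,
and anatomical variation beyond independent Gaussian draws of the
morphometric parameters. Passing tests therefore demonstrate correctness of
the measurement chain under a faithful geometric/kinetic model, not
robustness to every clinical artifact.

## Surface detection and lumen segmentation

The air level is estimated from the top three rows and the tissue level
from the bottom half of the (axially smoothed, σ = 2 voxels) volume — the
volume is required to have air above tissue. If the two levels are not
separated by 3× the sum of their median absolute deviations, there is no
interface and detection fails loudly. Per A-scan, the surface is the first
of two consecutive samples above the midpoint of the two levels (a single
speckle-bled air voxel must not trigger early); the height map is
median-filtered (3 × 3).

Segmentation smooths the volume (Gaussian, σ = 0.8 voxels), thresholds
sub-surface voxels (default: Otsu; if the threshold falls below the
sub-surface 75th percentile it latched onto the dark epithelium/tissue
split — the lumen is ~1% of tissue — and is recomputed on the bright half),
applies a 1-voxel morphological closing (larger radii would erase the thin
horizontal lumen), and keeps the connected component containing (or within
10 voxels of) the seed. Quantile and fixed-threshold methods exist; every
parameter actually used is stored in the mask's `method_record`.

The blind extremity is the shallowest lumen voxel's axial distance to the
surface directly above it (the clinical B-scan reading, not a surface
normal). A lumen within 1.5 axial voxels of the surface is an open punctum
(depth 0): the surface row and the lumen top row each quantize by a voxel.

Meshes are marching-cubes isosurfaces at level 0.5 on the physical grid,
zero-padded so boundary-touching masks are capped; faces are wound for
outward normals, vertices in µm.

## Centerline and curved reslicing

The default tracer orders the seed component by geodesic distance from the
punctal seed (26-connected Dijkstra, physically weighted edges) and takes
the centroid of each 25 µm distance shell, extrapolating the first and last
segments to distances 0 and max. This is robust for the ribbon-shaped
horizontal lumen, whose 3D thinning skeleton is a medial *surface*: the
farthest-geodesic skeleton branch then runs to a sheet corner, which would
tilt cross-section planes and inflate the transverse measurement by ~6%.
The classical skeleton-branch tracer is available as `method="skeleton"`
(with end-cap extension, since thinning erodes tube ends); paths are
moving-average smoothed (window 5) and resampled to a uniform 25 µm arc
step.

Longitudinal reslices sample full axial columns along an en-face curve
resampled at the finer in-plane spacing (curved planar reformation).
Cross-sections are spanned by the axial unit vector and the in-plane normal
to the tangent's en-face projection — appropriate for the shallow
canalicular course; a fully 3D frame exists for steep segments.
Out-of-volume samples get a recorded fill value and a validity mask rather
than an error, because ±halfwidth routinely leaves the grid near edges.

## Morphometry

At three stations 1 mm apart (starting 1 mm distal to the vertical/
horizontal split, which is where the path tangent first leaves a 45° cone
around the axial direction): AP length = maximum per-column axial extent,
transverse length = maximum per-row in-plane extent, area = pixel count ×
pixel area, each on the nearest-neighbour-resampled mask cross-section.
Epithelium thickness is the mean, over epithelial pixels bordering the
lumen cavity, of the Euclidean distance through the lumen+epithelium
foreground to surrounding tissue; the border is anchored on the epithelium
mask's own enclosed cavity so lumen-segmentation jitter cannot pull border
pixels into the shell interior. Means ± sample SD over stations are
reported; a single station reports SD as NaN.

The vertical AP length is the maximum axial lumen extent over the
longitudinal-section columns of the vertical window. Counting mask voxels
across two thresholded interfaces carries up to two voxels of quantization,
so the pipeline refines the extent by half-maximum edge interpolation on
the smoothed intensity profile at each candidate column (the caliper
convention used for layer thickness in OCT); open-punctum columns are first
closed up to the detected surface, where the vertical lumen anatomically
begins.

## Washout kinetics

ROI means average pixels whose centers fall in any of the ROI circles
(overlap counted once); lumen ROIs must total > 100 µm², combining multiple
circles when the lumen is too narrow for one. Curves are lumen mean minus
air mean per frame — adding any constant to all voxels changes nothing.
T1/2 is the time from the earliest maximum to the first *strictly* lower-
than-half sample; a plateau at exactly half, or no crossing within the
10-minute window, is an explicit censored state, never an exception or an
imputed value. On the one-minute grid a true exponential half-life *h*
therefore reads ⌊h⌋ + 1 minutes — in [h, h+1) for non-integer *h*, and one
minute above an exactly-integer *h*, the knife-edge the strict inequality
creates. Cohort summaries are arithmetic mean ± sample SD over non-censored
eyes with the censored count alongside. Phantom cohorts draw true
half-lives from N(6.1, 1.9²) min clipped to [2.2, 8.9] min (the published
cohort reports a T1/2 for every eye, so noiseless crossings must stay
inside the 10-minute window): the +0.5 min grid bias then reproduces the
published ~6.55 min cohort scale. Cohort half-lives are sampled by
jittered inverse-CDF stratification — one random draw per
equal-probability stratum, randomly ordered — so a 20-eye cohort
represents the population without the ±0.4 min Monte Carlo error an
i.i.d. draw would add to the cohort mean; that error is about the
simulation, not the estimator under test.

## Group statistics

Published results are mean ± SD with group sizes, so the unpaired t-test is
reconstructed from summaries: pooled variance with df = n₁ + n₂ − 2 by
default (a "Student's t-test" by name), Welch–Satterthwaite as an option.
The tail probability comes from the Student-t CDF (regularized incomplete
beta); tests verify it against direct numeric integration of the t density
to 10⁻⁸. Two zero-variance groups give t = 0, p = 1 when means agree, and a
flagged below-machine-resolution p when they differ. The published
horizontal-segment NLDO comparison (P = 0.54) is not recoverable from its
printed summaries (pooled ≈ 0.52, Welch ≈ 0.44); it is computed and
reported but not asserted.

## Known limitations

* All accuracy statements are phantom-based; no clinical images were
  available to the package.
* Epithelium thickness is measured against label (ground-truth) epithelium;
  epithelial segmentation from intensity is out of scope.
* The shell-centroid centerline assumes the lumen widens monotonically away
  from the seed along the duct; highly convoluted or looping ducts would
  need a proper minimal-path tracer.
* The cross-section transverse measurement reads the chord of the section
  plane; on strongly curved ducts a curved (unrolled) transverse length
  would differ.
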