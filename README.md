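# octd — quantitative OCT dacryography of the lacrimal canaliculus

Optical coherence tomography dacryography (OCTD) images the lacrimal
canaliculus — the small duct draining tears from the punctum toward the
lacrimal sac — by instilling a light-scattering contrast agent (2%
rebamipide suspension) and acquiring anterior-segment OCT cube scans every
minute. From those volumes one can measure the duct's morphology
(anteroposterior and transverse lumen lengths, lumen area, epithelium
thickness), reconstruct it in 3D, locate the blind extremity under the
conjunctiva in punctal obstruction, and quantify drainage via the washout
half-life of the contrast signal. `octd` implements that entire
quantification chain for researchers in lacrimal imaging, together with a
synthetic phantom generator that provides voxel-level ground truth — so
every stage is testable without clinical data.

## What it computes

* **Refractive axial correction** — raw OCT depth is optical path length;
  the axial scale is divided by the tissue refractive index,
  `dz → dz / n` with `n = 1.42` (13 µm air resolution → ≈ 9 µm in tissue).
* **Curved reslicing** — the canaliculus crosses many B-scans, so
  longitudinal views are curved planar reformations along an en-face
  curve, and measurement planes are cross-sections perpendicular to a
  traced centerline at stations 1 mm apart.
* **Morphometry** — on each cross-section: AP length (max axial extent),
  transverse length (max in-plane extent), lumen area (mm²), epithelium
  thickness (distance-transform normal runs), averaged over three
  stations; plus the maximum AP length of the flask-shaped vertical
  segment on the longitudinal view.
* **Washout kinetics** — normalized ROI curves `I(t) = lumen − air`, and
  the elimination half-life
  `T1/2 = t_cross − t_peak`, where `t_cross` is the first time the signal
  falls *strictly* below half its maximum (censored if it never does
  within the 10-minute window).
* **Group statistics** — unpaired two-sample t-tests reconstructed from
  `mean ± SD, n` summaries (pooled by default, Welch optional):
  `t = (m₁ − m₂) / √(s_p²(1/n₁ + 1/n₂))`, `df = n₁ + n₂ − 2`.

## Worked example

The numbered scripts under `analysis/` rerun the study-style analyses on
phantom cohorts and write tables under `results/`. For example:

```text
$ python analysis/02_morphometry_cohort.py
20-eye healthy cohort (measured vs generated truth):
  vertical_ap_um         365.110 ±  69.105   truth   364.654 ±  69.675
  horizontal_ap_um       140.868 ±  20.977   truth   141.520 ±  21.081
  transverse_um         2850.750 ± 443.564   truth  2864.717 ± 447.255
  lumen_area_mm2           0.314 ±   0.072   truth     0.319 ±   0.072
  epithelium_um           82.610 ±  10.700   truth    86.645 ±  10.102
  mean segmentation Dice vs ground truth: 0.990

$ python analysis/03_washout_kinetics.py
20-eye washout cohort:
  T1/2 vertical   6.21 ± 1.81 min (1 censored)
  T1/2 horizontal 6.26 ± 1.79 min (1 censored)
  true half-life  6.06 ± 1.79 min; grid-quantized expectation 6.55 min
```

Each eye is simulated, refraction-corrected, surface-mapped, segmented,
traced and measured end to end; "truth" columns are the generator's drawn
anatomy, so the table reads as measurement accuracy. The washout means sit
about half a minute above the true half-lives because the one-minute
sampling grid quantizes the crossing upward. Segmentation Dice is computed
against the phantom's ground-truth lumen labels.

The same pipeline is scriptable from the shell:

```bash
octd simulate --out run/ --seed 1          # 11-frame phantom acquisition
octd correct run/frame_t01.tif run/corr.tif
octd segment run/corr.tif --seed-voxel 45,100,51 --out run/mask.tif \
     --mesh-out run/lumen.ply
octd trace run/mask.tif --seed-voxel 32,100,51 --out run/path.csv
octd measure --mask run/mask.tif --path run/path.csv --out run/report.csv
octd stats --group-a 6.80,1.94,5 --group-b 6.55,1.91,20   # p ≈ 0.80
octd demo --out demo/ --seed 1             # full 20-eye cohort + summary table
```

## Layout

```
src/octd/        library: phantom, volume, reslice, segment, morphometry,
                 kinetics, stats, study (cohort pipelines), cli
analysis/        numbered narrative drivers writing tables to results/
tests/           pytest suite (unit, property and end-to-end accuracy)
scripts/         acceptance.py
docs/methods.md  models, conventions, numerical choices, limitations
```
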