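# Methods

## Segmentation model

The pipeline assumes a plaque that is locally the brightest structure around
the operator's seed click, separated from surrounding tissue by a negative
intensity gradient, on an image whose stored intensity scale is fine-grained
relative to tissue contrast (integer scanner units spanning hundreds to
thousands). It operates entirely on the native voxel grid: orientation
matrices are carried through to outputs but never used to resample.

Stage 1 (plaque extraction) is threshold-decrementing seeded region growing
on the Gaussian-smoothed image. The region at threshold `t` equals the
connected component of `{smoothed > t} ∪ {seed}` containing the seed — the
incremental implementation adds, at each pass, every supra-threshold
component touching the current region, which is provably the same set. The
comparison is strictly greater-than, so at the initial threshold (the window
maximum) the region is exactly the corrected seed, which is placed into the
region explicitly.

Stage 2 (HSP extraction) thresholds the plaque region on the **original**
image at `coefficient × muscle mean`, also strict. The muscle mean is always
measured on unsmoothed intensities, because the contrast-ratio cutoffs that
motivate the coefficient are defined on native tissue signal. Seed
correction defaults to the smoothed image for noise robustness
(`seed_on_smoothed=False` switches to the raw image).

### Stop conditions

Three mutually exclusive reasons end the growing loop; each is recorded in
the trace:

* `volume_doubled` — a pass grew the region by more than `doubling_factor`
  (default 2.0) relative to its previous size. The pass is recorded but the
  region **reverts** to the previous pass: the condition exists to catch the
  moment the region spills into background, and keeping the flooded region
  would defeat that purpose. The comparison is against the immediately
  preceding pass, and the guard is armed only once the region holds at least
  `doubling_min_size` voxels (default 10), because a jump from a handful of
  voxels to a few dozen is legitimate early growth, not flooding.
* `no_new_voxels` — growth is exhausted: a pass added nothing **and** no
  voxel adjacent to the region exceeds the threshold floor, so no later pass
  could ever add a voxel. A pass that merely adds nothing (a gap in the
  local intensity histogram) does not stop the loop — stopping there would
  truncate growth at the first flat spot below a smoothed plateau and is
  incompatible with recovering a plaque whose core is locally homogeneous.
* `floor_reached` — the next threshold would fall below the floor (default:
  the minimum of the smoothed volume). This guarantees termination; the two
  conditions above alone do not.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `window_radius` | 3 | voxels | 7×7×7 seed-correction / initial-threshold window |
| `sigma` | 0.5 | voxels (per axis) | Gaussian smoothing before growing |
| `connectivity` | 26 | – | voxel neighborhood (6/18/26); 26 suits blob-like plaques on near-isotropic grids |
| `threshold_step` | 1.0 | intensity | decrement per pass, on the native stored scale |
| `doubling_factor` | 2.0 | – | flooding stop ratio |
| `doubling_min_size` | 10 | voxels | region size arming the flooding stop |
| `threshold_floor` | min(smoothed) | intensity | lowest threshold attempted |
| `coefficient` | 1.3 | – | contrast-ratio cutoff vs muscle; 1.52 isolates IPH-like signal (exposed, not separately validated) |

`sigma` is interpreted in voxel units, not mm: on the anisotropic grid this
matches the convention of the numerical environments such software is
typically built in, and keeps the kernel separable per axis. Ambiguities the
method description leaves open — voxel vs mm sigma, raw vs smoothed seed
correction, keep vs revert on doubling, predecessor vs baseline for the
doubling comparison — are resolved as above and every choice is exposed as a
switch or parameter.

Ties in the seed-correction and initial-threshold windows are broken toward
the lowest `(i, j, k)` lexicographically, making the pipeline fully
deterministic; there is no randomness anywhere in the core.

Floating-point handling: thresholds are generated as `t0 − k·step` (no
accumulated subtraction), and the floor comparison uses a relative tolerance
of 1e-9 so integer-valued data behaves exactly.

## Volumetry

`voxel_sum` returns `count × dx·dy·dz`; `slice_area` sums the in-plane area
per slice and multiplies by slice thickness. On a regular grid these are
algebraically identical; both are provided because manual readings are
conventionally computed slice-wise.

## Phantom

The generator emulates the signal configuration the method depends on, not
MRI physics. A scene is: homogeneous background; a homogeneous muscle block
(the reference ROI is the block eroded by a margin, so its noise-free mean
equals the nominal muscle intensity exactly); an ellipsoidal plaque rim at
contrast ratio 1.1 (fibrous-like, below the 1.3 cutoff); an ellipsoidal core
at 1.6 (IPH-like, above both cutoffs); additive Gaussian noise. Defaults:
64×64×32 voxels at 0.45×0.45×0.9 mm; background 240, muscle 400, rim 440,
core 640; `noise_sd` 8 (2% of the muscle mean); core semiaxes
(1.9, 1.9, 2.6) mm inside rim semiaxes (2.8, 2.8, 3.4) mm — a small carotid
plaque, ~39 mm³ core inside a ~115 mm³ plaque.

The intensity scale is a deliberate design choice: the unit threshold
decrement must be fine relative to tissue contrast and noise, as it is on
stored scanner units. On a coarse scale (e.g. muscle at 100) a single step
spans ~1 sd of the smoothed noise, so the pass crossing the flat core's mean
admits about half the core at once and trips the doubling guard — a
granularity artifact, not a property of the method.

Shapes are rasterized by voxel-center inclusion and ground-truth volumes are
those of the rasterized masks, so noise-free volume recovery is exact by
construction. The manual seed is a random core voxel jittered by up to two
voxels per axis (re-drawn until inside the plaque), emulating an imprecise
operator click; generation is deterministic given `rng_seed`.

What the phantom does **not** model: Rician noise statistics (immaterial for
threshold logic at vessel-wall SNR; Gaussian is used), partial-volume
blurring at acquisition, bias fields, flow artifacts, lumen/vessel geometry,
and irregular real plaque morphology with internal texture. Passing the
recovery tests therefore demonstrates the pipeline's correctness and its
behavior under additive noise on idealized geometry — not clinical accuracy,
which requires patient data and expert raters.

## Agreement statistics

ICC is fixed to ICC(2,1) — two-way random effects, absolute agreement,
single measures — the standard form for inter-rater/test–retest reliability
of single measurements; other forms are available via `form`. The value and
F-based 95% CI are computed by `pingouin.intraclass_corr` (CI bounds are
reported at that routine's 2-decimal precision). Tables with zero residual
disagreement are degenerate for the F machinery and are reported as ICC 1.0
with a collapsed CI and a warning flag. Bland–Altman limits of agreement use
the sample (n−1) standard deviation and the 1.96 multiplier; both absolute
(mm³) and percent-difference modes are provided, since both conventions
appear in practice. Spearman is Pearson on mid-ranks (ties averaged) and is
refused for constant series, where it is undefined.

## Problem sizes and runtimes

The test suite and the acceptance script size their simulations for a single
CPU: the grower-vs-oracle comparison uses 200 random integer volumes up to
10³ voxels (values 0–50) plus 60 hypothesis-generated cases; phantom
recovery uses one noise-free and 20 independently seeded 2%-noise phantoms
on the default 64×64×32 grid; the ICC simulation uses n = 500 lesions (and
5×200 in the unit test). The full suite runs in under two minutes.

## Known limitations

* The doubling guard assumes gradual growth; lesions whose intensity
  histogram is coarsely quantized relative to `threshold_step` can trip it
  early (lower `threshold_step` in that case).
* A seed placed outside the lesion's basin of attraction corrects to the
  wrong local maximum; the correction window is small by design and does not
  search globally.
* The 1.52 IPH coefficient is exposed but not validated here beyond the
  generic contrast-ratio mechanism.
* Multi-lesion batch orchestration, lumen segmentation and plaque-type
  classification beyond the single contrast-ratio threshold are out of
  scope.
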