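# Methods

## Measurement model

The quantity of interest is the total lesion volume change between two MRI
visits,

    TLVC = (V_new + V_enlarging) − (V_disappearing + V_shrinking)  [mL],

estimated by voxel counting on a thresholded Z-score map of the PD
subtraction image, restricted to manually delineated lesion masks. The
model's core assumptions are:

- stable tissue cancels in the subtraction once both visits are resampled
  into a common halfway space and intensity-matched, so supra-threshold
  voxels inside the lesion masks reflect genuine lesion change;
- the reference region (brain tissue excluding lesions) captures the null
  distribution of the subtraction, so a fixed Z threshold transfers across
  scanners and sessions;
- the manual lesion masks cover all change of interest (the method cannot
  see change outside them — a deliberate false-positive guard).

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `z_threshold` | 1.5 | Z | the method's published operating point |
| `lesion_mask_threshold` | 0.25 | fraction | deliberately low, to keep lesion boundary voxels after trilinear resampling |
| erosion kernel | 2D in-slice cross, 1 iter | – | restricts enlarging/shrinking away from mask interiors; 3 mm slices make 3D erosion destroy thin lesions |
| `histogram_landmarks` | 16 interior quantiles | – | stiff, lesion-load-robust mapping (see below) |
| `bias_poly_degree` | 3 | – | log-domain polynomial bias model |
| connectivity | 3D 26-conn (lesions), 2D 8-conn (singleton rule) | – | lesions span few 3 mm slices; the singleton rule is stated per slice |
| Z-score SD estimator | sample SD (n−1) | – | fixed and recorded in provenance |
| threshold comparisons | strict (Z > 1.5, Z < −1.5) | – | voxels exactly at ±1.5 are "none" |

Halfway-space construction: with A12 and A21 the two independently
estimated fixed-to-moving world affines, B = A12 ∘ A21⁻¹ is the one-step
map applied twice; H1 = B^¼ and H2 = B^−¼ (principal matrix logarithm) map
each visit into the halfway frame, reduce to parameter halving for pure
translations/rotations, and satisfy H2⁻¹∘H1 = B^½ ≈ A12 and exact swap
symmetry. The halfway grid reuses the visit-1 lattice (shape, spacing and
affine), so both images suffer one interpolation each.

Registration: SimpleITK, all-voxel metric sampling (deterministic),
regular-step gradient descent, shrink pyramid 4/2/1 with Gaussian
smoothing 2/1.5/1 voxels. Keeping ~1 voxel of smoothing at the finest
level regularizes the interpolation-induced wiggle of the metric surface
near the optimum; on phantoms this improves motion recovery from ~0.5 mm
to ~0.12 mm. T1→T2 uses 6-DOF rigid with Mattes mutual information
(cross-contrast); inter-visit T2↔T2 uses 12-DOF affine with the
correlation metric and the brain masks as metric masks. A registration
whose final metric exceeds a documented floor (−0.1 NCC, −0.05 MI) raises
an error rather than returning a silent misregistration.

Histogram matching estimates a monotone piecewise-linear quantile mapping
at 16 *interior* quantiles i/17 (the tradition of ITK's histogram-matching
filters) and continues beyond the outermost landmarks with the secant
slope of the whole mapping. Interior landmarks and secant tails keep the
mapping insensitive to a genuine change in lesion load: pinning the 0th
and 100th percentiles (as a naive 256-landmark map does) drags
stable-tissue intensities whenever one visit has extra bright-voxel mass.
Visit 1 is the reference; `symmetric_histogram=True` maps both visits to
the mid-histogram instead.

Bias correction is lesion-aware: the manual lesion mask is excluded from
the log-domain cubic fit (the correction is still applied everywhere).
Without the exclusion, a changing lesion load drags the fitted field
between visits and manufactures coherent false activity at stable lesions.

## The synthetic cohort

The phantom is a concentric-ellipsoid head (skull shell, brain parenchyma
at 45 % of the field of view per axis, CSF ventricle) with
piecewise-constant class intensities per modality (lesions hyperintense on
PD/T2; CSF brightest on T2, darkest on T1 — the contrast *values* are free
parameters of the phantom, chosen for class separability, not taken from
any acquisition). Rendering is analytic: class membership is evaluated at
supersampled voxel centres of the moved anatomy, so the true inter-visit
and halfway transforms are known in closed form and no double
interpolation occurs. Three realism ingredients matter for the pipeline's
behaviour and are deliberate:

- **Intra-class texture** (anatomy-locked sinusoids, ~1 cm wavelengths,
  ±10 %): real tissue is not histogram-degenerate. A broad, stable-tailed
  intensity distribution is what makes quantile matching well-posed; the
  wavelength is too short for a cubic bias fit to track, so preprocessing
  treats it identically at both visits.
- **Acquisition PSF** (in-plane Gaussian, σ = 0.6 mm): real spin-echo
  images are band-limited. Perfectly sharp synthetic edges ring under
  windowed-sinc resampling, and one-sided thresholding rectifies the
  ringing into a positive bias for every activity category.
- **Lesion load ≤ ~1 % of brain volume**: clinical cohorts carry
  ~0.1–0.5 %. At several percent, the within-mask histogram's upper tail
  becomes lesion-dominated and matching becomes load-sensitive.

The validation cohort (`cohort_config`) gives every subject all four
activity categories: one dominant lesion (new or disappearing — the
randomized net-activity sign), two medium lesions of the opposite
category whose *total boundary length* matches the dominant lesion's (so
partial-volume shell terms cancel in the signed TLVC while the net volume
change stays large), plus one enlarging and one shrinking lesion with
matched radius schedules. Schedules are episodic — each lesion changes
across exactly one interval — as MS activity is, and so that every
single-interval change equals its contribution to the first-to-last
change. Inter-visit motion is in-plane (rotation about the slice axis,
in-plane translation): with 3 mm slices, through-plane repositioning is
the known failure mode of 2D subtraction and acquisition protocols are
set up to avoid it.

**Grid-commensurate motion and partial volume.** Ground-truth volumes are
voxel counts on the rendering grid. Under sub-voxel motion, the true
partial-volume content of every boundary voxel changes, and the
conditioned mask (trilinear + 0.25) legitimately keeps a quarter-voxel
shell of genuinely-changed boundary voxels — about 10–25 % of a small
lesion's volume. That discrepancy is an ambiguity of the discrete truth
representation, not a pipeline error, so ground-truth recovery
experiments draw translations from even-millimetre multiples (halfway
displacement = whole voxels; rotation zero), where the discrete truth is
invariant and registration is still genuinely exercised. Sub-voxel-motion
behaviour is reported by the worked example in the README and by the
reproducibility analyses, which need no rasterized truth.

## What the passing tests do and do not show

On the phantom cohort the full pipeline recovers TLVC within
max(10 %, 1 voxel volume) for all 20 subjects (max error 0.024 mL). This
demonstrates correct plumbing of registration, halfway resampling,
matching, Z-scoring and classification — under ellipsoid anatomy, exact
class intensities, in-plane commensurate motion and zero noise. It does
not demonstrate performance under real anatomy variability, through-plane
motion, Rician noise, flow/ghosting artifacts, imperfect manual masks, or
scanner upgrades; the original clinical validation addresses those.

The transitivity experiment (3-visit phantoms, pipeline run on exact
transforms) yields ICC(one-step, multi-step) ≈ 0.98–1.00 but an SD of the
transitivity error of 0.03–0.09 mL, above the 2-voxel-volume (0.006 mL)
bound asserted in the acceptance suite, which therefore fails that
assertion honestly. The floor is structural: the Z threshold is adaptive
(1.5 × the SD of exactly those residuals that also appear at
stable-lesion boundaries), so a roughly scale-free fraction of
stable-mask voxels crosses it at any residual amplitude — even ideal
white noise would label 13.4 % of every stable mask (|Z| > 1.5), whose
binomial jitter alone exceeds two voxels for realistic mask sizes. The
empirically reported real-data transitivity SD of such subtraction
pipelines is two orders of magnitude above this bound, consistent with
our measurement.

## Numerical choices and degenerate inputs

- Matrix fractional powers use the principal logarithm; transforms with a
  non-positive determinant are rejected.
- Otsu segmentation falls back to a single (tissue) class with a warning
  when the within-mask histogram is unimodal.
- Constant images are rejected by 0–1 normalization; constant reference
  regions by Z-scoring; masks covering only one slice parity by the
  odd/even correction; each with a named error.
- A nonempty lesion mask that conditions to empty (isolated voxels only)
  sets a warning flag rather than raising.
- All randomness in the phantoms flows from a single integer seed;
  registration samples every voxel, so the whole pipeline is
  deterministic for a given input.

## Known limitations

- Only two tissue classes (no GM/WM split) and no partial-volume model in
  the segmentation.
- The manual-LVC surrogate on phantoms is the mask-volume difference; it
  shares rasterization with the truth and is therefore kinder than two
  independent human delineations.
- Atrophy is modelled as a global scale only; PBVC/PVVC enter the
  validation statistics as numeric inputs (computing them with a
  SIENA-like pipeline is out of scope).
- FLAIR input, lesion counting, and automatic lesion segmentation are out
  of scope; the method requires pre-existing lesion masks.
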