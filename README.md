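# lesionsub

Semi-automated quantification of white-matter lesion **volume change** on
serial 2D proton-density (PD)-weighted MRI, by halfway-space registration,
intensity matching and image subtraction — with synthetic longitudinal
phantoms and a transitivity/accuracy validation toolkit.

## Who this is for

Longitudinal studies of multiple sclerosis (MS) often hold only "legacy"
dual-echo PD-/T2-weighted acquisitions (1 × 1 × 3 mm axial slices), for which
most automated lesion-change tools (built around 3D FLAIR) do not apply.
Given per-visit PD/T2/T1 volumes, a T1-space brain mask and a manual lesion
mask, `lesionsub` quantifies how much lesion volume appeared, enlarged,
shrank or disappeared between two visits — including *negative* activity,
which new/enlarging-only pipelines ignore.

## The method

For a visit pair (1, 2):

1. **Per-visit preparation** — rigid (6-DOF, mutual information) T1→T2
   registration propagates the brain mask to the dual-echo grid; odd/even
   slice intensity differences (interleaved acquisition) are equalized
   within the brain mask; a smooth multiplicative bias field (log-domain
   cubic, lesion-aware) is divided out of the PD image.
2. **Halfway space** — the T2 images are registered affinely (12 DOF,
   masked correlation) in both directions, giving A12 and A21
   (fixed-to-moving world maps). With B = A12 ∘ A21⁻¹, the halfway maps are
   H1 = B^¼ and H2 = B^−¼ (matrix-logarithm sense), so both visits suffer
   equal interpolation. Images move by windowed sinc, brain masks by nearest
   neighbour, lesion masks by trilinear interpolation.
3. **Intensity comparability** — each halfway PD image is rescaled to
   [0, 1]; the halfway T2 is segmented into brain tissue vs CSF (Otsu; CSF
   is the brighter class on T2); lesions are folded back into the tissue
   class; a monotone quantile mapping estimated within the tissue+lesion
   mask maps visit-2 intensities onto visit-1 and is applied to the whole
   image.
4. **Change quantification** — the subtraction image (visit 2 − visit 1) is
   converted to Z-scores using the mean/SD of brain tissue *excluding*
   lesions. Manual lesion masks are brought to halfway space (trilinear,
   threshold 0.25, in-slice singletons removed). Each lesion is classified
   by mask presence: visit 2 only → voxels with Z > 1.5 are **new**;
   visit 1 only → Z < −1.5 are **disappearing**; overlapping masks →
   Z > 1.5 is **enlarging** (outside the eroded visit-1 mask) and Z < −1.5
   is **shrinking** (outside the eroded visit-2 mask). The total lesion
   volume change is

   ```
   TLVC = (V_new + V_enlarging) − (V_disappearing + V_shrinking)   [mL]
   ```

5. **Validation protocol** — reproducibility as transitivity
   (ICC(A,1) and SD of Δ_trans = TLVC_multi-step − TLVC_one-step, where
   TLVC_multi-step = Σ yearly TLVC), accuracy vs the manually measured
   lesion volume change (ICC, mean difference, paired t-test), Spearman
   correlations against atrophy (PBVC/PVVC, compounded multiplicatively
   over years) and lesion volume.

No study data ship with the package: the `phantoms` module renders
longitudinal ellipsoid head phantoms with scheduled spherical lesions,
known inter-visit motion and acquisition artifacts, so every stage is
testable against exact ground truth.

## Worked example

```bash
lesionsub phantom --seed 7 --out-dir subj      # 2-visit phantom + truth.json
lesionsub pair subj/visit1 subj/visit2 --out-dir out
```

prints (this phantom schedules one new 4 mm lesion appearing at visit 2,
with 1.5° / ~1 mm of inter-visit head motion):

```json
{
  "vol_new_ml": 0.294,
  "vol_enlarging_ml": 0.0,
  "vol_shrinking_ml": 0.0,
  "vol_disappearing_ml": 0.0,
  "positive_activity_ml": 0.294,
  "negative_activity_ml": 0.0,
  "tlvc_ml": 0.294
}
```

`truth.json` records the scheduled change: 0.264 mL (88 voxels × 3 mm³) of
new activity. The pipeline reports 0.294 mL — the true lesion plus about
ten boundary voxels, because under sub-voxel motion the 0.25-thresholded
conditioned mask keeps partial-volume boundary voxels whose intensity
genuinely changed (see the partial-volume discussion in
`docs/methods.md`). `out/` also holds the Z-map, the integer-coded activity label map
(0 none, 1 new, 2 enlarging, 3 shrinking, 4 disappearing), and a provenance
record with both affine transforms and the Z-reference statistics.

The same objects are available as a library:

```python
from lesionsub import PhantomConfig, generate_study, run_pair

study = generate_study(PhantomConfig(...))
result = run_pair(study.visits[0], study.visits[1]).result
print(result.tlvc, result.vol_new)
```

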