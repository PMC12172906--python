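"""End-to-end orchestration: preprocess → register → match → quantify.

``run_pair`` executes the full two-visit pipeline and returns the lesion
change result with all intermediates; ``run_study`` runs every consecutive
pair plus the direct first-to-last pair of a multi-visit subject and
assembles the validation table row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core import AffineTransform, BinaryMask, DataError, ImageVolume
from .intensity import (
    build_tissue_plus_lesion_mask,
    match_histograms,
    normalize_range,
    segment_brain_csf,
)
from .phantoms import VisitData
from .preprocess import (
    correct_bias_field,
    correct_odd_even_slices,
    propagate_brain_mask,
    register_t1_to_t2,
)
from .quantify import (
    LesionChangeResult,
    check_fov_coverage,
    classify_activity,
    compute_tlvc,
    condition_lesion_mask,
    pair_lesion_components,
    subtract,
    to_zscores,
)
from .registration import GridSpec, compute_halfway, register_visits, resample_to_halfway
from .validation import IntervalMeasurements

__all__ = ["PipelineConfig", "PairResult", "run_pair", "run_study", "load_visit"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the pipeline; the defaults are the method's
    published operating point (|Z| > 1.5, lesion-mask threshold 0.25)."""

    z_threshold: float = 1.5
    lesion_mask_threshold: float = 0.25
    erosion_kernel: str = "cross-2d"
    histogram_landmarks: int = 16
    symmetric_histogram: bool = False
    robust_normalize_percentile: float = 0.0
    bias_poly_degree: int = 3
    seed: int = 0
    keep_intermediates: bool = False

    def as_dict(self) -> dict:
        return {
            "z_threshold": self.z_threshold,
            "lesion_mask_threshold": self.lesion_mask_threshold,
            "erosion_kernel": self.erosion_kernel,
            "histogram_landmarks": self.histogram_landmarks,
            "symmetric_histogram": self.symmetric_histogram,
            "robust_normalize_percentile": self.robust_normalize_percentile,
            "bias_poly_degree": self.bias_poly_degree,
            "seed": self.seed,
        }


@dataclass
class PairResult:
    result: LesionChangeResult
    excluded_fov: bool
    zmap: "object"
    labels: "object"
    A12: AffineTransform
    A21: AffineTransform
    halfway: "object"
    lesion_mask1_hw: BinaryMask
    lesion_mask2_hw: BinaryMask
    lesion_mask_emptied: bool = False
    intermediates: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def load_visit(visit_dir) -> VisitData:
    """Read one visit's NIfTI file set (pd/t2/t1/brain_mask/lesion_mask)."""
    from .core import load_mask, load_volume

    d = Path(visit_dir)
    for name in ("pd", "t2", "t1", "brain_mask", "lesion_mask"):
        if not (d / f"{name}.nii.gz").exists() and not (d / f"{name}.nii").exists():
            raise DataError(f"missing input file: {d / (name + '.nii.gz')}")

    def p(name):
        f = d / f"{name}.nii.gz"
        return f if f.exists() else d / f"{name}.nii"

    pd_img = load_volume(p("pd"), "PD")
    fov = BinaryMask(np.ones(pd_img.shape, dtype=np.uint8), pd_img.affine.copy())
    return VisitData(
        pd=pd_img,
        t2=load_volume(p("t2"), "T2"),
        t1=load_volume(p("t1"), "T1"),
        brain_mask_t1=load_mask(p("brain_mask")),
        lesion_mask=load_mask(p("lesion_mask")),
        fov_mask=fov,
    )


def _preprocess_visit(visit: VisitData, config: PipelineConfig,
                      t1_to_t2: AffineTransform | None = None):
    if t1_to_t2 is None:
        t1_to_t2 = register_t1_to_t2(visit.t1, visit.t2)
    brain = propagate_brain_mask(visit.brain_mask_t1, t1_to_t2, visit.t2)
    pd_img = correct_odd_even_slices(visit.pd, brain)
    pd_img = correct_bias_field(
        pd_img, brain, degree=config.bias_poly_degree,
        exclude_mask=visit.lesion_mask,
    )
    return pd_img, brain, t1_to_t2


def run_pair(
    visit1: VisitData,
    visit2: VisitData,
    config: PipelineConfig | None = None,
    known_transforms: tuple[AffineTransform, AffineTransform] | None = None,
    known_t1_transforms: tuple[AffineTransform, AffineTransform] | None = None,
) -> PairResult:
    """Quantify lesion volume change between two visits.

    ``known_transforms`` supplies precomputed (A12, A21) inter-visit affines
    (fixed-to-moving world maps) in place of running the registration, e.g.
    transform matrices from an external registration tool or the exact
    transforms of a phantom study; ``known_t1_transforms`` does the same for
    the per-visit T1-to-dual-echo rigid transforms.
    """
    config = config or PipelineConfig()
    t1a = t1b = None
    if known_t1_transforms is not None:
        t1a, t1b = known_t1_transforms
    pd1, brain1, t1t2_1 = _preprocess_visit(visit1, config, t1a)
    pd2, brain2, t1t2_2 = _preprocess_visit(visit2, config, t1b)

    if known_transforms is not None:
        a12, a21 = known_transforms
    else:
        a12, a21 = register_visits(visit1.t2, visit2.t2, brain1, brain2)
    grid = GridSpec.from_image(visit1.pd)
    hw = compute_halfway(a12, a21, grid)

    pd1_hw = resample_to_halfway(pd1, hw.H1, grid, "sinc")
    pd2_hw = resample_to_halfway(pd2, hw.H2, grid, "sinc")
    t2_1_hw = resample_to_halfway(visit1.t2, hw.H1, grid, "sinc")
    t2_2_hw = resample_to_halfway(visit2.t2, hw.H2, grid, "sinc")
    brain1_hw = resample_to_halfway(brain1, hw.H1, grid, "nearest")
    brain2_hw = resample_to_halfway(brain2, hw.H2, grid, "nearest")
    fov1_hw = resample_to_halfway(visit1.fov_mask, hw.H1, grid, "nearest")
    fov2_hw = resample_to_halfway(visit2.fov_mask, hw.H2, grid, "nearest")

    les1_hw, emptied1 = condition_lesion_mask(
        visit1.lesion_mask, hw.H1, grid, config.lesion_mask_threshold
    )
    les2_hw, emptied2 = condition_lesion_mask(
        visit2.lesion_mask, hw.H2, grid, config.lesion_mask_threshold
    )
    excluded = check_fov_coverage(les1_hw, les2_hw, fov1_hw, fov2_hw)

    pd1_n = normalize_range(pd1_hw, config.robust_normalize_percentile)
    pd2_n = normalize_range(pd2_hw, config.robust_normalize_percentile)

    tissue1 = segment_brain_csf(t2_1_hw, brain1_hw)
    tissue2 = segment_brain_csf(t2_2_hw, brain2_hw)
    # common stable-tissue region: the class must be tissue at both visits
    tissue_common = BinaryMask(
        (tissue1.brain_tissue.as_bool() & tissue2.brain_tissue.as_bool()).astype(
            np.uint8
        ),
        grid.affine.copy(),
    )
    from .intensity import TissueMasks

    match_mask = build_tissue_plus_lesion_mask(
        TissueMasks(brain_tissue=tissue_common, csf=tissue1.csf), les1_hw, les2_hw
    )
    pd1_m, pd2_m, transfer = match_histograms(
        pd1_n,
        pd2_n,
        match_mask,
        n_landmarks=config.histogram_landmarks,
        symmetric=config.symmetric_histogram,
    )

    diff = subtract(pd2_m, pd1_m)
    lesion_union = BinaryMask(
        (les1_hw.as_bool() | les2_hw.as_bool()).astype(np.uint8), grid.affine.copy()
    )
    zmap = to_zscores(diff, tissue_common, lesion_union)

    correspondence = pair_lesion_components(les1_hw, les2_hw)
    labels = classify_activity(
        zmap, correspondence, les1_hw, les2_hw, config.z_threshold
    )
    result = compute_tlvc(labels)

    intermediates = {}
    if config.keep_intermediates:
        intermediates = {
            "pd1_halfway": pd1_m,
            "pd2_halfway": pd2_m,
            "subtraction": diff,
            "brain1_hw": brain1_hw,
            "brain2_hw": brain2_hw,
            "tissue_common": tissue_common,
            "match_mask": match_mask,
            "transfer_table": transfer,
            "t1_to_t2": (t1t2_1, t1t2_2),
        }
    provenance = {
        "tool": "lesionsub",
        "version": __version__,
        "config": config.as_dict(),
        "transform_convention": "fixed-to-moving world maps (RAS, mm)",
        "A12": a12.matrix.tolist(),
        "A21": a21.matrix.tolist(),
        "H1": hw.H1.matrix.tolist(),
        "H2": hw.H2.matrix.tolist(),
        "z_reference": {
            "mean": zmap.reference_mean,
            "sd": zmap.reference_sd,
            "mask": zmap.mask_provenance,
        },
    }
    return PairResult(
        result=result,
        excluded_fov=excluded,
        zmap=zmap,
        labels=labels,
        A12=a12,
        A21=a21,
        halfway=hw,
        lesion_mask1_hw=les1_hw,
        lesion_mask2_hw=les2_hw,
        lesion_mask_emptied=emptied1 or emptied2,
        intermediates=intermediates,
        provenance=provenance,
    )


def run_study(
    visits: list[VisitData],
    config: PipelineConfig | None = None,
    subject: str = "subject",
    truth=None,
) -> tuple[IntervalMeasurements, dict[tuple[int, int], PairResult]]:
    """All consecutive-pair TLVCs plus the direct first-to-last TLVC.

    Returns the assembled validation-table row and the per-interval results
    keyed by (visit_a, visit_b) 0-based indices.  When a phantom
    ``StudyTruth`` is supplied, its exact inter-visit and T1 transforms are
    used in place of the registration stage.
    """
    if len(visits) < 2:
        raise DataError("at least two visits are required")
    config = config or PipelineConfig()

    def pair_args(a: int, b: int) -> dict:
        if truth is None:
            return {}
        return {
            "known_transforms": (
                truth.true_pair_transform(a, b),
                truth.true_pair_transform(b, a),
            ),
            "known_t1_transforms": (truth.t1_offsets[a], truth.t1_offsets[b]),
        }

    results: dict[tuple[int, int], PairResult] = {}
    yearly = []
    for a in range(len(visits) - 1):
        res = run_pair(visits[a], visits[a + 1], config, **pair_args(a, a + 1))
        results[(a, a + 1)] = res
        yearly.append(res.result.tlvc)
    first_last = (0, len(visits) - 1)
    if len(visits) == 2:
        one_step = yearly[0]
    else:
        res = run_pair(visits[0], visits[-1], config, **pair_args(*first_last))
        results[first_last] = res
        one_step = res.result.tlvc
    # manual LVC surrogate: numerical difference of the two manual lesion
    # mask volumes, as in a manual lesion volume assessment
    vox1 = visits[0].lesion_mask.volume_ml()
    voxN = visits[-1].lesion_mask.volume_ml()
    record = IntervalMeasurements(
        subject=subject,
        interval=f"v1-v{len(visits)}",
        tlvc_one_step=one_step,
        tlvc_yearly_steps=yearly,
        manual_lvc=voxN - vox1,
        manual_lesion_volume_avg=0.5 * (vox1 + voxN),
    )
    return record, results


def save_pair_result(res: PairResult, out_dir, keep_intermediates: bool = False):
    """Write the result JSON, label/Z maps and the provenance record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = dict(res.result.as_dict())
    payload["excluded_incomplete_fov"] = res.excluded_fov
    payload["lesion_mask_emptied_by_conditioning"] = res.lesion_mask_emptied
    (out / "result.json").write_text(json.dumps(payload, indent=2))
    (out / "provenance.json").write_text(json.dumps(res.provenance, indent=2))
    ImageVolume(res.zmap.data, res.zmap.affine, "ZSCORE").save(out / "zmap.nii.gz")
    ImageVolume(
        res.labels.labels.astype(float), res.labels.affine, "LABELS"
    ).save(out / "activity_labels.nii.gz")
    if keep_intermediates and res.intermediates:
        for name, obj in res.intermediates.items():
            if isinstance(obj, (ImageVolume, BinaryMask)):
                obj.save(out / f"{name}.nii.gz")
            elif isinstance(obj, np.ndarray):
                np.savetxt(out / f"{name}.txt", obj)
    return out
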