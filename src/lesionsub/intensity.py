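"""Intensity comparability of the two halfway PD images.

Each halfway PD image is linearly rescaled to [0, 1], the halfway T2 image is
segmented into two classes (brain tissue vs CSF — CSF is the brighter class
on T2), lesions are folded back into the tissue class, and the visit-2 PD
intensities are remapped onto the visit-1 distribution by a monotone
piecewise-linear quantile mapping estimated within the tissue+lesion mask and
applied to the whole image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import BinaryMask, DataError, ImageVolume

__all__ = [
    "TissueMasks",
    "normalize_range",
    "segment_brain_csf",
    "build_tissue_plus_lesion_mask",
    "match_histograms",
    "NormalizationError",
]


class NormalizationError(DataError):
    """Image has a degenerate (zero) intensity range."""


@dataclass
class TissueMasks:
    brain_tissue: BinaryMask
    csf: BinaryMask
    brain_tissue_plus_lesions: BinaryMask | None = None
    single_class_fallback: bool = False


def normalize_range(pd_halfway: ImageVolume, robust_percentile: float = 0.0) -> ImageVolume:
    """Linearly rescale intensities so min maps to 0 and max to 1.

    With ``robust_percentile`` = p > 0, the p-th and (100-p)-th percentiles
    are used instead of absolute min/max (off by default) and the output is
    clipped to [0, 1].
    """
    data = pd_halfway.data
    if robust_percentile > 0:
        lo, hi = np.percentile(data, [robust_percentile, 100.0 - robust_percentile])
    else:
        lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise NormalizationError("constant image: intensity range is degenerate")
    out = (data - lo) / (hi - lo)
    if robust_percentile > 0:
        out = np.clip(out, 0.0, 1.0)
    return pd_halfway.with_data(out)


def segment_brain_csf(t2_halfway: ImageVolume, brain_mask: BinaryMask) -> TissueMasks:
    """Two-class segmentation of the brain-masked T2 image by Otsu threshold.

    Every brain-mask voxel goes to exactly one class; the brighter class on
    T2 is CSF.  If the within-mask histogram is effectively unimodal, a
    warning is issued and all voxels fall back to the tissue class with
    ``single_class_fallback`` set.
    """
    if not t2_halfway.same_geometry(brain_mask):
        raise DataError("T2 image and brain mask geometries differ")
    m = brain_mask.as_bool()
    if not m.any():
        raise DataError("brain mask is empty")
    vals = t2_halfway.data[m]
    fallback = False
    if np.ptp(vals) == 0:
        fallback = True
    else:
        thr = threshold_otsu(vals)
        csf_sel = vals > thr
        # degenerate split: one class empty or the split explains almost no
        # variance (unimodal histogram)
        if not csf_sel.any() or csf_sel.all():
            fallback = True
    if fallback:
        warnings.warn(
            "T2 histogram is unimodal within the brain mask; "
            "assigning all voxels to the tissue class",
            stacklevel=2,
        )
        tissue = m
        csf = np.zeros_like(m)
    else:
        csf = np.zeros_like(m)
        csf[m] = t2_halfway.data[m] > thr
        tissue = m & ~csf
    return TissueMasks(
        brain_tissue=BinaryMask(tissue.astype(np.uint8), brain_mask.affine.copy()),
        csf=BinaryMask(csf.astype(np.uint8), brain_mask.affine.copy()),
        single_class_fallback=fallback,
    )


def build_tissue_plus_lesion_mask(
    tissue: TissueMasks, lesion_hw_v1: BinaryMask, lesion_hw_v2: BinaryMask
) -> BinaryMask:
    """Union of the brain-tissue class with both visits' halfway lesion masks,
    preventing lesions (bright on PD, CSF-like on some contrasts) from being
    excluded from the tissue class."""
    bt = tissue.brain_tissue
    if not (bt.same_geometry(lesion_hw_v1) and bt.same_geometry(lesion_hw_v2)):
        raise DataError("tissue and lesion masks are on different grids")
    combined = bt.as_bool() | lesion_hw_v1.as_bool() | lesion_hw_v2.as_bool()
    return BinaryMask(combined.astype(np.uint8), bt.affine.copy())


def match_histograms(
    pd1: ImageVolume,
    pd2: ImageVolume,
    mask: BinaryMask,
    n_landmarks: int = 16,
    symmetric: bool = False,
) -> tuple[ImageVolume, ImageVolume, np.ndarray]:
    """Monotone quantile mapping of pd2's intensities onto pd1's.

    The mapping is estimated from within-mask voxels at ``n_landmarks``
    *interior* quantiles (i/(L+1), i = 1..L, as histogram-matching tools in
    the ITK tradition do) and applied to the *entire* pd2 image, with linear
    extrapolation beyond the outermost landmarks; pd1 is returned unchanged.
    Interior landmarks keep the mapping stiff at the distribution tails, so
    a genuine change in lesion load between the visits (extra bright-voxel
    mass in one tail) does not drag stable-tissue intensities with it.
    With ``symmetric=True`` both images are mapped to the mid-point
    histogram instead.  Also returns the fitted transfer function as an
    (n_landmarks, 2) table (input level, mapped level).
    """
    if not (pd1.same_geometry(pd2) and pd1.same_geometry(mask)):
        raise DataError("images and mask are on different grids")
    m = mask.as_bool()
    if int(m.sum()) < n_landmarks:
        raise DataError(
            f"mask has fewer voxels ({int(m.sum())}) than histogram landmarks "
            f"({n_landmarks})"
        )
    q = np.arange(1, n_landmarks + 1) / (n_landmarks + 1.0)
    q1 = np.quantile(pd1.data[m], q)
    q2 = np.quantile(pd2.data[m], q)
    # quantile curves are non-decreasing by construction; enforce against
    # floating-point wiggle so the transfer function is monotone
    q1 = np.maximum.accumulate(q1)
    q2 = np.maximum.accumulate(q2)
    if symmetric:
        target = 0.5 * (q1 + q2)
        out1 = pd1.with_data(_apply_map(pd1.data, q1, target))
        out2 = pd2.with_data(_apply_map(pd2.data, q2, target))
        table = np.column_stack([q2, target])
        return out1, out2, table
    out2 = pd2.with_data(_apply_map(pd2.data, q2, q1))
    table = np.column_stack([q2, q1])
    return pd1, out2, table


def _apply_map(data: np.ndarray, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    # np.interp clamps outside [src[0], src[-1]]; beyond the outermost
    # landmarks, continue with the overall secant slope of the mapping (the
    # global gain), which is robust against quantile noise in the first and
    # last landmark segments — the tails are exactly where lesions live
    out = np.interp(data, src, dst)
    span = src[-1] - src[0]
    slope = float((dst[-1] - dst[0]) / span) if span > 0 else 1.0
    below = data < src[0]
    above = data > src[-1]
    out[below] = dst[0] + (data[below] - src[0]) * slope
    out[above] = dst[-1] + (data[above] - src[-1]) * slope
    return out
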