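"""Per-visit preparation of the dual-echo images.

The T1-space brain mask is brought to the dual-echo grid via a 6-DOF rigid
registration (mutual information, suitable for the differing T1 vs T2
contrast), then the PD image is corrected for odd/even slice intensity
differences (an interleaved-acquisition artifact) and for a smooth
multiplicative bias field.
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk

from .core import AffineTransform, BinaryMask, DataError, ImageVolume
from .registration import run_registration

__all__ = [
    "register_t1_to_t2",
    "propagate_brain_mask",
    "correct_odd_even_slices",
    "correct_bias_field",
    "SliceParityError",
]


class SliceParityError(DataError):
    """Brain mask does not intersect both odd and even slices."""


def register_t1_to_t2(t1: ImageVolume, t2: ImageVolume) -> AffineTransform:
    """Rigid (6-DOF) registration of the T1 image onto the T2 grid.

    Returns the fixed(T2)-to-moving(T1) world transform, i.e. the transform
    that resamples T1-space data (such as the brain mask) onto the T2 image.
    """
    transform, _ = run_registration(
        t2, t1, dof="rigid", metric="mi",
        shrink_factors=(2, 1), smoothing_sigmas=(1.5, 1.0), iterations=150,
    )
    return transform


def propagate_brain_mask(
    mask_t1: BinaryMask, transform: AffineTransform, target: ImageVolume
) -> BinaryMask:
    """Nearest-neighbour resampling of the T1 brain mask onto the target grid."""
    ref = target.to_sitk()
    out = sitk.Resample(
        mask_t1.to_sitk(), ref, transform.to_sitk(), sitk.sitkNearestNeighbor, 0
    )
    arr = sitk.GetArrayFromImage(out).T
    return BinaryMask((arr > 0).astype(np.uint8), target.affine.copy())


def correct_odd_even_slices(pd: ImageVolume, brain_mask: BinaryMask) -> ImageVolume:
    """Equalize the within-mask mean signal of odd and even axial slices.

    Both parities are rescaled to the overall within-mask mean, so parity
    means become equal while the overall within-mask mean is preserved
    exactly.  Slice parity is 0-based along the third (axial) axis.
    """
    if not pd.same_geometry(brain_mask):
        raise DataError("PD image and brain mask geometries differ")
    m = brain_mask.as_bool()
    odd = np.zeros_like(m)
    odd[:, :, 1::2] = True
    in_odd, in_even = m & odd, m & ~odd
    if not in_odd.any() or not in_even.any():
        raise SliceParityError(
            "brain mask must intersect both odd and even slices"
        )
    mean_odd = pd.data[in_odd].mean()
    mean_even = pd.data[in_even].mean()
    if mean_odd == 0 or mean_even == 0:
        raise DataError("zero mean intensity within one slice parity")
    overall = pd.data[m].mean()
    data = pd.data.copy()
    data[:, :, 1::2] *= overall / mean_odd
    data[:, :, 0::2] *= overall / mean_even
    return pd.with_data(data)


def _poly_design(shape, degree: int) -> np.ndarray:
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                cols.append((X**i) * (Y**j) * (Z**k))
    return np.stack([c.ravel() for c in cols], axis=1)


def correct_bias_field(
    pd: ImageVolume,
    brain_mask: BinaryMask,
    degree: int = 3,
    exclude_mask: BinaryMask | None = None,
) -> ImageVolume:
    """Divide out a smooth multiplicative intensity field.

    The field is estimated as the exponential of a low-order (default cubic)
    polynomial fitted to the log intensity within the brain mask, then
    normalized so the within-mask mean intensity is preserved.  The estimated
    field is positive everywhere by construction.  ``exclude_mask`` (e.g.
    the manual lesion mask) removes known intensity outliers from the fit —
    lesion-aware estimation, so a changing lesion load cannot drag the
    field between visits; the correction is still applied everywhere.
    """
    if not pd.same_geometry(brain_mask):
        raise DataError("PD image and brain mask geometries differ")
    m = brain_mask.as_bool()
    if exclude_mask is not None:
        if not pd.same_geometry(exclude_mask):
            raise DataError("PD image and exclusion mask geometries differ")
        m_fit = m & ~exclude_mask.as_bool()
        if m_fit.any():
            m = m_fit
    if not m.any():
        raise DataError("brain mask is empty")
    vals = pd.data[m]
    positive = vals > 0
    if not positive.any():
        raise DataError("degenerate image: no positive intensities within mask")
    design = _poly_design(pd.shape, degree)
    dm = design[m.ravel()][positive]
    logv = np.log(vals[positive])
    coeffs, *_ = np.linalg.lstsq(dm, logv, rcond=None)
    log_field = (design @ coeffs).reshape(pd.shape)
    # remove the constant component: only the *shape* of the field is a bias
    log_field -= log_field[m].mean()
    field = np.exp(np.clip(log_field, -2.0, 2.0))
    corrected = pd.data / field
    mean_before = vals.mean()
    mean_after = corrected[m].mean()
    if mean_after == 0:
        raise DataError("degenerate image after correction")
    corrected *= mean_before / mean_after
    return pd.with_data(corrected)
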