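"""Lesion-change quantification on the halfway subtraction image.

The matched visit-2 PD image minus the visit-1 PD image is converted to
Z-scores using the mean/SD of the brain-tissue region excluding lesions, so
the |Z| > 1.5 activity threshold is comparable across scanners.  Change is
only scored inside the conditioned manual lesion masks; each lesion is
assigned to one of three situations (present only at visit 2, only at
visit 1, or at both), which maps supra-threshold voxels to the categories
new / disappearing / enlarging / shrinking.  The total lesion volume change
(TLVC) is the positive-activity volume minus the negative-activity volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AffineTransform, BinaryMask, ConfigurationError, DataError, ImageVolume
from .registration import GridSpec, resample_to_halfway

__all__ = [
    "LABEL_CODES",
    "ZScoreMap",
    "ActivityLabelMap",
    "LesionChangeResult",
    "LesionCorrespondence",
    "subtract",
    "to_zscores",
    "condition_lesion_mask",
    "pair_lesion_components",
    "classify_activity",
    "compute_tlvc",
    "check_fov_coverage",
]

LABEL_CODES = {"none": 0, "new": 1, "enlarging": 2, "shrinking": 3, "disappearing": 4}

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_CROSS_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_SQUARE_2D = np.ones((3, 3), dtype=bool)


@dataclass
class ZScoreMap:
    data: np.ndarray
    affine: np.ndarray
    reference_mean: float
    reference_sd: float
    mask_provenance: str = "brain-tissue-excluding-lesions"


@dataclass
class ActivityLabelMap:
    """Per-voxel activity category, integer-coded per :data:`LABEL_CODES`."""

    labels: np.ndarray
    affine: np.ndarray

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def count(self, category: str) -> int:
        return int((self.labels == LABEL_CODES[category]).sum())


@dataclass
class LesionChangeResult:
    vol_new: float
    vol_enlarging: float
    vol_shrinking: float
    vol_disappearing: float

    @property
    def positive_activity(self) -> float:
        return self.vol_new + self.vol_enlarging

    @property
    def negative_activity(self) -> float:
        return self.vol_disappearing + self.vol_shrinking

    @property
    def tlvc(self) -> float:
        return self.positive_activity - self.negative_activity

    def as_dict(self) -> dict:
        return {
            "vol_new_ml": self.vol_new,
            "vol_enlarging_ml": self.vol_enlarging,
            "vol_shrinking_ml": self.vol_shrinking,
            "vol_disappearing_ml": self.vol_disappearing,
            "positive_activity_ml": self.positive_activity,
            "negative_activity_ml": self.negative_activity,
            "tlvc_ml": self.tlvc,
        }


@dataclass
class LesionCorrespondence:
    """One entry of the lesion correspondence table.

    ``situation`` is 1 (present only at visit 2: candidate new), 2 (present
    only at visit 1: candidate disappearing) or 3 (masks overlap across the
    visits: candidate enlarging/shrinking); ``region`` is the component (or,
    for situation 3, the union of all transitively overlapping components).
    """

    situation: int
    region: np.ndarray
    v1_labels: tuple[int, ...] = ()
    v2_labels: tuple[int, ...] = ()


def subtract(pd2_matched: ImageVolume, pd1: ImageVolume) -> ImageVolume:
    """Voxelwise visit-2 minus visit-1: intensity increase over time is positive."""
    if not pd2_matched.same_geometry(pd1):
        raise DataError("subtraction operands are on different grids")
    return ImageVolume(
        pd2_matched.data - pd1.data, pd1.affine.copy(), "SUBTRACTION"
    )


def to_zscores(
    subtraction: ImageVolume,
    brain_tissue_mask: BinaryMask,
    lesion_mask_union: BinaryMask,
    ddof: int = 1,
) -> ZScoreMap:
    """Standardize the whole subtraction image by the mean/SD of the
    brain-tissue-excluding-lesions reference region (sample SD by default)."""
    if not (
        subtraction.same_geometry(brain_tissue_mask)
        and subtraction.same_geometry(lesion_mask_union)
    ):
        raise DataError("inputs are on different grids")
    ref = brain_tissue_mask.as_bool() & ~lesion_mask_union.as_bool()
    vals = subtraction.data[ref]
    if vals.size < 2:
        raise DataError("reference region has fewer than 2 voxels")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof))
    if sd == 0:
        raise DataError("zero variance in the reference region")
    return ZScoreMap(
        data=(subtraction.data - mean) / sd,
        affine=subtraction.affine.copy(),
        reference_mean=mean,
        reference_sd=sd,
    )


def remove_in_slice_singletons(mask: np.ndarray) -> np.ndarray:
    """Drop connected components of size 1 within each axial slice
    (2D 8-connectivity)."""
    out = mask.astype(bool).copy()
    for k in range(out.shape[2]):
        sl = out[:, :, k]
        if not sl.any():
            continue
        lab, n = ndimage.label(sl, structure=_SQUARE_2D)
        sizes = np.bincount(lab.ravel())
        drop = np.flatnonzero(sizes == 1)
        drop = drop[drop > 0]
        if drop.size:
            sl[np.isin(lab, drop)] = False
    return out


def condition_lesion_mask(
    manual_mask: BinaryMask,
    H: AffineTransform,
    grid: GridSpec,
    threshold: float = 0.25,
) -> tuple[BinaryMask, bool]:
    """Bring a native-space manual lesion mask to the halfway grid.

    Trilinear resampling yields a fractional mask; a deliberately low
    threshold (>= 0.25 by default) keeps lesion boundary voxels; isolated
    single voxels within an axial slice are then removed.  Returns the mask
    plus a warning flag set when a nonempty input conditions to empty.
    """
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold: must be in (0, 1]")
    frac = resample_to_halfway(manual_mask, H, grid, "trilinear")
    binary = frac.data >= threshold
    binary = remove_in_slice_singletons(binary)
    emptied = manual_mask.count() > 0 and not binary.any()
    return BinaryMask(binary.astype(np.uint8), grid.affine.copy()), emptied


def pair_lesion_components(
    mask1_hw: BinaryMask, mask2_hw: BinaryMask
) -> list[LesionCorrespondence]:
    """Label individual lesions per visit (3D 26-connectivity) and classify
    each into one of the three situations; transitively overlapping
    components across visits are merged into one combined region."""
    if not mask1_hw.same_geometry(mask2_hw):
        raise DataError("masks are on different grids")
    m1, m2 = mask1_hw.as_bool(), mask2_hw.as_bool()
    lab1, n1 = ndimage.label(m1, structure=_STRUCT_26)
    lab2, n2 = ndimage.label(m2, structure=_STRUCT_26)
    # union-find over visit-1 components (0..n1-1) and visit-2 (n1..n1+n2-1)
    parent = list(range(n1 + n2))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    overlap = m1 & m2
    linked1, linked2 = set(), set()
    if overlap.any():
        pairs = np.unique(
            np.stack([lab1[overlap], lab2[overlap]], axis=1), axis=0
        )
        for a, b in pairs:
            union(a - 1, n1 + b - 1)
            linked1.add(int(a))
            linked2.add(int(b))
    entries: list[LesionCorrespondence] = []
    for b in range(1, n2 + 1):
        if b not in linked2:
            entries.append(
                LesionCorrespondence(1, lab2 == b, v2_labels=(b,))
            )
    for a in range(1, n1 + 1):
        if a not in linked1:
            entries.append(
                LesionCorrespondence(2, lab1 == a, v1_labels=(a,))
            )
    groups: dict[int, tuple[list[int], list[int]]] = {}
    for a in sorted(linked1):
        groups.setdefault(find(a - 1), ([], []))[0].append(a)
    for b in sorted(linked2):
        groups.setdefault(find(n1 + b - 1), ([], []))[1].append(b)
    for root in sorted(groups):
        v1s, v2s = groups[root]
        region = np.zeros_like(m1)
        for a in v1s:
            region |= lab1 == a
        for b in v2s:
            region |= lab2 == b
        entries.append(
            LesionCorrespondence(3, region, tuple(v1s), tuple(v2s))
        )
    return entries


def erode_in_slice(mask: np.ndarray, structure: np.ndarray = _CROSS_2D) -> np.ndarray:
    """One iteration of 2D in-slice erosion (4-neighbour cross by default);
    3 mm slices make full 3D erosion destroy thin lesions."""
    out = np.zeros_like(mask, dtype=bool)
    for k in range(mask.shape[2]):
        if mask[:, :, k].any():
            out[:, :, k] = ndimage.binary_erosion(mask[:, :, k], structure=structure)
    return out


def classify_activity(
    z: ZScoreMap,
    correspondence: list[LesionCorrespondence],
    mask1_hw: BinaryMask,
    mask2_hw: BinaryMask,
    z_threshold: float = 1.5,
    erosion_structure: np.ndarray = _CROSS_2D,
) -> ActivityLabelMap:
    """Apply the |Z| > threshold rule within the three situations.

    Situation 1 regions: Z > thr → new.  Situation 2: Z < −thr →
    disappearing.  Situation 3 combined regions: Z > thr → enlarging unless
    inside the eroded visit-1 mask; Z < −thr → shrinking unless inside the
    eroded visit-2 mask.  Comparisons are strict, so Z exactly at ±thr is
    "none".
    """
    if z_threshold <= 0:
        raise ConfigurationError("z_threshold: must be > 0")
    labels = np.zeros(z.data.shape, dtype=np.uint8)
    pos = z.data > z_threshold
    neg = z.data < -z_threshold
    eroded1 = erode_in_slice(mask1_hw.as_bool(), erosion_structure)
    eroded2 = erode_in_slice(mask2_hw.as_bool(), erosion_structure)
    for entry in correspondence:
        r = entry.region
        if entry.situation == 1:
            labels[r & pos] = LABEL_CODES["new"]
        elif entry.situation == 2:
            labels[r & neg] = LABEL_CODES["disappearing"]
        else:
            labels[r & pos & ~eroded1] = LABEL_CODES["enlarging"]
            labels[r & neg & ~eroded2] = LABEL_CODES["shrinking"]
    return ActivityLabelMap(labels=labels, affine=z.affine.copy())


def compute_tlvc(labels: ActivityLabelMap) -> LesionChangeResult:
    """Category volumes (voxel count x voxel volume, in mL) and their signed
    sum: TLVC = (new + enlarging) − (disappearing + shrinking)."""
    voxvol_ml = labels.voxel_volume_mm3 / 1000.0
    return LesionChangeResult(
        vol_new=labels.count("new") * voxvol_ml,
        vol_enlarging=labels.count("enlarging") * voxvol_ml,
        vol_shrinking=labels.count("shrinking") * voxvol_ml,
        vol_disappearing=labels.count("disappearing") * voxvol_ml,
    )


def check_fov_coverage(
    mask1_hw: BinaryMask,
    mask2_hw: BinaryMask,
    fov1: BinaryMask,
    fov2: BinaryMask,
) -> bool:
    """True (exclusion flag) when a lesion voxel of one visit falls outside
    the other visit's acquired field of view in halfway space."""
    if not (
        mask1_hw.same_geometry(mask2_hw)
        and mask1_hw.same_geometry(fov1)
        and mask1_hw.same_geometry(fov2)
    ):
        raise DataError("masks are on different grids")
    out1 = mask1_hw.as_bool() & ~fov2.as_bool()
    out2 = mask2_hw.as_bool() & ~fov1.as_bool()
    return bool(out1.any() or out2.any())
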