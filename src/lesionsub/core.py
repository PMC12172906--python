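"""Core containers: image volumes, binary masks and world-space affine transforms.

All geometry follows the NIfTI convention: a 4x4 voxel-to-world affine maps
0-based voxel indices ``(i, j, k)`` to RAS world coordinates in mm.  Affine
*transforms* between images map fixed-space world points to moving-space world
points (the resampling convention), and are stated as such wherever they are
serialized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "AffineTransform",
    "DataError",
    "ConfigurationError",
    "RegistrationError",
    "load_volume",
    "load_mask",
]


class DataError(ValueError):
    """Raised when input data violate an operation's preconditions."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration values; names the offending field."""


class RegistrationError(RuntimeError):
    """Raised when a registration fails to converge or its metric is degenerate."""


# RAS <-> LPS flip used when talking to ITK.
_FLIP = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass(frozen=True)
class AffineTransform:
    """A 4x4 invertible homogeneous world-coordinate transform.

    Maps fixed-space points to moving-space points unless documented otherwise
    at the call site.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ConfigurationError("matrix: expected a 4x4 array")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ConfigurationError("matrix: bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ConfigurationError("matrix: transform is not invertible")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rigid(
        cls,
        rotation_deg: Sequence[float] = (0.0, 0.0, 0.0),
        translation_mm: Sequence[float] = (0.0, 0.0, 0.0),
        center_mm: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """Rigid transform from Euler angles (deg, applied x then y then z)
        rotating about ``center_mm``, followed by a translation."""
        rx, ry, rz = np.deg2rad(rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        R = Rz @ Ry @ Rx
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(translation_mm, dtype=float)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c - R @ c + t
        return cls(m)

    @classmethod
    def from_scaling(cls, scale, center_mm=(0.0, 0.0, 0.0)) -> "AffineTransform":
        s = np.broadcast_to(np.asarray(scale, dtype=float), (3,))
        c = np.asarray(center_mm, dtype=float)
        m = np.eye(4)
        m[:3, :3] = np.diag(s)
        m[:3, 3] = c - s * c
        return cls(m)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return AffineTransform(self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single (3,) point) of world points."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = p @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if np.asarray(points_mm).ndim == 1 else out

    def to_sitk(self) -> sitk.AffineTransform:
        """As a SimpleITK transform (converted to ITK's LPS world frame)."""
        m = _FLIP @ self.matrix @ _FLIP
        t = sitk.AffineTransform(3)
        t.SetMatrix(m[:3, :3].ravel())
        t.SetTranslation(m[:3, 3])
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform) -> "AffineTransform":
        if isinstance(t, sitk.CompositeTransform):
            if t.GetNumberOfTransforms() != 1:
                raise ConfigurationError("composite transforms with >1 member unsupported")
            t = t.GetNthTransform(0)
        if hasattr(t, "Downcast"):
            t = t.Downcast()
        m = np.eye(4)
        m[:3, :3] = np.asarray(t.GetMatrix(), dtype=float).reshape(3, 3)
        m[:3, 3] = np.asarray(t.GetTranslation(), dtype=float)
        c = np.asarray(t.GetCenter(), dtype=float)
        # fold the ITK rotation center into the translation
        m[:3, 3] += c - m[:3, :3] @ c
        return cls(_FLIP @ m @ _FLIP)

    def save_json(self, path, convention: str = "fixed-to-moving world (RAS, mm)"):
        payload = {"convention": convention, "matrix": self.matrix.tolist()}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load_json(cls, path) -> "AffineTransform":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["matrix"], dtype=float))


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing and a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = "PD"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DataError("image data must be 3-D")
        if self.affine.shape != (4, 4):
            raise DataError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise DataError("image contains non-finite intensities")

    @property
    def shape(self):
        return self.data.shape

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "ImageVolume":
        return ImageVolume(data, self.affine.copy(), modality or self.modality)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = p @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if np.asarray(ijk).ndim == 1 else out

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        _set_sitk_geometry(img, self.affine)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, modality: str = "PD") -> "ImageVolume":
        data = sitk.GetArrayFromImage(img).T
        return cls(np.asarray(data, dtype=np.float64), _sitk_affine(img), modality)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


@dataclass
class BinaryMask:
    """A {0,1} grid sharing an :class:`ImageVolume` geometry."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise DataError("mask values must be exactly {0, 1}")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DataError("mask data must be 3-D")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def count(self) -> int:
        return int(self.data.sum())

    def volume_ml(self) -> float:
        return self.count() * self.voxel_volume_mm3 / 1000.0

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def same_geometry(self, other) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def with_data(self, data) -> "BinaryMask":
        return BinaryMask(np.asarray(data).astype(np.uint8), self.affine.copy())

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T.astype(np.uint8)))
        _set_sitk_geometry(img, self.affine)
        return img

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))


def _set_sitk_geometry(img: sitk.Image, affine: np.ndarray) -> None:
    lps = _FLIP @ affine
    R = lps[:3, :3]
    spacing = np.linalg.norm(R, axis=0)
    direction = R / spacing
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(lps[:3, 3]))
    img.SetDirection(tuple(direction.ravel()))


def _sitk_affine(img: sitk.Image) -> np.ndarray:
    D = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    lps = np.eye(4)
    lps[:3, :3] = D * spacing
    lps[:3, 3] = np.asarray(img.GetOrigin(), dtype=float)
    return _FLIP @ lps


def load_volume(path, modality: str = "PD") -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(np.asarray(img.get_fdata(), dtype=np.float64), img.affine, modality)


def load_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return BinaryMask((data > 0.5).astype(np.uint8), img.affine)
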