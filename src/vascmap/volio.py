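"""Volume I/O, grid alignment and intensity normalization.

Conventions
-----------
Arrays are indexed ``(slice, row, col)`` with the axial slicing axis
first; voxel indices are 0-based. World coordinates (mm) are obtained
through a NIfTI-style 4x4 affine, and all resampling is defined in
world space. Images read from or written to disk are NIfTI-1
(gzip-compressed accepted); a DICOM series can optionally be collapsed
into a single volume.

Registration itself is not performed here: grid alignment accepts an
externally supplied rigid transform (identity for phantom data). A
translation-only cross-correlation registration is provided purely as a
convenience for roughly pre-aligned volumes.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "read_dicom_series",
    "resample_to_reference",
    "normalize_slices",
    "normalize_slices_array",
    "stack_modalities",
    "register_translation",
]

VALID_TAGS = ("tof", "t1c", "t2", "label", "mask")


class GridMismatchError(ValueError):
    """Two volumes expected on one voxel grid differ (shape or affine)."""


@dataclasses.dataclass
class ImageVolume:
    """A scalar 3D volume on a regular grid.

    Parameters
    ----------
    data :
        Array of shape ``(slices, rows, cols)``. Label/mask volumes are
        integer typed; image contrasts are float.
    affine :
        4x4 voxel-to-world (mm) affine for the ``(slice, row, col)``
        index order.
    contrast_tag :
        One of ``{"tof", "t1c", "t2", "label", "mask"}``.
    """

    data: np.ndarray
    affine: np.ndarray
    contrast_tag: str = "tof"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.contrast_tag not in VALID_TAGS:
            raise ValueError(
                f"contrast_tag {self.contrast_tag!r} not in {VALID_TAGS}"
            )
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be positive on every axis")
        if self.contrast_tag == "label":
            codes = np.unique(self.data)
            if codes.size and (codes.min() < 0 or codes.max() > 5):
                raise ValueError(
                    f"label volume contains codes outside 0..5: {codes}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm) per array axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "ImageVolume") -> None:
        if self.shape != other.shape:
            raise GridMismatchError(
                f"shape mismatch: {self.shape} vs {other.shape}"
            )
        if not np.allclose(self.affine, other.affine, atol=1e-6):
            raise GridMismatchError("affine mismatch between volumes")


@dataclasses.dataclass
class RigidTransform:
    """World-space rigid transform mapping moving -> reference coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def default_affine(spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_volume(path, contrast_tag: str | None = None) -> ImageVolume:
    """Read a NIfTI-1 volume.

    The contrast tag is inferred from the file stem (``tof.nii.gz`` ->
    ``"tof"``) unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if contrast_tag is None:
        stem = path.name.split(".")[0].lower()
        contrast_tag = stem if stem in VALID_TAGS else (
            "label" if "label" in stem else "tof"
        )
    if contrast_tag in ("label", "mask"):
        data = np.asarray(data).astype(np.uint8)
    else:
        data = np.asarray(data, dtype=np.float32)
    return ImageVolume(data, np.asarray(img.affine), contrast_tag)


def write_volume(volume: ImageVolume, path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), deterministically.

    Integer label/mask volumes are stored as uint8 (bit-exact round
    trip); image volumes as float32. Gzip members are written with a
    zeroed mtime so identical volumes produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if volume.contrast_tag in ("label", "mask"):
        data = volume.data.astype(np.uint8)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_data_dtype(data.dtype)
    if path.name.endswith(".gz"):
        raw = img.to_bytes()
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        nib.save(img, str(path))
    return path


def read_dicom_series(directory, contrast_tag: str = "tof") -> ImageVolume:
    """Collapse a single-frame DICOM series into one ImageVolume.

    Slices are ordered by their projection onto the slice normal. Only
    the common axial single-frame layout is supported; series with
    mixed orientations are rejected.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files under {directory}")
    dsets = [pydicom.dcmread(str(p)) for p in files]
    iop = np.asarray(dsets[0].ImageOrientationPatient, dtype=float)
    for d in dsets[1:]:
        if not np.allclose(np.asarray(d.ImageOrientationPatient, float), iop, atol=1e-4):
            raise ValueError("DICOM series has inconsistent orientation")
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    dsets.sort(key=lambda d: float(np.dot(np.asarray(d.ImagePositionPatient, float), normal)))
    data = np.stack([d.pixel_array.astype(np.float32) for d in dsets], axis=0)
    ps = np.asarray(dsets[0].PixelSpacing, dtype=float)
    if len(dsets) > 1:
        p0 = np.asarray(dsets[0].ImagePositionPatient, float)
        p1 = np.asarray(dsets[1].ImagePositionPatient, float)
        slice_vec = p1 - p0
    else:
        slice_vec = normal * float(getattr(dsets[0], "SliceThickness", 1.0))
    aff = np.eye(4)
    aff[:3, 0] = slice_vec
    aff[:3, 1] = row_dir * ps[0]
    aff[:3, 2] = col_dir * ps[1]
    aff[:3, 3] = np.asarray(dsets[0].ImagePositionPatient, float)
    return ImageVolume(data, aff, contrast_tag)


def resample_to_reference(
    moving: ImageVolume,
    reference: ImageVolume,
    transform: RigidTransform | None = None,
    interpolation: str = "trilinear",
) -> ImageVolume:
    """Resample ``moving`` onto the exact grid of ``reference``.

    ``transform`` maps moving world coordinates to reference world
    coordinates (the output of a rigid registration); identity by
    default. Voxels that map outside the moving volume are filled with
    0. Use ``"trilinear"`` for image contrasts and ``"nearest"`` for
    labels/masks.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(
            f"unknown interpolation {interpolation!r}; use 'trilinear' or 'nearest'"
        )
    if transform is None:
        transform = RigidTransform.identity()
    order = 1 if interpolation == "trilinear" else 0
    # reference voxel -> reference world -> moving world -> moving voxel
    m = np.linalg.inv(moving.affine) @ transform.inverse().matrix() @ reference.affine
    out = ndimage.affine_transform(
        moving.data.astype(np.float32),
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=reference.shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if moving.contrast_tag in ("label", "mask"):
        out = np.rint(out).astype(moving.data.dtype)
    return ImageVolume(out, reference.affine.copy(), moving.contrast_tag)


def normalize_slices_array(data: np.ndarray) -> np.ndarray:
    """Min-max normalize each axial slice of a 3D array to [0, 1].

    Each slice (first axis) is mapped by ``(x - min) / (max - min)``
    independently; constant slices map to all zeros.
    """
    data = np.asarray(data, dtype=np.float32)
    lo = data.min(axis=(1, 2), keepdims=True)
    hi = data.max(axis=(1, 2), keepdims=True)
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    out = (data - lo) / safe
    out[np.broadcast_to(rng == 0, out.shape)] = 0.0
    return out.astype(np.float32)


def normalize_slices(volume: ImageVolume) -> ImageVolume:
    """Per-slice linear normalization of an image contrast volume."""
    if volume.contrast_tag in ("label", "mask"):
        raise ValueError("normalize_slices applies to image contrasts, not labels")
    return ImageVolume(
        normalize_slices_array(volume.data), volume.affine.copy(), volume.contrast_tag
    )


def stack_modalities(
    tof: ImageVolume, t1c: ImageVolume, t2: ImageVolume
) -> np.ndarray:
    """Stack the three contrasts into per-slice 3-channel samples.

    Returns an array of shape ``(slices, 3, rows, cols)`` with the
    channel order fixed as (TOF, T1+c, T2) — part of the model
    contract; a trained network must never silently receive another
    order.
    """
    for vol, tag in ((tof, "tof"), (t1c, "t1c"), (t2, "t2")):
        if vol.contrast_tag != tag:
            raise ValueError(
                f"channel-order contract violated: expected {tag!r} volume, "
                f"got {vol.contrast_tag!r}"
            )
    tof.require_same_grid(t1c)
    tof.require_same_grid(t2)
    return np.stack(
        [tof.data, t1c.data, t2.data], axis=1
    ).astype(np.float32)


def register_translation(
    moving: ImageVolume, reference: ImageVolume
) -> RigidTransform:
    """Translation-only registration by normalized cross-correlation.

    Convenience helper for roughly pre-aligned volumes on equal grids;
    full rigid registration is expected to be supplied externally.
    """
    from skimage.registration import phase_cross_correlation

    moving.require_same_grid(reference)
    shift, _, _ = phase_cross_correlation(
        reference.data.astype(np.float32),
        moving.data.astype(np.float32),
        upsample_factor=4,
    )
    # voxel shift -> world translation
    translation = reference.affine[:3, :3] @ np.asarray(shift, float)
    return RigidTransform(np.eye(3), translation)
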