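"""NIfTI volume I/O and 2D slice (de)composition.

Volumes are carried with their affine untouched — no registration to a
standard space is ever performed — and array indices are 0-based throughout.
Masks are unsigned integers restricted to {0, 1}; a mask read with other
values is binarized at 0.5 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .exceptions import ConsistencyError, VolumeFormatError

MODALITIES = ("t1", "t2", "mask", "unknown")


@dataclass
class Volume:
    """A 3D scalar image with grid metadata and an optional modality tag."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = "unknown"
    subject_id: str = ""
    site_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"volume data must be 3D, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeFormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise VolumeFormatError("affine is not invertible")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.modality == "mask":
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                warnings.warn("mask volume has values outside {0,1}; "
                              "binarizing at 0.5", stacklevel=2)
                self.data = (self.data > 0.5)
            self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class SliceStack:
    """Ordered 2D planes cut from a volume, with restoration bookkeeping."""

    slices: list[np.ndarray]
    axis: int
    original_shape: tuple[int, int, int]
    source_subject: str = ""

    def __post_init__(self):
        if self.axis not in (0, 1, 2):
            raise ValueError(f"axis must be in {{0,1,2}}, got {self.axis}")
        if len(self.slices) != self.original_shape[self.axis]:
            raise ConsistencyError(
                f"{len(self.slices)} slices vs extent "
                f"{self.original_shape[self.axis]} along axis {self.axis}")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ConsistencyError(f"slices have mixed shapes {shapes}")

    def __len__(self) -> int:
        return len(self.slices)


def read_volume(path, modality: str = "unknown",
                subject_id: str = "", site_id: str = "") -> Volume:
    """Load a NIfTI-1 file; intensities are returned unmodified."""
    import os
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
    except FileNotFoundError:
        raise
    except Exception as e:  # unreadable header, truncated file, ...
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {e}") from e
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    if modality != "mask":
        data = data.astype(np.float32)
    return Volume(data=data, affine=affine, modality=modality,
                  subject_id=subject_id, site_id=site_id)


def write_volume(volume: Volume, path) -> str:
    """Write a NIfTI-1 file; masks are stored with an integer dtype."""
    if volume.modality == "mask":
        data = volume.data.astype(np.uint8)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    try:
        nib.save(img, str(path))
    except Exception as e:
        raise IOError(f"cannot write volume to {path}: {e}") from e
    return str(path)


def extract_slices(volume: Volume, axis: int = 2) -> SliceStack:
    """Cut a volume into its 2D planes along one axis."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be in {{0,1,2}}, got {axis}")
    moved = np.moveaxis(volume.data, axis, 0)
    return SliceStack(slices=[np.ascontiguousarray(s) for s in moved],
                      axis=axis, original_shape=volume.shape,
                      source_subject=volume.subject_id)


def assemble_volume(stack: SliceStack, reference: Volume) -> Volume:
    """Re-stack 2D planes into a volume on the reference grid."""
    axis = stack.axis
    expected_inplane = tuple(e for i, e in enumerate(reference.shape) if i != axis)
    got_inplane = stack.slices[0].shape
    if (len(stack) != reference.shape[axis]
            or tuple(got_inplane) != expected_inplane):
        raise ConsistencyError(
            f"stack ({len(stack)} slices of {got_inplane}) does not match "
            f"reference shape {reference.shape} along axis {axis}")
    data = np.moveaxis(np.stack(stack.slices, axis=0), 0, axis)
    vals = np.unique(data)
    modality = "mask" if np.isin(vals, (0, 1)).all() else "unknown"
    return Volume(data=data, affine=reference.affine, modality=modality,
                  subject_id=stack.source_subject or reference.subject_id,
                  site_id=reference.site_id)
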