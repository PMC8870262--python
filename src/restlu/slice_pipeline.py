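"""Per-slice resampling, normalization, channel assembly and restoration.

Every slice is resampled to the square network grid (bilinear for
intensities, nearest-neighbor for masks), standardized to zero mean and
unit variance per slice, replicated (or stacked with its neighbors) into
the network's 3 input channels, and — after prediction — resampled back to
the original in-plane shape by nearest-neighbor and re-stacked into a
volume. No denoising, bias correction or registration is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .exceptions import ConsistencyError
from .network import ModelState, decode_mask, forward
from .volume_io import SliceStack, Volume, assemble_volume, extract_slices

VAR_EPS = 1e-12  # below this a slice counts as constant
CHANNEL_POLICIES = ("replicate", "adjacent")


@dataclass
class NetInput:
    """A (batch, 3, H, W) model-input tensor with slice provenance."""

    tensor: np.ndarray
    provenance: list[tuple[str, int]]
    grid: tuple[int, int]

    def __post_init__(self):
        if self.tensor.ndim != 4 or self.tensor.shape[1] != 3:
            raise ValueError(f"tensor must be (batch, 3, H, W), "
                             f"got {self.tensor.shape}")
        if tuple(self.tensor.shape[2:]) != tuple(self.grid):
            raise ConsistencyError(
                f"tensor grid {self.tensor.shape[2:]} != declared {self.grid}")


def resample_slice(image: np.ndarray, target: tuple[int, int],
                   mode: str = "linear") -> np.ndarray:
    """Resample one 2D slice to the target shape.

    linear: bilinear interpolation (intensity slices); nearest: preserves the
    value set exactly (masks).
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2D array")
    if len(target) != 2 or any(t <= 0 for t in target):
        raise ValueError(f"target dims must be positive, got {target}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if tuple(image.shape) == tuple(target):
        return image.astype(np.float32, copy=True)
    order = 1 if mode == "linear" else 0
    out = resize(image.astype(np.float32), target, order=order, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def normalize_slice(image: np.ndarray) -> np.ndarray:
    """Standardize one slice to mean 0, population variance 1.

    A constant slice (variance below 1e-12) maps to all zeros.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    var = image.var()
    if var <= VAR_EPS:
        return np.zeros_like(image, dtype=np.float32)
    return ((image - image.mean()) / np.sqrt(var)).astype(np.float32)


def make_net_input(stack: SliceStack, policy: str = "replicate") -> NetInput:
    """Assemble a 3-channel model input from prepared (resampled, normalized)
    slices.

    replicate copies each slice to all three channels; adjacent stacks the
    k-1, k, k+1 neighbors (edge slices replicate themselves outward).
    """
    if policy not in CHANNEL_POLICIES:
        raise ValueError(f"unknown channel policy {policy!r}")
    if len(stack) == 0:
        raise ValueError("empty slice stack")
    n = len(stack)
    planes = [np.asarray(s, dtype=np.float32) for s in stack.slices]
    if policy == "replicate":
        chans = [np.stack([p, p, p]) for p in planes]
    else:
        chans = [np.stack([planes[max(k - 1, 0)], planes[k],
                           planes[min(k + 1, n - 1)]]) for k in range(n)]
    tensor = np.stack(chans).astype(np.float32)
    prov = [(stack.source_subject, k) for k in range(n)]
    return NetInput(tensor=tensor, provenance=prov,
                    grid=tuple(planes[0].shape))


def prepare_stack(volume: Volume, grid: int | tuple[int, int],
                  axis: int = 2) -> SliceStack:
    """Slice a volume and resample+normalize every plane to the network grid."""
    grid = (grid, grid) if np.isscalar(grid) else tuple(grid)
    raw = extract_slices(volume, axis)
    mode = "nearest" if volume.modality == "mask" else "linear"
    slices = []
    for s in raw.slices:
        s = resample_slice(s, grid, mode)
        if volume.modality != "mask":
            s = normalize_slice(s)
        slices.append(s)
    return SliceStack(slices=slices, axis=axis,
                      original_shape=volume.shape,
                      source_subject=volume.subject_id)


def restore_prediction(mask_slices: SliceStack, original: Volume) -> Volume:
    """Resample predicted mask slices back to the original in-plane shape
    (nearest-neighbor) and reassemble them on the original grid."""
    axis = mask_slices.axis
    if len(mask_slices) != original.shape[axis]:
        raise ConsistencyError(
            f"{len(mask_slices)} predicted slices vs original extent "
            f"{original.shape[axis]} along axis {axis}")
    inplane = tuple(e for i, e in enumerate(original.shape) if i != axis)
    restored = [resample_slice(s, inplane, "nearest").astype(np.uint8)
                for s in mask_slices.slices]
    stack = SliceStack(slices=restored, axis=axis,
                       original_shape=original.shape,
                       source_subject=mask_slices.source_subject
                       or original.subject_id)
    out = assemble_volume(stack, original)
    out.modality = "mask"
    out.data = (out.data > 0.5).astype(np.uint8)
    return out


def extract_volume(state: ModelState, volume: Volume, axis: int = 2,
                   policy: str = "replicate", batch_size: int = 8) -> Volume:
    """Full brain-extraction pipeline for one volume:
    slice -> resample -> normalize -> forward -> decode -> restore."""
    grid = state.spec.grid
    stack = prepare_stack(volume, grid, axis)
    net_in = make_net_input(stack, policy)
    x = net_in.tensor
    masks = []
    for i in range(0, x.shape[0], batch_size):
        scores = forward(state, x[i:i + batch_size], train=False)
        masks.append(decode_mask(scores))
    pred = np.concatenate(masks, axis=0)
    pred_stack = SliceStack(slices=list(pred), axis=axis,
                            original_shape=volume.shape,
                            source_subject=volume.subject_id)
    return restore_prediction(pred_stack, volume)
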