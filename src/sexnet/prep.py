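"""Hemisphere flipping, rigid augmentation, and class balancing.

Training treats each subject as two samples: the volume itself and its
left-right mirror (sex effects are assumed bilateral).  Training folds are
augmented with small random rigid transforms -- translations within one
voxel and rotations within one degree about each axis -- and oversampled so
both classes reach a fixed target count.  Held-out data is never augmented.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import LR_AXIS, BrainVolume, HemispherePair

__all__ = ["mirror", "flip_to_pair", "apply_rigid", "augment_rigid", "balance_augment"]


def mirror(data: np.ndarray, lr_axis: int = LR_AXIS) -> np.ndarray:
    """Mirror a volume across the mid-plane of the left-right axis."""
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
    if not 0 <= lr_axis < 3:
        raise ValueError("lr_axis must be 0, 1 or 2")
    return np.flip(data, axis=lr_axis)


def flip_to_pair(v: BrainVolume, lr_axis: int = LR_AXIS) -> HemispherePair:
    """Pair a volume with its left-right mirror (an exact involution)."""
    flipped = BrainVolume(mirror(v.data, lr_axis).copy(), spacing=v.spacing)
    return HemispherePair(native_right=v, flipped_left=flipped)


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    """Compose rotations about the three grid axes (x then y then z)."""
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment_rigid(
    data: np.ndarray,
    max_shift: float = 1.0,
    max_rot: float = 1.0,
    rng: np.random.Generator | int | None = None,
    order: int = 1,
) -> np.ndarray:
    """Apply a random rigid transform: shifts in [-max_shift, max_shift]
    voxels and rotations in [-max_rot, max_rot] degrees about each axis.

    Shifts are continuous (the one-voxel limit is read as a bound, not a
    grid step).  Resampling is trilinear (``order=1``) with constant
    zero fill outside the grid; ``order=0`` gives nearest-neighbour, which
    makes an integer shift an exact array roll.
    """
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
    if max_shift < 0 or max_rot < 0:
        raise ValueError("augmentation bounds must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shift = rng.uniform(-max_shift, max_shift, size=3)
    angles = rng.uniform(-max_rot, max_rot, size=3)
    return apply_rigid(data, shift, angles, order=order)


def apply_rigid(
    data: np.ndarray,
    shift: np.ndarray,
    angles_deg: np.ndarray,
    order: int = 1,
) -> np.ndarray:
    """Resample a volume under an explicit rigid transform about the grid centre."""
    shift = np.asarray(shift, dtype=np.float64)
    angles = np.asarray(angles_deg, dtype=np.float64)
    if np.all(shift == 0) and np.all(angles == 0):
        return data.copy()
    rot = _rotation_matrix(angles)
    centre = (np.asarray(data.shape, dtype=np.float64) - 1) / 2.0
    # output voxel o maps to input voxel rot^-1 @ (o - centre - shift) + centre
    inv = rot.T  # affine_transform maps output voxel o to input voxel inv @ o + offset
    offset = centre - inv @ (centre + shift)
    out = ndimage.affine_transform(
        data.astype(np.float64), inv, offset=offset, order=order, mode="constant", cval=0.0
    )
    return out.astype(data.dtype, copy=False)


def balance_augment(
    items: list[tuple[np.ndarray, int]],
    target_per_class: int,
    rng: np.random.Generator | int | None = None,
    max_shift: float = 1.0,
    max_rot: float = 1.0,
) -> list[tuple[np.ndarray, int]]:
    """Oversample to exactly ``target_per_class`` items per class.

    Originals are always retained; the extras are rigid-augmented copies of
    items sampled uniformly with replacement from the same class.
    """
    labels = {lab for _, lab in items}
    if len(labels) < 2:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    by_class: dict[int, list[np.ndarray]] = {lab: [] for lab in labels}
    for vol, lab in items:
        by_class[lab].append(vol)
    largest = max(len(v) for v in by_class.values())
    if target_per_class < largest:
        raise ValueError(
            f"target_per_class={target_per_class} below largest class size {largest}"
        )
    out: list[tuple[np.ndarray, int]] = [(vol, lab) for vol, lab in items]
    for lab in sorted(by_class):
        pool = by_class[lab]
        n_extra = target_per_class - len(pool)
        if n_extra <= 0:
            continue
        picks = rng.integers(0, len(pool), size=n_extra)
        for idx in picks:
            out.append((augment_rigid(pool[idx], max_shift, max_rot, rng), lab))
    return out
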