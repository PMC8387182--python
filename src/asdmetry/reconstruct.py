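"""Scan conversion of rotational slice stacks and full-volume wedge assembly.

A rotational stack samples the anatomy on a cylindrical-polar raster: slice
rows index the depth ``z`` directly, slice columns index the signed radius
``R`` about the rotation axis, and the slice number indexes the rotation
angle ``alpha``. Scan conversion inverts this: every Cartesian output voxel
is mapped to ``(R, alpha, z)`` and its gray value obtained by bilinear
interpolation in the ``(alpha, R)`` plane (``z`` needs no interpolation
because rows are shared across slices).

The angular coordinate wraps at 180 degrees with a sign flip of ``R``: the
imaging plane at ``alpha`` and at ``alpha + 180`` are the same plane with the
radius axis mirrored, which is what lets 180 one-degree slices cover the full
360-degree sweep.
"""

from __future__ import annotations

import numpy as np

from .core import WEDGE_RANGES, CartesianVolume, SliceStack, WedgeSet
from .errors import ConfigError
from .phantom import wedge_mask

__all__ = ["scan_convert", "assemble_wedges"]


def scan_convert(stack: SliceStack) -> CartesianVolume:
    """Reconstruct a Cartesian volume from a rotational slice stack.

    For a stack of ``W x D`` slices the output grid is ``W x W x D`` with the
    stack's spacing. Voxels outside the scanned disc (``|R|`` beyond the
    slice half-width) are set to 0.
    """
    n = stack.n_slices
    if n < 2:
        raise ConfigError("scan conversion needs at least 2 slices")
    steps = np.diff(stack.angles)
    if not np.allclose(steps, steps[0]):
        raise ConfigError("slice angles must be uniformly spaced")
    step = float(steps[0])
    if not np.isclose(n * step, 180.0):
        raise ConfigError(f"{n} slices at {step} deg do not cover 180 degrees")

    _, W, D = stack.slices.shape
    half = (W - 1) / 2.0

    xi = np.arange(W, dtype=np.float32) - half
    dx, dy = np.meshgrid(xi, xi, indexing="ij")
    R = np.hypot(dx, dy)
    alpha = np.degrees(np.arctan2(dy, dx))
    alpha = np.mod(alpha, 360.0)
    sign = np.where(alpha >= 180.0, -1.0, 1.0).astype(np.float32)
    alpha = np.where(alpha >= 180.0, alpha - 180.0, alpha)
    Rs = R * sign

    a = alpha / step
    i0 = np.floor(a).astype(np.int64)
    w = (a - i0).astype(np.float32)
    np.clip(i0, 0, n - 1, out=i0)
    i1 = i0 + 1
    wrap = i1 >= n
    i1 = np.where(wrap, 0, i1)
    # crossing 180 deg back to slice 0 mirrors the radius axis
    R1 = np.where(wrap, -Rs, Rs)

    slices = np.asarray(stack.slices, dtype=np.float32)
    inside = R <= half

    def sample(idx: np.ndarray, radii: np.ndarray) -> np.ndarray:
        c = np.clip(radii + half, 0.0, W - 1.0)
        cf = np.floor(c).astype(np.int64)
        np.clip(cf, 0, W - 2, out=cf)
        cw = (c - cf).astype(np.float32)[..., None]
        lo = slices[idx, cf, :]
        hi = slices[idx, cf + 1, :]
        return (1.0 - cw) * lo + cw * hi

    out = (1.0 - w)[..., None] * sample(i0, Rs) + w[..., None] * sample(i1, R1)
    out[~inside] = 0.0
    return CartesianVolume(out.astype(np.float32), stack.spacing)


def assemble_wedges(wedges: WedgeSet) -> tuple[CartesianVolume, np.ndarray]:
    """Merge the four 15-degree wedges onto their common grid.

    Voxels covered by two wedges (the shared seam azimuths) are averaged.
    Returns the merged volume together with the integer coverage-count mask
    (0 where no wedge covers a voxel).
    """
    if len(wedges.wedges) != 4:
        raise ConfigError("full-volume assembly requires exactly 4 wedges")
    shape = wedges.wedges[0][0].shape
    spacing = wedges.wedges[0][0].spacing
    total = np.zeros(shape, dtype=float)
    count = np.zeros(shape, dtype=np.int32)
    for (vol, rng), expected in zip(wedges.wedges, WEDGE_RANGES):
        if vol.shape != shape:
            raise ConfigError("wedges must share one grid")
        m = wedge_mask(shape, rng)
        total += np.where(m, vol.data.astype(float), 0.0)
        count += m
    merged = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return CartesianVolume(merged, spacing), count
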