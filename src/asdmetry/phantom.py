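"""Digital heart phantoms with a parameterised atrial septal defect (ASD)
and simulators for the two 3D-echo acquisition modes.

The phantom is deliberately simple: a spherical blood-filled chamber embedded
in a solid block of echogenic tissue, divided into two hemispherical "atria"
by a planar septum slab of finite thickness. The defect is an elliptical
through-hole punched in the slab, centred on the chamber axis. The geometry
is minimal but carries exactly the quantities the measurement pipeline must
recover: the hole's long diameter, short diameter and area on each atrial
face.

Two acquisitions are simulated:

* **Rotational (TTO-style)** — a planar sector image rotated in 1/2/3 degree
  steps about the central depth axis; 180/90/60 slices cover the full 360
  degrees because each slice spans the full scan diameter.
* **Full volume** — four 15-degree azimuthal wedges acquired in consecutive
  cardiac cycles and later reassembled into a 60-degree pyramid; optional
  rigid jitter per wedge models inter-cycle misalignment.

Speckle is modelled as multiplicative, unit-mean Gamma noise (standard for
envelope-detected ultrasound), followed by salt-and-pepper impulses and
quantisation to the configured number of gray levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, shift as nd_shift

from .core import WEDGE_RANGES, CartesianVolume, SeptumPlane, SliceStack, WedgeSet
from .errors import ConfigError, GeometryError

__all__ = [
    "PhantomSpec",
    "AcquisitionConfig",
    "generate_phantom",
    "simulate_tto",
    "simulate_full_volume",
    "septum_plane_of",
    "true_defect_metrics",
    "seam_discontinuity",
    "LABEL_BACKGROUND",
    "LABEL_MYOCARDIUM",
    "LABEL_BLOOD",
]

LABEL_BACKGROUND = 0
LABEL_MYOCARDIUM = 1
LABEL_BLOOD = 2


@dataclass
class PhantomSpec:
    """Geometry and intensity description of one ASD phantom.

    All lengths are millimetres. ``defect_long``/``defect_short`` are the
    full major/minor axes of the elliptical hole; ``defect_angle`` rotates
    the ellipse within the septum plane. The surrounding tissue block shares
    the myocardial intensity so that the image is a genuine two-class
    (tissue vs. blood pool) problem; labels still distinguish background
    (outside the heart) from myocardium (septum + wall shell).
    """

    grid_shape: tuple[int, int, int] = (120, 120, 64)
    spacing: float = 0.5
    chamber_radius: float = 14.0
    septum_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    septum_offset: float = 0.0
    septum_thickness: float = 3.0
    defect_long: float = 10.0
    defect_short: float = 8.0
    defect_angle: float = 0.0
    wall_thickness: float = 3.0
    intensity_myocardium: int = 180
    intensity_blood: int = 30

    def validate(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise GeometryError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.spacing <= 0:
            raise GeometryError("spacing must be positive")
        if self.chamber_radius <= 0:
            raise GeometryError("chamber_radius must be positive")
        if self.defect_short > self.defect_long:
            raise GeometryError(
                f"defect_short ({self.defect_short}) must not exceed "
                f"defect_long ({self.defect_long})"
            )
        if min(self.defect_long, self.defect_short) < 0:
            raise GeometryError("defect axes must be non-negative")
        r_plane = self.septum_plane_radius()
        if self.defect_long / 2 > r_plane:
            raise GeometryError(
                f"defect semi-major axis {self.defect_long / 2:.2f} mm does not fit "
                f"inside the septum extent (radius {r_plane:.2f} mm)"
            )
        for v in (self.intensity_myocardium, self.intensity_blood):
            if not (0 <= v <= 255):
                raise GeometryError("intensities must lie in [0, 255]")

    def septum_plane_radius(self) -> float:
        """Radius of the septum's circular footprint inside the chamber."""
        r2 = self.chamber_radius**2 - self.septum_offset**2
        return float(np.sqrt(max(r2, 0.0)))


def septum_plane_of(spec: PhantomSpec) -> SeptumPlane:
    """The septum slab of a phantom in centred world coordinates."""
    n = np.asarray(spec.septum_normal, dtype=float)
    n = n / np.linalg.norm(n)
    return SeptumPlane(point=n * spec.septum_offset, normal=n, thickness=spec.septum_thickness)


def true_defect_metrics(spec: PhantomSpec) -> dict[str, float]:
    """Ground-truth long/short diameter (mm) and ellipse area (mm^2)."""
    a = spec.defect_long / 2.0
    b = spec.defect_short / 2.0
    return {
        "long_diameter": spec.defect_long,
        "short_diameter": spec.defect_short,
        "area": float(np.pi * a * b),
    }


def _world_grid(shape: tuple[int, int, int], spacing: float) -> tuple[np.ndarray, ...]:
    axes = [(np.arange(n) - (n - 1) / 2.0) * spacing for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[CartesianVolume, CartesianVolume]:
    """Build the intensity volume and the ground-truth label volume.

    Returns ``(intensity, labels)``; both share the grid and spacing of
    ``spec``. Labels are 0 = background, 1 = myocardium (septum + wall
    shell), 2 = blood. The result is deterministic given the spec; ``seed``
    is accepted for interface symmetry with the simulators (acquisition is
    where noise enters).
    """
    spec.validate()
    x, y, z = _world_grid(tuple(spec.grid_shape), spec.spacing)
    r = np.sqrt(x * x + y * y + z * z)

    n = np.asarray(spec.septum_normal, dtype=float)
    n /= np.linalg.norm(n)
    d = x * n[0] + y * n[1] + z * n[2] - spec.septum_offset

    inside_chamber = r <= spec.chamber_radius
    shell = (r > spec.chamber_radius) & (r <= spec.chamber_radius + spec.wall_thickness)
    septum = inside_chamber & (np.abs(d) <= spec.septum_thickness / 2.0)

    plane = septum_plane_of(spec)
    u, v = plane.in_plane_basis()
    qx, qy, qz = x - plane.point[0], y - plane.point[1], z - plane.point[2]
    pu = qx * u[0] + qy * u[1] + qz * u[2]
    pv = qx * v[0] + qy * v[1] + qz * v[2]
    ang = np.deg2rad(spec.defect_angle)
    pu_r = pu * np.cos(ang) + pv * np.sin(ang)
    pv_r = -pu * np.sin(ang) + pv * np.cos(ang)
    a, b = spec.defect_long / 2.0, spec.defect_short / 2.0
    if a > 0 and b > 0:
        hole = septum & ((pu_r / a) ** 2 + (pv_r / b) ** 2 <= 1.0)
    else:
        hole = np.zeros_like(septum)

    labels = np.full(spec.grid_shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[shell | (septum & ~hole)] = LABEL_MYOCARDIUM
    labels[(inside_chamber & ~septum) | hole] = LABEL_BLOOD

    intensity = np.full(spec.grid_shape, spec.intensity_myocardium, dtype=np.uint8)
    intensity[labels == LABEL_BLOOD] = spec.intensity_blood

    sp = (spec.spacing,) * 3
    return CartesianVolume(intensity, sp), CartesianVolume(labels, sp)


@dataclass
class AcquisitionConfig:
    """Parameters of the simulated ultrasound acquisition.

    ``angular_step`` is the rotational increment in degrees (1, 2 or 3,
    yielding 180/90/60 slices); slices are ``slice_width`` pixels across the
    full scan diameter by ``slice_depth`` pixels deep. ``speckle_sigma`` is
    the standard deviation of the unit-mean multiplicative speckle;
    ``impulse_prob`` the per-pixel probability of a salt-or-pepper impulse.
    ``jitter_mm`` applies only to full-volume wedges (rigid in-plane
    misalignment between cardiac cycles).
    """

    angular_step: int = 1
    slice_width: int = 240
    slice_depth: int = 128
    gray_levels: int = 256
    speckle_sigma: float = 0.3
    impulse_prob: float = 0.01
    jitter_mm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.angular_step not in (1, 2, 3):
            raise ConfigError(f"angular_step must be 1, 2 or 3 degrees, got {self.angular_step}")
        if 180 % self.angular_step != 0:
            raise ConfigError("180 must be divisible by angular_step")
        if self.slice_width < 2 or self.slice_depth < 1:
            raise ConfigError("slice dimensions too small")
        if self.gray_levels < 2:
            raise ConfigError("gray_levels must be at least 2")
        if self.speckle_sigma < 0 or not (0 <= self.impulse_prob <= 1):
            raise ConfigError("invalid noise parameters")


def _corrupt_and_quantize(
    img: np.ndarray, cfg: AcquisitionConfig, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative speckle, then impulses, then integer quantisation."""
    out = np.asarray(img, dtype=float)
    s = cfg.speckle_sigma
    if s > 0:
        # Gamma(k, 1/k) has mean 1 and sd 1/sqrt(k); k = 1/s^2 gives sd = s.
        k = 1.0 / (s * s)
        out = out * rng.gamma(shape=k, scale=1.0 / k, size=out.shape)
    if cfg.impulse_prob > 0:
        u = rng.random(out.shape)
        out[u < cfg.impulse_prob / 2] = 0
        out[(u >= cfg.impulse_prob / 2) & (u < cfg.impulse_prob)] = cfg.gray_levels - 1
    out = np.clip(np.rint(out), 0, cfg.gray_levels - 1)
    dtype = np.uint8 if cfg.gray_levels <= 256 else np.uint16
    return out.astype(dtype)


def simulate_tto(volume: CartesianVolume, cfg: AcquisitionConfig) -> SliceStack:
    """Rotational-probe acquisition: planar resampling at each rotation angle.

    Slice ``i`` samples the plane at ``i * angular_step`` degrees about the
    central depth (z) axis; columns run over the signed radius across the
    full diameter, rows over depth. Trilinear sampling; out-of-volume reads
    are 0. Speckle and impulse noise are applied per slice and the result is
    quantised to ``gray_levels`` integer levels.
    """
    cfg.validate()
    nx, ny, nz = volume.shape
    W, D = cfg.slice_width, cfg.slice_depth
    if min(nx, ny) < W:
        raise ConfigError(f"volume in-plane extent {(nx, ny)} smaller than slice_width {W}")
    if nz < D:
        raise ConfigError(f"volume depth {nz} smaller than slice_depth {D}")

    n_slices = 180 // cfg.angular_step
    angles = np.arange(n_slices) * float(cfg.angular_step)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    z0 = (nz - D) / 2.0
    R = np.arange(W, dtype=float) - (W - 1) / 2.0
    zi = z0 + np.arange(D, dtype=float)
    Rg, Zg = np.meshgrid(R, zi, indexing="ij")

    vol = np.asarray(volume.data, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    slices = np.empty((n_slices, W, D), dtype=np.uint16 if cfg.gray_levels > 256 else np.uint8)
    for i, ang in enumerate(angles):
        t = np.deg2rad(ang)
        xs = cx + Rg * np.cos(t)
        ys = cy + Rg * np.sin(t)
        plane = map_coordinates(vol, [xs, ys, Zg], order=1, mode="constant", cval=0.0)
        slices[i] = _corrupt_and_quantize(plane, cfg, rng)
    return SliceStack(slices=slices, angles=angles, spacing=volume.spacing)


def _azimuth_deg(shape: tuple[int, int, int]) -> np.ndarray:
    """Per-voxel azimuth (degrees in [0, 360)) about the central depth axis."""
    nx, ny, _ = shape
    x = np.arange(nx, dtype=float) - (nx - 1) / 2.0
    y = np.arange(ny, dtype=float) - (ny - 1) / 2.0
    X, Y = np.meshgrid(x, y, indexing="ij")
    az = np.degrees(np.arctan2(Y, X))
    az[az < 0] += 360.0
    return az


def wedge_mask(shape: tuple[int, int, int], az_range: tuple[float, float]) -> np.ndarray:
    """Boolean in-plane coverage of one azimuthal wedge, broadcast over depth.

    Boundary azimuths are inclusive on both ends, so voxels exactly on a
    15-degree seam are covered by both adjacent wedges.
    """
    az = _azimuth_deg(shape)
    lo, hi = az_range
    m2d = (az >= lo) & (az <= hi)
    return np.broadcast_to(m2d[:, :, None], shape)


def simulate_full_volume(volume: CartesianVolume, cfg: AcquisitionConfig) -> WedgeSet:
    """Full-volume acquisition: four independently acquired 15-degree wedges.

    Each wedge is the source volume restricted to its azimuth range, with an
    independent noise realisation; ``jitter_mm > 0`` additionally applies a
    random rigid in-plane shift per wedge before masking, emulating
    misalignment between the consecutive cardiac cycles.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    streams = rng.spawn(4)
    wedges = []
    for (lo, hi), sub in zip(WEDGE_RANGES, streams):
        data = np.asarray(volume.data, dtype=float)
        if cfg.jitter_mm > 0:
            dx, dy = sub.normal(0.0, cfg.jitter_mm, size=2) / np.array(volume.spacing[:2])
            data = nd_shift(data, shift=(dx, dy, 0.0), order=1, mode="constant", cval=0.0)
        data = _corrupt_and_quantize(data, cfg, sub).astype(float)
        data = np.where(wedge_mask(volume.shape, (lo, hi)), data, 0.0)
        dtype = np.uint8 if cfg.gray_levels <= 256 else np.uint16
        wedges.append(
            (CartesianVolume(data.astype(dtype), volume.spacing), (lo, hi))
        )
    return WedgeSet(wedges=wedges)


def seam_discontinuity(wedges: WedgeSet, reference: CartesianVolume) -> float:
    """Mean absolute deviation from ``reference`` in a band around the
    interior 15/30/45-degree seams — zero for noise- and jitter-free wedges,
    strictly positive once wedges are misaligned."""
    az = _azimuth_deg(reference.shape)
    band = np.zeros(az.shape, dtype=bool)
    for seam in (15.0, 30.0, 45.0):
        band |= np.abs(az - seam) <= 1.0
    band3 = np.broadcast_to(band[:, :, None], reference.shape)
    total = np.zeros(reference.shape, dtype=float)
    count = np.zeros(reference.shape, dtype=float)
    for vol, rng_ in wedges.wedges:
        m = wedge_mask(reference.shape, rng_)
        total += np.where(m, vol.data.astype(float), 0.0)
        count += m
    merged = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    sel = band3 & (count > 0)
    return float(np.abs(merged[sel] - reference.data.astype(float)[sel]).mean())
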