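"""Core in-memory containers shared by every pipeline stage.

World coordinates are physical millimetres with the origin at the centre of
the voxel grid, i.e. ``world = (index - (n - 1) / 2) * spacing`` per axis.
Volumes are indexed ``(x, y, z)`` where ``z`` is the probe depth axis (the
rotation axis of the rotational acquisition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CartesianVolume",
    "SliceStack",
    "WedgeSet",
    "TriangleMesh",
    "SeptumPlane",
    "WEDGE_RANGES",
]

#: Fixed azimuthal ranges (degrees) of the four full-volume sub-sectors.
WEDGE_RANGES: tuple[tuple[float, float], ...] = (
    (0.0, 15.0),
    (15.0, 30.0),
    (30.0, 45.0),
    (45.0, 60.0),
)


@dataclass
class CartesianVolume:
    """A 3D scalar grid with physical voxel spacing in mm.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)``.
    spacing:
        Physical size of one voxel along each axis, mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        sp = tuple(float(s) for s in np.atleast_1d(self.spacing).ravel())
        if len(sp) == 1:
            sp = sp * 3
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.spacing = sp

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices ``(..., 3)`` to centred mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        half = (np.array(self.shape) - 1) / 2.0
        return (idx - half) * np.array(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        half = (np.array(self.shape) - 1) / 2.0
        return pts / np.array(self.spacing) + half


@dataclass
class SliceStack:
    """Ordered 2D sector slices from a rotational (TTO-style) acquisition.

    ``slices[i]`` has shape ``(width, depth)``: the signed-radius axis across
    the full scan diameter, and the depth axis shared with the volume's z.
    ``angles[i]`` is the rotation angle of slice ``i`` in degrees in [0, 180).
    """

    slices: np.ndarray
    angles: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError("slices must be (n, width, depth)")
        if len(self.angles) != len(self.slices):
            raise ValueError("one angle per slice required")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def angular_step(self) -> float:
        steps = np.diff(self.angles)
        return float(steps[0]) if len(steps) else 0.0


@dataclass
class WedgeSet:
    """The four 15-degree azimuthal sub-volumes of a full-volume acquisition."""

    wedges: list[tuple[CartesianVolume, tuple[float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranges = tuple(tuple(float(a) for a in rng) for _, rng in self.wedges)
        if len(self.wedges) != 4 or ranges != WEDGE_RANGES:
            raise ValueError(
                f"a wedge set holds exactly 4 wedges with ranges {WEDGE_RANGES}, got {ranges}"
            )


@dataclass
class SeptumPlane:
    """The atrial septum as an (infinite) slab: mid-plane point, unit normal
    and slab thickness, all in centred world mm coordinates.

    The two atrial faces sit at ``point ± (thickness / 2) * normal``; by
    convention the ``left_atrial`` face lies on the +normal side.
    """

    point: np.ndarray
    normal: np.ndarray
    thickness: float

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("septum normal must be non-zero")
        self.normal = n / nn
        self.thickness = float(self.thickness)
        if self.thickness < 0:
            raise ValueError("septum thickness must be non-negative")

    def in_plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal vectors spanning the septum plane."""
        n = self.normal
        helper = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, helper)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v


@dataclass
class TriangleMesh:
    """Triangulated surface in physical mm coordinates."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)
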