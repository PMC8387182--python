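"""Readers and writers for every on-disk format the pipeline touches.

Internal convention: volumes are ``(x, y, z)`` index order; every reader
normalises to it at the boundary. Supported formats:

* volumes — NRRD (default) and MetaImage, via SimpleITK; lossless for
  integer payloads, spacing preserved;
* multiframe DICOM full-volume files (read only) whose frames are ordered
  height, width, depth, time — one Cartesian volume per time point falls
  out by slicing the frame axis, with no resampling;
* surface meshes — STL and PLY, via trimesh;
* rotational slice stacks — a directory of 8-bit PGM/PNG images plus a JSON
  manifest carrying the rotation angles and spacing.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
import SimpleITK as sitk
import trimesh

from .core import CartesianVolume, SliceStack, TriangleMesh
from .errors import FormatError

__all__ = [
    "VolumeHeader",
    "read_dicom_fullvolume",
    "write_volume",
    "read_volume",
    "write_mesh",
    "read_mesh",
    "write_slice_stack",
    "read_slice_stack",
]

_VOLUME_EXTS = {".nrrd", ".mha", ".mhd"}
_MESH_EXTS = {".stl", ".ply"}
_EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
# VRs carrying a 2-byte reserved field and a 4-byte length in explicit VR
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"OV", b"SQ", b"UC", b"UR", b"UT", b"UN"}


@dataclass
class VolumeHeader:
    """Geometry of a full-volume DICOM file.

    ``shape`` follows the file's fixed axis order (height, width, depth,
    time); ``spacing`` is mm per voxel along (x, y, z).
    """

    shape: tuple[int, int, int, int]
    spacing: tuple[float, float, float]
    axis_order: tuple[str, str, str, str] = ("height", "width", "depth", "time")
    frame_count: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.shape):
            raise FormatError(f"volume shape must be strictly positive, got {self.shape}")


# ---------------------------------------------------------------------------
# DICOM multiframe reading
# ---------------------------------------------------------------------------


def iter_element_spans(buf: bytes, offset: int):
    """Walk top-level explicit-VR little-endian data elements.

    Yields ``(tag, start, end)`` where ``tag`` is the 32-bit (group << 16 |
    element) value and ``start:end`` spans the whole element. Stops at an
    undefined-length element (not produced by the supported dialect).
    """
    n = len(buf)
    while offset + 8 <= n:
        start = offset
        group, elem = struct.unpack_from("<HH", buf, offset)
        vr = buf[offset + 4 : offset + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, offset + 8)
            offset += 12
        else:
            (length,) = struct.unpack_from("<H", buf, offset + 6)
            offset += 8
        if length == 0xFFFFFFFF:
            return
        offset += length
        if offset > n:
            raise FormatError("truncated DICOM data element")
        yield (group << 16) | elem, start, offset


def _meta_and_dataset_offsets(buf: bytes) -> tuple[str, int]:
    """Return (transfer syntax UID, offset of the first dataset element)."""
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise FormatError("not a DICOM part-10 file (missing DICM magic)")
    ts = ""
    offset = 132
    for tag, start, end in iter_element_spans(buf, 132):
        if tag >> 16 != 0x0002:
            offset = start
            break
        if tag == 0x00020010:
            vr = buf[start + 4 : start + 6]
            skip = 12 if vr in _LONG_VRS else 8
            ts = buf[start + skip : end].decode("ascii").rstrip("\x00 ")
        offset = end
    return ts, offset


def _check_element_order(buf: bytes, offset: int) -> None:
    last = -1
    for tag, _, _ in iter_element_spans(buf, offset):
        if tag <= last:
            raise FormatError(
                f"data elements not arranged in ascending tag order "
                f"(tag {tag >> 16:04X},{tag & 0xFFFF:04X} follows a larger tag)"
            )
        last = tag


_REQUIRED_TAGS = {
    "Rows": (0x0028, 0x0010),
    "Columns": (0x0028, 0x0011),
    "BitsAllocated": (0x0028, 0x0100),
    "PixelData": (0x7FE0, 0x0010),
}


def read_dicom_fullvolume(path) -> tuple[list[CartesianVolume], VolumeHeader]:
    """Read a multiframe full-volume DICOM file into per-timepoint volumes.

    Frames must be ordered depth-fastest, time-slowest (the height, width,
    depth, time layout), so separating the time points is pure slicing —
    no resampling is performed. Returns volumes in ``(x, y, z)`` order.
    """
    path = Path(path)
    buf = path.read_bytes()
    ts, ds_offset = _meta_and_dataset_offsets(buf)
    if ts in ("", _EXPLICIT_VR_LE):
        _check_element_order(buf, ds_offset)

    ds = pydicom.dcmread(path)
    for name, tag in _REQUIRED_TAGS.items():
        if tag not in ds:
            raise FormatError(
                f"missing required DICOM tag {name} ({tag[0]:04X},{tag[1]:04X})"
            )

    frames = int(getattr(ds, "NumberOfFrames", 1))
    n_time = int(getattr(ds, "NumberOfTemporalPositions", 1))
    if frames % n_time != 0:
        raise FormatError(
            f"NumberOfFrames ({frames}) not divisible by "
            f"NumberOfTemporalPositions ({n_time})"
        )
    depth = frames // n_time

    arr = ds.pixel_array
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != frames:
        raise FormatError(f"pixel data holds {arr.shape[0]} frames, header says {frames}")

    row_sp, col_sp = (float(v) for v in getattr(ds, "PixelSpacing", [1.0, 1.0]))
    z_sp = float(getattr(ds, "SpacingBetweenSlices", 1.0))
    spacing = (col_sp, row_sp, z_sp)

    volumes = [
        CartesianVolume(arr[t * depth : (t + 1) * depth].transpose(2, 1, 0), spacing)
        for t in range(n_time)
    ]
    header = VolumeHeader(
        shape=(int(ds.Rows), int(ds.Columns), depth, n_time),
        spacing=spacing,
        frame_count=frames,
    )
    return volumes, header


# ---------------------------------------------------------------------------
# volumes (NRRD / MetaImage)
# ---------------------------------------------------------------------------


def write_volume(path, volume: CartesianVolume) -> None:
    path = Path(path)
    if path.suffix.lower() not in _VOLUME_EXTS:
        raise FormatError(f"unsupported volume format {path.suffix!r} (use .nrrd/.mha/.mhd)")
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> CartesianVolume:
    path = Path(path)
    if path.suffix.lower() not in _VOLUME_EXTS:
        raise FormatError(f"unsupported volume format {path.suffix!r} (use .nrrd/.mha/.mhd)")
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return CartesianVolume(data, tuple(img.GetSpacing()))


# ---------------------------------------------------------------------------
# meshes (STL / PLY)
# ---------------------------------------------------------------------------


def write_mesh(path, mesh: TriangleMesh) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTS:
        raise FormatError(f"unsupported mesh format {path.suffix!r} (use .stl/.ply)")
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise ValueError("refusing to write an empty mesh")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def read_mesh(path) -> TriangleMesh:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTS:
        raise FormatError(f"unsupported mesh format {path.suffix!r} (use .stl/.ply)")
    tm = trimesh.load_mesh(str(path), process=False)
    return TriangleMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# slice stacks (PGM/PNG directory + manifest)
# ---------------------------------------------------------------------------


def write_slice_stack(directory, stack: SliceStack, fmt: str = "png") -> None:
    """Write each slice as an 8-bit image plus a JSON manifest of angles,
    spacing and layout."""
    if fmt not in ("png", "pgm"):
        raise FormatError(f"slice stacks support png/pgm, not {fmt!r}")
    if stack.slices.dtype != np.uint8:
        raise FormatError("slice stacks are written as 8-bit images; expected uint8 data")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, sl in enumerate(stack.slices):
        name = f"slice_{i:03d}.{fmt}"
        iio.imwrite(directory / name, np.ascontiguousarray(sl))
        names.append(name)
    manifest = {
        "files": names,
        "angles_deg": [float(a) for a in stack.angles],
        "spacing_mm": [float(s) for s in stack.spacing],
        "slice_shape": list(stack.slices.shape[1:]),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_slice_stack(directory) -> SliceStack:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    slices = np.stack([iio.imread(directory / name) for name in manifest["files"]])
    if list(slices.shape[1:]) != manifest["slice_shape"]:
        raise FormatError("slice images disagree with the manifest slice_shape")
    return SliceStack(
        slices=slices,
        angles=np.array(manifest["angles_deg"], dtype=float),
        spacing=tuple(manifest["spacing_mm"]),
    )
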