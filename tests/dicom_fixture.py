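"""Minimal multiframe DICOM fixture writer (synthetic files for tests only).

Emits uncompressed explicit-VR little-endian secondary-capture objects whose
frames are ordered depth-fastest, time-slowest, plus a deliberately
mis-ordered variant produced by swapping two adjacent data elements at the
byte level.
"""

from __future__ import annotations

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from asdmetry.io import _meta_and_dataset_offsets, iter_element_spans


def write_multiframe(
    path,
    frames: np.ndarray,
    n_time: int = 1,
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    omit: tuple[str, ...] = (),
) -> None:
    """Write ``frames`` of shape (F, rows, cols), uint8, as one multiframe
    file; ``omit`` drops named attributes to exercise missing-tag errors."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=["asdmetry-fixture"])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Rows = frames.shape[1]
    ds.Columns = frames.shape[2]
    ds.NumberOfFrames = frames.shape[0]
    ds.NumberOfTemporalPositions = n_time
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [spacing[1], spacing[0]]
    ds.SpacingBetweenSlices = spacing[2]
    ds.PixelData = np.ascontiguousarray(frames, dtype=np.uint8).tobytes()
    for name in omit:
        delattr(ds, name)
    ds.save_as(str(path), enforce_file_format=True)


def shuffle_elements(src_path, dst_path) -> None:
    """Copy a fixture file with two adjacent top-level data elements swapped,
    breaking the ascending-tag ordering the format requires."""
    buf = bytearray(open(src_path, "rb").read())
    _, offset = _meta_and_dataset_offsets(bytes(buf))
    spans = list(iter_element_spans(bytes(buf), offset))
    for i, (tag, start, end) in enumerate(spans[:-1]):
        if tag == 0x00280010:  # Rows; swap with the element that follows it
            _, s2, e2 = spans[i + 1]
            out = buf[:start] + buf[s2:e2] + buf[start:end] + buf[e2:]
            open(dst_path, "wb").write(out)
            return
    raise AssertionError("Rows element not found in fixture")
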