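"""Minimal DICOM series reader/writer (explicit VR little endian only).

No DICOM library is available in this environment, so this module implements
the small subset the package needs: uncompressed single-frame MR slices with
the geometry tags (position, orientation, pixel spacing) and 16-bit signed
pixel data with rescale slope/intercept.  It is not a general DICOM
implementation.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

# VRs that use the 4-byte length form (2 reserved bytes + 32-bit length).
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}

# (group, element) -> (VR, name)
_TAGS = {
    (0x0008, 0x0016): ("UI", "SOPClassUID"),
    (0x0008, 0x0018): ("UI", "SOPInstanceUID"),
    (0x0008, 0x0060): ("CS", "Modality"),
    (0x0018, 0x0050): ("DS", "SliceThickness"),
    (0x0020, 0x000D): ("UI", "StudyInstanceUID"),
    (0x0020, 0x000E): ("UI", "SeriesInstanceUID"),
    (0x0020, 0x0013): ("IS", "InstanceNumber"),
    (0x0020, 0x0032): ("DS", "ImagePositionPatient"),
    (0x0020, 0x0037): ("DS", "ImageOrientationPatient"),
    (0x0028, 0x0002): ("US", "SamplesPerPixel"),
    (0x0028, 0x0004): ("CS", "PhotometricInterpretation"),
    (0x0028, 0x0010): ("US", "Rows"),
    (0x0028, 0x0011): ("US", "Columns"),
    (0x0028, 0x0030): ("DS", "PixelSpacing"),
    (0x0028, 0x0100): ("US", "BitsAllocated"),
    (0x0028, 0x0101): ("US", "BitsStored"),
    (0x0028, 0x0102): ("US", "HighBit"),
    (0x0028, 0x0103): ("US", "PixelRepresentation"),
    (0x0028, 0x1052): ("DS", "RescaleIntercept"),
    (0x0028, 0x1053): ("DS", "RescaleSlope"),
    (0x7FE0, 0x0010): ("OW", "PixelData"),
}


def _encode_element(group: int, elem: int, vr: str, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr not in ("UI",) else b"\x00"
    head = struct.pack("<HH", group, elem) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _txt(s: str) -> bytes:
    b = s.encode("ascii")
    return b + b" " if len(b) % 2 else b


def _ui(s: str) -> bytes:
    b = s.encode("ascii")
    return b + b"\x00" if len(b) % 2 else b


def _ds(values) -> bytes:
    return _txt("\\".join(f"{v:.10g}" for v in np.atleast_1d(values)))


def write_slice(
    path,
    pixel_array: np.ndarray,
    *,
    series_uid: str,
    instance_number: int,
    position,
    orientation6,
    pixel_spacing,
    slice_thickness: float,
    slope: float,
    intercept: float,
) -> None:
    """Write one int16 slice as an explicit-VR-LE DICOM file.

    ``pixel_array`` is (Rows, Columns) int16; ``orientation6`` is the DICOM
    (column-direction, row-direction) 6-vector; ``pixel_spacing`` is
    (row spacing, column spacing) in mm.
    """
    arr = np.ascontiguousarray(pixel_array, dtype="<i2")
    rows, cols = arr.shape
    sop_uid = f"{series_uid}.{instance_number}"
    elems = [
        ((0x0008, 0x0016), "UI", _ui("1.2.840.10008.5.1.4.1.1.4")),
        ((0x0008, 0x0018), "UI", _ui(sop_uid)),
        ((0x0008, 0x0060), "CS", _txt("MR")),
        ((0x0018, 0x0050), "DS", _ds([slice_thickness])),
        ((0x0020, 0x000D), "UI", _ui(series_uid.rsplit(".", 1)[0])),
        ((0x0020, 0x000E), "UI", _ui(series_uid)),
        ((0x0020, 0x0013), "IS", _txt(str(instance_number))),
        ((0x0020, 0x0032), "DS", _ds(position)),
        ((0x0020, 0x0037), "DS", _ds(orientation6)),
        ((0x0028, 0x0002), "US", struct.pack("<H", 1)),
        ((0x0028, 0x0004), "CS", _txt("MONOCHROME2")),
        ((0x0028, 0x0010), "US", struct.pack("<H", rows)),
        ((0x0028, 0x0011), "US", struct.pack("<H", cols)),
        ((0x0028, 0x0030), "DS", _ds(pixel_spacing)),
        ((0x0028, 0x0100), "US", struct.pack("<H", 16)),
        ((0x0028, 0x0101), "US", struct.pack("<H", 16)),
        ((0x0028, 0x0102), "US", struct.pack("<H", 15)),
        ((0x0028, 0x0103), "US", struct.pack("<H", 1)),
        ((0x0028, 0x1052), "DS", _ds([intercept])),
        ((0x0028, 0x1053), "DS", _ds([slope])),
        ((0x7FE0, 0x0010), "OW", arr.tobytes()),
    ]
    body = b"".join(_encode_element(g, e, vr, v) for (g, e), vr, v in elems)

    meta_elems = [
        ((0x0002, 0x0002), "UI", _ui("1.2.840.10008.5.1.4.1.1.4")),
        ((0x0002, 0x0003), "UI", _ui(sop_uid)),
        ((0x0002, 0x0010), "UI", _ui(EXPLICIT_VR_LE)),
    ]
    meta = b"".join(_encode_element(g, e, vr, v) for (g, e), vr, v in meta_elems)
    meta = _encode_element(0x0002, 0x0000, "UL", struct.pack("<I", len(meta))) + meta

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)


def _parse_elements(buf: bytes) -> dict:
    """Parse explicit-VR-LE data elements into {(group, elem): raw bytes}."""
    out = {}
    pos = 0
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        vr = buf[pos + 4 : pos + 6].decode("ascii", errors="replace")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            start = pos + 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            start = pos + 8
        out[(group, elem)] = buf[start : start + length]
        pos = start + length
    return out


def read_file(path) -> dict:
    """Read one DICOM file into a dict of decoded attributes."""
    raw = Path(path).read_bytes()
    if raw[128:132] != b"DICM":
        raise ValueError(f"{path}: not a DICOM file (missing DICM marker)")
    elems = _parse_elements(raw[132:])
    meta_ts = elems.get((0x0002, 0x0010))
    if meta_ts is not None and meta_ts.rstrip(b"\x00 ").decode("ascii") != EXPLICIT_VR_LE:
        raise ValueError(f"{path}: unsupported transfer syntax")

    def ds(tag):
        return np.array(
            [float(x) for x in elems[tag].decode("ascii").strip("\x00 ").split("\\")]
        )

    def us(tag):
        return struct.unpack("<H", elems[tag][:2])[0]

    rows, cols = us((0x0028, 0x0010)), us((0x0028, 0x0011))
    pixels = np.frombuffer(elems[(0x7FE0, 0x0010)][: rows * cols * 2], dtype="<i2")
    slope = ds((0x0028, 0x1053))[0] if (0x0028, 0x1053) in elems else 1.0
    intercept = ds((0x0028, 0x1052))[0] if (0x0028, 0x1052) in elems else 0.0
    return {
        "series_uid": elems[(0x0020, 0x000E)].rstrip(b"\x00 ").decode("ascii"),
        "position": ds((0x0020, 0x0032)),
        "orientation6": ds((0x0020, 0x0037)),
        "pixel_spacing": ds((0x0028, 0x0030)),
        "pixel_array": pixels.reshape(rows, cols).astype(float) * slope + intercept,
    }


def read_series(directory):
    """Read one DICOM series from a directory.

    Returns ``(data, geometry)`` with data indexed (i, j, k): i = column
    direction, j = row direction, k = slice, matching the package's internal
    layout.  Slices are sorted by projected position along the slice normal.
    Raises ``ValueError`` on mixed series UIDs or non-uniform slice spacing
    (> 1e-3 mm deviation).
    """
    from aclloc.volio import Geometry

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = [read_file(p) for p in files]
    if not slices:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    uids = {s["series_uid"] for s in slices}
    if len(uids) != 1:
        raise ValueError(f"directory mixes {len(uids)} series UIDs: {sorted(uids)}")

    o6 = slices[0]["orientation6"]
    col_dir, row_dir = o6[:3], o6[3:]
    normal = np.cross(col_dir, row_dir)
    slices.sort(key=lambda s: float(np.dot(s["position"], normal)))

    proj = np.array([np.dot(s["position"], normal) for s in slices])
    if len(slices) > 1:
        steps = np.diff(proj)
        if np.any(steps <= 0):
            raise ValueError("duplicate or non-monotone slice positions")
        if np.max(steps) - np.min(steps) > 1e-3:
            raise ValueError(
                f"non-uniform slice spacing: range {np.min(steps):.6f}-{np.max(steps):.6f} mm"
            )
        slice_spacing = float(np.mean(steps))
    else:
        slice_spacing = 1.0

    ps = slices[0]["pixel_spacing"]  # (row spacing, column spacing)
    data = np.stack([s["pixel_array"].T for s in slices], axis=-1)  # (i, j, k)
    geom = Geometry(
        spacing=np.array([ps[1], ps[0], slice_spacing]),
        origin=slices[0]["position"],
        orientation=np.column_stack([col_dir, row_dir, normal]),
    )
    return data, geom


def write_series(volume, directory, *, series_uid: str = "1.2.826.0.1.3680043.9999.1") -> np.ndarray:
    """Export a Volume as a DICOM series of int16 slices.

    Intensities are quantized to the 16-bit rescale grid; the quantized array
    is returned so callers can export the *same* values to other formats.
    Near-integral data are stored losslessly with slope 1.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.asarray(volume.data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    if np.allclose(data, np.rint(data), atol=1e-9) and lo >= -32000 and hi <= 32000:
        slope, intercept = 1.0, 0.0
        stored = np.rint(data).astype(np.int16)
    else:
        slope = (hi - lo) / 64000.0 if hi > lo else 1.0
        intercept = lo + 32000.0 * slope
        stored = np.rint((data - lo) / slope).astype(np.int64) - 32000
        stored = stored.astype(np.int16)
    quantized = stored.astype(float) * slope + intercept

    geom = volume.geometry
    o = geom.orientation
    orientation6 = np.concatenate([o[:, 0], o[:, 1]])
    n_slices = data.shape[2]
    for k in range(n_slices):
        write_slice(
            directory / f"slice_{k:04d}.dcm",
            stored[:, :, k].T,  # (Rows=j, Columns=i)
            series_uid=series_uid,
            instance_number=k + 1,
            position=geom.voxel_to_physical((0, 0, k)),
            orientation6=orientation6,
            pixel_spacing=(geom.spacing[1], geom.spacing[0]),
            slice_thickness=geom.spacing[2],
            slope=slope,
            intercept=intercept,
        )
    return quantized
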