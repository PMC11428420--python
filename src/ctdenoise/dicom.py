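"""Minimal single-frame grayscale DICOM reader/writer.

Supports uncompressed little-endian transfer syntaxes (implicit and explicit
VR), MONOCHROME1/2 photometric interpretation, 8/16-bit integer pixel data,
and the rescale slope/intercept needed to map stored values to HU.  This is
deliberately small: no sequences-of-items beyond skipping, no compressed
syntaxes, no multi-frame.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_dicom", "write_dicom", "DicomError"]

_IMPLICIT_LE = "1.2.840.10008.1.2"
_EXPLICIT_LE = "1.2.840.10008.1.2.1"

# VRs with a 2-byte reserved field and 4-byte length in explicit encoding
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

_TAG_ROWS = (0x0028, 0x0010)
_TAG_COLS = (0x0028, 0x0011)
_TAG_BITS_ALLOC = (0x0028, 0x0100)
_TAG_PIXEL_REP = (0x0028, 0x0103)
_TAG_PHOTOMETRIC = (0x0028, 0x0004)
_TAG_INTERCEPT = (0x0028, 0x1052)
_TAG_SLOPE = (0x0028, 0x1053)
_TAG_PIXEL_DATA = (0x7FE0, 0x0010)
_TAG_TSUID = (0x0002, 0x0010)


class DicomError(ValueError):
    pass


def _next_element(buf: bytes, pos: int, explicit: bool):
    """Parse one element at ``pos``; return (tag, value_bytes, next_pos)."""
    group, elem = struct.unpack_from("<HH", buf, pos)
    pos += 4
    if explicit or group == 0x0002:
        vr = buf[pos:pos + 2]
        if vr in _LONG_VRS:
            length = struct.unpack_from("<I", buf, pos + 4)[0]
            pos += 8
        else:
            length = struct.unpack_from("<H", buf, pos + 2)[0]
            pos += 4
    else:
        length = struct.unpack_from("<I", buf, pos)[0]
        pos += 4
    if length == 0xFFFFFFFF:
        raise DicomError("undefined-length elements are not supported")
    return (group, elem), buf[pos:pos + length], pos + length


def read_dicom(path) -> tuple[np.ndarray, dict]:
    """Read a single-frame grayscale DICOM file.

    Returns ``(pixels_hu, info)`` where pixels already have
    ``slope * stored + intercept`` applied.
    """
    path = Path(path)
    buf = path.read_bytes()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomError(f"not a DICOM file (missing DICM magic): {path}")

    # file meta group is always explicit VR little endian
    pos = 132
    tsuid = _EXPLICIT_LE
    while pos + 8 <= len(buf):
        tag, value, nxt = _next_element(buf, pos, explicit=True)
        if tag[0] != 0x0002:
            break
        if tag == _TAG_TSUID:
            tsuid = value.decode("ascii").rstrip("\x00 ")
        pos = nxt

    if tsuid == _EXPLICIT_LE:
        explicit = True
    elif tsuid == _IMPLICIT_LE:
        explicit = False
    else:
        raise DicomError(f"unsupported transfer syntax {tsuid!r} in {path}")

    elements = {}
    while pos + 8 <= len(buf):
        tag, value, pos = _next_element(buf, pos, explicit=explicit)
        elements[tag] = value
        if tag == _TAG_PIXEL_DATA:
            break
    try:
        rows = int(np.frombuffer(elements[_TAG_ROWS], "<u2")[0])
        cols = int(np.frombuffer(elements[_TAG_COLS], "<u2")[0])
        bits = int(np.frombuffer(elements[_TAG_BITS_ALLOC], "<u2")[0])
        pixel_bytes = elements[_TAG_PIXEL_DATA]
    except KeyError as exc:
        raise DicomError(f"missing required element in {path}: {exc}") from exc

    photometric = elements.get(_TAG_PHOTOMETRIC, b"MONOCHROME2").decode("ascii").strip("\x00 ")
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise DicomError(
            f"unsupported photometric interpretation {photometric!r} in {path}"
        )
    signed = bool(int(np.frombuffer(elements.get(_TAG_PIXEL_REP, b"\x00\x00"), "<u2")[0]))
    slope = float(elements.get(_TAG_SLOPE, b"1").decode("ascii").strip("\x00 ") or 1.0)
    intercept = float(elements.get(_TAG_INTERCEPT, b"0").decode("ascii").strip("\x00 ") or 0.0)

    if bits == 16:
        dtype = "<i2" if signed else "<u2"
    elif bits == 8:
        dtype = "i1" if signed else "u1"
    else:
        raise DicomError(f"unsupported BitsAllocated={bits} in {path}")

    stored = np.frombuffer(pixel_bytes, dtype=dtype, count=rows * cols)
    stored = stored.reshape(rows, cols).astype(np.float64)
    pixels = slope * stored + intercept
    if photometric == "MONOCHROME1":
        pixels = pixels.max() - pixels + pixels.min()
    info = {
        "rows": rows,
        "columns": cols,
        "bits_allocated": bits,
        "slope": slope,
        "intercept": intercept,
        "photometric": photometric,
        "transfer_syntax": tsuid,
    }
    return pixels, info


def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr != b"DS" else b" "
    head = struct.pack("<HH", group, elem)
    if vr in _LONG_VRS:
        return head + vr + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + vr + struct.pack("<H", len(value)) + value


def write_dicom(path, pixels: np.ndarray, slope: float = 1.0,
                intercept: float = -1024.0) -> None:
    """Write a 16-bit signed, explicit-VR little-endian single-frame file.

    Stored values are computed as ``(pixels - intercept) / slope`` and rounded.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise DicomError("only 2D single-frame images are supported")
    stored = np.round((pixels - intercept) / slope)
    if stored.min() < -32768 or stored.max() > 32767:
        raise DicomError("stored values exceed int16 range; adjust slope/intercept")
    stored = stored.astype("<i2")
    rows, cols = pixels.shape

    def us(v):
        return struct.pack("<H", v)

    sop_class = b"1.2.840.10008.5.1.4.1.1.2"  # CT Image Storage
    sop_inst = b"1.2.826.0.1.3680043.9999.1"
    meta = b"".join([
        _element(0x0002, 0x0001, b"OB", b"\x00\x01"),
        _element(0x0002, 0x0002, b"UI", sop_class),
        _element(0x0002, 0x0003, b"UI", sop_inst),
        _element(0x0002, 0x0010, b"UI", _EXPLICIT_LE.encode()),
    ])
    meta = _element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta))) + meta

    body = b"".join([
        _element(0x0008, 0x0016, b"UI", sop_class),
        _element(0x0008, 0x0018, b"UI", sop_inst),
        _element(0x0008, 0x0060, b"CS", b"CT"),
        _element(0x0028, 0x0002, b"US", us(1)),           # samples per pixel
        _element(0x0028, 0x0004, b"CS", b"MONOCHROME2"),
        _element(0x0028, 0x0010, b"US", us(rows)),
        _element(0x0028, 0x0011, b"US", us(cols)),
        _element(0x0028, 0x0100, b"US", us(16)),          # bits allocated
        _element(0x0028, 0x0101, b"US", us(16)),          # bits stored
        _element(0x0028, 0x0102, b"US", us(15)),          # high bit
        _element(0x0028, 0x0103, b"US", us(1)),           # signed
        _element(0x0028, 0x1052, b"DS", f"{intercept:g}".encode()),
        _element(0x0028, 0x1053, b"DS", f"{slope:g}".encode()),
        _element(0x7FE0, 0x0010, b"OW", stored.tobytes()),
    ])
    Path(path).write_bytes(b"\x00" * 128 + b"DICM" + meta + body)
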