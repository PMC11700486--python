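"""Minimal C3D reader/writer (Intel floating-point variant).

C3D is the binary interchange standard of motion-capture labs: a 512-byte
header block, a parameter section (grouped key/value records) and a frame
data section.  This implementation covers what the gait pipeline needs:

* 3D point trajectories (float storage; integer storage with a positive
  POINT:SCALE is also read), with unit conversion to millimetres from the
  POINT:UNITS parameter;
* an optional rotation section carrying per-frame 4x4 segment pose
  matrices (ROTATION group: USED, LABELS, DATA_START), as emitted by
  markerless pose-estimation pipelines; poses are stored as 16 float32
  values per segment per frame, row-major, translations in mm.

Files written here round-trip bit-exactly through :func:`load_c3d` (point
coordinates at float32 precision).  Frame counts are limited to what the
16-bit header fields can hold, which is ample for single walking trials.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from ..datasets import TrialRecording
from ..errors import FormatError

__all__ = ["load_c3d", "write_c3d"]

_PROC_INTEL = 84
_BLOCK = 512


# ---------------------------------------------------------------------------
# reading


def _read_params(buf: bytes, start: int) -> dict[tuple[str, str], object]:
    """Parse the parameter section into {(GROUP, PARAM): value}."""
    if len(buf) < start + 4:
        raise FormatError("parameter section truncated")
    proc = buf[start + 3]
    if proc != _PROC_INTEL:
        raise FormatError(f"unsupported processor type {proc} (only Intel/84)")
    groups: dict[int, str] = {}
    raw_params: list[tuple[int, str, object]] = []
    pos = start + 4
    while pos + 2 <= len(buf):
        nlen = struct.unpack_from("b", buf, pos)[0]
        gid = struct.unpack_from("b", buf, pos + 1)[0]
        if nlen == 0 or gid == 0:
            break
        name = buf[pos + 2 : pos + 2 + abs(nlen)].decode("ascii", "replace").upper()
        offset_pos = pos + 2 + abs(nlen)
        offset = struct.unpack_from("<h", buf, offset_pos)[0]
        if gid < 0:
            groups[-gid] = name
        else:
            p = offset_pos + 2
            dtype = struct.unpack_from("b", buf, p)[0]
            ndims = buf[p + 1]
            dims = list(buf[p + 2 : p + 2 + ndims])
            dstart = p + 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            size = {-1: 1, 1: 1, 2: 2, 4: 4}.get(dtype)
            if size is None:
                raise FormatError(f"unknown parameter type {dtype} for {name}")
            rawdata = buf[dstart : dstart + count * size]
            if dtype == -1:
                if len(dims) >= 2:
                    width = dims[0]
                    n = count // width if width else 0
                    value = [
                        rawdata[i * width : (i + 1) * width].decode("ascii", "replace").strip()
                        for i in range(n)
                    ]
                else:
                    value = rawdata.decode("ascii", "replace").strip()
            elif dtype == 1:
                value = np.frombuffer(rawdata, dtype=np.int8).tolist()
            elif dtype == 2:
                value = np.frombuffer(rawdata, dtype="<i2").tolist()
            else:
                value = np.frombuffer(rawdata, dtype="<f4").tolist()
            if isinstance(value, list) and len(value) == 1 and dtype != -1:
                value = value[0]
            raw_params.append((gid, name, value))
        if offset <= 0:
            break
        pos = offset_pos + offset
    params: dict[tuple[str, str], object] = {}
    for gid, name, value in raw_params:
        params[(groups.get(gid, f"G{gid}"), name)] = value
    return params


def load_c3d(
    path: str | Path,
    required_labels: tuple[str, ...] = (),
    label_map: dict[str, str] | None = None,
) -> TrialRecording:
    """Read points (and pose matrices, when present) from a C3D file.

    Point coordinates are converted to millimetres whatever the stored
    units.  ``required_labels`` asserts that certain point labels exist
    (the error lists the labels that are available); ``label_map`` renames
    labels on the way in, accommodating vendor-specific naming.
    """
    path = Path(path)
    buf = path.read_bytes()
    if len(buf) < _BLOCK:
        raise FormatError(f"{path.name}: shorter than one 512-byte block")
    if buf[1] != 0x50:
        raise FormatError(
            f"{path.name}: corrupt header: byte at offset 1 is {buf[1]:#x}, expected 0x50"
        )
    param_block = buf[0]
    npoints = struct.unpack_from("<H", buf, 2)[0]
    first_frame = struct.unpack_from("<H", buf, 6)[0]
    last_frame = struct.unpack_from("<H", buf, 8)[0]
    hdr_scale = struct.unpack_from("<f", buf, 12)[0]
    data_block = struct.unpack_from("<H", buf, 16)[0]
    frame_rate = struct.unpack_from("<f", buf, 20)[0]
    n_frames = last_frame - first_frame + 1

    params = _read_params(buf, (param_block - 1) * _BLOCK)

    npoints = int(params.get(("POINT", "USED"), npoints))
    scale = float(params.get(("POINT", "SCALE"), hdr_scale))
    frame_rate = float(params.get(("POINT", "RATE"), frame_rate))
    data_block = int(params.get(("POINT", "DATA_START"), data_block))
    units = params.get(("POINT", "UNITS"), "mm")
    if isinstance(units, list):
        units = units[0] if units else "mm"
    units = str(units).lower()
    unit_scale = {"m": 1000.0, "cm": 10.0, "mm": 1.0}.get(units, 1.0)
    labels = params.get(("POINT", "LABELS"), [])
    if isinstance(labels, str):
        labels = [labels]
    labels = list(labels)[:npoints]
    while len(labels) < npoints:
        labels.append(f"point{len(labels) + 1}")
    if label_map:
        labels = [label_map.get(lbl, lbl) for lbl in labels]
    missing = [lbl for lbl in required_labels if lbl not in labels]
    if missing:
        raise FormatError(
            f"{path.name}: missing required labels {missing}; available: {labels}"
        )

    points: dict[str, np.ndarray] = {}
    if npoints:
        offset = (data_block - 1) * _BLOCK
        if scale < 0:
            frame_words = npoints * 4
            raw = np.frombuffer(
                buf, dtype="<f4", count=n_frames * frame_words, offset=offset
            ).reshape(n_frames, npoints, 4)
            xyz = raw[:, :, :3].astype(float)
        else:
            raw = np.frombuffer(
                buf, dtype="<i2", count=n_frames * npoints * 4, offset=offset
            ).reshape(n_frames, npoints, 4)
            xyz = raw[:, :, :3].astype(float) * scale
        xyz = xyz * unit_scale
        for i, lbl in enumerate(labels):
            points[lbl] = xyz[:, i, :]

    poses: dict[str, np.ndarray] = {}
    n_rot = int(params.get(("ROTATION", "USED"), 0))
    if n_rot:
        rot_labels = params.get(("ROTATION", "LABELS"), [])
        if isinstance(rot_labels, str):
            rot_labels = [rot_labels]
        rot_block = int(params[("ROTATION", "DATA_START")])
        raw = np.frombuffer(
            buf, dtype="<f4", count=n_frames * n_rot * 16,
            offset=(rot_block - 1) * _BLOCK,
        ).reshape(n_frames, n_rot, 4, 4)
        for i in range(n_rot):
            name = rot_labels[i] if i < len(rot_labels) else f"segment{i + 1}"
            poses[name] = raw[:, i].astype(float)

    return TrialRecording(
        frame_rate=frame_rate,
        points=points,
        poses=poses,
        meta={"first_frame": first_frame, "source": str(path)},
    )


# ---------------------------------------------------------------------------
# writing


class _ParamWriter:
    def __init__(self) -> None:
        self.chunks: list[bytes] = []

    def group(self, gid: int, name: str) -> None:
        nm = name.encode("ascii")
        self.chunks.append(
            struct.pack("bb", len(nm), -gid) + nm + struct.pack("<h", 3) + b"\x00"
        )

    def param(self, gid: int, name: str, dtype: int, dims: list[int], data: bytes) -> None:
        nm = name.encode("ascii")
        body = struct.pack("b", dtype) + bytes([len(dims)]) + bytes(dims) + data + b"\x00"
        self.chunks.append(
            struct.pack("bb", len(nm), gid)
            + nm
            + struct.pack("<h", 2 + len(body))
            + body
        )

    def int16(self, gid: int, name: str, value: int) -> None:
        self.param(gid, name, 2, [], struct.pack("<h", int(value)))

    def float32(self, gid: int, name: str, value: float) -> None:
        self.param(gid, name, 4, [], struct.pack("<f", float(value)))

    def chars(self, gid: int, name: str, values: list[str]) -> None:
        width = max((len(v) for v in values), default=1) or 1
        data = b"".join(v.ljust(width).encode("ascii") for v in values)
        self.param(gid, name, -1, [width, len(values)], data)

    def render(self) -> bytes:
        body = b"".join(self.chunks) + struct.pack("bb", 0, 0)
        n_blocks = -(-(4 + len(body)) // _BLOCK)
        out = bytes([0x01, 0x50, n_blocks, _PROC_INTEL]) + body
        return out.ljust(n_blocks * _BLOCK, b"\x00")


def write_c3d(trial: TrialRecording, path: str | Path, units: str = "mm") -> Path:
    """Write a recording's points (and poses) as a C3D file.

    ``units`` controls the stored POINT:UNITS tag; coordinates are divided
    accordingly on the way out so that a reader converting back to mm
    recovers the original values.
    """
    path = Path(path)
    labels = sorted(trial.points)
    n = trial.n_frames
    if n > 65535:
        raise FormatError("C3D writer limited to 65535 frames")
    npoints = len(labels)
    unit_scale = {"m": 1000.0, "cm": 10.0, "mm": 1.0}.get(units)
    if unit_scale is None:
        raise FormatError(f"unsupported units {units!r}")

    pw = _ParamWriter()
    pw.group(1, "POINT")
    pw.int16(1, "USED", npoints)
    pw.int16(1, "FRAMES", min(n, 32767))
    pw.float32(1, "SCALE", -1.0)
    pw.float32(1, "RATE", trial.frame_rate)
    pw.chars(1, "UNITS", [units])
    if labels:
        pw.chars(1, "LABELS", labels)

    seg_labels = sorted(trial.poses)
    if seg_labels:
        pw.group(2, "ROTATION")
        pw.int16(2, "USED", len(seg_labels))
        pw.int16(2, "RATIO", 1)
        pw.chars(2, "LABELS", seg_labels)

    # reserve space: data-start placeholders need the rendered size, so
    # render once with dummy values, then patch and re-render
    point_words = n * npoints * 4
    pw.int16(1, "DATA_START", 0)
    if seg_labels:
        pw.int16(2, "DATA_START", 0)
    param_bytes = pw.render()
    n_param_blocks = len(param_bytes) // _BLOCK
    point_start = 2 + n_param_blocks
    rot_start = point_start + (-(-point_words * 4 // _BLOCK) if npoints else 0)

    pw = _ParamWriter()
    pw.group(1, "POINT")
    pw.int16(1, "USED", npoints)
    pw.int16(1, "FRAMES", min(n, 32767))
    pw.float32(1, "SCALE", -1.0)
    pw.float32(1, "RATE", trial.frame_rate)
    pw.chars(1, "UNITS", [units])
    if labels:
        pw.chars(1, "LABELS", labels)
    pw.int16(1, "DATA_START", point_start)
    if seg_labels:
        pw.group(2, "ROTATION")
        pw.int16(2, "USED", len(seg_labels))
        pw.int16(2, "RATIO", 1)
        pw.chars(2, "LABELS", seg_labels)
        pw.int16(2, "DATA_START", rot_start)
    param_bytes = pw.render()
    if len(param_bytes) // _BLOCK != n_param_blocks:
        raise FormatError("internal error: parameter section size changed")

    header = bytearray(_BLOCK)
    header[0] = 2  # parameter section starts at block 2
    header[1] = 0x50
    struct.pack_into("<H", header, 2, npoints)
    struct.pack_into("<H", header, 4, 0)
    struct.pack_into("<H", header, 6, 1)
    struct.pack_into("<H", header, 8, n)
    struct.pack_into("<f", header, 12, -1.0)
    struct.pack_into("<H", header, 16, point_start)
    struct.pack_into("<f", header, 20, float(trial.frame_rate))

    chunks = [bytes(header), param_bytes]
    if npoints:
        frame_data = np.zeros((n, npoints, 4), dtype="<f4")
        for i, lbl in enumerate(labels):
            frame_data[:, i, :3] = trial.points[lbl] / unit_scale
        raw = frame_data.tobytes()
        chunks.append(raw.ljust(-(-len(raw) // _BLOCK) * _BLOCK, b"\x00"))
    if seg_labels:
        rot = np.stack([trial.poses[s] for s in seg_labels], axis=1).astype("<f4")
        raw = rot.tobytes()
        chunks.append(raw.ljust(-(-len(raw) // _BLOCK) * _BLOCK, b"\x00"))
    path.write_bytes(b"".join(chunks))
    return path
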