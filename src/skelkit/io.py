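"""Readers and writers for skeleton sequences, point clouds and angle series.

Formats:

* Skeleton CSV — columns ``frame,timestamp,joint_id,joint_name,x,y,z``
  (header required, UTF-8), one row per joint per frame.
* Skeleton JSON — array of frame objects
  ``{"frame": i, "timestamp": t, "joints": {name: [x, y, z]}}``.
* Point clouds — standard PLY with x,y,z vertex properties, ASCII or
  binary little-endian.  Written in double precision so coordinates
  round-trip exactly; ``plyfile``-style float32 clouds read fine.
* Angle CSV — columns ``frame,timestamp,angle_name,value_deg,defined``.

Missing joints are stored as the tracker's ``(0,0,0)`` sentinel in both
skeleton formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import PointCloudSegment, SkeletonFrame, SkeletonSequence
from .topology import DEFAULT_TOPOLOGY, N_JOINTS, SkeletonTopology


class ParseError(ValueError):
    """Malformed record in a skeleton or point-cloud file."""


class SchemaError(ValueError):
    """A record refers to an unknown joint or misses required fields."""


# ---------------------------------------------------------------------------
# skeleton sequences


def _frame_from_joint_map(frame_idx, timestamp, joints, topology, where):
    positions = np.full((N_JOINTS, 3), np.nan)
    for name, xyz in joints.items():
        if name not in topology.joint_names:
            raise SchemaError(f"{where}: unknown joint name {name!r}")
        if len(xyz) != 3:
            raise ParseError(f"{where}: joint {name!r} needs 3 coordinates")
        positions[topology.joint_id(name)] = xyz
    if np.isnan(positions).any():
        absent = [topology.name(j) for j in range(N_JOINTS)
                  if np.isnan(positions[j]).any()]
        raise SchemaError(f"{where}: frame {frame_idx} misses joints {absent}")
    return SkeletonFrame(int(frame_idx), float(timestamp), positions)


def load_sequence(path, format: str | None = None,
                  topology: SkeletonTopology = DEFAULT_TOPOLOGY,
                  frame_rate: float = 30.0) -> SkeletonSequence:
    """Load a skeleton sequence from CSV or JSON.

    ``format`` defaults to the file suffix.  Records with exact (0,0,0)
    coordinates enter the frame's missing set.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _load_csv(path, topology, frame_rate)
    if fmt == "json":
        return _load_json(path, topology, frame_rate)
    raise ValueError(f"unsupported skeleton format {fmt!r}")


def _load_csv(path, topology, frame_rate):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: {exc}") from exc
    required = {"frame", "timestamp", "joint_id", "joint_name", "x", "y", "z"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    for col in ("x", "y", "z", "timestamp"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ParseError(f"{path}: non-numeric {col!r} at data row {bad}")
    frames = []
    for frame_idx, group in df.groupby("frame", sort=True):
        joints = {}
        for row in group.itertuples(index=True):
            name = row.joint_name
            if name not in topology.joint_names:
                raise SchemaError(f"{path}: row {row.Index}: unknown joint {name!r}")
            if int(row.joint_id) != topology.joint_id(name):
                raise SchemaError(
                    f"{path}: row {row.Index}: joint_id {row.joint_id} does not "
                    f"match name {name!r}")
            joints[name] = (row.x, row.y, row.z)
        frames.append(_frame_from_joint_map(
            frame_idx, group["timestamp"].iloc[0], joints, topology, str(path)))
    return SkeletonSequence(frames, frame_rate=frame_rate)


def _load_json(path, topology, frame_rate):
    try:
        records = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(records, list):
        raise ParseError(f"{path}: top level must be an array of frames")
    frames = []
    for i, rec in enumerate(records):
        try:
            frames.append(_frame_from_joint_map(
                rec["frame"], rec["timestamp"], rec["joints"], topology,
                f"{path}[{i}]"))
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: frame record {i} malformed: {exc}") from exc
    return SkeletonSequence(frames, frame_rate=frame_rate)


def save_sequence(sequence: SkeletonSequence, path, format: str | None = None,
                  topology: SkeletonTopology = DEFAULT_TOPOLOGY) -> None:
    """Write a sequence as CSV or JSON; missing joints become (0,0,0)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        rows = []
        for f in sequence:
            for j in range(N_JOINTS):
                x, y, z = f.positions[j]
                rows.append((f.frame_index, repr(float(f.timestamp)), j,
                             topology.name(j), repr(float(x)), repr(float(y)),
                             repr(float(z))))
        df = pd.DataFrame(rows, columns=["frame", "timestamp", "joint_id",
                                         "joint_name", "x", "y", "z"])
        df.to_csv(path, index=False)
    elif fmt == "json":
        records = [
            {"frame": f.frame_index, "timestamp": f.timestamp,
             "joints": {topology.name(j): [float(c) for c in f.positions[j]]
                        for j in range(N_JOINTS)}}
            for f in sequence
        ]
        Path(path).write_text(json.dumps(records))
    else:
        raise ValueError(f"unsupported skeleton format {fmt!r}")


# ---------------------------------------------------------------------------
# PLY point clouds

_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4",
    "double": "<f8", "float64": "<f8",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
    "short": "<i2", "ushort": "<u2", "char": "<i1", "uchar": "<u1",
    "int8": "<i1", "uint8": "<u1", "int16": "<i2", "uint16": "<u2",
}


def load_point_cloud(path, label: str | None = None,
                     allow_empty: bool = False) -> PointCloudSegment:
    """Read x,y,z vertices from an ASCII or binary little-endian PLY file.

    ``label`` defaults to the file stem.  An empty vertex element raises
    unless ``allow_empty`` is set (the estimation search assumes a
    non-empty cloud).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    elements[-1][2].append((tokens[-1], "list"))
                else:
                    elements[-1][2].append((tokens[-1], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise ParseError(f"{path}: no vertex element")
        _, count, props = vertex
        names = [n for n, _ in props]
        if not {"x", "y", "z"} <= set(names):
            raise ParseError(f"{path}: vertex element lacks x/y/z properties")
        if any(t == "list" for _, t in props):
            raise ParseError(f"{path}: list properties on vertices unsupported")
        if fmt == "ascii":
            rows = []
            for i in range(count):
                parts = fh.readline().split()
                if len(parts) < len(props):
                    raise ParseError(f"{path}: vertex row {i} truncated")
                rows.append([float(v) for v in parts[: len(props)]])
            data = np.asarray(rows, dtype=float).reshape(count, len(props))
        else:
            dtype = np.dtype([(n, _PLY_DTYPES[t]) for n, t in props])
            raw = fh.read(dtype.itemsize * count)
            if len(raw) < dtype.itemsize * count:
                raise ParseError(f"{path}: binary vertex data truncated")
            rec = np.frombuffer(raw, dtype=dtype, count=count)
            data = np.column_stack([rec[n].astype(float) for n in names])
    cols = [names.index(c) for c in ("x", "y", "z")]
    pts = data[:, cols] if count else np.empty((0, 3))
    if count == 0 and not allow_empty:
        raise ParseError(f"{path}: PLY has no vertices")
    return PointCloudSegment(label or path.stem, pts)


def save_point_cloud(segment: PointCloudSegment, path,
                     binary: bool = False) -> None:
    """Write a point cloud as PLY with double-precision x,y,z."""
    path = Path(path)
    n = len(segment.points)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        f"ply\nformat {fmt} 1.0\n"
        f"element vertex {n}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(segment.points, dtype="<f8").tobytes())
        else:
            for x, y, z in segment.points:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n"
                         .encode("ascii"))


def cloud_filename(frame_index: int, label: str) -> str:
    """Canonical per-(frame, segment) PLY filename."""
    return f"frame{frame_index}_{label}.ply"


def load_frame_clouds(directory, frame_index: int) -> dict[str, PointCloudSegment]:
    """Load all ``frame{N}_{label}.ply`` segments for one frame."""
    directory = Path(directory)
    prefix = f"frame{frame_index}_"
    out = {}
    for p in sorted(directory.glob(f"{prefix}*.ply")):
        label = p.stem[len(prefix):]
        out[label] = load_point_cloud(p, label=label)
    return out


# ---------------------------------------------------------------------------
# angle series


def save_angles(angles, path) -> None:
    """Write an :class:`~skelkit.angles.AngleSeries` as long-form CSV."""
    rows = []
    for i, t in enumerate(angles.timestamps):
        for name in angles.names:
            v = angles.values[i, angles.names.index(name)]
            defined = bool(np.isfinite(v))
            rows.append((angles.frame_indices[i], repr(float(t)), name,
                         repr(float(v)) if defined else "", defined))
    pd.DataFrame(rows, columns=["frame", "timestamp", "angle_name",
                                "value_deg", "defined"]).to_csv(path, index=False)


def load_angles(path):
    from .angles import AngleSeries

    df = pd.read_csv(path)
    frames = sorted(df["frame"].unique())
    names = list(dict.fromkeys(df["angle_name"]))
    values = np.full((len(frames), len(names)), np.nan)
    ts = np.zeros(len(frames))
    fpos = {f: i for i, f in enumerate(frames)}
    npos = {n: i for i, n in enumerate(names)}
    for row in df.itertuples():
        i = fpos[row.frame]
        ts[i] = row.timestamp
        if row.defined:
            values[i, npos[row.angle_name]] = row.value_deg
    return AngleSeries(np.asarray(frames, dtype=int), ts, names, values)
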