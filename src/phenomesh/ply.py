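"""PLY reading and writing for point clouds and triangle meshes.

Supported dialect: ``ascii`` and ``binary_little_endian`` PLY with a vertex
element carrying x/y/z (float or double) and optional uchar red/green/blue
(the aliases r/g/b are accepted; alpha is ignored), plus an optional face
element of vertex-index triples. ``binary_big_endian`` files are rejected —
they do not occur in the Meshlab/CloudCompare toolchain this package
interoperates with.

Parsing is delegated to :mod:`trimesh`; writing uses an in-package
serializer so that coordinates survive a round trip bit-exactly (binary,
double precision) or to at least 9 significant digits (ascii).
"""

from __future__ import annotations

import io
import logging
import struct
from pathlib import Path

import numpy as np
import trimesh

from .geometry import ColoredPointCloud, TriangleMesh

__all__ = ["read_ply", "write_ply", "PlyFormatError", "PlyKindError"]

log = logging.getLogger(__name__)


class PlyFormatError(ValueError):
    """Malformed or unsupported PLY content."""


class PlyKindError(ValueError):
    """File content does not match the requested kind (cloud vs. mesh)."""


_COLOR_ALIASES = {"r": "red", "g": "green", "b": "blue"}


def _scan_header(raw: bytes, path: str) -> tuple[bytes, bool, int]:
    """Validate the header, normalise r/g/b aliases, report face presence.

    Returns the (possibly rewritten) file bytes, whether a face element
    with nonzero count is declared, and the declared vertex count.
    """
    n_vertices = -1
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise PlyFormatError(f"{path}: not a PLY file (missing ply/end_header)")
    header = raw[: raw.index(b"\n", end) + 1]
    lines = header.decode("ascii", errors="replace").splitlines()

    has_faces = False
    fmt_seen = False
    current_element = None
    out_lines: list[str] = []
    for line in lines:
        tok = line.split()
        if not tok:
            out_lines.append(line)
            continue
        if tok[0] == "format":
            fmt_seen = True
            if len(tok) < 3:
                raise PlyFormatError(f"{path}: malformed header line: {line!r}")
            if tok[1] == "binary_big_endian":
                raise PlyFormatError(
                    f"{path}: binary_big_endian PLY is not supported "
                    "(use ascii or binary_little_endian)"
                )
            if tok[1] not in ("ascii", "binary_little_endian"):
                raise PlyFormatError(f"{path}: unknown PLY format in line: {line!r}")
        elif tok[0] == "element":
            if len(tok) != 3:
                raise PlyFormatError(f"{path}: malformed header line: {line!r}")
            current_element = tok[1]
            try:
                count = int(tok[2])
            except ValueError as exc:
                raise PlyFormatError(
                    f"{path}: malformed header line: {line!r}"
                ) from exc
            if tok[1] == "face" and count > 0:
                has_faces = True
            if tok[1] == "vertex":
                n_vertices = count
        elif tok[0] == "property":
            if len(tok) < 3:
                raise PlyFormatError(f"{path}: malformed header line: {line!r}")
            # normalise single-letter color names so the parser sees red/green/blue
            if current_element == "vertex" and tok[-1] in _COLOR_ALIASES:
                line = " ".join(tok[:-1] + [_COLOR_ALIASES[tok[-1]]])
        elif tok[0] not in ("ply", "comment", "obj_info", "end_header"):
            raise PlyFormatError(f"{path}: malformed header line: {line!r}")
        out_lines.append(line)
    if not fmt_seen:
        raise PlyFormatError(f"{path}: header has no format line")

    new_header = ("\n".join(out_lines) + "\n").encode("ascii")
    return new_header + raw[len(header):], has_faces, n_vertices


def read_ply(path: str | Path, kind: str = "cloud") -> ColoredPointCloud | TriangleMesh:
    """Read a PLY file as a point cloud or a triangle mesh.

    Parameters
    ----------
    path : path
        PLY file, ascii or binary-little-endian.
    kind : {"cloud", "mesh"}
        What to return. ``mesh`` requires the file to declare faces.

    Notes
    -----
    Faces repeating a vertex index (degenerate, common in raw SfM meshes)
    are dropped with a logged count rather than raised.
    """
    if kind not in ("cloud", "mesh"):
        raise ValueError(f"kind must be 'cloud' or 'mesh', got {kind!r}")
    path = Path(path)
    raw = path.read_bytes()
    data, has_faces, n_vertices = _scan_header(raw, str(path))
    if kind == "mesh" and not has_faces:
        raise PlyKindError(f"{path}: mesh requested but the file declares no faces")
    if n_vertices == 0:
        return ColoredPointCloud(points=np.zeros((0, 3)))

    loaded = trimesh.load(io.BytesIO(data), file_type="ply", process=False)

    if kind == "cloud":
        if isinstance(loaded, trimesh.Trimesh):
            verts = np.asarray(loaded.vertices, dtype=np.float64)
            colors = _vertex_colors(loaded)
        else:
            verts = np.asarray(loaded.vertices, dtype=np.float64)
            colors = None
            if getattr(loaded, "colors", None) is not None and len(loaded.colors):
                colors = np.asarray(loaded.colors)[:, :3].astype(np.uint8)
        return ColoredPointCloud(points=verts, colors=colors)

    faces = np.asarray(loaded.faces, dtype=np.int64)
    mesh = TriangleMesh(
        vertices=np.asarray(loaded.vertices, dtype=np.float64),
        faces=faces,
        colors=_vertex_colors(loaded),
    )
    bad = mesh.degenerate_faces()
    if bad.any():
        log.warning("%s: dropped %d faces with repeated vertex indices", path, bad.sum())
        mesh = TriangleMesh(mesh.vertices, mesh.faces[~bad], colors=mesh.colors)
    return mesh


def _vertex_colors(m: trimesh.Trimesh) -> np.ndarray | None:
    try:
        vc = m.visual.vertex_colors
    except Exception:
        return None
    if vc is None or len(vc) != len(m.vertices):
        return None
    vc = np.asarray(vc)
    # trimesh synthesises a uniform default when the file had no colors
    if getattr(m.visual, "kind", None) != "vertex":
        return None
    return vc[:, :3].astype(np.uint8)


def write_ply(
    obj: ColoredPointCloud | TriangleMesh,
    path: str | Path,
    encoding: str = "binary",
) -> None:
    """Write a cloud or mesh as PLY (``ascii`` or ``binary`` little-endian).

    Coordinates are stored as doubles: binary round trips are bit-exact and
    ascii output carries 17 significant digits.
    """
    if encoding not in ("ascii", "binary"):
        raise ValueError(f"encoding must be 'ascii' or 'binary', got {encoding!r}")
    path = Path(path)

    if isinstance(obj, ColoredPointCloud):
        verts, colors, faces = obj.points, obj.colors, None
    elif isinstance(obj, TriangleMesh):
        verts, colors, faces = obj.vertices, obj.colors, obj.faces
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")

    fmt = "ascii" if encoding == "ascii" else "binary_little_endian"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {len(verts)}"]
    header += [f"property double {ax}" for ax in "xyz"]
    if colors is not None:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    if faces is not None:
        header += [
            f"element face {len(faces)}",
            "property list uchar int vertex_indices",
        ]
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if encoding == "ascii":
            for i in range(len(verts)):
                row = " ".join(f"{v:.17g}" for v in verts[i])
                if colors is not None:
                    row += " " + " ".join(str(int(c)) for c in colors[i])
                fh.write((row + "\n").encode("ascii"))
            if faces is not None:
                for f in faces:
                    fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))
        else:
            if colors is not None:
                dt = np.dtype(
                    [("xyz", "<f8", 3), ("rgb", "u1", 3)]
                )
                rec = np.empty(len(verts), dtype=dt)
                rec["xyz"] = verts
                rec["rgb"] = colors
                fh.write(rec.tobytes())
            else:
                fh.write(np.ascontiguousarray(verts, dtype="<f8").tobytes())
            if faces is not None:
                for f in faces:
                    fh.write(struct.pack("<Biii", 3, int(f[0]), int(f[1]), int(f[2])))
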