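"""Readers and writers: correspondence JSON/CSV, point CSV, OBJ/PLY polylines.

JSON files carry a ``format_version`` field; CSV uses comma separation,
dot decimals and a header row.  Coordinates are written with 17
significant digits so a write/read round trip is bit-exact for float64.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .geometry import Camera
from .recovery import ImageCorrespondenceSet, RecoveredShape

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1


def read_correspondences(path) -> ImageCorrespondenceSet:
    """Load paired image points from JSON
    ``{"format_version": 1, "camera": {"z_F": ...}, "pairs": [{"p": [x, y], "q": [x, y]}, ...]}``
    or CSV with header ``px,py,qx,qy``.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        data = np.genfromtxt(path, delimiter=",", names=True)
        for col in ("px", "py", "qx", "qy"):
            if col not in (data.dtype.names or ()):
                raise ValueError(f"correspondence CSV missing column {col!r}")
        p = np.column_stack([data["px"], data["py"]])
        q = np.column_stack([data["qx"], data["qy"]])
        return _validated(p, q, Camera(), path)

    with open(path) as fh:
        doc = json.load(fh)
    for key in ("camera", "pairs"):
        if key not in doc:
            raise ValueError(f"correspondence file {path} missing field {key!r}")
    if "z_F" not in doc["camera"]:
        raise ValueError(f"correspondence file {path}: camera block missing 'z_F'")
    zf = doc["camera"]["z_F"]
    camera = Camera(float("inf") if zf in ("inf", None) else float(zf))
    p, q = [], []
    for i, pair in enumerate(doc["pairs"]):
        if "p" not in pair or "q" not in pair or len(pair["p"]) != 2 or len(pair["q"]) != 2:
            raise ValueError(f"correspondence file {path}: malformed pair at index {i}")
        p.append(pair["p"])
        q.append(pair["q"])
    return _validated(np.asarray(p, dtype=float), np.asarray(q, dtype=float), camera, path)


def _validated(p, q, camera, path) -> ImageCorrespondenceSet:
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError(f"correspondence file {path} contains NaN/inf coordinates")
    return ImageCorrespondenceSet(p, q, camera)


def write_correspondences(corr: ImageCorrespondenceSet, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "camera": {"z_F": "inf" if corr.camera.orthographic else corr.camera.z_F},
        "pairs": [{"p": [float(a), float(b)], "q": [float(c), float(d)]}
                  for (a, b), (c, d) in zip(corr.p, corr.q)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_points_csv(path, dim: int = 3) -> np.ndarray:
    """Point list from CSV with header x,y[,z]."""
    names = ("x", "y", "z")[:dim]
    data = np.genfromtxt(path, delimiter=",", names=True)
    for col in names:
        if col not in (data.dtype.names or ()):
            raise ValueError(f"point CSV missing column {col!r}")
    return np.column_stack([data[c] for c in names])


def write_points_csv(points, path) -> None:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    header = ",".join(("x", "y", "z")[: pts.shape[1]])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in pts:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def write_shape(shape: RecoveredShape, path, fmt: str | None = None) -> None:
    """Write a recovered shape's two half-polylines and midpoint path.

    Formats: OBJ (vertices + ``l`` polyline records), PLY (ascii vertices +
    edges), CSV (curve label + coordinates).  Vertex order is Φ points,
    then Ψ points, then midpoints.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "obj"
    fmt = fmt.lower()
    n = shape.P.shape[0]
    if n == 0:
        logger.warning("writing empty shape to %s", path)
    verts = np.vstack([shape.P, shape.Q, shape.midpoints])

    if fmt == "obj":
        with open(path, "w") as fh:
            fh.write("# mirrorshape recovered 3D curves: phi, psi, midpoint path\n")
            for v in verts:
                fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for block in range(3):
                if n >= 2:
                    idx = " ".join(str(block * n + i + 1) for i in range(n))
                    fh.write(f"l {idx}\n")
    elif fmt == "ply":
        edges = []
        for block in range(3):
            edges.extend((block * n + i, block * n + i + 1) for i in range(n - 1))
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(verts)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element edge {len(edges)}\n")
            fh.write("property int vertex1\nproperty int vertex2\nend_header\n")
            for v in verts:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for a, b in edges:
                fh.write(f"{a} {b}\n")
    elif fmt == "csv":
        labels = ["phi"] * n + ["psi"] * n + ["midpoint"] * n
        with open(path, "w") as fh:
            fh.write("curve,x,y,z\n")
            for lab, v in zip(labels, verts):
                fh.write(f"{lab},{v[0]:.17g},{v[1]:.17g},{v[2]:.17g}\n")
    else:
        raise ValueError(f"unknown shape format {fmt!r} (expected obj, ply or csv)")


def read_obj_vertices(path) -> np.ndarray:
    """Vertex records of an OBJ file, in file order."""
    verts = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("v "):
                verts.append([float(tok) for tok in line.split()[1:4]])
    return np.asarray(verts, dtype=float)


def shape_report(shape: RecoveredShape) -> dict:
    """JSON-serializable diagnostic summary of a recovery."""
    return {
        "format_version": FORMAT_VERSION,
        "n_pairs": int(shape.P.shape[0]),
        "x_v": shape.x_v,
        "x_h": shape.x_h,
        "d_c": shape.d_c,
        "frame_rotation_rad": shape.frame_rotation,
        "vanishing_point_residual": shape.residual,
        "camera_z_F": "inf" if shape.camera.orthographic else shape.camera.z_F,
        "symmetry_plane": [shape.plane.a, shape.plane.b, shape.plane.c, shape.plane.d],
    }
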