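"""Surface-mesh data model, I/O and ring-based vessel measurements.

The vessel wall is represented as an open triangulated tube with two
boundary loops (inlet and outlet).  All geometric quantities are in
millimetres.  Measurements follow the ring convention used for murine
aortic imaging: a set of equally spaced rings along the axial coordinate,
each summarised by its mean radius about the ring centroid, with axial
lengthening taken from distances between consecutive ring centroids.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh


class MeshError(ValueError):
    """Structured error for defective surface meshes."""


@dataclass
class SurfaceMesh:
    """Open triangulated tube wall.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices
    inlet_loop, outlet_loop : ordered boundary vertex index lists
    """

    vertices: np.ndarray
    triangles: np.ndarray
    inlet_loop: list = field(default_factory=list)
    outlet_loop: list = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @classmethod
    def from_arrays(cls, vertices, triangles, axis: int = 2) -> "SurfaceMesh":
        """Build a mesh, auto-detecting the two boundary loops.

        The loop with the smaller mean coordinate along ``axis`` is
        labelled the inlet.
        """
        vertices = np.asarray(vertices, dtype=float)
        triangles = np.asarray(triangles, dtype=np.int64)
        if triangles.size and triangles.max() >= len(vertices):
            raise MeshError("triangle index out of range")
        loops = boundary_loops(triangles)
        if len(loops) != 2:
            raise MeshError(
                f"expected 2 boundary loops, found {len(loops)}"
            )
        a, b = loops
        za = vertices[a, axis].mean()
        zb = vertices[b, axis].mean()
        inlet, outlet = (a, b) if za <= zb else (b, a)
        return cls(vertices, triangles, list(inlet), list(outlet))


def boundary_loops(triangles: np.ndarray) -> list:
    """Ordered boundary loops of a triangulation.

    A boundary edge belongs to exactly one triangle; an interior edge to
    exactly two.  Edges on more than two triangles make the surface
    non-manifold and raise :class:`MeshError`.
    """
    triangles = np.asarray(triangles, dtype=np.int64)
    if triangles.size == 0:
        return []
    edges = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    key = np.sort(edges, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    if (counts > 2).any():
        raise MeshError("non-manifold mesh: edge shared by >2 triangles")
    bdry = uniq[counts == 1]
    if len(bdry) == 0:
        return []
    # walk loops through the boundary-edge adjacency
    nbr: dict = {}
    for u, v in bdry:
        nbr.setdefault(int(u), []).append(int(v))
        nbr.setdefault(int(v), []).append(int(u))
    for v, ns in nbr.items():
        if len(ns) != 2:
            raise MeshError("boundary is not a collection of simple loops")
    unvisited = set(nbr)
    loops = []
    while unvisited:
        start = min(unvisited)
        loop = [start]
        unvisited.discard(start)
        prev, cur = None, start
        while True:
            a, b = nbr[cur]
            nxt = b if a == prev else a
            if nxt == start:
                break
            loop.append(nxt)
            unvisited.discard(nxt)
            prev, cur = cur, nxt
        loops.append(loop)
    return loops


# ---------------------------------------------------------------------------
# I/O: STL and OBJ via trimesh, legacy-VTK ASCII polydata in-repo.

def _read_vtk_polydata(path: Path):
    text = Path(path).read_text().split()
    toks = iter(text)
    verts, tris = None, None
    for tok in toks:
        if tok.upper() == "POINTS":
            n = int(next(toks))
            next(toks)  # dtype
            flat = [float(next(toks)) for _ in range(3 * n)]
            verts = np.array(flat).reshape(n, 3)
        elif tok.upper() == "POLYGONS":
            n = int(next(toks))
            size = int(next(toks))
            flat = [int(next(toks)) for _ in range(size)]
            cells, i = [], 0
            for _ in range(n):
                k = flat[i]
                if k != 3:
                    raise MeshError("VTK polydata contains non-triangle cells")
                cells.append(flat[i + 1 : i + 4])
                i += k + 1
            tris = np.array(cells, dtype=np.int64)
    if verts is None or tris is None:
        raise MeshError("not a triangulated VTK polydata file")
    return verts, tris


def _write_vtk_polydata(path: Path, vertices, triangles, point_data=None):
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\nvesselgrow surface\nASCII\n")
    buf.write("DATASET POLYDATA\n")
    buf.write(f"POINTS {len(vertices)} float\n")
    for p in vertices:
        buf.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
    buf.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
    for t in triangles:
        buf.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    if point_data:
        buf.write(f"POINT_DATA {len(vertices)}\n")
        for name, vals in point_data.items():
            buf.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for v in vals:
                buf.write(f"{v:.9g}\n")
    Path(path).write_text(buf.getvalue())


def read_mesh(path, fmt: str | None = None, axis: int = 2) -> SurfaceMesh:
    """Read an STL, OBJ or legacy-VTK polydata surface into a SurfaceMesh.

    Boundary loops are auto-detected; the lower loop along ``axis`` is the
    inlet.  Raises :class:`MeshError` on closed or non-manifold surfaces.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("stl", "obj"):
        tm = trimesh.load(str(path), file_type=fmt, process=False)
        verts = np.asarray(tm.vertices, dtype=float)
        tris = np.asarray(tm.faces, dtype=np.int64)
        # STL stores triangle soup; merge exactly coincident vertices so
        # boundary detection sees shared edges.
        verts, tris = _merge_duplicate_vertices(verts, tris)
    elif fmt == "vtk":
        verts, tris = _read_vtk_polydata(path)
    else:
        raise MeshError(f"unsupported mesh format: {fmt!r}")
    return SurfaceMesh.from_arrays(verts, tris, axis=axis)


def _merge_duplicate_vertices(verts, tris):
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    return uniq, inverse[tris]


def write_mesh(path, mesh: SurfaceMesh, fmt: str | None = None,
               point_data: dict | None = None) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("stl", "obj"):
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                             process=False)
        tm.export(str(path), file_type=fmt)
    elif fmt == "vtk":
        _write_vtk_polydata(path, mesh.vertices, mesh.triangles, point_data)
    else:
        raise MeshError(f"unsupported mesh format: {fmt!r}")


# ---------------------------------------------------------------------------
# Ring measurements

@dataclass
class RingSet:
    """Ordered rings of surface points along the axial coordinate."""

    rings: list  # list of (k, 3) position arrays, mm
    n_rings: int

    def __post_init__(self):
        for j, r in enumerate(self.rings):
            if len(r) == 0:
                raise MeshError(
                    f"ring {j} is empty: widen the axial band or refine the mesh"
                )


@dataclass
class RingMetrics:
    """Per-ring radii and centroid-chain lengths (mm)."""

    radii: np.ndarray
    centroids: np.ndarray
    segment_lengths: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def n_rings(self) -> int:
        return len(self.radii)

    def observation_vector(self) -> np.ndarray:
        """Radii followed by segment lengths: the 2n-1 fitting observables."""
        return np.concatenate([self.radii, self.segment_lengths])


@dataclass
class WallSpec:
    """Uniform unloaded wall thickness, mm."""

    thickness: float

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("wall thickness must be positive")


def extract_rings(mesh: SurfaceMesh, axial_field: np.ndarray,
                  n_rings: int = 6, band_width: float | None = None) -> RingSet:
    """Collect mesh vertices into equally spaced axial rings.

    Ring ``j`` gathers vertices whose axial coordinate lies in a half-open
    band centred at ``j/(n_rings-1)``; the end bands are closed so the
    inlet (s=0) and outlet (s=1) vertices are kept.  The default band
    width is a fifth of the ring spacing: wide enough to catch a vertex
    row on meshes of ordinary resolution, narrow enough that the axial
    spread of the selected points does not inflate the ring radius (the
    mean point-to-centroid distance picks up any axial scatter).
    """
    s = np.asarray(axial_field, dtype=float)
    if s.min() < -1e-9 or s.max() > 1 + 1e-9:
        raise ValueError("axial field must lie in [0, 1]")
    if n_rings < 2:
        raise ValueError("need at least 2 rings")
    spacing = 1.0 / (n_rings - 1)
    width = band_width if band_width is not None else spacing / 5.0
    rings = []
    for j in range(n_rings):
        c = j * spacing
        lo, hi = c - width / 2, c + width / 2
        if j == n_rings - 1:
            mask = (s >= lo) & (s <= hi + 1e-12)
        else:
            mask = (s >= lo) & (s < hi)
        rings.append(mesh.vertices[mask])
    return RingSet(rings=rings, n_rings=n_rings)


def ring_radius(points: np.ndarray) -> float:
    """Mean distance of ring points to their arithmetic centroid."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise MeshError("ring needs at least 3 points for a radius")
    centroid = points.mean(axis=0)
    return float(np.linalg.norm(points - centroid, axis=1).mean())


def ring_metrics(ring_set: RingSet) -> RingMetrics:
    """Radii, centroids and consecutive-centroid segment lengths."""
    if ring_set.n_rings < 2:
        raise MeshError("need at least 2 rings for segment lengths")
    radii = np.array([ring_radius(r) for r in ring_set.rings])
    centroids = np.array([np.asarray(r).mean(axis=0) for r in ring_set.rings])
    seg = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    return RingMetrics(radii=radii, centroids=centroids, segment_lengths=seg)


# alias matching the measurement vocabulary
segment_lengths = ring_metrics


def metrics_to_csv(metrics: RingMetrics, path) -> None:
    import pandas as pd

    seg = np.concatenate([[np.nan], metrics.segment_lengths])
    pd.DataFrame(
        {
            "ring_index": np.arange(metrics.n_rings),
            "radius_mm": metrics.radii,
            "centroid_x": metrics.centroids[:, 0],
            "centroid_y": metrics.centroids[:, 1],
            "centroid_z": metrics.centroids[:, 2],
            "segment_length_mm": seg,
        }
    ).to_csv(path, index=False)
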