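"""Harmonic (diffusion-based) tube parameterization and cross-time mapping.

The axial coordinate s solves the Laplace equation on the surface with
s=0 on the inlet loop and s=1 on the outlet loop.  The circumferential
coordinate theta solves the same equation after the tube is cut open along
a shortest edge-path from inlet to outlet, with 0 on one bank of the cut
and 1 on the other; theta is periodic (0 identified with 1).  Together
(s, theta) give every wall point a tube coordinate that is comparable
between independently meshed time points, which is what makes longitudinal
ring measurements on re-segmented geometries well defined.

Discretization: cotangent-weight finite elements on the triangulation with
Dirichlet elimination and a sparse direct solve.  The cut is approximated
by the edge-graph shortest path (Dijkstra), which is topologically exact
and metrically within one edge length of the true geodesic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from scipy.sparse.linalg import spsolve

from .mesh_geometry import MeshError, SurfaceMesh


@dataclass
class TubeCoordinates:
    """Per-vertex axial s in [0,1] and circumferential theta in [0,1)."""

    s: np.ndarray
    theta: np.ndarray


def cotangent_laplacian(vertices: np.ndarray, triangles: np.ndarray) -> sp.csr_matrix:
    """Symmetric cotangent-weight Laplacian (positive semi-definite)."""
    v = np.asarray(vertices, dtype=float)
    t = np.asarray(triangles, dtype=np.int64)
    i0, i1, i2 = t[:, 0], t[:, 1], t[:, 2]
    rows, cols, vals = [], [], []
    for a, b, c in ((i0, i1, i2), (i1, i2, i0), (i2, i0, i1)):
        # cotangent at vertex c, weighting edge (a, b)
        u = v[a] - v[c]
        w = v[b] - v[c]
        cross = np.linalg.norm(np.cross(u, w), axis=1)
        cross = np.maximum(cross, 1e-300)
        cot = (u * w).sum(axis=1) / cross
        half = 0.5 * cot
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([-half, -half])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = len(v)
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())
    return L.tocsr()


def solve_laplace(vertices, triangles, dirichlet_idx, dirichlet_vals) -> np.ndarray:
    """Solve the discrete Laplace problem with Dirichlet data eliminated."""
    n = len(vertices)
    L = cotangent_laplacian(vertices, triangles)
    fixed = np.zeros(n, dtype=bool)
    fixed[np.asarray(dirichlet_idx, dtype=int)] = True
    vals = np.zeros(n)
    vals[np.asarray(dirichlet_idx, dtype=int)] = dirichlet_vals
    free = ~fixed
    if not free.any():
        return vals
    A = L[free][:, free]
    b = -L[free][:, fixed] @ vals[fixed]
    try:
        x = spsolve(A.tocsc(), b)
    except Exception as exc:  # pragma: no cover - singular system
        raise MeshError(f"singular Laplace system (disconnected mesh?): {exc}")
    if not np.all(np.isfinite(x)):
        raise MeshError("singular Laplace system (disconnected mesh?)")
    out = vals.copy()
    out[free] = x
    return out


def solve_axial_coordinate(mesh: SurfaceMesh) -> np.ndarray:
    """Harmonic axial coordinate: 0 on the inlet loop, 1 on the outlet loop."""
    idx = np.concatenate([mesh.inlet_loop, mesh.outlet_loop]).astype(int)
    vals = np.concatenate(
        [np.zeros(len(mesh.inlet_loop)), np.ones(len(mesh.outlet_loop))]
    )
    s = solve_laplace(mesh.vertices, mesh.triangles, idx, vals)
    return np.clip(s, 0.0, 1.0)


def _edge_graph(mesh: SurfaceMesh) -> sp.csr_matrix:
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    w = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    n = mesh.n_vertices
    g = sp.coo_matrix(
        (np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]],
                       np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    )
    return g.tocsr()


def geodesic_cut(mesh: SurfaceMesh) -> list:
    """Shortest edge-path from the inlet loop to the outlet loop.

    A virtual source connected at zero cost to every inlet-loop vertex
    yields the globally closest inlet/outlet pair in one Dijkstra run;
    equidistant ties resolve to the lowest outlet index (deterministic).
    """
    g = _edge_graph(mesh)
    n = mesh.n_vertices
    src_row = sp.coo_matrix(
        (np.full(len(mesh.inlet_loop), 1e-12),
         (np.zeros(len(mesh.inlet_loop), dtype=int), mesh.inlet_loop)),
        shape=(1, n),
    )
    aug = sp.bmat([[g, src_row.T], [src_row, None]]).tocsr()
    dist, pred = csgraph.dijkstra(
        aug, indices=[n], return_predecessors=True, directed=False
    )
    dist, pred = dist[0], pred[0]
    outlet = np.asarray(mesh.outlet_loop, dtype=int)
    if not np.isfinite(dist[outlet]).any():
        raise MeshError("no path between inlet and outlet loops")
    d = dist[outlet]
    end = int(outlet[np.lexsort((outlet, d))[0]])
    path = [end]
    cur = end
    while pred[cur] != n and pred[cur] >= 0:
        cur = int(pred[cur])
        path.append(cur)
    path.reverse()
    if path[0] not in set(map(int, mesh.inlet_loop)):
        raise MeshError("cut path failed to reach the inlet loop")
    return path


def _split_seam(mesh: SurfaceMesh, cut: list):
    """Duplicate cut vertices, opening the tube along the seam.

    Triangles incident to the cut are partitioned into the two banks by
    connectivity across non-cut edges; bank-B triangles are re-indexed to
    the duplicated copies.  Returns (vertices, triangles, seam_a, seam_b).
    """
    cut = [int(c) for c in cut]
    cut_set = set(cut)
    cut_edges = {tuple(sorted(e)) for e in zip(cut[:-1], cut[1:])}
    tris = mesh.triangles
    inc = [i for i, t in enumerate(tris) if cut_set & set(map(int, t))]
    if not inc:
        raise MeshError("cut path touches no triangles")
    # adjacency between incident triangles across shared non-cut edges
    edge_owner: dict = {}
    adj: dict = {i: [] for i in inc}
    for i in inc:
        t = tris[i]
        for e in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            key = tuple(sorted(map(int, e)))
            if key in cut_edges:
                continue
            if key in edge_owner:
                j = edge_owner[key]
                adj[i].append(j)
                adj[j].append(i)
            else:
                edge_owner[key] = i
    # connected components
    comp = {}
    for seed in inc:
        if seed in comp:
            continue
        label = len(set(comp.values()))
        stack = [seed]
        comp[seed] = label
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in comp:
                    comp[v] = label
                    stack.append(v)
    labels = sorted(set(comp.values()))
    if len(labels) != 2:
        raise MeshError(
            f"cut does not separate the tube locally "
            f"({len(labels)} banks found, expected 2)"
        )
    side_b = {i for i, l in comp.items() if l == labels[1]}
    verts = np.asarray(mesh.vertices)
    dup_index = {v: len(verts) + k for k, v in enumerate(cut)}
    new_verts = np.vstack([verts, verts[cut]])
    new_tris = tris.copy()
    for i in side_b:
        for slot in range(3):
            v = int(new_tris[i, slot])
            if v in dup_index:
                new_tris[i, slot] = dup_index[v]
    seam_a = np.array(cut, dtype=int)
    seam_b = np.array([dup_index[v] for v in cut], dtype=int)
    return new_verts, new_tris, seam_a, seam_b


def solve_circumferential_coordinate(mesh: SurfaceMesh, cut: list) -> np.ndarray:
    """Harmonic circumferential coordinate, periodic across the cut seam.

    The cut vertices are duplicated; one seam copy is held at 0, the other
    at 1, and theta is reported modulo 1 (seam vertices get theta = 0).
    """
    new_verts, new_tris, seam_a, seam_b = _split_seam(mesh, cut)
    idx = np.concatenate([seam_a, seam_b])
    vals = np.concatenate([np.zeros(len(seam_a)), np.ones(len(seam_b))])
    field = solve_laplace(new_verts, new_tris, idx, vals)
    theta = field[: mesh.n_vertices].copy()
    theta[seam_a] = 0.0
    return np.mod(theta, 1.0)


def parameterize(mesh: SurfaceMesh) -> TubeCoordinates:
    """Full (s, theta) tube parameterization of a two-loop surface."""
    s = solve_axial_coordinate(mesh)
    cut = geodesic_cut(mesh)
    theta = solve_circumferential_coordinate(mesh, cut)
    return TubeCoordinates(s=s, theta=theta)


def periodic_theta_distance(t1, t2) -> np.ndarray:
    d = np.abs(np.asarray(t1) - np.asarray(t2))
    return np.minimum(d, 1.0 - d)


def map_between_geometries(coords_a: TubeCoordinates,
                           coords_b: TubeCoordinates,
                           chunk: int = 512) -> np.ndarray:
    """For each vertex of A, the index of the nearest vertex of B in (s, theta).

    Distance is sqrt(ds^2 + dtheta_periodic^2); evaluated exactly in
    chunks to bound memory.
    """
    sa, ta = coords_a.s, coords_a.theta
    sb, tb = coords_b.s, coords_b.theta
    out = np.empty(len(sa), dtype=np.int64)
    for lo in range(0, len(sa), chunk):
        hi = min(lo + chunk, len(sa))
        ds = sa[lo:hi, None] - sb[None, :]
        dt = np.abs(ta[lo:hi, None] - tb[None, :])
        dt = np.minimum(dt, 1.0 - dt)
        out[lo:hi] = np.argmin(ds * ds + dt * dt, axis=1)
    return out


def coordinates_to_csv(coords: TubeCoordinates, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "vertex_id": np.arange(len(coords.s)),
            "s": coords.s,
            "theta": coords.theta,
        }
    ).to_csv(path, index=False)
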