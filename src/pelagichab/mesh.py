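"""Triangular meshes for the SPDE spatial effect.

The mesh is a Delaunay triangulation of (i) the observation locations,
thinned so no two retained points are closer than ``cutoff``, plus (ii)
optional regular fill-in points — finer inside the convex hull of the
observations, coarser in an extension ring around it — so the spatial field
is resolved where the data are and the boundary effect of the SPDE
approximation is pushed away from them.  Coordinates are plate-carrée
degrees treated as planar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay

__all__ = ["Mesh", "build_mesh", "projector_matrix"]


@dataclass
class Mesh:
    vertices: np.ndarray  # (n, 2) lon/lat
    triangles: np.ndarray  # (m, 3) vertex indices
    boundary_extension: float = 0.0
    _tri: Delaunay | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if np.any(self.areas() <= 0):
            raise ValueError("mesh contains a degenerate (zero-area) triangle")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def delaunay(self) -> Delaunay:
        if self._tri is None:
            self._tri = Delaunay(self.vertices)
        return self._tri

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.delaunay().find_simplex(pts, tol=1e-10) >= 0

    def write(self, path) -> None:
        """OFF-like plain-text format: counts, vertices, triangles."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_vertices} {len(self.triangles)} {self.boundary_extension}\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.10f} {v[1]:.10f}\n")
            for t in self.triangles:
                fh.write(f"{t[0]} {t[1]} {t[2]}\n")

    @classmethod
    def read(cls, path) -> "Mesh":
        with open(path) as fh:
            nv, nt, ext = fh.readline().split()
            verts = np.array([[float(x) for x in fh.readline().split()] for _ in range(int(nv))])
            tris = np.array([[int(x) for x in fh.readline().split()] for _ in range(int(nt))])
        return cls(vertices=verts, triangles=tris, boundary_extension=float(ext))


def _thin(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Greedy thinning: keep a point only if >= cutoff from all kept points."""
    if cutoff <= 0:
        return np.unique(points, axis=0)
    kept: list[np.ndarray] = []
    for p in points:
        if all(np.hypot(*(p - q)) >= cutoff for q in kept):
            kept.append(p)
    return np.array(kept)


def _fill_points(hull: shapely.Polygon, spacing: float, region: shapely.Polygon) -> np.ndarray:
    """Regular lattice at the given spacing, restricted to ``region``."""
    minx, miny, maxx, maxy = region.bounds
    xs = np.arange(minx, maxx + spacing / 2, spacing)
    ys = np.arange(miny, maxy + spacing / 2, spacing)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.c_[xx.ravel(), yy.ravel()]
    keep = shapely.covers(region, shapely.points(pts[:, 0], pts[:, 1]))
    return pts[keep]


def build_mesh(
    locations: np.ndarray,
    max_edge_inner: float | None = None,
    max_edge_outer: float | None = None,
    cutoff: float = 0.0,
    extension: float = 0.0,
) -> Mesh:
    """Delaunay mesh covering the observation locations.

    ``cutoff`` thins near-duplicate locations; ``max_edge_inner`` /
    ``max_edge_outer`` set the target edge lengths of regular fill-in points
    inside the observation hull and in the ``extension`` ring around it.
    With no refinement arguments the mesh is the plain Delaunay triangulation
    of the (thinned) locations.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    pts = _thin(locations, cutoff)
    if len(pts) < 3:
        raise ValueError("need at least 3 locations after thinning")

    # hull of ALL locations (pre-thinning) so every observation stays inside;
    # its vertices are always kept as mesh vertices
    hull = shapely.convex_hull(shapely.multipoints(locations))
    if hull.area == 0:
        raise ValueError("locations are collinear")
    hull_pts = np.asarray(hull.exterior.coords)[:-1]
    parts = [hull_pts, pts]
    if max_edge_inner is not None:
        inner = _fill_points(hull, max_edge_inner, hull)
        if len(inner):
            parts.append(inner)
    if extension > 0:
        ring = hull.buffer(extension, quad_segs=4)
        spacing = max_edge_outer if max_edge_outer is not None else (max_edge_inner or extension)
        outer = _fill_points(hull, spacing, ring)
        if len(outer):
            # keep only ring points, the hull interior is already covered
            inside = shapely.covers(hull, shapely.points(outer[:, 0], outer[:, 1]))
            outer = outer[~inside]
            if len(outer):
                parts.append(outer)

    allpts = np.vstack(parts)
    # drop fill points that collide with existing ones
    allpts = _dedup(allpts, tol=1e-9 if cutoff == 0 else min(cutoff, 1e-3) * 0.5)
    tri = Delaunay(allpts)
    # discard degenerate slivers qhull may emit on collinear boundary points
    mesh_tris = tri.simplices
    p = allpts[mesh_tris]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    mesh_tris = mesh_tris[areas > 1e-12]
    return Mesh(vertices=allpts, triangles=mesh_tris, boundary_extension=extension, _tri=tri)


def _dedup(points: np.ndarray, tol: float) -> np.ndarray:
    if tol <= 0:
        return np.unique(points, axis=0)
    scale = np.round(points / tol).astype(np.int64)
    _, idx = np.unique(scale, axis=0, return_index=True)
    return points[np.sort(idx)]


def projector_matrix(mesh: Mesh, locations: np.ndarray):
    """Sparse barycentric projector A: (field at vertices) -> (field at points).

    Row i holds the barycentric coordinates of location i inside its
    containing triangle: at most 3 nonzeros, summing to 1.
    """
    from scipy import sparse

    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    tri = mesh.delaunay()
    simplex = tri.find_simplex(locations, tol=1e-8)
    if np.any(simplex < 0):
        bad = np.where(simplex < 0)[0]
        raise ValueError(f"locations outside mesh hull at rows {bad[:10].tolist()}")
    X = tri.transform[simplex]
    b = np.einsum("ijk,ik->ij", X[:, :2, :], locations - X[:, 2, :])
    bary = np.c_[b, 1.0 - b.sum(axis=1)]
    bary = np.clip(bary, 0.0, None)
    bary /= bary.sum(axis=1, keepdims=True)
    rows = np.repeat(np.arange(len(locations)), 3)
    cols = tri.simplices[simplex].ravel()
    A = sparse.csr_matrix(
        (bary.ravel(), (rows, cols)), shape=(len(locations), mesh.n_vertices)
    )
    A.eliminate_zeros()
    return A
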