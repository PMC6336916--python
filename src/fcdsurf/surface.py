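"""Cortical surface data structures and geometry primitives.

The pipeline represents each hemisphere as a pair of triangle meshes with
1:1 vertex correspondence: the *white* surface (gray/white matter boundary)
and the *pial* surface (gray matter / CSF boundary).  All coordinates are in
RAS millimetres; vertex and voxel indices are 0-based.

Geometry conventions
--------------------
* Per-vertex area is one third of the summed incident triangle areas, so the
  vertex areas partition the total surface area exactly.
* Outward vertex normals follow counter-clockwise face winding (viewed from
  outside the surface).
* Mean curvature uses the cotangent-Laplacian estimator and is signed so that
  sulcal concavities (surface bending toward the outward normal) are
  positive; a convex sphere with outward normals therefore has H = -1/R.
* Geodesic distance is the shortest path along mesh edges (Dijkstra on the
  edge-length graph).  This slightly overestimates exact polyhedral
  geodesics but is adequate at the 6 mm / 25 mm neighbourhood scales used
  here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra


class SurfaceFormatError(ValueError):
    """Raised when a surface/label/map file is malformed or inconsistent."""


class MeshError(ValueError):
    """Raised when a mesh violates the 2-manifold triangle-surface contract."""


@dataclass
class TriangleMesh:
    """A 2-manifold triangle surface.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in RAS mm.
    faces : (M, 3) int array
        Counter-clockwise vertex index triples.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (M, 3) array")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshError(f"face index out of range [0, {n})")
        referenced = np.zeros(n, dtype=bool)
        referenced[self.faces.ravel()] = True
        if not referenced.all():
            missing = int(np.flatnonzero(~referenced)[0])
            raise MeshError(f"vertex {missing} is not referenced by any face")
        # manifold check: every edge shared by one (boundary) or two faces
        counts = _edge_face_counts(self.faces)
        if counts.max(initial=0) > 2:
            raise MeshError("non-manifold edge shared by more than 2 faces")

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2), sorted pairs."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices on a boundary edge (open meshes)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[uniq[counts == 1].ravel()] = True
        return mask

    @cached_property
    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(cross, axis=1)
        areas = 0.5 * norm
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cross / norm[:, None]
        normals[norm == 0] = 0.0
        return normals, areas

    @cached_property
    def face_areas(self) -> np.ndarray:
        return self.face_normals_areas[1]

    @cached_property
    def vertex_areas(self) -> np.ndarray:
        """One third of incident triangle areas (partition of unity)."""
        areas = np.zeros(self.n_vertices)
        fa = self.face_areas / 3.0
        for k in range(3):
            np.add.at(areas, self.faces[:, k], fa)
        return areas

    @cached_property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward unit normals (CCW winding convention)."""
        fn, fa = self.face_normals_areas
        vn = np.zeros_like(self.vertices)
        w = fn * fa[:, None]
        for k in range(3):
            np.add.at(vn, self.faces[:, k], w)
        norm = np.linalg.norm(vn, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vn = vn / norm[:, None]
        vn[norm == 0] = 0.0
        return vn

    @cached_property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric vertex adjacency matrix (unweighted)."""
        e = self.edges
        n = self.n_vertices
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    @cached_property
    def edge_graph(self) -> sparse.csr_matrix:
        """Symmetric adjacency weighted by Euclidean edge length."""
        e = self.edges
        lengths = np.linalg.norm(
            self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.concatenate([lengths, lengths])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    @cached_property
    def vertex_neighbors(self) -> list[np.ndarray]:
        adj = self.adjacency
        return [adj.indices[adj.indptr[i]:adj.indptr[i + 1]]
                for i in range(self.n_vertices)]

    def total_area(self) -> float:
        return float(self.face_areas.sum())


def _edge_face_counts(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return counts


@dataclass
class CorticalSurfacePair:
    """White and pial meshes with 1:1 vertex correspondence."""

    white: TriangleMesh
    pial: TriangleMesh

    def __post_init__(self) -> None:
        if self.white.n_vertices != self.pial.n_vertices:
            raise MeshError("white/pial vertex counts differ")
        if not np.array_equal(self.white.faces, self.pial.faces):
            raise MeshError("white/pial face arrays differ")

    @property
    def n_vertices(self) -> int:
        return self.white.n_vertices


@dataclass
class SurfaceScalarMap:
    """One float per vertex; NaN marks masked (invalid) vertices."""

    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def check_mesh(self, mesh: TriangleMesh) -> None:
        if len(self.values) != mesh.n_vertices:
            raise SurfaceFormatError(
                f"map '{self.name}' has {len(self.values)} values but mesh "
                f"has {mesh.n_vertices} vertices")


@dataclass
class VertexLabel:
    """A named set of vertex indices (lesion, resection, ...)."""

    indices: np.ndarray
    name: str = "label"

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64).ravel())
        if idx.size and idx.min() < 0:
            raise ValueError("negative vertex index in label")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def check_mesh(self, mesh: TriangleMesh) -> None:
        if len(self.indices) and self.indices.max() >= mesh.n_vertices:
            raise SurfaceFormatError(
                f"label '{self.name}' references vertex "
                f"{int(self.indices.max())} beyond mesh size {mesh.n_vertices}")

    def to_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        mask[self.indices] = True
        return mask


@dataclass
class ScalarVolume:
    """A 3-D scalar volume with a voxel-to-RAS affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) RAS mm points to continuous 0-based voxel indices."""
        inv = np.linalg.inv(self.affine)
        pts = np.asarray(points, dtype=np.float64)
        return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class HomotopicCorrespondence:
    """Bijective left <-> right vertex mapping at homotopic locations."""

    left_to_right: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.left_to_right, dtype=np.int64).ravel()
        if len(np.unique(m)) != len(m):
            raise ValueError("homotopic mapping is not injective")
        if m.size and (m.min() < 0 or m.max() >= len(m)):
            raise ValueError("homotopic mapping index out of range")
        self.left_to_right = m

    @cached_property
    def right_to_left(self) -> np.ndarray:
        inv = np.empty_like(self.left_to_right)
        inv[self.left_to_right] = np.arange(len(self.left_to_right))
        return inv

    def __len__(self) -> int:
        return len(self.left_to_right)

    @classmethod
    def identity(cls, n: int) -> "HomotopicCorrespondence":
        return cls(np.arange(n))


# ----------------------------------------------------------------------
# geodesics
# ----------------------------------------------------------------------

def geodesic_neighborhood(mesh: TriangleMesh, center: int,
                          radius: float) -> dict[int, float]:
    """Vertices within geodesic (edge-path) distance ``radius`` of ``center``.

    Returns a mapping vertex -> distance; ``center`` is included at 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = mesh.n_vertices
    if not 0 <= center < n:
        raise IndexError(f"center {center} out of range [0, {n})")
    dist = dijkstra(mesh.edge_graph, directed=False, indices=center,
                    limit=radius)
    hit = np.flatnonzero(np.isfinite(dist))
    return {int(i): float(dist[i]) for i in hit}


def geodesic_distances(mesh: TriangleMesh, sources=None,
                       limit: float = np.inf) -> np.ndarray:
    """Dijkstra edge-path distances from ``sources`` (all vertices if None).

    Entries farther than ``limit`` are +inf.  With multiple sources and
    ``min_only`` semantics left to the caller, the result has one row per
    source (or the full matrix when sources is None).
    """
    return dijkstra(mesh.edge_graph, directed=False, indices=sources,
                    limit=limit)


def multi_source_geodesic(mesh: TriangleMesh,
                          sources: Iterable[int]) -> np.ndarray:
    """Distance from every vertex to the nearest of ``sources``."""
    idx = np.asarray(list(sources), dtype=np.int64)
    if idx.size == 0:
        raise ValueError("no source vertices")
    return dijkstra(mesh.edge_graph, directed=False, indices=idx,
                    min_only=True)


# ----------------------------------------------------------------------
# curvature
# ----------------------------------------------------------------------

def _cotangent_laplacian(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Symmetric cotangent-weight Laplacian L with (Lx)_i = sum w_ij (x_j-x_i)."""
    v = mesh.vertices
    f = mesh.faces
    areas = mesh.face_areas
    good = areas > 1e-12
    if not good.all():
        warnings.warn(f"excluding {int((~good).sum())} degenerate "
                      "(zero-area) triangles from curvature estimation")
        f = f[good]
    rows, cols, vals = [], [], []
    for k in range(3):
        i = f[:, k]
        j = f[:, (k + 1) % 3]
        o = f[:, (k + 2) % 3]  # vertex opposite edge (i, j)
        a = v[i] - v[o]
        b = v[j] - v[o]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cot = np.einsum("ij,ij->i", a, b) / np.maximum(cross, 1e-300)
        w = 0.5 * cot
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([w, w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = mesh.n_vertices
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    D = sparse.diags(np.asarray(W.sum(axis=1)).ravel())
    return (W - D).tocsr()


def mean_curvature(mesh: TriangleMesh) -> SurfaceScalarMap:
    """Discrete mean curvature (mm^-1), cotangent-Laplacian estimator.

    Sign convention: positive in concavities (sulci) with outward normals;
    a convex sphere yields -1/R.  Boundary vertices (open meshes) are
    masked NaN since the estimator is undefined there.
    """
    L = _cotangent_laplacian(mesh)
    lap = L @ mesh.vertices  # mean-curvature normal, scaled by vertex area
    h = np.einsum("ij,ij->i", lap, mesh.vertex_normals) / (
        2.0 * np.maximum(mesh.vertex_areas, 1e-300))
    h = np.asarray(h, dtype=np.float64)
    h[mesh.boundary_vertices] = np.nan
    zero = mesh.vertex_areas <= 1e-12
    if zero.any():
        h[zero] = np.nan
    return SurfaceScalarMap(h, name="mean_curvature", units="mm^-1")


def gaussian_curvature(mesh: TriangleMesh) -> SurfaceScalarMap:
    """Angle-deficit (Gauss-Bonnet) Gaussian curvature (mm^-2).

    Interior vertices use (2*pi - sum of incident angles) / vertex area;
    boundary vertices of open meshes are masked NaN (the deficit is not
    meaningful there).
    """
    v = mesh.vertices
    f = mesh.faces
    good = mesh.face_areas > 1e-12
    if not good.all():
        warnings.warn(f"excluding {int((~good).sum())} degenerate "
                      "(zero-area) triangles from curvature estimation")
        f = f[good]
    angle_sum = np.zeros(mesh.n_vertices)
    for k in range(3):
        i = f[:, k]
        a = v[f[:, (k + 1) % 3]] - v[i]
        b = v[f[:, (k + 2) % 3]] - v[i]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.clip(np.einsum("ij,ij->i", a, b) /
                         np.maximum(na * nb, 1e-300), -1.0, 1.0)
        np.add.at(angle_sum, i, np.arccos(cosang))
    areas = mesh.vertex_areas
    with np.errstate(invalid="ignore", divide="ignore"):
        k = (2.0 * np.pi - angle_sum) / areas
    k[areas <= 1e-12] = np.nan
    k[mesh.boundary_vertices] = np.nan
    return SurfaceScalarMap(k, name="gaussian_curvature", units="mm^-2")
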