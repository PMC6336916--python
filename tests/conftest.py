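"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import heapq

import numpy as np
import pytest

from fcdsurf.surface import ScalarVolume, TriangleMesh
from fcdsurf.synthetic import flat_grid, icosphere


# ----------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ----------------------------------------------------------------------

def dijkstra_oracle(mesh: TriangleMesh, sources) -> np.ndarray:
    """Plain heapq Dijkstra over the edge graph, independent of scipy."""
    n = mesh.n_vertices
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for a, b in mesh.edges:
        d = float(np.linalg.norm(mesh.vertices[a] - mesh.vertices[b]))
        adj[a].append((b, d))
        adj[b].append((a, d))
    dist = np.full(n, np.inf)
    heap = []
    for s in np.atleast_1d(sources):
        dist[int(s)] = 0.0
        heapq.heappush(heap, (0.0, int(s)))
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist[v] - 1e-15:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def flood_fill_oracle(mesh: TriangleMesh, member_mask: np.ndarray
                      ) -> list[set[int]]:
    """Connected components of a vertex subset by breadth-first search."""
    neighbors = mesh.vertex_neighbors
    remaining = set(np.flatnonzero(member_mask).tolist())
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            u = frontier.pop()
            for v in neighbors[u]:
                v = int(v)
                if v in remaining:
                    remaining.discard(v)
                    comp.add(v)
                    frontier.append(v)
        comps.append(comp)
    return comps


def make_volume(func, lo=-5.0, hi=35.0, step=1.0) -> ScalarVolume:
    """Volume whose voxel (i,j,k) holds func(x, y, z) at world coords."""
    coords = np.arange(lo, hi + step / 2, step)
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    affine = np.diag([step, step, step, 1.0])
    affine[:3, 3] = lo
    return ScalarVolume(func(X, Y, Z), affine)


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

@pytest.fixture(scope="session")
def ico162() -> TriangleMesh:
    return icosphere(2, 50.0)


@pytest.fixture(scope="session")
def sphere50() -> TriangleMesh:
    return icosphere(4, 50.0)


@pytest.fixture(scope="session")
def plane() -> TriangleMesh:
    return flat_grid(15, 15, 2.0)


@pytest.fixture(scope="session")
def fine_plane() -> TriangleMesh:
    # ~60 x 60 mm at 1 mm spacing; used for smoothing calibration checks
    return flat_grid(61, 71, 1.0)


@pytest.fixture()
def planar_pair():
    """White plane at z=0 and pial at z=3 over a 30 x 26 mm patch."""
    from fcdsurf.surface import CorticalSurfacePair
    white = flat_grid(16, 16, 2.0)
    pial_v = white.vertices.copy()
    pial_v[:, 2] += 3.0
    pial = TriangleMesh(pial_v, white.faces)
    return CorticalSurfacePair(white=white, pial=pial)
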