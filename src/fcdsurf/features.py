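"""Per-vertex multimodal features for dysplasia detection.

Morphology
    cortical thickness, gray/white intensity contrast (GWC), mean curvature,
    sulcal depth, local cortical deformation (LCD).
Intensity
    FLAIR sampled at the gray/white boundary, 25/50/75 % of cortical
    thickness, and 0.5 mm / 1 mm below the boundary.
Metabolism
    PET intensity normalised to the whole-cortex mean (hypometabolic lesions
    fall below 1), and its interhemispheric asymmetry.
Context
    "doughnut" maps (geodesic disc mean minus surrounding annulus mean) of
    GWC, thickness and FLAIR; interhemispheric asymmetry of every base
    feature through a homotopic vertex correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampling import sample_at_fraction, sample_below_white
from .surface import (CorticalSurfacePair, HomotopicCorrespondence,
                      ScalarVolume, SurfaceScalarMap, TriangleMesh,
                      geodesic_distances, gaussian_curvature,
                      multi_source_geodesic)

#: Depth fractions / offsets of the FLAIR intensity profile.
FLAIR_DEPTHS = (("flair_00", "fraction", 0.0),
                ("flair_25", "fraction", 0.25),
                ("flair_50", "fraction", 0.50),
                ("flair_75", "fraction", 0.75),
                ("flair_m05", "below", 0.5),
                ("flair_m10", "below", 1.0))


# ----------------------------------------------------------------------
# morphology
# ----------------------------------------------------------------------

def cortical_thickness(pair: CorticalSurfacePair) -> SurfaceScalarMap:
    """Euclidean distance between corresponding white and pial vertices."""
    d = np.linalg.norm(pair.pial.vertices - pair.white.vertices, axis=1)
    return SurfaceScalarMap(d, name="thickness", units="mm")


def gwc(t1: ScalarVolume, pair: CorticalSurfacePair,
        gm_fraction: float = 0.30,
        wm_depth_mm: float = 1.0) -> SurfaceScalarMap:
    """Gray/white intensity contrast: GM at 30 % ribbon depth over WM 1 mm
    below the boundary.  Blurred boundaries pull the ratio toward 1."""
    gm = sample_at_fraction(t1, pair, gm_fraction).values
    wm = sample_below_white(t1, pair, wm_depth_mm).values
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = gm / wm
    ratio[~np.isfinite(ratio)] = np.nan
    ratio[np.nan_to_num(wm, nan=-1.0) <= 0] = np.nan
    return SurfaceScalarMap(ratio, name="gwc", units="ratio")


def sulcal_depth(pial: TriangleMesh, smoothing_iterations: int = 200,
                 crown_epsilon_mm: float = 0.5,
                 crown_quantile: float = 0.95) -> SurfaceScalarMap:
    """Geodesic distance from each vertex to the nearest gyral crown vertex.

    Crowns are found against a heavily smoothed outer envelope of the pial
    surface: vertex coordinates are neighbourhood-averaged
    ``smoothing_iterations`` times, the signed offset of each original
    vertex from its smoothed position along the smoothed normal is taken,
    and vertices within ``crown_epsilon_mm`` of the outermost offsets
    (``crown_quantile`` of the offset distribution) are crowns.  Depth is
    then a multi-source Dijkstra distance from the crown set and is zero on
    crowns.  On a flat sheet every vertex is a crown and the depth is zero.
    """
    coords = pial.vertices.copy()
    adj = pial.adjacency
    deg = np.asarray(adj.sum(axis=1)).ravel()
    for _ in range(smoothing_iterations):
        coords = (adj @ coords) / deg[:, None]
    smoothed = TriangleMesh(coords, pial.faces)
    offset = np.einsum("ij,ij->i", pial.vertices - coords,
                       smoothed.vertex_normals)
    cutoff = np.quantile(offset, crown_quantile) - crown_epsilon_mm
    crowns = np.flatnonzero(offset >= cutoff)
    if crowns.size == 0:
        raise RuntimeError("no gyral crown vertices found; adjust the "
                           "crown quantile/epsilon configuration")
    depth = multi_source_geodesic(pial, crowns)
    return SurfaceScalarMap(depth, name="sulcal_depth", units="mm")


def local_cortical_deformation(mesh: TriangleMesh, radius: float = 25.0,
                               distances: np.ndarray | None = None
                               ) -> SurfaceScalarMap:
    """Area-weighted mean |Gaussian curvature| over a geodesic disc.

    Captures the degree of intrinsic cortical folding in the 25 mm disc
    centred on each vertex.
    """
    if distances is None:
        distances = geodesic_distances(mesh, limit=radius)
    K = np.abs(gaussian_curvature(mesh).values)
    areas = mesh.vertex_areas
    inside = np.isfinite(distances) & (distances <= radius)
    aw = areas * np.isfinite(K)
    kw = np.where(np.isfinite(K), K, 0.0)
    denom = inside @ aw
    counts = inside.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lcd = (inside @ (aw * kw)) / denom
    lcd[(counts < 3) | (denom <= 0)] = np.nan
    return SurfaceScalarMap(lcd, name="lcd", units="mm^-2")


# ----------------------------------------------------------------------
# metabolism
# ----------------------------------------------------------------------

def pet_hypointensity(pet: ScalarVolume,
                      *pairs: CorticalSurfacePair,
                      depth_fraction: float = 0.5
                      ) -> tuple[SurfaceScalarMap, ...]:
    """PET uptake at mid-cortex, normalised by the area-weighted mean
    uptake over the valid cortical vertices of all supplied hemispheres.

    Returns one map per hemisphere pair, in input order.  The subject-level
    normalisation makes the map invariant to global uptake scaling;
    hypometabolic lesions fall below 1.
    """
    if not pairs:
        raise ValueError("at least one hemisphere pair required")
    raws, weights = [], []
    for pair in pairs:
        raw = sample_at_fraction(pet, pair, depth_fraction).values
        raws.append(raw)
        weights.append(pair.white.vertex_areas)
    allvals = np.concatenate(raws)
    allw = np.concatenate(weights)
    valid = np.isfinite(allvals)
    total = float((allvals[valid] * allw[valid]).sum())
    wsum = float(allw[valid].sum())
    if wsum <= 0 or total <= 0:
        raise ValueError("non-positive global PET mean; corrupt volume?")
    mean = total / wsum
    return tuple(SurfaceScalarMap(raw / mean, name="pet_hypo", units="")
                 for raw in raws)


def interhemispheric_asymmetry(feature_l: SurfaceScalarMap,
                               feature_r: SurfaceScalarMap,
                               corr: HomotopicCorrespondence,
                               eps: float = 1e-9
                               ) -> tuple[SurfaceScalarMap, SurfaceScalarMap]:
    """Asymmetry index 2*(L - R)/(L + R) at homotopic vertex pairs.

    Returns (asym_left, asym_right); the right map is the negated left map
    carried through the correspondence, so asym_L(i) == -asym_R(corr(i)).
    Vertices where |L + R| < eps are masked.
    """
    L = feature_l.values
    R = feature_r.values[corr.left_to_right]
    denom = L + R
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = 2.0 * (L - R) / denom
    ai[np.abs(np.nan_to_num(denom)) < eps] = np.nan
    ai[~(np.isfinite(L) & np.isfinite(R))] = np.nan
    asym_l = SurfaceScalarMap(ai, name=f"asym_{feature_l.name}")
    right = np.full_like(ai, np.nan)
    right[corr.left_to_right] = -ai
    asym_r = SurfaceScalarMap(right, name=f"asym_{feature_r.name}")
    return asym_l, asym_r


# ----------------------------------------------------------------------
# doughnut maps
# ----------------------------------------------------------------------

def doughnut_map(smap: SurfaceScalarMap, mesh: TriangleMesh,
                 radius: float = 6.0,
                 distances: np.ndarray | None = None) -> SurfaceScalarMap:
    """Disc-minus-annulus local contrast.

    value(i) = area-weighted mean of the map over the geodesic disc of
    ``radius`` centred at i, minus the same mean over the annulus
    radius..2*radius.  Distances are taken on ``mesh`` (conventionally the
    inflated surface); pass ``distances`` to reuse a precomputed limited
    Dijkstra matrix (limit >= 2*radius).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    smap.check_mesh(mesh)
    if distances is None:
        distances = geodesic_distances(mesh, limit=2.0 * radius)
    x = smap.values
    areas = mesh.vertex_areas
    ok = np.isfinite(x)
    w = areas * ok
    xw = np.where(ok, x, 0.0) * areas
    finite = np.isfinite(distances)
    disc = finite & (distances <= radius)
    ring = finite & (distances > radius) & (distances <= 2.0 * radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc_mean = (disc @ xw) / (disc @ w)
        ring_mean = (ring @ xw) / (ring @ w)
    out = disc_mean - ring_mean
    out[(ring @ w) <= 0] = np.nan
    out[(disc @ w) <= 0] = np.nan
    return SurfaceScalarMap(out, name=f"doughnut_{smap.name}",
                            units=smap.units)


# ----------------------------------------------------------------------
# feature bundles
# ----------------------------------------------------------------------

@dataclass
class FeatureBundle:
    """Named per-vertex feature maps for one hemisphere of one subject."""

    n_vertices: int
    maps: dict[str, SurfaceScalarMap] = field(default_factory=dict)

    def add(self, smap: SurfaceScalarMap) -> None:
        if len(smap) != self.n_vertices:
            raise ValueError(
                f"feature '{smap.name}' has {len(smap)} values, "
                f"expected {self.n_vertices}")
        if smap.name in self.maps:
            raise ValueError(f"feature '{smap.name}' already registered")
        self.maps[smap.name] = smap

    def __getitem__(self, name: str) -> SurfaceScalarMap:
        return self.maps[name]

    def __contains__(self, name: str) -> bool:
        return name in self.maps

    @property
    def names(self) -> list[str]:
        return list(self.maps)

    def matrix(self, names: list[str]) -> np.ndarray:
        """(n_vertices, len(names)) feature matrix in registry order."""
        missing = [n for n in names if n not in self.maps]
        if missing:
            raise KeyError(f"missing features: {missing}")
        return np.column_stack([self.maps[n].values for n in names])


def flair_profile(flair: ScalarVolume,
                  pair: CorticalSurfacePair) -> dict[str, SurfaceScalarMap]:
    """FLAIR intensity at six cortical depths (see FLAIR_DEPTHS)."""
    out: dict[str, SurfaceScalarMap] = {}
    for name, kind, value in FLAIR_DEPTHS:
        if kind == "fraction":
            smap = sample_at_fraction(flair, pair, value)
        else:
            smap = sample_below_white(flair, pair, value)
        smap.name = name
        smap.units = "intensity"
        out[name] = smap
    return out
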