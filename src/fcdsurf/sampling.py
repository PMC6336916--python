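"""Sampling co-registered scalar volumes at surface-defined points.

Intensity features are read from the volumes either at a fractional depth
through the cortical ribbon (0 = gray/white boundary, 1 = pial surface) or
at a fixed millimetre offset below the gray/white boundary, measured inward
along the white-surface normal.  Interpolation is trilinear; sample points
outside the volume grid become masked NaN rather than being clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .surface import CorticalSurfacePair, ScalarVolume, SurfaceScalarMap


@dataclass(frozen=True)
class DepthSpec:
    """Where to sample through the cortical ribbon.

    kind='fraction_of_thickness' with value in [0, 1], or
    kind='mm_below_white' with value > 0 (mm into white matter).
    """

    kind: str
    value: float

    def __post_init__(self):
        if self.kind == "fraction_of_thickness":
            if not 0.0 <= self.value <= 1.0:
                raise ValueError("fraction must be in [0, 1]")
        elif self.kind == "mm_below_white":
            if self.value <= 0:
                raise ValueError("mm offset must be > 0")
        else:
            raise ValueError(f"unknown DepthSpec kind {self.kind!r}")


def sample_volume_at_points(volume: ScalarVolume, points: np.ndarray,
                            interpolation: str = "trilinear") -> np.ndarray:
    """Interpolate ``volume`` at (n, 3) RAS mm ``points``; NaN outside grid."""
    vox = volume.world_to_voxel(points)
    order = {"trilinear": 1, "nearest": 0}[interpolation]
    return map_coordinates(volume.data, vox.T, order=order,
                           mode="constant", cval=np.nan)


def sample_at_fraction(volume: ScalarVolume, pair: CorticalSurfacePair,
                       fraction: float,
                       interpolation: str = "trilinear") -> SurfaceScalarMap:
    """Sample at white + fraction * (pial - white) per vertex."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    pts = pair.white.vertices + fraction * (pair.pial.vertices -
                                            pair.white.vertices)
    vals = sample_volume_at_points(volume, pts, interpolation)
    return SurfaceScalarMap(vals, name=f"frac{fraction:g}")


def sample_below_white(volume: ScalarVolume, pair: CorticalSurfacePair,
                       depth_mm: float,
                       interpolation: str = "trilinear") -> SurfaceScalarMap:
    """Sample ``depth_mm`` inward along the white-surface outward normal."""
    if depth_mm <= 0:
        raise ValueError("depth_mm must be > 0")
    pts = pair.white.vertices - depth_mm * pair.white.vertex_normals
    vals = sample_volume_at_points(volume, pts, interpolation)
    return SurfaceScalarMap(vals, name=f"below{depth_mm:g}mm")


def sample_at_depth(volume: ScalarVolume, pair: CorticalSurfacePair,
                    spec: DepthSpec) -> SurfaceScalarMap:
    if spec.kind == "fraction_of_thickness":
        return sample_at_fraction(volume, pair, spec.value)
    return sample_below_white(volume, pair, spec.value)
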