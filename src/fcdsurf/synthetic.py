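"""Synthetic cortical cohorts with planted dysplasia-like lesions.

Each subject is a pair of mirror-image "hemispheres" built from a folded
icosphere: the pial surface is a radial graph r(u) = R + A*g(R*u) over unit
directions u with a smooth sinusoidal fold field g, and the white surface
sits a cortical thickness below it along the same ray.  Because both
surfaces and the tissue compartments of the phantom volumes are evaluated
from the same analytic radius functions, mesh geometry and voxel data are
exactly consistent, and the mirrored right hemisphere gives an exact
homotopic vertex correspondence (identity index map).

Phantom volumes (1 mm isotropic by default) contain WM/GM/CSF compartments
with T1, FLAIR and PET intensities; a planted lesion is a geodesic disc
around a chosen vertex carrying the classic dysplasia signatures: cortical
thickening (pial pushed outward), gray/white boundary blurring (local
Gaussian smoothing of T1/FLAIR), FLAIR hyperintensity, and a PET uptake
reduction that also produces interhemispheric PET asymmetry.  Controls are
identical constructions without a lesion.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter

from . import io as fio
from .surface import (CorticalSurfacePair, HomotopicCorrespondence,
                      ScalarVolume, TriangleMesh, VertexLabel)

# tissue intensities of the phantom volumes
T1_WM, T1_GM, T1_CSF = 120.0, 80.0, 30.0
FLAIR_WM, FLAIR_GM, FLAIR_CSF = 70.0, 100.0, 30.0
PET_WM, PET_GM, PET_CSF = 40.0, 100.0, 10.0

_PHASES = (0.7, 1.3, 2.1)  # fixed fold phases; break mirror degeneracies


def _fold_field_phases(points: np.ndarray, wavelength: float,
                       phases) -> np.ndarray:
    k = 2.0 * np.pi / wavelength
    out = np.ones(len(points))
    for axis, phase in enumerate(phases):
        out = out * np.sin(k * points[:, axis] + phase)
    return out


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Effect sizes are the planted lesion's radiological signatures:
    ``delta_thickness`` (mm of cortical thickening), ``blur_sigma`` (mm of
    gray/white boundary blurring), ``flair_increase`` (fractional FLAIR
    hyperintensity), ``pet_reduction`` (fractional uptake loss, which also
    drives interhemispheric PET asymmetry).
    """

    n_patients: int = 10
    n_controls: int = 10
    resolution: int = 4            # icosphere subdivisions
    sphere_radius: float = 30.0    # mm, scaled-down hemisphere
    fold_amplitude: float = 2.0    # mm
    fold_wavelength: float = 18.0  # mm
    base_thickness: float = 3.0    # mm
    lesion_radius: float = 10.0    # geodesic mm
    resection_margin: float = 4.0  # mm dilation of the lesion disc
    delta_thickness: float = 1.5   # mm
    blur_sigma: float = 2.0        # mm
    flair_increase: float = 0.15   # fraction of GM FLAIR
    pet_reduction: float = 0.40    # fraction of GM uptake
    boundary_blur: float = 0.5     # global image PSF sigma, mm (T1/FLAIR)
    pet_psf: float = 2.0           # PET scanner PSF sigma, mm
    noise_sd_t1: float = 3.0
    noise_sd_flair: float = 3.0
    noise_sd_pet: float = 3.0
    voxel_size: float = 1.0        # mm isotropic
    thickness_jitter: float = 0.03  # per-subject fractional sd
    amplitude_jitter: float = 0.05
    # hemispheres are not exact mirror images in vivo: each hemisphere gets
    # its own low-amplitude secondary fold field and a spatially varying
    # cortical thickness, so interhemispheric asymmetry maps carry
    # realistic non-zero background (set both to 0 for exact mirrors)
    hemi_asym_amplitude: float = 0.3   # mm
    hemi_asym_wavelength: float = 25.0  # mm
    thickness_variation: float = 0.05   # fractional, per-hemisphere field
    seed: int = 0

    def __post_init__(self):
        for name in ("delta_thickness", "blur_sigma", "flair_increase",
                     "pet_reduction"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"effect size {name} must be finite")
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2 subdivisions")


# ----------------------------------------------------------------------
# basic meshes
# ----------------------------------------------------------------------

def icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))


def flat_grid(nx: int, ny: int, spacing: float = 1.0) -> TriangleMesh:
    """Planar triangulated grid (staggered rows, near-equilateral)."""
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing * np.sqrt(3) / 2
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    X[1::2] += spacing / 2  # stagger odd rows
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = a + 1
            c = a + nx
            d = c + 1
            if j % 2 == 0:
                faces.append([a, b, c])
                faces.append([b, d, c])
            else:
                faces.append([a, b, d])
                faces.append([a, d, c])
    return TriangleMesh(verts, np.asarray(faces))


# ----------------------------------------------------------------------
# analytic scene
# ----------------------------------------------------------------------

def _fold_field(points: np.ndarray, wavelength: float) -> np.ndarray:
    """Smooth sinusoidal fold field in [-1, 1], hemisphere-local mm."""
    k = 2.0 * np.pi / wavelength
    out = np.ones(len(points))
    for axis, phase in enumerate(_PHASES):
        out = out * np.sin(k * points[:, axis] + phase)
    return out


def _cap_weight(u: np.ndarray, center_dir: np.ndarray, alpha0: float,
                taper: float = 0.3) -> np.ndarray:
    """Smooth indicator of the spherical cap: 1 inside angle alpha0,
    smoothstep to 0 at alpha0*(1+taper)."""
    cosang = np.clip(u @ center_dir, -1.0, 1.0)
    ang = np.arccos(cosang)
    w = np.clip((alpha0 * (1 + taper) - ang) / (alpha0 * taper), 0.0, 1.0)
    return w * w * (3.0 - 2.0 * w)


@dataclass
class SyntheticSubject:
    """One generated subject: geometry, phantom volumes, labels."""

    spec: CohortSpec
    subject_id: str
    seed: int
    group: str = "control"                 # 'patient' or 'control'
    lesion_hemi: str | None = None
    lesion_center: int | None = None       # vertex index on lesion_hemi
    # derived state
    thickness: float = field(init=False)
    amplitude: float = field(init=False)
    _geom: dict | None = field(default=None, init=False, repr=False)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        self.thickness = self.spec.base_thickness * float(
            1.0 + self.spec.thickness_jitter * rng.standard_normal())
        self.amplitude = self.spec.fold_amplitude * float(
            1.0 + self.spec.amplitude_jitter * rng.standard_normal())
        self.noise_seed = int(rng.integers(2 ** 31))
        # per-hemisphere phases of the asymmetric secondary fold field and
        # the thickness-variation field (lh drawn first, deterministically)
        self.hemi_phases = {h: rng.uniform(0.0, 2.0 * np.pi, 6)
                            for h in ("lh", "rh")}

    # -- geometry ------------------------------------------------------
    @property
    def hemi_offset(self) -> float:
        s = self.spec
        return s.sphere_radius + s.fold_amplitude + s.delta_thickness + 6.0

    def _center(self, hemi: str) -> np.ndarray:
        d = self.hemi_offset
        return np.array([-d, 0.0, 0.0]) if hemi == "lh" else \
            np.array([+d, 0.0, 0.0])

    def _lesion_dir(self) -> np.ndarray | None:
        if self.lesion_center is None:
            return None
        base = icosphere(self.spec.resolution)
        u = base.vertices / np.linalg.norm(base.vertices, axis=1)[:, None]
        return u[self.lesion_center]

    def _radii(self, u: np.ndarray, hemi: str) -> tuple[np.ndarray, ...]:
        """(r_white, r_pial, capw) at canonical-frame unit directions."""
        s = self.spec
        pts = s.sphere_radius * u
        base = s.sphere_radius + self.amplitude * _fold_field(
            pts, s.fold_wavelength)
        phases = self.hemi_phases[hemi]
        if s.hemi_asym_amplitude > 0:
            base = base + s.hemi_asym_amplitude * _fold_field_phases(
                pts, s.hemi_asym_wavelength, phases[:3])
        t_local = self.thickness
        if s.thickness_variation > 0:
            t_local = t_local * (1.0 + s.thickness_variation *
                                 _fold_field_phases(pts, s.hemi_asym_wavelength,
                                                    phases[3:]))
        capw = np.zeros(len(u))
        if self.group == "patient" and hemi == self.lesion_hemi:
            alpha0 = s.lesion_radius / s.sphere_radius
            capw = _cap_weight(u, self._lesion_dir(), alpha0)
        r_pial = base + s.delta_thickness * capw
        r_white = base - t_local
        return r_white, r_pial, capw

    def geometry(self) -> dict:
        """pairs / inflated meshes per hemisphere + homotopic identity."""
        if self._geom is not None:
            return self._geom
        s = self.spec
        base = icosphere(s.resolution)
        u = base.vertices / np.linalg.norm(base.vertices, axis=1)[:, None]
        mirror = np.array([-1.0, 1.0, 1.0])
        pairs, inflated = {}, {}
        for hemi in ("lh", "rh"):
            r_w, r_p, _ = self._radii(u, hemi)
            if (r_w <= 0).any():
                raise ValueError("white surface radius non-positive; "
                                 "reduce fold amplitude or thickness")
            c = self._center(hemi)
            if hemi == "lh":
                pial_v = c + r_p[:, None] * u
                white_v = c + r_w[:, None] * u
                infl_v = c + s.sphere_radius * u
                faces = base.faces
            else:
                pial_v = c + (r_p[:, None] * u) * mirror
                white_v = c + (r_w[:, None] * u) * mirror
                infl_v = c + (s.sphere_radius * u) * mirror
                faces = base.faces[:, ::-1]  # restore outward winding
            pairs[hemi] = CorticalSurfacePair(
                white=TriangleMesh(white_v, faces),
                pial=TriangleMesh(pial_v, faces))
            inflated[hemi] = TriangleMesh(infl_v, faces)
        self._geom = {"pairs": pairs, "inflated": inflated,
                      "corr": HomotopicCorrespondence.identity(
                          base.n_vertices)}
        return self._geom

    # -- labels --------------------------------------------------------
    def lesion_label(self) -> VertexLabel | None:
        if self.group != "patient":
            return None
        return self._cap_label(self.spec.lesion_radius, "lesion")

    def resection_label(self) -> VertexLabel | None:
        if self.group != "patient":
            return None
        return self._cap_label(
            self.spec.lesion_radius + self.spec.resection_margin,
            "resection")

    def _cap_label(self, radius_mm: float, name: str) -> VertexLabel:
        s = self.spec
        base = icosphere(s.resolution)
        u = base.vertices / np.linalg.norm(base.vertices, axis=1)[:, None]
        ang = np.arccos(np.clip(u @ self._lesion_dir(), -1, 1))
        idx = np.flatnonzero(ang <= radius_mm / s.sphere_radius)
        return VertexLabel(idx, name=name)

    # -- volumes -------------------------------------------------------
    def volumes(self) -> dict[str, ScalarVolume]:
        """Render T1 / FLAIR / PET phantoms consistent with the meshes."""
        s = self.spec
        d = self.hemi_offset
        half = s.sphere_radius + s.fold_amplitude + s.delta_thickness + 5.0
        vx = s.voxel_size
        xs = np.arange(-(d + half), d + half + vx / 2, vx)
        ys = np.arange(-half, half + vx / 2, vx)
        zs = np.arange(-half, half + vx / 2, vx)
        affine = np.diag([vx, vx, vx, 1.0])
        affine[:3, 3] = [xs[0], ys[0], zs[0]]
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        shape = X.shape
        t1 = np.full(shape, T1_CSF)
        flair = np.full(shape, FLAIR_CSF)
        pet = np.full(shape, PET_CSF)
        lesion_w = np.zeros(shape)
        for hemi in ("lh", "rh"):
            side = (X < 0) if hemi == "lh" else (X >= 0)
            c = self._center(hemi)
            qx = X[side] - c[0]
            if hemi == "rh":
                qx = -qx  # canonical frame
            q = np.column_stack([qx.ravel(), (Y[side] - c[1]).ravel(),
                                 (Z[side] - c[2]).ravel()])
            r = np.linalg.norm(q, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                u = q / np.maximum(r, 1e-12)[:, None]
            r_w, r_p, capw = self._radii(u, hemi)
            wm = r <= r_w
            gm = (~wm) & (r <= r_p)
            t1v = np.where(wm, T1_WM, np.where(gm, T1_GM, T1_CSF))
            flv = np.where(wm, FLAIR_WM,
                           np.where(gm, FLAIR_GM *
                                    (1.0 + s.flair_increase * capw),
                                    FLAIR_CSF))
            pev = np.where(wm, PET_WM,
                           np.where(gm, PET_GM *
                                    (1.0 - s.pet_reduction * capw),
                                    PET_CSF))
            t1[side] = t1v
            flair[side] = flv
            pet[side] = pev
            # the blurring pathology sits at the gray/white interface:
            # weight the lesion blur by a radial Gaussian window around the
            # white-surface radius so upper cortex keeps its FLAIR signal
            if s.blur_sigma > 0:
                radial = np.exp(-0.5 * ((r - r_w) / s.blur_sigma) ** 2)
                lesion_w[side] = capw * radial
        # lesion-local gray/white boundary blurring
        if self.group == "patient" and s.blur_sigma > 0:
            sig = s.blur_sigma / vx
            for vol in (t1, flair):
                blurred = gaussian_filter(vol, sig)
                vol += lesion_w * (blurred - vol)
        # acquisition point-spread and noise
        rng = np.random.default_rng(self.noise_seed)
        out = {}
        for name, vol, psf, sd in (("t1", t1, s.boundary_blur, s.noise_sd_t1),
                                   ("flair", flair, s.boundary_blur,
                                    s.noise_sd_flair),
                                   ("pet", pet, s.pet_psf, s.noise_sd_pet)):
            if psf > 0:
                vol = gaussian_filter(vol, psf / vx)
            noise = rng.standard_normal(shape) * sd
            out[name] = ScalarVolume(vol + (noise if sd > 0 else 0.0),
                                     affine)
        return out

    def manifest_entry(self) -> dict:
        return {"subject_id": self.subject_id, "group": self.group,
                "seed": self.seed,
                "lesion_hemi": self.lesion_hemi,
                "lesion_center": self.lesion_center,
                "thickness": self.thickness,
                "amplitude": self.amplitude}


# ----------------------------------------------------------------------
# spec-level operations
# ----------------------------------------------------------------------

def make_hemisphere(spec: CohortSpec, seed: int = 0) -> dict:
    """Lesion-free surfaces for one subject: CorticalSurfacePairs,
    inflated meshes, and the homotopic correspondence."""
    return SyntheticSubject(spec, "anon", seed).geometry()


def make_volumes(spec: CohortSpec, seed: int = 0) -> dict[str, ScalarVolume]:
    """Lesion-free phantom volumes for one subject."""
    return SyntheticSubject(spec, "anon", seed).volumes()


def plant_lesion(spec: CohortSpec, seed: int, center: int,
                 hemi: str = "lh") -> tuple[VertexLabel, VertexLabel,
                                            SyntheticSubject]:
    """Plant a lesion disc at ``center``: returns the lesion and resection
    labels together with the patient subject whose meshes and volumes carry
    the radiological signatures."""
    n = icosphere(spec.resolution).n_vertices
    if not 0 <= center < n:
        raise IndexError(f"lesion center {center} out of range [0, {n})")
    subj = SyntheticSubject(spec, "anon", seed, group="patient",
                            lesion_hemi=hemi, lesion_center=center)
    return subj.lesion_label(), subj.resection_label(), subj


def generate_cohort(spec: CohortSpec) -> tuple[list[SyntheticSubject], dict]:
    """Generate the full cohort in memory with a reproducible manifest.

    Lesion centers are drawn without replacement from the vertex set;
    lesion hemispheres alternate pseudo-randomly.  Controls carry no
    cortical lesion.
    """
    rng = np.random.default_rng(spec.seed)
    n_vertices = icosphere(spec.resolution).n_vertices
    centers = rng.choice(n_vertices, size=spec.n_patients, replace=False)
    hemis = rng.choice(["lh", "rh"], size=spec.n_patients)
    subjects = []
    for i in range(spec.n_patients):
        subjects.append(SyntheticSubject(
            spec, f"patient{i:03d}", seed=int(rng.integers(2 ** 31)),
            group="patient", lesion_hemi=str(hemis[i]),
            lesion_center=int(centers[i])))
    for i in range(spec.n_controls):
        subjects.append(SyntheticSubject(
            spec, f"control{i:03d}", seed=int(rng.integers(2 ** 31)),
            group="control"))
    manifest = {"spec": asdict(spec), "seed": spec.seed,
                "n_vertices": n_vertices,
                "subjects": [s.manifest_entry() for s in subjects]}
    return subjects, manifest


def write_cohort(spec: CohortSpec, outdir, force: bool = False) -> dict:
    """Materialize a cohort on disk (GIFTI surfaces, NIfTI volumes,
    FreeSurfer labels, JSON manifest with relative paths)."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise FileExistsError(f"{outdir} exists; pass force=True")
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects, manifest = generate_cohort(spec)
    for subj, entry in zip(subjects, manifest["subjects"]):
        sdir = outdir / subj.subject_id
        sdir.mkdir()
        geom = subj.geometry()
        paths = {}
        for hemi in ("lh", "rh"):
            for kind, mesh in (("white", geom["pairs"][hemi].white),
                               ("pial", geom["pairs"][hemi].pial),
                               ("inflated", geom["inflated"][hemi])):
                rel = f"{subj.subject_id}/{hemi}.{kind}.surf.gii"
                fio.write_surface(mesh, outdir / rel)
                paths[f"{hemi}_{kind}"] = rel
        for name, vol in subj.volumes().items():
            rel = f"{subj.subject_id}/{name}.nii.gz"
            fio.write_volume(vol, outdir / rel)
            paths[name] = rel
        if subj.group == "patient":
            for kind, label in (("lesion", subj.lesion_label()),
                                ("resection", subj.resection_label())):
                rel = f"{subj.subject_id}/{subj.lesion_hemi}.{kind}.label"
                mesh = geom["pairs"][subj.lesion_hemi].pial
                fio.write_label(label, outdir / rel, mesh=mesh)
                paths[kind] = rel
        entry["paths"] = paths
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
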