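"""Readers and writers for the surface, map, label, and volume formats.

Supported formats (all via :mod:`nibabel` except FreeSurfer ``.label``
writing, which nibabel does not provide):

* surfaces      — FreeSurfer binary geometry, GIFTI ``.surf.gii``
* scalar maps   — FreeSurfer ``curv``, GIFTI ``.func.gii``
* vertex labels — FreeSurfer ``.label``, GIFTI ``.label.gii``
* volumes       — NIfTI-1

Format selection is by filename suffix when ``fmt`` is not given:
``*.gii`` files are GIFTI, anything else the FreeSurfer dialect.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.gifti import GiftiDataArray, GiftiImage

from .surface import (ScalarVolume, SurfaceFormatError, SurfaceScalarMap,
                      TriangleMesh, VertexLabel)


def _is_gifti(path, fmt) -> bool:
    if fmt is not None:
        f = fmt.lower()
        if f in ("gifti", "gii"):
            return True
        if f in ("freesurfer", "fs"):
            return False
        raise ValueError(f"unknown format {fmt!r}")
    return str(path).endswith(".gii")


# ----------------------------------------------------------------------
# surfaces
# ----------------------------------------------------------------------

def read_surface(path, fmt: str | None = None) -> TriangleMesh:
    path = os.fspath(path)
    try:
        if _is_gifti(path, fmt):
            img = nib.load(path)
            verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
            faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
            if not verts or not faces:
                raise SurfaceFormatError(
                    f"{path}: GIFTI file lacks pointset/triangle arrays")
            return TriangleMesh(verts[0].data, faces[0].data)
        coords, faces = nib.freesurfer.read_geometry(path)
        return TriangleMesh(coords, faces)
    except SurfaceFormatError:
        raise
    except Exception as exc:  # malformed header / truncated payload
        raise SurfaceFormatError(f"cannot read surface {path}: {exc}") from exc


def write_surface(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    path = os.fspath(path)
    if _is_gifti(path, fmt):
        img = GiftiImage(darrays=[
            GiftiDataArray(mesh.vertices.astype(np.float32),
                           intent="NIFTI_INTENT_POINTSET"),
            GiftiDataArray(mesh.faces.astype(np.int32),
                           intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, path)
    else:
        nib.freesurfer.write_geometry(path, mesh.vertices, mesh.faces)


# ----------------------------------------------------------------------
# scalar maps
# ----------------------------------------------------------------------

def read_scalar_map(path, fmt: str | None = None,
                    mesh: TriangleMesh | None = None) -> SurfaceScalarMap:
    path = os.fspath(path)
    try:
        if _is_gifti(path, fmt):
            img = nib.load(path)
            if not img.darrays:
                raise SurfaceFormatError(f"{path}: empty GIFTI func file")
            values = img.darrays[0].data
        else:
            values = nib.freesurfer.read_morph_data(path)
    except SurfaceFormatError:
        raise
    except Exception as exc:
        raise SurfaceFormatError(f"cannot read map {path}: {exc}") from exc
    smap = SurfaceScalarMap(values, name=Path(path).stem)
    if mesh is not None:
        smap.check_mesh(mesh)
    return smap


def write_scalar_map(smap: SurfaceScalarMap, path,
                     fmt: str | None = None) -> None:
    path = os.fspath(path)
    if _is_gifti(path, fmt):
        img = GiftiImage(darrays=[
            GiftiDataArray(smap.values.astype(np.float32),
                           intent="NIFTI_INTENT_NONE")])
        nib.save(img, path)
    else:
        nib.freesurfer.write_morph_data(path, smap.values.astype(np.float32))


# ----------------------------------------------------------------------
# labels
# ----------------------------------------------------------------------

def read_label(path, fmt: str | None = None,
               mesh: TriangleMesh | None = None) -> VertexLabel:
    path = os.fspath(path)
    try:
        if _is_gifti(path, fmt):
            img = nib.load(path)
            data = img.darrays[0].data
            indices = np.flatnonzero(np.asarray(data) != 0)
        else:
            indices = nib.freesurfer.read_label(path)
    except Exception as exc:
        raise SurfaceFormatError(f"cannot read label {path}: {exc}") from exc
    label = VertexLabel(indices, name=Path(path).stem)
    if mesh is not None:
        label.check_mesh(mesh)
    return label


def write_label(label: VertexLabel, path, fmt: str | None = None,
                mesh: TriangleMesh | None = None) -> None:
    path = os.fspath(path)
    if _is_gifti(path, fmt):
        if mesh is None:
            raise ValueError("writing a GIFTI label requires the mesh "
                             "(to size the key array)")
        keys = np.zeros(mesh.n_vertices, dtype=np.int32)
        keys[label.indices] = 1
        img = GiftiImage(darrays=[
            GiftiDataArray(keys, intent="NIFTI_INTENT_LABEL",
                           datatype="NIFTI_TYPE_INT32")])
        lt = nib.gifti.GiftiLabelTable()
        for key, name in ((0, "unknown"), (1, label.name)):
            gl = nib.gifti.GiftiLabel(key=key)
            gl.label = name
            lt.labels.append(gl)
        img.labeltable = lt
        nib.save(img, path)
        return
    # FreeSurfer .label text format: nibabel reads but does not write it
    if mesh is not None:
        coords = mesh.vertices[label.indices]
    else:
        coords = np.zeros((len(label.indices), 3))
    with open(path, "w") as fh:
        fh.write(f"#!ascii label {label.name}\n")
        fh.write(f"{len(label.indices)}\n")
        for idx, (x, y, z) in zip(label.indices, coords):
            fh.write(f"{int(idx)}  {x:.6f}  {y:.6f}  {z:.6f}  0.000000\n")


# ----------------------------------------------------------------------
# volumes
# ----------------------------------------------------------------------

def read_volume(path) -> ScalarVolume:
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ScalarVolume(np.asarray(data, dtype=np.float64), img.affine)


def write_volume(volume: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, os.fspath(path))
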