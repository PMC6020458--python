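"""Volume, mask, and mesh input/output.

Volumes are carried as :class:`ScalarVolume` (a 3D intensity grid with
voxel spacing and origin metadata, indexed ``data[x, y, z]``); binary
segmentations as :class:`BinaryMask`.  NIfTI-1/2 is the primary on-disk
format; a plain raw-array file with a JSON sidecar serves as a
dependency-light fallback.  Extracted isosurfaces are written as binary
STL or ASCII OBJ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarVolume",
    "BinaryMask",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_mesh",
]


class VolumeFormatError(ValueError):
    """Raised for unreadable files or payloads that are not 3D volumes."""


@dataclass
class ScalarVolume:
    """A 3D scalar intensity image μ0(x, y, z).

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensity values; must be finite.
    spacing : tuple of float
        Voxel edge lengths (dx, dy, dz) in mm; carried as metadata.  The
        level-set lattice treats voxels as unit cubes by default.
    origin : tuple of float
        World coordinates of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.data.ndim}D payload"
            )
        if min(self.data.shape) < 1:
            raise VolumeFormatError("all three dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive components")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A {0,1}-valued segmentation on the same lattice as a volume."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D mask, got {arr.ndim}D payload"
            )
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _read_raw(path: Path):
    side = _sidecar(path)
    if not side.exists():
        raise VolumeFormatError(f"missing JSON sidecar for raw volume: {side}")
    meta = json.loads(side.read_text())
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    shape = tuple(meta["shape"])
    if len(shape) != 3:
        raise VolumeFormatError(f"sidecar declares {len(shape)}D payload")
    if data.size != int(np.prod(shape)):
        raise VolumeFormatError("raw payload size does not match sidecar shape")
    data = data.reshape(shape)
    return data, tuple(meta.get("spacing", (1, 1, 1))), tuple(
        meta.get("origin", (0, 0, 0))
    )


def _read_any(path) -> Tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several error types
            raise VolumeFormatError(f"unreadable NIfTI file {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {data.ndim}D payload in {path}"
            )
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(t) for t in img.affine[:3, 3])
        return np.asarray(data, dtype=np.float64), spacing, origin
    return _read_raw(path)


def read_volume(path) -> ScalarVolume:
    """Read a 3D scalar volume from NIfTI or the raw+sidecar fallback.

    Spacing is taken from the NIfTI header; the fallback format carries
    its own spacing in the sidecar (defaulting to unit voxels).
    """
    data, spacing, origin = _read_any(path)
    if not np.all(np.isfinite(data)):
        raise VolumeFormatError(f"non-finite intensities in {path}")
    return ScalarVolume(data, spacing, origin)


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a volume as NIfTI (by extension) or raw+JSON sidecar."""
    path = Path(path)
    if _is_nifti(path):
        img = nib.Nifti1Image(vol.data, _affine(vol.spacing, vol.origin))
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
        return
    vol.data.tofile(path)
    _sidecar(path).write_text(
        json.dumps(
            {
                "shape": list(vol.data.shape),
                "spacing": list(vol.spacing),
                "origin": list(vol.origin),
                "dtype": vol.data.dtype.str,
            }
        )
    )


def read_mask(path) -> BinaryMask:
    """Read a binary mask; values are binarized at 0.5 to tolerate float storage."""
    data, spacing, origin = _read_any(path)
    return BinaryMask((data > 0.5).astype(np.uint8), spacing, origin)


def write_mask(mask: BinaryMask, path) -> None:
    path = Path(path)
    if _is_nifti(path):
        img = nib.Nifti1Image(
            mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin)
        )
        img.header.set_zooms(mask.spacing)
        nib.save(img, str(path))
        return
    mask.data.tofile(path)
    _sidecar(path).write_text(
        json.dumps(
            {
                "shape": list(mask.data.shape),
                "spacing": list(mask.spacing),
                "origin": list(mask.origin),
                "dtype": mask.data.dtype.str,
            }
        )
    )


def write_mesh(mesh, path, fmt: str | None = None) -> None:
    """Write a triangle mesh as binary STL or ASCII OBJ.

    Parameters
    ----------
    mesh : TriangleMesh
        Non-empty surface with in-range triangle indices.
    path : path-like
        Destination; extension selects the format unless ``fmt`` is given.
    fmt : {"stl", "obj"}, optional
    """
    import trimesh

    verts = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.triangles, dtype=np.int64)
    if verts.size == 0 or faces.size == 0:
        raise ValueError("cannot write an empty mesh")
    if faces.min() < 0 or faces.max() >= len(verts):
        raise ValueError("triangle indices out of vertex range")
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("stl", "obj"):
        raise ValueError(f"unsupported mesh format: {fmt!r} (use 'stl' or 'obj')")
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    tm.export(str(path), file_type=fmt)
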