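"""Core data model: 3-D volumes, surface meshes, label lookup tables.

Conventions used throughout the package:

* voxel indices are 0-based;
* world coordinates are RAS millimetres, obtained by applying the volume's
  4x4 affine to the homogeneous voxel index;
* all electrode contact coordinates are stored in world mm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeFormatError(Exception):
    """Raised when a volume file cannot be read as a NIfTI-1 image."""


@dataclass
class Volume3D:
    """A scalar 3-D image with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities (arbitrary units).
    affine : ndarray, shape (4, 4)
        Invertible voxel-index -> RAS-mm transform.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Physical voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def copy(self, data: np.ndarray | None = None) -> "Volume3D":
        return Volume3D(self.data.copy() if data is None else data,
                        self.affine.copy())


@dataclass
class SurfaceMesh:
    """A triangulated surface: vertices in world mm, 0-based face triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    def drop_degenerate_faces(self) -> "SurfaceMesh":
        """Remove zero-area faces (repeated or collinear vertices)."""
        v = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)
        return SurfaceMesh(self.vertices, self.faces[areas > 1e-12])

    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())


@dataclass
class LabelLUT:
    """Integer label -> (area name, optional RGB color). Label 0 is background."""

    entries: dict[int, tuple[str, tuple[int, int, int] | None]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        self.entries.setdefault(0, ("unknown", (0, 0, 0)))

    def name(self, label: int) -> str:
        return self.entries.get(int(label), (f"label-{label}", None))[0]

    def __contains__(self, label: int) -> bool:
        return int(label) in self.entries


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | os.PathLike) -> Volume3D:
    """Load a NIfTI-1 volume (.nii or .nii.gz), squeezing singleton 4th dims."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise VolumeFormatError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path!r}: expected a 3-D image, got shape {data.shape}")
    return Volume3D(np.asarray(data), np.asarray(affine, dtype=float))


def save_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a Volume3D as NIfTI-1 (.nii or .nii.gz chosen by extension)."""
    nib.save(nib.Nifti1Image(vol.data, vol.affine), str(path))


def load_mesh(path: str | os.PathLike) -> SurfaceMesh:
    """Read a surface mesh from Wavefront OBJ or FreeSurfer binary format."""
    path = str(path)
    if path.endswith((".obj", ".OBJ")):
        verts, faces = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0] == "v":
                    verts.append([float(x) for x in parts[1:4]])
                elif parts[0] == "f":
                    faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
        return SurfaceMesh(np.array(verts), np.array(faces))
    # fall back to FreeSurfer binary surface
    verts, faces = nib.freesurfer.read_geometry(path)
    return SurfaceMesh(verts, faces)


def save_mesh(mesh: SurfaceMesh, path: str | os.PathLike) -> None:
    """Write a surface mesh as Wavefront OBJ."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def load_lut(path: str | os.PathLike) -> LabelLUT:
    """Read a tab-separated label table: index, name[, R, G, B]."""
    entries: dict[int, tuple[str, tuple[int, int, int] | None]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            idx = int(parts[0])
            name = parts[1]
            color = None
            if len(parts) >= 5:
                color = (int(parts[2]), int(parts[3]), int(parts[4]))
            entries[idx] = (name, color)
    return LabelLUT(entries)


def save_lut(lut: LabelLUT, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for idx in sorted(lut.entries):
            name, color = lut.entries[idx]
            r, g, b = color if color is not None else (0, 0, 0)
            fh.write(f"{idx}\t{name}\t{r}\t{g}\t{b}\n")


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def voxel_to_world(vol: Volume3D, index) -> np.ndarray:
    """Map (fractional) voxel indices to world mm via the volume affine."""
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    out = idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    return out[0] if np.asarray(index).ndim == 1 else out


def world_to_voxel(vol: Volume3D, point) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`."""
    pt = np.atleast_2d(np.asarray(point, dtype=float))
    inv = np.linalg.inv(vol.affine)
    out = pt @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if np.asarray(point).ndim == 1 else out


def resample_into(src: Volume3D, ref: Volume3D, transform: np.ndarray | None = None,
                  interpolation: str = "trilinear") -> Volume3D:
    """Resample ``src`` onto the grid of ``ref``.

    ``transform`` is a world-to-world map taking src-world coordinates to
    ref-world coordinates (identity if None).  Out-of-field voxels are 0.
    """
    if transform is None:
        transform = np.eye(4)
    transform = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(transform)) < 1e-12:
        raise ValueError("world-to-world transform is singular")
    # ref voxel -> ref world -> src world -> src voxel, composed as one affine
    full = np.linalg.inv(src.affine) @ np.linalg.inv(transform) @ ref.affine
    order = {"nearest": 0, "trilinear": 1}[interpolation]
    # ndimage.affine_transform maps output index -> input index
    out = ndimage.affine_transform(
        src.data.astype(float), full[:3, :3], offset=full[:3, 3],
        output_shape=ref.shape, order=order, mode="constant", cval=0.0)
    return Volume3D(out, ref.affine.copy())
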