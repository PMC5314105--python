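"""Display-layer mathematics: density maps, oblique reslicing, isosurfaces.

These are the computations behind the toolbox's viewer; the interactive
windowing itself is out of scope, so everything here renders to arrays,
meshes, or image files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .volumes import SurfaceMesh, Volume3D, world_to_voxel

#: FWHM of the density kernel, mm, matched to typical electrode size
FWHM_ECOG = 5.0
FWHM_SEEG = 2.0


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian scale c with half maximum at fwhm/2: c = FWHM / (2 sqrt(2 ln 2))."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class DensityConfig:
    fwhm: float = FWHM_ECOG
    weights: np.ndarray | None = None   # default: unit weight per electrode

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")

    @property
    def sigma(self) -> float:
        return fwhm_to_sigma(self.fwhm)


def density_at(points, centers, cfg: DensityConfig) -> np.ndarray:
    """Analytic density sum_i w_i exp(-||p - p_i||^2 / (2 c^2)) at points."""
    pts = np.atleast_2d(np.asarray(points, float))
    ctr = np.atleast_2d(np.asarray(centers, float))
    w = (np.ones(len(ctr)) if cfg.weights is None
         else np.asarray(cfg.weights, float))
    d2 = np.sum((pts[:, None, :] - ctr[None, :, :]) ** 2, axis=2)
    return (w[None, :] * np.exp(-d2 / (2.0 * cfg.sigma ** 2))).sum(axis=1)


def density_map(centers, grid: Volume3D, cfg: DensityConfig) -> Volume3D:
    """Gaussian density of electrode positions evaluated on a volume grid.

    The kernel is evaluated analytically per voxel (no discrete
    convolution), so an isolated electrode's peak equals its weight exactly
    at its own coordinate.  Contributions beyond 5 sigma are dropped.
    """
    centers = np.atleast_2d(np.asarray(centers, float)).reshape(-1, 3)
    out = np.zeros(grid.shape, dtype=float)
    if len(centers) == 0:
        return Volume3D(out, grid.affine.copy())
    w = (np.ones(len(centers)) if cfg.weights is None
         else np.asarray(cfg.weights, float))
    vs = grid.voxel_sizes
    reach = 5.0 * cfg.sigma
    aff = grid.affine
    for c, wi in zip(centers, w):
        cv = world_to_voxel(grid, c)
        lo = np.maximum(np.floor(cv - reach / vs).astype(int), 0)
        hi = np.minimum(np.ceil(cv + reach / vs).astype(int) + 1,
                        np.asarray(grid.shape))
        if np.any(hi <= lo):
            continue
        ax = [aff[i, i] * np.arange(lo[i], hi[i]) + aff[i, 3] for i in range(3)]
        # local world grid assumes an axis-aligned affine for speed
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
            idx = np.stack(np.meshgrid(
                *[np.arange(lo[i], hi[i]) for i in range(3)],
                indexing="ij"), -1).reshape(-1, 3).astype(float)
            world = idx @ aff[:3, :3].T + aff[:3, 3]
            d2 = np.sum((world - c) ** 2, axis=1).reshape(
                tuple(hi - lo))
        else:
            X, Y, Z = np.meshgrid(*ax, indexing="ij")
            d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += \
            wi * np.exp(-d2 / (2.0 * cfg.sigma ** 2))
    return Volume3D(out, grid.affine.copy())


def measure_fwhm(profile: np.ndarray, spacing: float) -> float:
    """Width of the region above half the profile's maximum, with linear
    interpolation of the two half-maximum crossings."""
    prof = np.asarray(profile, float)
    peak = prof.max()
    half = peak / 2.0
    above = np.where(prof >= half)[0]
    if above.size == 0:
        return 0.0
    i0, i1 = above[0], above[-1]
    left = float(i0)
    if i0 > 0:
        left = i0 - (prof[i0] - half) / (prof[i0] - prof[i0 - 1])
    right = float(i1)
    if i1 < len(prof) - 1:
        right = i1 + (prof[i1] - half) / (prof[i1] - prof[i1 + 1])
    return (right - left) * spacing


# ---------------------------------------------------------------------------
# oblique (peri-coronal) reslicing
# ---------------------------------------------------------------------------

_VIEW_NORMALS = {
    # the toolbox convention: (0, 0, 1) is the "coronal" view normal
    "coronal": np.array([0.0, 0.0, 1.0]),
    "axial": np.array([0.0, 1.0, 0.0]),
    "sagittal": np.array([1.0, 0.0, 0.0]),
}


@dataclass
class ObliquePlane:
    """Slicing plane containing a full depth electrode.

    v_r: unit vector along the electrode's two end contacts (the plane
    normal is rotated so the view plane contains the electrode);
    v_c: the constructed view's normal; v_a = v_c x v_r is the rotation
    axis and theta = acos(v_c . v_r) the rotation angle.
    """

    v_r: np.ndarray
    v_c: np.ndarray
    v_a: np.ndarray
    theta: float
    origin: np.ndarray
    no_rotation: bool = False


def oblique_plane(deep_contact, superficial_contact,
                  view: str = "coronal") -> ObliquePlane:
    """Axis/angle of the rotation bringing the view normal onto the
    electrode direction; the plane is centered on the electrode midpoint."""
    p0 = np.asarray(deep_contact, float)
    p1 = np.asarray(superficial_contact, float)
    diff = p1 - p0
    norm = np.linalg.norm(diff)
    if norm < 1e-12:
        raise ValueError("end contacts coincide; electrode direction undefined")
    v_r = diff / norm
    v_c = _VIEW_NORMALS[view]
    v_a = np.cross(v_c, v_r)
    theta = float(np.arccos(np.clip(v_c @ v_r, -1.0, 1.0)))
    no_rot = np.linalg.norm(v_a) < 1e-12
    if not no_rot:
        v_a = v_a / np.linalg.norm(v_a)
    else:
        v_a = np.zeros(3)
    return ObliquePlane(v_r=v_r, v_c=v_c, v_a=v_a, theta=theta,
                        origin=(p0 + p1) / 2.0, no_rotation=no_rot)


def _rodrigues(axis: np.ndarray, theta: float) -> np.ndarray:
    if np.linalg.norm(axis) < 1e-12 or abs(theta) < 1e-15:
        return np.eye(3)
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def plane_rotation(plane: ObliquePlane) -> np.ndarray:
    """Rotation matrix (about v_a by theta) taking v_c onto v_r."""
    if plane.no_rotation:
        return np.eye(3) if plane.theta < np.pi / 2 else -np.eye(3)
    return _rodrigues(plane.v_a, plane.theta)


@dataclass
class ObliqueSlice:
    image: np.ndarray             # (nu, nv)
    u: np.ndarray                 # in-plane world direction of axis 0
    v: np.ndarray                 # in-plane world direction of axis 1
    origin: np.ndarray
    spacing: float
    warning: str | None = None

    def world(self, a, b) -> np.ndarray:
        """World coordinate of pixel (a, b) (fractional allowed)."""
        nu, nv = self.image.shape
        return (self.origin
                + (np.asarray(a, float) - (nu - 1) / 2)[..., None]
                * self.spacing * self.u
                + (np.asarray(b, float) - (nv - 1) / 2)[..., None]
                * self.spacing * self.v).squeeze()


def reslice_oblique(vol: Volume3D, plane: ObliquePlane, extent_mm: float = 80.0,
                    spacing_mm: float = 0.5) -> ObliqueSlice:
    """Trilinear sample of the volume on the peri-coronal plane.

    The slice is the plane spanned by the view normal ``v_c`` and the
    electrode direction ``v_r`` (its normal is the rotation axis ``v_a``),
    so the full electrode lies inside the slice while the view axis is
    preserved.  When the electrode is parallel to the view normal (theta
    0 or pi) this degenerates to the ordinary orthogonal slice through the
    electrode midpoint.  The sampling grid spans ``extent_mm`` in both
    in-plane directions, centered on the electrode midpoint.
    """
    v_c = plane.v_c
    if plane.no_rotation:
        # degenerate: ordinary v_c-normal slice through the midpoint
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(tmp @ v_c) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        u = tmp - (tmp @ v_c) * v_c
        u /= np.linalg.norm(u)
        w = np.cross(v_c, u)
    else:
        u = v_c.copy()
        w = plane.v_r - (plane.v_r @ v_c) * v_c
        w /= np.linalg.norm(w)

    n = int(round(extent_mm / spacing_mm)) + 1
    coords = (np.arange(n) - (n - 1) / 2) * spacing_mm
    A, B = np.meshgrid(coords, coords, indexing="ij")
    world = (plane.origin[None, None, :] + A[..., None] * u[None, None, :]
             + B[..., None] * w[None, None, :])
    vox = world_to_voxel(vol, world.reshape(-1, 3)).T
    img = ndimage.map_coordinates(vol.data.astype(float), vox, order=1,
                                  mode="constant", cval=0.0).reshape(n, n)
    warning = None
    in_field = np.all((vox >= -0.5)
                      & (vox <= (np.asarray(vol.shape)[:, None] - 0.5)), axis=0)
    if not in_field.any():
        warning = "slicing plane lies entirely outside the volume"
    return ObliqueSlice(image=img, u=u, v=w, origin=plane.origin,
                        spacing=spacing_mm, warning=warning)


# ---------------------------------------------------------------------------
# isosurface extraction
# ---------------------------------------------------------------------------

def laplacian_smooth(mesh: SurfaceMesh, passes: int,
                     lam: float = 0.5) -> SurfaceMesh:
    """Uniform-weight Laplacian smoothing; 0 passes returns a copy."""
    from .phantom import _laplacian_smooth
    return _laplacian_smooth(mesh, passes, lam)


def brain_outline_surface(brain_vol: Volume3D, level: float,
                          smoothing_passes: int = 5) -> SurfaceMesh:
    """Marching-cubes isosurface of the brain volume at ``level``, followed
    by Laplacian smoothing (the brain-outline surface of the viewer)."""
    data = brain_vol.data.astype(float)
    if not (data.min() < level < data.max()):
        raise ValueError(f"isosurface level {level} outside the intensity "
                         f"range [{data.min()}, {data.max()}]")
    verts, faces, _, _ = measure.marching_cubes(data, level=level)
    world = verts @ brain_vol.affine[:3, :3].T + brain_vol.affine[:3, 3]
    mesh = SurfaceMesh(world, faces).drop_degenerate_faces()
    return laplacian_smooth(mesh, smoothing_passes)
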