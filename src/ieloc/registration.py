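"""CT -> T1 rigid coregistration and T1 -> template affine registration.

The similarity metric is Studholme's normalized mutual information
NMI = (H(A) + H(B)) / H(A, B), computed from the joint intensity histogram
of the overlapping field of view.  The optimizer is a deterministic
derivative-free search (Powell) run coarse-to-fine over a resolution
pyramid; the paper trail for this method names only the metric, so any
well-behaved local optimizer is acceptable and this one needs no seed.

Transforms are world-to-world (RAS mm) maps.  Rotations are parameterized
as extrinsic x/y/z Euler angles about the fixed image's world center, so
translations and rotations stay decoupled during the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volumes import Volume3D


class RegistrationError(Exception):
    pass


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class RigidTransform:
    """6-dof rigid transform: rotation angles (rad) + translation (mm).

    The rotation acts about ``center`` (world mm), so the 4x4 matrix is
    p -> R (p - c) + c + t.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def matrix(self) -> np.ndarray:
        R = _euler_matrix(*self.rotation)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center + self.translation - R @ self.center
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        m = self.matrix
        return np.atleast_2d(points) @ m[:3, :3].T + m[:3, 3]


@dataclass
class AffineTransform:
    """General 12-parameter affine as a 4x4 world-to-world matrix."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine transform is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))


# ---------------------------------------------------------------------------
# metric
# ---------------------------------------------------------------------------

def nmi(a: Volume3D | np.ndarray, b: Volume3D | np.ndarray,
        bins: int = 64) -> float:
    """Studholme normalized mutual information, in [1, 2].

    Non-finite samples (out-of-field after resampling) are excluded from the
    joint histogram.  A constant image has zero entropy; NMI is defined as 1
    in that case rather than raising.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = (a.data if isinstance(a, Volume3D) else np.asarray(a)).ravel()
    y = (b.data if isinstance(b, Volume3D) else np.asarray(b)).ravel()
    if x.shape != y.shape:
        raise ValueError("volumes must have the same shape")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise RegistrationError("no overlapping field of view")
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    hxy = -np.sum(p[p > 0] * np.log(p[p > 0]))
    if hxy <= 0:
        return 1.0
    return float((hx + hy) / hxy)


# ---------------------------------------------------------------------------
# resampling for the metric (NaN outside the field of view)
# ---------------------------------------------------------------------------

def _resample_nan(moving: Volume3D, fixed: Volume3D,
                  world_mat: np.ndarray) -> np.ndarray:
    """Trilinear resampling of ``moving`` onto ``fixed``'s grid under the
    world-to-world map, NaN outside the moving field of view."""
    full = np.linalg.inv(moving.affine) @ np.linalg.inv(world_mat) @ fixed.affine
    return ndimage.affine_transform(
        moving.data.astype(float), full[:3, :3], offset=full[:3, 3],
        output_shape=fixed.shape, order=1, mode="constant", cval=np.nan)


#: Gaussian prefilter (voxels) applied to every pyramid level before the
#: metric; damps the interpolation-induced noise bias of histogram NMI.
METRIC_SMOOTH_VOX = 2.0


def _downsample(vol: Volume3D, factor: int) -> Volume3D:
    data = ndimage.gaussian_filter(vol.data.astype(float), METRIC_SMOOTH_VOX)
    if factor > 1:
        data = data[::factor, ::factor, ::factor]
    aff = vol.affine.copy()
    aff[:3, :3] *= factor
    return Volume3D(data, aff)


def _fixed_center(fixed: Volume3D) -> np.ndarray:
    c_idx = (np.asarray(fixed.shape) - 1) / 2.0
    return fixed.affine[:3, :3] @ c_idx + fixed.affine[:3, 3]


# ---------------------------------------------------------------------------
# rigid
# ---------------------------------------------------------------------------

def register_rigid(moving: Volume3D, fixed: Volume3D,
                   init: RigidTransform | None = None, bins: int = 64,
                   multi_res_levels: int = 3) -> RigidTransform:
    """Find the 6-dof transform maximizing NMI(resample(moving, T), fixed).

    Coarse-to-fine over ``multi_res_levels`` pyramid levels (factor 2),
    Powell search at each level; fully deterministic.
    """
    center = _fixed_center(fixed)
    init = init or RigidTransform(center=center)
    x0 = np.concatenate([np.rad2deg(init.rotation), init.translation])

    probe = _resample_nan(moving, fixed,
                          RigidTransform(init.rotation, init.translation,
                                         center).matrix)
    if not np.isfinite(probe).any():
        raise RegistrationError(
            "no overlap between moving and fixed under the initial transform; "
            "supply a manual initialization")

    def make_cost(mov_l, fix_l):
        def cost(x):
            t = RigidTransform(np.deg2rad(x[:3]), x[3:], center)
            res = _resample_nan(mov_l, fix_l, t.matrix)
            if not np.isfinite(res).any():
                return 1.0  # -NMI lower bound; push back toward overlap
            return -nmi(res, fix_l.data, bins=bins)
        return cost

    x = x0
    for level in range(multi_res_levels - 1, -1, -1):
        f = 2 ** level
        fix_l = _downsample(fixed, f)
        mov_l = _downsample(moving, f)
        res = optimize.minimize(
            make_cost(mov_l, fix_l), x, method="Powell",
            options={"xtol": 1e-3 if level <= 1 else 3e-2,
                     "ftol": 1e-7, "maxiter": 5 if level == 0 else 15})
        x = res.x
    return RigidTransform(np.deg2rad(x[:3]), np.asarray(x[3:]), center)


# ---------------------------------------------------------------------------
# affine
# ---------------------------------------------------------------------------

def _affine_from_params(x: np.ndarray, center: np.ndarray) -> np.ndarray:
    """rot(deg) 3, trans 3, scale 3, shear 3 -> 4x4 about center."""
    R = _euler_matrix(*np.deg2rad(x[:3]))
    S = np.diag(x[6:9])
    Sh = np.eye(3)
    Sh[0, 1], Sh[0, 2], Sh[1, 2] = x[9], x[10], x[11]
    A = R @ Sh @ S
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = center + x[3:6] - A @ center
    return m


def register_affine(moving: Volume3D, template: Volume3D, bins: int = 64,
                    multi_res_levels: int = 3,
                    matrix: np.ndarray | None = None) -> AffineTransform:
    """12-parameter affine maximizing NMI against a template.

    If ``matrix`` is supplied (e.g. a transform exported from another tool),
    it is returned as-is without estimation.
    """
    if matrix is not None:
        return AffineTransform(np.asarray(matrix, dtype=float))
    center = _fixed_center(template)

    probe = _resample_nan(moving, template, np.eye(4))
    if not np.isfinite(probe).any():
        raise RegistrationError(
            "no overlap between moving and template; supply a matrix")

    x = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float)

    def make_cost(mov_l, fix_l):
        def cost(p):
            m = _affine_from_params(p, center)
            if abs(np.linalg.det(m[:3, :3])) < 1e-6:
                return 1.0
            res = _resample_nan(mov_l, fix_l, m)
            if not np.isfinite(res).any():
                return 1.0
            return -nmi(res, fix_l.data, bins=bins)
        return cost

    for level in range(multi_res_levels - 1, -1, -1):
        f = 2 ** level
        fix_l = _downsample(template, f)
        mov_l = _downsample(moving, f)
        res = optimize.minimize(
            make_cost(mov_l, fix_l), x, method="Powell",
            options={"xtol": 1e-3 if level == 0 else 5e-3,
                     "ftol": 1e-6,
                     "maxiter": 2 if level == 0 else (5 if level == 1 else 8)})
        x = res.x
    return AffineTransform(_affine_from_params(x, center))


def save_transform(matrix: np.ndarray, path) -> None:
    """Write a 4x4 world-to-world matrix as plain text."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.10g")


def load_transform(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {m.shape}")
    return m
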