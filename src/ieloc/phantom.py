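"""Synthetic head and implanted-electrode phantoms with ground truth.

The phantom emulates the inputs a clinical run would take from the scanner
and from FreeSurfer: a T1-like volume, a skull-stripped brain mask, a
parcellation with a label table, pial / smoothed-pial meshes, and a
post-implant CT containing a skull-intensity shell plus bright electrode
metal.  Geometry is an ellipsoidal brain inside an ellipsoidal skull shell;
depth electrodes are chains of 0.8 mm x 2 mm cylinders at 3.5 mm center
spacing along possibly-bent trajectories, subdural grids are 4 mm disks at
10 mm pitch on the pial surface.

Everything is reproducible bit-exactly from (spec, seed).  Electrode metal
is painted by super-sampled partial-volume coverage with a saturation knee,
which mimics the blooming of metal in CT and keeps contact voxels at the
full electrode intensity even though the hardware is thinner than a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .volumes import LabelLUT, SurfaceMesh, Volume3D


@dataclass
class PhantomSpec:
    """Geometry, intensity, and noise settings for the synthetic head.

    Intensities are CT-like arbitrary units ordered
    electrode > skull > brain > background; the default noise standard
    deviation is 2% of the electrode intensity.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    voxel_mm: float = 1.0
    brain_radii_mm: tuple[float, float, float] = (55.0, 65.0, 50.0)
    mask_margin_mm: float = 2.0       # brain mask extends this far beyond the pial
    skull_gap_mm: float = 2.0         # gap between brain mask and inner skull
    skull_thickness_mm: float = 3.0
    background: float = 0.0
    brain_intensity: float = 40.0
    skull_intensity: float = 1200.0
    electrode_intensity: float = 3000.0
    noise_sigma: float = 60.0         # additive Gaussian on the CT
    t1_brain: float = 110.0
    t1_skull: float = 20.0
    t1_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.electrode_intensity > self.skull_intensity
                > self.brain_intensity > self.background):
            raise ValueError("intensities must be ordered "
                             "electrode > skull > brain > background")

    @property
    def affine(self) -> np.ndarray:
        """Isotropic voxel->world affine with the world origin at grid center."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_mm
        aff[:3, 3] = -self.voxel_mm * (np.asarray(self.shape) - 1) / 2.0
        return aff


@dataclass
class GroundTruth:
    """True contact geometry for a phantom implant.

    ``centers`` maps electrode name -> (n, 3) world-mm contact centers,
    ordered deep -> superficial for depth electrodes and row-major for grids.
    """

    kind: str                                   # "seeg" | "ecog"
    centers: dict[str, np.ndarray]
    grid_shape: tuple[int, int] | None = None
    pitch_mm: float | None = None
    surface_centers: dict[str, np.ndarray] | None = None   # ECoG, pre-shift
    trajectories: dict[str, dict] | None = None            # SEEG geometry

    @property
    def names(self) -> list[str]:
        return list(self.centers)

    def all_centers(self) -> np.ndarray:
        return np.vstack([self.centers[n] for n in self.centers])

    @property
    def n_contacts(self) -> int:
        return sum(len(c) for c in self.centers.values())


@dataclass
class PhantomHead:
    t1: Volume3D
    brain_mask: Volume3D
    parcellation: Volume3D
    lut: LabelLUT
    pial: SurfaceMesh
    smoothed_pial: SurfaceMesh
    spec: PhantomSpec
    _cache: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _world_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    aff = spec.affine
    ax = [aff[i, i] * np.arange(spec.shape[i]) + aff[i, 3] for i in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid_mask(spec: PhantomSpec, radii, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    X, Y, Z = _world_grid(spec)
    r = np.asarray(radii, dtype=float)
    c = np.asarray(center, dtype=float)
    return ((X - c[0]) / r[0]) ** 2 + ((Y - c[1]) / r[1]) ** 2 \
        + ((Z - c[2]) / r[2]) ** 2 <= 1.0


# CSF-filled internal structures (ventricle-like), asymmetric on purpose so
# both modalities carry full 3-D orientation information
_CSF_BLOBS = [
    ((-14.0, 10.0, 6.0), (10.0, 16.0, 9.0)),
    ((14.0, 6.0, -4.0), (8.0, 12.0, 10.0)),
    ((2.0, -20.0, -12.0), (9.0, 7.0, 8.0)),
]


def _csf_mask(spec: PhantomSpec) -> np.ndarray:
    out = np.zeros(spec.shape, dtype=bool)
    for center, radii in _CSF_BLOBS:
        out |= _ellipsoid_mask(spec, radii, center)
    return out


def _project_to_ellipsoid(p: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Radially rescale ``p`` onto the ellipsoid surface."""
    s = np.sqrt(np.sum((p / radii) ** 2))
    return p / s


def _ellipsoid_normal(p: np.ndarray, radii: np.ndarray) -> np.ndarray:
    n = p / radii ** 2
    return n / np.linalg.norm(n)


def _laplacian_smooth(mesh: SurfaceMesh, passes: int, lam: float = 0.5) -> SurfaceMesh:
    """Uniform-weight Laplacian smoothing: v <- v + lam*(mean(neighbors) - v)."""
    if passes <= 0:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())
    n = len(mesh.vertices)
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                   mesh.faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    deg = np.bincount(e.ravel(), minlength=n).astype(float)
    deg[deg == 0] = 1.0
    verts = mesh.vertices.copy()
    for _ in range(passes):
        acc = np.zeros_like(verts)
        np.add.at(acc, e[:, 0], verts[e[:, 1]])
        np.add.at(acc, e[:, 1], verts[e[:, 0]])
        verts += lam * (acc / deg[:, None] - verts)
    return SurfaceMesh(verts, mesh.faces.copy())


# ---------------------------------------------------------------------------
# head construction
# ---------------------------------------------------------------------------

def make_head(spec: PhantomSpec, n_parcels: int = 6) -> PhantomHead:
    """Build the synthetic head: T1, brain mask, parcellation, pial surfaces.

    The brain mask is the pial ellipsoid plus a small margin (a skull-stripped
    mask normally keeps some CSF/dura); the skull shell starts a further
    ``skull_gap_mm`` out.
    """
    radii = np.asarray(spec.brain_radii_mm, dtype=float)
    mask_radii = radii + spec.mask_margin_mm
    skull_in = mask_radii + spec.skull_gap_mm
    skull_out = skull_in + spec.skull_thickness_mm
    half_extent = spec.voxel_mm * (np.asarray(spec.shape) - 1) / 2.0
    if np.any(skull_out >= half_extent):
        raise ValueError("brain radius + skull thickness exceed the grid")

    brain = _ellipsoid_mask(spec, radii)
    mask = _ellipsoid_mask(spec, mask_radii)
    shell = _ellipsoid_mask(spec, skull_out) & ~_ellipsoid_mask(spec, skull_in)
    vent = _csf_mask(spec)

    rng = np.random.default_rng(spec.seed)
    t1 = np.full(spec.shape, 0.0)
    t1[mask] = spec.t1_brain
    t1[vent & mask] = 30.0
    t1[shell] = spec.t1_skull
    t1 += rng.normal(0.0, spec.t1_noise_sigma, spec.shape)

    # Voronoi parcellation of the brain interior from seeded points
    prng = np.random.default_rng(spec.seed + 1)
    seeds = prng.uniform(-0.6, 0.6, size=(n_parcels, 3)) * radii
    X, Y, Z = _world_grid(spec)
    pts = np.stack([X[brain], Y[brain], Z[brain]], axis=1)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    parc = np.zeros(spec.shape, dtype=np.int32)
    parc[brain] = np.argmin(d2, axis=1) + 1
    lut = LabelLUT({0: ("unknown", (0, 0, 0)),
                    **{i + 1: (f"region-{i + 1}",
                               tuple(int(c) for c in prng.integers(40, 255, 3)))
                       for i in range(n_parcels)}})

    aff = spec.affine
    verts, faces, _, _ = measure.marching_cubes(
        ndimage.gaussian_filter(brain.astype(float), 1.0), level=0.5)
    pial = SurfaceMesh(verts * spec.voxel_mm + aff[:3, 3],
                       faces).drop_degenerate_faces()
    smoothed = _laplacian_smooth(pial, passes=10)

    return PhantomHead(
        t1=Volume3D(t1, aff),
        brain_mask=Volume3D(mask.astype(np.uint8), aff),
        parcellation=Volume3D(parc, aff),
        lut=lut,
        pial=pial,
        smoothed_pial=smoothed,
        spec=spec,
    )


def _base_ct(head: PhantomHead) -> np.ndarray:
    spec = head.spec
    if "base_ct" not in head._cache:
        radii = np.asarray(spec.brain_radii_mm) + spec.mask_margin_mm
        skull_in = radii + spec.skull_gap_mm
        skull_out = skull_in + spec.skull_thickness_mm
        in_mask = _ellipsoid_mask(spec, radii)
        ct = np.full(spec.shape, spec.background)
        ct[in_mask] = spec.brain_intensity
        ct[_csf_mask(spec) & in_mask] = 5.0   # CSF visible in CT too
        ct[_ellipsoid_mask(spec, skull_out)
           & ~_ellipsoid_mask(spec, skull_in)] = spec.skull_intensity
        head._cache["base_ct"] = ct
    return head._cache["base_ct"].copy()


# ---------------------------------------------------------------------------
# electrode painting
# ---------------------------------------------------------------------------

_SUB = None


def _suboffsets() -> np.ndarray:
    global _SUB
    if _SUB is None:
        q = (np.arange(4) + 0.5) / 4 - 0.5          # 4 sub-samples per voxel edge
        _SUB = np.stack(np.meshgrid(q, q, q, indexing="ij"), -1).reshape(-1, 3)
    return _SUB


def _paint_cylinder(ct: np.ndarray, spec: PhantomSpec, center: np.ndarray,
                    axis: np.ndarray, radius: float, half_length: float,
                    knee: float = 0.25) -> None:
    """Add a metal cylinder by partial-volume coverage with saturation.

    Voxel intensity = electrode_intensity * min(1, coverage/knee), combined
    with the existing image by maximum.
    """
    aff = spec.affine
    vox = spec.voxel_mm
    axis = axis / np.linalg.norm(axis)
    reach = half_length + radius + vox
    lo = np.floor((center - reach - aff[:3, 3]) / vox).astype(int)
    hi = np.ceil((center + reach - aff[:3, 3]) / vox).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(spec.shape))
    if np.any(hi <= lo):
        return
    idx = np.stack(np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                               indexing="ij"), -1).reshape(-1, 3)
    sub = _suboffsets()
    pts = (idx[:, None, :] + sub[None, :, :]) * vox + aff[:3, 3]  # (n, 64, 3)
    rel = pts - center
    ax = rel @ axis
    rad2 = np.einsum("ijk,ijk->ij", rel, rel) - ax ** 2
    inside = (np.abs(ax) <= half_length) & (rad2 <= radius ** 2)
    cov = inside.mean(axis=1)
    val = spec.electrode_intensity * np.minimum(1.0, cov / knee)
    sl = (idx[:, 0], idx[:, 1], idx[:, 2])
    ct[sl] = np.maximum(ct[sl], val)


# ---------------------------------------------------------------------------
# depth electrodes
# ---------------------------------------------------------------------------

def _seeg_trajectory(entry: np.ndarray, direction: np.ndarray, length: float,
                     bend_magnitude: float, bend_normal: np.ndarray):
    """Return p(s), tangent(s) for s in [0, length] mm from the entry.

    The bend is a quadratic perpendicular offset, zero at both ends and
    ``bend_magnitude`` (the sagitta) at mid-length.
    """
    d = direction / np.linalg.norm(direction)
    n = bend_normal - (bend_normal @ d) * d
    n = n / np.linalg.norm(n) if np.linalg.norm(n) > 1e-12 else np.zeros(3)

    def pos(s):
        s = np.asarray(s, dtype=float)
        u = s / length
        off = bend_magnitude * 4.0 * u * (1.0 - u)
        return entry + np.outer(s, d).reshape(s.shape + (3,)) \
            + np.multiply.outer(off, n)

    def tan(s):
        s = np.asarray(s, dtype=float)
        doff = bend_magnitude * 4.0 * (1.0 - 2.0 * s / length) / length
        t = d + np.multiply.outer(doff, n)
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    return pos, tan


def _cap_directions(n: int, rng: np.random.Generator,
                    cap_deg: float = 42.0) -> np.ndarray:
    """n outward unit directions spread over a polar cap around +z."""
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    golden = np.pi * (3.0 - np.sqrt(5.0))
    ks = np.arange(n)
    polar = np.deg2rad(cap_deg) * np.sqrt((ks + 0.5) / n)
    azim = ks * golden + rng.uniform(0, 2 * np.pi)
    return np.stack([np.sin(polar) * np.cos(azim),
                     np.sin(polar) * np.sin(azim),
                     np.cos(polar)], axis=1)


def implant_seeg(head: PhantomHead, n_electrodes: int = 1,
                 contacts_per_electrode: int = 8, bend_magnitude: float = 0.0,
                 noise_sigma: float | None = None,
                 contact_length: float = 2.0, contact_diameter: float = 0.8,
                 spacing: float = 3.5) -> tuple[Volume3D, GroundTruth]:
    """Implant depth electrodes and return the post-op CT plus ground truth.

    Each electrode enters through the skull roughly radially, its deepest
    contact sitting ``(contacts-1) * spacing + 3 mm`` along the (possibly
    bent) trajectory.  Contact centers are exactly ``spacing`` mm apart in
    arc length.
    """
    spec = head.spec
    sigma = spec.noise_sigma if noise_sigma is None else noise_sigma
    radii = np.asarray(spec.brain_radii_mm, dtype=float)
    rng = np.random.default_rng(spec.seed + 2)
    dirs = _cap_directions(n_electrodes, rng)

    length = (contacts_per_electrode - 1) * spacing + 6.0
    ct = _base_ct(head)
    centers: dict[str, np.ndarray] = {}
    trajectories: dict[str, dict] = {}
    for k, u in enumerate(dirs):
        name = f"E{k + 1}"
        entry = _project_to_ellipsoid(u * radii.max(), radii)
        inward = -_ellipsoid_normal(entry, radii)
        bend_n = np.cross(inward, [0.0, 1.0, 0.0])
        if np.linalg.norm(bend_n) < 1e-6:
            bend_n = np.cross(inward, [1.0, 0.0, 0.0])
        pos, tan = _seeg_trajectory(entry, inward, length, bend_magnitude, bend_n)
        # deepest contact near the tip; order contacts deep -> superficial
        s_deep = length - 3.0
        svals = s_deep - spacing * np.arange(contacts_per_electrode)
        if np.any(svals < -1.0):
            raise ValueError("trajectory too short for contact count")
        pts = pos(svals)
        tangents = tan(svals)
        centers[name] = pts
        trajectories[name] = {"entry": entry, "direction": inward,
                              "length": length, "bend": bend_magnitude,
                              "bend_normal": bend_n}
        for c, t in zip(pts, tangents):
            _paint_cylinder(ct, spec, c, t, contact_diameter / 2.0,
                            contact_length / 2.0)

    _check_separation(centers, min_dist=2.0)
    if sigma > 0:
        ct += np.random.default_rng(spec.seed + 3).normal(0.0, sigma, spec.shape)
    truth = GroundTruth(kind="seeg", centers=centers, trajectories=trajectories)
    return Volume3D(ct, spec.affine), truth


def _check_separation(centers: dict[str, np.ndarray], min_dist: float) -> None:
    names = list(centers)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = centers[names[i]], centers[names[j]]
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            if d.min() < min_dist:
                raise ValueError(
                    f"electrodes {names[i]} and {names[j]} come within "
                    f"{d.min():.2f} mm (< {min_dist} mm)")


# ---------------------------------------------------------------------------
# subdural grids
# ---------------------------------------------------------------------------

def _march_on_surface(p: np.ndarray, t: np.ndarray, dist: float,
                      radii: np.ndarray, step: float = 1.0):
    """Walk ``dist`` mm along the ellipsoid surface from p in direction t.

    Returns the end point and the parallel-transported tangent.
    """
    sgn = np.sign(dist) if dist != 0 else 1.0
    remaining = abs(dist)
    t = t / np.linalg.norm(t)
    while remaining > 1e-9:
        h = min(step, remaining)
        p = _project_to_ellipsoid(p + sgn * h * t, radii)
        n = _ellipsoid_normal(p, radii)
        t = t - (t @ n) * n
        t = t / np.linalg.norm(t)
        remaining -= h
    return p, t


def implant_ecog(head: PhantomHead, rows: int = 4, cols: int = 5,
                 pitch: float = 10.0, inward_shift_mm: float = 0.0,
                 noise_sigma: float | None = None,
                 disk_diameter: float = 4.0, disk_thickness: float = 1.4,
                 ) -> tuple[Volume3D, GroundTruth]:
    """Implant a rows x cols subdural grid on the pial surface.

    Contacts are metal disks placed by marching along the ellipsoidal pial at
    the given pitch.  ``inward_shift_mm`` emulates post-implant brain shift:
    contacts are displaced along the inward normal by a linear ramp from 0 at
    the first column to the full shift at the last column.
    """
    spec = head.spec
    sigma = spec.noise_sigma if noise_sigma is None else noise_sigma
    radii = np.asarray(spec.brain_radii_mm, dtype=float)
    extent = max(rows, cols) * pitch
    if extent > 0.7 * np.pi / 2.0 * radii.min():
        raise ValueError("grid larger than the available surface patch")

    pole = _project_to_ellipsoid(np.array([0.0, 0.0, radii[2]]), radii)
    n0 = _ellipsoid_normal(pole, radii)
    e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 - (e1 @ n0) * n0
    e1 /= np.linalg.norm(e1)

    surface_pts = np.zeros((rows, cols, 3))
    normals = np.zeros((rows, cols, 3))
    for i in range(rows):
        off_r = (i - (rows - 1) / 2.0) * pitch
        p_row, t_row = _march_on_surface(pole, e1, off_r, radii)
        n_row = _ellipsoid_normal(p_row, radii)
        e2 = np.cross(n_row, t_row)
        for j in range(cols):
            off_c = (j - (cols - 1) / 2.0) * pitch
            p, _ = _march_on_surface(p_row, e2, off_c, radii)
            surface_pts[i, j] = p
            normals[i, j] = _ellipsoid_normal(p, radii)

    shift = np.zeros((rows, cols))
    if cols > 1 and inward_shift_mm:
        shift = np.tile(inward_shift_mm * np.arange(cols) / (cols - 1), (rows, 1))
    pts = surface_pts - shift[..., None] * normals

    ct = _base_ct(head)
    for i in range(rows):
        for j in range(cols):
            _paint_cylinder(ct, spec, pts[i, j], normals[i, j],
                            disk_diameter / 2.0, disk_thickness / 2.0)
    if sigma > 0:
        ct += np.random.default_rng(spec.seed + 4).normal(0.0, sigma, spec.shape)

    truth = GroundTruth(
        kind="ecog",
        centers={"G": pts.reshape(-1, 3)},
        grid_shape=(rows, cols),
        pitch_mm=pitch,
        surface_centers={"G": surface_pts.reshape(-1, 3)},
    )
    return Volume3D(ct, spec.affine), truth
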