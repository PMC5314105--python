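"""Depth-electrode (SEEG) segmentation and contact tracking.

Stages, in pipeline order:

1. :func:`erode_mask` — erode the brain mask by a physical depth (default
   4 mm) and multiply with the coregistered CT, cutting off the outer skull.
2. threshold + connected components (``clusters`` module) on the masked CT.
3. :func:`assign_clusters` — map clusters to named electrodes (the
   programmatic stand-in for the interactive cluster picker); an optional
   threshold re-adjustment first separates touching electrodes.
4. :func:`fit_trajectory` — per-axis polynomial (default cubic) of the
   electrode's voxels against their principal-axis projection, resampled as
   equally spaced dots along arc length.
5. :func:`find_start` — of the two farthest trajectory endpoints, the one
   deeper inside the brain mask is the starting (deepest) point.
6. :func:`track_contacts` — walk from the start in fixed 3.5 mm arc-length
   steps, refining each contact by an intensity-weighted centroid within a
   small radius, rejecting refinements that bend the track beyond a maximum
   axis deviation, and padding missing superficial contacts along the fitted
   curve until the predefined contact count is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .clusters import ClusterSet, connected_components, threshold_volume
from .contacts import Contact, ElectrodeSet
from .volumes import Volume3D, voxel_to_world, world_to_voxel


@dataclass
class SeegSegConfig:
    """Tunable parameters of the depth-electrode pipeline.

    ``contact_spacing`` is the fixed center-to-center distance of DIXI-style
    depth contacts: 2 mm contact length + 1.5 mm gap = 3.5 mm.
    """

    erode_mm: float = 4.0
    threshold: float | None = None        # None -> Otsu on in-mask intensities
    poly_order: int = 3
    dot_spacing: float = 0.1              # mm between resampled trajectory dots
    contact_spacing: float = 3.5          # mm between contact centers
    refine_radius: float = 1.5            # mm, centroid refinement ball
    max_axis_deviation_deg: float = 10.0
    spacing_tolerance_mm: float = 0.35    # allowed |spacing - 3.5| after refine
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.poly_order not in (1, 2, 3, 4):
            raise ValueError("poly_order must be in 1..4")
        if self.dot_spacing <= 0 or self.contact_spacing <= 0:
            raise ValueError("spacings must be positive")


# ---------------------------------------------------------------------------
# mask erosion
# ---------------------------------------------------------------------------

def erode_mask(brain_mask: Volume3D, depth_mm: float) -> Volume3D:
    """Erode a binary mask by a physical depth (exact Euclidean erosion).

    A voxel survives iff its distance to the nearest background voxel is at
    least ``depth_mm``; depth 0 returns the mask unchanged.
    """
    if depth_mm < 0:
        raise ValueError("erosion depth must be >= 0")
    mask = brain_mask.data > 0
    if depth_mm == 0:
        return Volume3D(mask.astype(np.uint8), brain_mask.affine.copy())
    dt = ndimage.distance_transform_edt(mask, sampling=brain_mask.voxel_sizes)
    out = (dt >= depth_mm) & mask
    if not out.any():
        raise ValueError(f"eroding by {depth_mm} mm left an empty mask")
    return Volume3D(out.astype(np.uint8), brain_mask.affine.copy())


def masked_ct(ct_in_t1: Volume3D, brain_mask: Volume3D,
              erode_mm: float = 4.0) -> Volume3D:
    """CT multiplied by the eroded brain mask."""
    er = erode_mask(brain_mask, erode_mm)
    return Volume3D(ct_in_t1.data * (er.data > 0), ct_in_t1.affine.copy())


def default_threshold(vol_masked: Volume3D, cfg: SeegSegConfig) -> float:
    """Threshold rule used when none is supplied: Otsu between tissue and
    metal, floored at the midpoint between the in-mask median and maximum
    (metal occupies far too few voxels for a percentile rule)."""
    if cfg.threshold is not None:
        return cfg.threshold
    vals = vol_masked.data[vol_masked.data != 0].astype(float)
    if vals.size == 0:
        raise ValueError("masked CT is empty")
    from skimage.filters import threshold_otsu
    tau = float(threshold_otsu(vals))
    floor = 0.5 * (float(np.median(vals)) + float(vals.max()))
    return max(tau, floor)


# ---------------------------------------------------------------------------
# cluster -> electrode assignment
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeClusterMap:
    """Per-electrode voxel sets after cluster selection, in display order."""

    electrodes: dict[str, dict]   # name -> {points (n,3) world, intensities (n,)}
    order: list[str]

    def reorder(self, order: list[str]) -> None:
        if set(order) != set(self.electrodes):
            raise ValueError("order must permute the electrode names")
        self.order = list(order)


def assign_clusters(clusters: ClusterSet, assignment: dict[str, list[int]],
                    vol_masked: Volume3D | None = None,
                    new_tau: float | None = None,
                    cfg: SeegSegConfig | None = None) -> ElectrodeClusterMap:
    """Select and merge clusters into named electrodes.

    ``assignment`` maps electrode name -> cluster ids; unassigned clusters
    are dropped.  If ``new_tau`` is given the masked CT is re-thresholded
    and re-clustered first (the instant threshold adjustment that separates
    near or crossing electrodes), and the ids refer to the new clustering.
    """
    if not assignment:
        raise ValueError("empty assignment")
    cfg = cfg or SeegSegConfig()
    if new_tau is not None:
        if vol_masked is None:
            raise ValueError("re-thresholding requires the masked CT")
        clusters = connected_components(
            threshold_volume(vol_masked, new_tau), intensity=vol_masked,
            connectivity=cfg.connectivity)
    used: dict[int, str] = {}
    for name, ids in assignment.items():
        for cid in ids:
            if cid in used:
                raise ValueError(
                    f"cluster {cid} assigned to both {used[cid]!r} and {name!r}")
            used[cid] = name
    vol = clusters.reference
    electrodes: dict[str, dict] = {}
    for name, ids in assignment.items():
        vox = np.vstack([clusters[cid].voxels for cid in ids])
        pts = voxel_to_world(vol, vox.astype(float))
        inten = np.asarray(vol.data[vox[:, 0], vox[:, 1], vox[:, 2]], float)
        electrodes[name] = {"points": pts, "intensities": inten}
    return ElectrodeClusterMap(electrodes, list(assignment))


def group_clusters_by_proximity(clusters: ClusterSet,
                                link_mm: float = 6.0,
                                prefix: str = "E") -> dict[str, list[int]]:
    """Automatic assignment for well-separated electrodes.

    Single-linkage grouping on the minimum voxel-to-voxel distance between
    clusters: clusters closer than ``link_mm`` belong to the same electrode.
    The default bridges one missing contact (a 7 mm center gap) while
    staying well below typical inter-electrode separations.  This is the
    programmatic counterpart of picking clusters interactively; close or
    crossing electrodes still need an explicit assignment.
    """
    vol = clusters.reference
    pts = [voxel_to_world(vol, c.voxels.astype(float)) for c in clusters]
    n = len(clusters)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(pts[i][:, None, :] - pts[j][None, :, :], axis=2)
            if d.min() < link_mm:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(clusters):
        groups.setdefault(find(i), []).append(c.id)
    ordered = sorted(groups.values(), key=lambda ids: min(ids))
    return {f"{prefix}{k + 1}": ids for k, ids in enumerate(ordered)}


# ---------------------------------------------------------------------------
# trajectory fitting
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryCurve:
    """Per-axis polynomial of a normalized axial parameter, plus dots.

    ``dots`` are equally spaced (arc length) points covering the fitted
    extent, ordered along the parameter; after :func:`find_start`, dot 0 is
    the deepest point.  ``coeffs`` has shape (order+1, 3) in numpy
    polynomial (ascending-power) convention.
    """

    coeffs: np.ndarray
    dots: np.ndarray
    dot_spacing: float
    rms_residual: float
    oriented: bool = False
    _deep_at_t0: bool = field(default=True, repr=False)

    def eval(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        powers = np.stack([t ** k for k in range(len(self.coeffs))])
        return np.tensordot(powers, self.coeffs, axes=(0, 0))

    @property
    def start(self) -> np.ndarray:
        return self.dots[0]

    @property
    def end(self) -> np.ndarray:
        return self.dots[-1]

    def extended_dots(self, margin_mm: float) -> np.ndarray:
        """Dots continued past the last one by extrapolating the polynomial
        at the same arc-length spacing (used for padding and for finding the
        surface crossing beyond the fitted extent)."""
        extra = _resample_arclength(self, t0=self._t_at_end(),
                                    direction=+1, total_mm=margin_mm)
        return np.vstack([self.dots, extra[1:]])

    def _t_at_end(self) -> float:
        return 0.0 if (self.oriented and not self._deep_at_t0) else 1.0

    def _t_direction_superficialward(self) -> float:
        return -1.0 if (self.oriented and not self._deep_at_t0) else 1.0


def _resample_arclength(traj: TrajectoryCurve, t0: float, direction: float,
                        total_mm: float) -> np.ndarray:
    """Walk the polynomial from parameter t0 in +/- t direction, emitting
    points every ``traj.dot_spacing`` mm of arc length."""
    sgn = traj._t_direction_superficialward() if direction == +1 else 1.0
    h = traj.dot_spacing
    pts = [traj.eval(t0)]
    t = t0
    travelled = 0.0
    # derivative step in t chosen from local speed
    while travelled < total_mm:
        d = _poly_speed(traj.coeffs, t)
        dt = sgn * h / max(d, 1e-9)
        t = t + dt
        pts.append(traj.eval(t))
        travelled += h
    return np.asarray(pts)


def _poly_speed(coeffs: np.ndarray, t: float) -> float:
    order = len(coeffs) - 1
    dv = np.zeros(3)
    for k in range(1, order + 1):
        dv += k * coeffs[k] * t ** (k - 1)
    return float(np.linalg.norm(dv))


def _centerline_residual(pts: np.ndarray, t: np.ndarray,
                         w: np.ndarray | None, coeffs: np.ndarray) -> float:
    """RMS distance from the curve to the electrode centerline.

    The voxel cloud is binned along the fit parameter; each bin's
    (intensity-weighted) centroid estimates the local centerline, and the
    residual is the RMS offset of those centroids from the curve.  Using
    raw voxels instead would report the cylinder's radial spread, not the
    fit quality.
    """
    weights = np.ones(len(pts)) if w is None else np.asarray(w, float)
    nbins = int(np.clip(len(pts) // 10, 4, 20))
    edges = np.linspace(0.0, 1.0 + 1e-9, nbins + 1)
    which = np.digitize(t, edges) - 1
    sq, tot = 0.0, 0.0
    for b in range(nbins):
        sel = which == b
        if not sel.any():
            continue
        wb = weights[sel]
        cen = (pts[sel] * wb[:, None]).sum(axis=0) / wb.sum()
        tb = (t[sel] * wb).sum() / wb.sum()
        on_curve = np.array(
            [np.polynomial.polynomial.polyval(tb, coeffs[:, ax])
             for ax in range(3)])
        sq += wb.sum() * float(np.sum((cen - on_curve) ** 2))
        tot += wb.sum()
    return float(np.sqrt(sq / tot)) if tot > 0 else 0.0


def fit_trajectory(points: np.ndarray, intensities: np.ndarray | None = None,
                   order: int = 3, dot_spacing: float = 0.1) -> TrajectoryCurve:
    """Least-squares polynomial trajectory through an electrode's voxels.

    The fit parameter is the projection of each point onto the cluster's
    principal axis, rescaled to [0, 1]; each world axis is fitted separately
    (optionally intensity-weighted).  Dots are resampled at uniform arc
    length by numerically inverting the arc-length integral.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < order + 1:
        raise ValueError(f"need at least {order + 1} points for order {order}")
    centered = pts - pts.mean(axis=0)
    if np.linalg.norm(centered, axis=1).max() < 1e-9:
        raise ValueError("degenerate electrode: all points coincide")
    # principal axis from the covariance of the (optionally weighted) cloud
    w = None if intensities is None else np.asarray(intensities, float)
    cov = np.cov(centered.T, aweights=w)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    t = centered @ axis
    tmin, tmax = t.min(), t.max()
    if tmax - tmin < 1e-9:
        raise ValueError("degenerate electrode: zero extent along axis")
    t = (t - tmin) / (tmax - tmin)

    coeffs = np.empty((order + 1, 3))
    for ax in range(3):
        coeffs[:, ax] = np.polynomial.polynomial.polyfit(t, pts[:, ax], order,
                                                         w=w)
    rms = _centerline_residual(pts, t, w, coeffs)

    # uniform arc-length resampling over t in [0, 1]
    tt = np.linspace(0.0, 1.0, 4001)
    curve = np.polynomial.polynomial.polyval(tt, coeffs).T
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n_dots = max(2, int(np.floor(total / dot_spacing)) + 1)
    s_targets = np.arange(n_dots) * dot_spacing
    s_targets = s_targets[s_targets <= total + 1e-12]
    t_of_s = np.interp(s_targets, arc, tt)
    dots = np.polynomial.polynomial.polyval(t_of_s, coeffs).T
    return TrajectoryCurve(coeffs=coeffs, dots=dots, dot_spacing=dot_spacing,
                           rms_residual=rms)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def find_start(traj: TrajectoryCurve, brain_mask: Volume3D) -> TrajectoryCurve:
    """Orient the trajectory so dot 0 is the deepest endpoint.

    Depth is the endpoint's distance to the brain-mask boundary (Euclidean
    distance transform, interpolated at the endpoint's position).
    """
    if len(traj.dots) < 2:
        raise ValueError("trajectory needs at least 2 dots")
    dt = ndimage.distance_transform_edt(brain_mask.data > 0,
                                        sampling=brain_mask.voxel_sizes)
    ends = np.vstack([traj.dots[0], traj.dots[-1]])
    vox = world_to_voxel(brain_mask, ends)
    depths = ndimage.map_coordinates(dt, vox.T, order=1, mode="constant",
                                     cval=0.0)
    if np.all(depths <= 0):
        raise ValueError("both trajectory endpoints lie outside the brain "
                         "mask (electrode fully stripped)")
    flip = depths[1] > depths[0]
    dots = traj.dots[::-1].copy() if flip else traj.dots.copy()
    return TrajectoryCurve(coeffs=traj.coeffs.copy(), dots=dots,
                           dot_spacing=traj.dot_spacing,
                           rms_residual=traj.rms_residual, oriented=True,
                           _deep_at_t0=not flip)


# ---------------------------------------------------------------------------
# contact tracking
# ---------------------------------------------------------------------------

def _refine_centroid(ct: Volume3D, point: np.ndarray, radius: float,
                     iterations: int = 3) -> tuple[np.ndarray, float]:
    """Iterated intensity-weighted center of mass within ``radius`` mm.

    Re-centering the ball a few times removes the bias a single pass keeps
    when the seed sits off the contact center and the ball covers the metal
    cylinder asymmetrically.  Returns (center, peak intensity in the final
    ball)."""
    peak = 0.0
    for _ in range(iterations):
        new, peak = _centroid_once(ct, point, radius)
        if np.linalg.norm(new - point) < 1e-6:
            point = new
            break
        point = new
    return np.asarray(point, float), peak


def _centroid_once(ct: Volume3D, point: np.ndarray,
                   radius: float) -> tuple[np.ndarray, float]:
    vs = ct.voxel_sizes
    ctr = world_to_voxel(ct, point)
    lo = np.maximum(np.floor(ctr - radius / vs).astype(int), 0)
    hi = np.minimum(np.ceil(ctr + radius / vs).astype(int) + 1,
                    np.asarray(ct.shape))
    if np.any(hi <= lo):
        return point.copy(), 0.0
    idx = np.stack(np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                               indexing="ij"), -1).reshape(-1, 3)
    world = voxel_to_world(ct, idx.astype(float))
    inside = np.linalg.norm(world - point, axis=1) <= radius
    if not inside.any():
        return point.copy(), 0.0
    idx, world = idx[inside], world[inside]
    w = np.maximum(np.asarray(
        ct.data[idx[:, 0], idx[:, 1], idx[:, 2]], float), 0.0)
    peak = float(w.max()) if w.size else 0.0
    if w.sum() <= 0:
        return point.copy(), peak
    return (world * w[:, None]).sum(axis=0) / w.sum(), peak


def track_contacts(traj: TrajectoryCurve, ct: Volume3D, cfg: SeegSegConfig,
                   count: int, electrode: str = "E1",
                   support_threshold: float | None = None) -> list[Contact]:
    """Track ``count`` contact centers deep -> superficial along a trajectory.

    The first contact is the refined centroid at the deepest dot; each next
    contact is seeded ``cfg.contact_spacing`` mm of arc length beyond the
    previous accepted center and refined the same way.  A refined center is
    rejected (the seed is kept) when the turn between successive
    inter-contact vectors exceeds ``cfg.max_axis_deviation_deg``.  Once the
    bright support ends, remaining centers are extrapolated along the fitted
    curve and flagged ``padded``.
    """
    if not traj.oriented:
        raise ValueError("trajectory must be oriented with find_start first")
    if count < 1:
        raise ValueError("contact count must be >= 1")
    # pool of walkable dots: fitted extent plus extrapolation reserve
    margin = cfg.contact_spacing * (count + 1)
    dots = traj.extended_dots(margin)
    if support_threshold is None:
        samp = _sample_along(ct, traj.dots)
        support_threshold = 0.25 * float(np.nanmax(samp)) if samp.size else 0.0

    step = int(round(cfg.contact_spacing / cfg.dot_spacing))
    if step < 1:
        raise ValueError("contact spacing below dot spacing")
    records: list[Contact] = []
    centers: list[np.ndarray] = []
    cursor = 0  # dot index of the previous accepted center's projection
    for k in range(count):
        if k == 0:
            seed_idx = 0
        else:
            cursor = _nearest_dot(dots, centers[-1], near=cursor)
            seed_idx = cursor + step
        if seed_idx >= len(dots):
            raise ValueError(
                f"electrode {electrode}: contact {k + 1} of {count} falls "
                "beyond the trajectory's reach inside the volume")
        seed = dots[seed_idx]
        refined, peak = _refine_centroid(ct, seed, cfg.refine_radius)
        padded = peak < support_threshold
        center = seed if padded else refined
        if not padded and len(centers) >= 1:
            # constraint 1: the fixed inter-contact center distance; a
            # refinement that breaks it (e.g. a contact truncated by the
            # mask pulling its centroid) is rejected for the curve seed
            gap = np.linalg.norm(center - centers[-1])
            if abs(gap - cfg.contact_spacing) > cfg.spacing_tolerance_mm:
                center = seed
        if not padded and len(centers) >= 2:
            # constraint 2: axis deviation along the trajectory stays under
            # the predefined level
            v_prev = centers[-1] - centers[-2]
            v_new = center - centers[-1]
            ang = _angle_deg(v_prev, v_new)
            if ang > cfg.max_axis_deviation_deg:
                center = seed  # curve seed wins over a deviating refinement
        centers.append(np.asarray(center, float))
        records.append(Contact(electrode, k + 1, np.asarray(center, float),
                               padded=padded))
    return records


def _sample_along(ct: Volume3D, pts: np.ndarray) -> np.ndarray:
    vox = world_to_voxel(ct, pts)
    return ndimage.map_coordinates(ct.data.astype(float), vox.T, order=1,
                                   mode="constant", cval=0.0)


def _nearest_dot(dots: np.ndarray, point: np.ndarray, near: int,
                 window: int = 400) -> int:
    lo = max(0, near - window)
    hi = min(len(dots), near + window)
    d = np.linalg.norm(dots[lo:hi] - point, axis=1)
    return lo + int(np.argmin(d))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        return 0.0
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def run_seeg(ct_in_t1: Volume3D, brain_mask: Volume3D, cfg: SeegSegConfig,
             contacts_per_electrode: dict[str, int] | int,
             assignment: dict[str, list[int]] | None = None,
             ) -> tuple[ElectrodeSet, dict]:
    """Full SEEG pipeline: erode + threshold + cluster + fit + track.

    ``assignment`` maps electrode names to cluster ids; if None, clusters
    are grouped automatically by proximity (well-separated electrodes only).
    ``contacts_per_electrode`` is the clinical contact count, either one
    integer for all electrodes or a per-name dict.
    """
    vol = masked_ct(ct_in_t1, brain_mask, cfg.erode_mm)
    tau = default_threshold(vol, cfg)
    clus = connected_components(threshold_volume(vol, tau), intensity=vol,
                                connectivity=cfg.connectivity)
    if len(clus) == 0:
        raise ValueError("no clusters above threshold in the masked CT")
    if assignment is None:
        assignment = group_clusters_by_proximity(clus)
    emap = assign_clusters(clus, assignment, vol_masked=vol, cfg=cfg)

    es = ElectrodeSet()
    info: dict = {"threshold": tau, "electrodes": {}}
    for name in emap.order:
        e = emap.electrodes[name]
        traj = fit_trajectory(e["points"], e["intensities"],
                              order=cfg.poly_order, dot_spacing=cfg.dot_spacing)
        traj = find_start(traj, brain_mask)
        n = (contacts_per_electrode if isinstance(contacts_per_electrode, int)
             else contacts_per_electrode[name])
        recs = track_contacts(traj, vol, cfg, n, electrode=name)
        es.contacts.extend(recs)
        info["electrodes"][name] = {"rms_residual": traj.rms_residual,
                                    "trajectory": traj}
    return es, info
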