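"""Reconstruction validation: surface-crossing points and the
pairwise-distance correlation statistic.

A depth electrode's superficial crossing point — where the reconstructed
trajectory pierces the pial surface — can be compared against ground truth
(on phantoms) or external evidence.  Consistency is measured by the Pearson
correlation between the two sets of pairwise Euclidean distances, which is
invariant to any rigid motion of either point set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .seeg import TrajectoryCurve
from .volumes import SurfaceMesh


@dataclass
class ValidationReport:
    true_points: np.ndarray
    reconstructed_points: np.ndarray
    true_distances: np.ndarray
    reconstructed_distances: np.ndarray
    correlation: float
    per_point_error_mm: np.ndarray
    mean_error_mm: float
    max_error_mm: float


def _moller_trumbore(origins: np.ndarray, dirs: np.ndarray,
                     tri: np.ndarray) -> np.ndarray:
    """Segment-triangle intersection parameters.

    Returns t (n_seg, n_tri): the ray parameter of the hit, inf if none.
    ``dirs`` are the full segment vectors, so a hit within the segment has
    t in [0, 1].
    """
    eps = 1e-12
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    t_out = np.full((len(origins), len(tri)), np.inf)
    for i, (o, d) in enumerate(zip(origins, dirs)):
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o - v0
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = np.einsum("ij,j->i", q, d) * inv
        t = np.einsum("ij,ij->i", q, e2) * inv
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
        t_out[i] = np.where(hit, t, np.inf)
    return t_out


def surface_crossing(traj: TrajectoryCurve, pial: SurfaceMesh,
                     margin_mm: float = 30.0) -> np.ndarray | None:
    """First intersection of the oriented trajectory with the pial surface,
    walking from the deep end superficial-ward over the resampled dots
    (extended past the fitted extent so the crossing is reachable).

    Returns None when the trajectory never pierces the mesh.
    """
    if not traj.oriented:
        raise ValueError("trajectory must be oriented (run find_start)")
    dots = traj.extended_dots(margin_mm)
    # coarse sub-sampling of the dot chain keeps the segment count modest
    stride = max(1, int(round(0.5 / traj.dot_spacing)))
    pts = np.vstack([dots[::stride], dots[-1]])
    origins = pts[:-1]
    dirs = np.diff(pts, axis=0)
    # prune faces far from the polyline bounding box
    tri = pial.vertices[pial.faces]
    lo = pts.min(axis=0) - 2.0
    hi = pts.max(axis=0) + 2.0
    near = np.all((tri.max(axis=1) >= lo) & (tri.min(axis=1) <= hi), axis=1)
    if not near.any():
        return None
    t = _moller_trumbore(origins, dirs, tri[near])
    t[t < 0] = np.inf
    t[t > 1] = np.inf
    seg_best = t.min(axis=1)
    hits = np.where(np.isfinite(seg_best))[0]
    if hits.size == 0:
        return None
    i = hits[0]
    return origins[i] + seg_best[i] * dirs[i]


def surface_crossings(trajectories: dict[str, TrajectoryCurve],
                      pial: SurfaceMesh) -> tuple[dict[str, np.ndarray],
                                                  list[str]]:
    """Crossing point per electrode; electrodes with no crossing are flagged
    and excluded."""
    points: dict[str, np.ndarray] = {}
    flagged: list[str] = []
    for name, traj in trajectories.items():
        p = surface_crossing(traj, pial)
        if p is None:
            flagged.append(name)
        else:
            points[name] = p
    return points, flagged


def distance_correlation_report(true_points: np.ndarray,
                                reconstructed_points: np.ndarray,
                                ) -> ValidationReport:
    """Pearson correlation of matched pairwise distances plus point errors."""
    tp = np.atleast_2d(np.asarray(true_points, float))
    rp = np.atleast_2d(np.asarray(reconstructed_points, float))
    if tp.shape != rp.shape:
        raise ValueError("point sets must have matching shapes")
    if len(tp) < 3:
        raise ValueError("need at least 3 points (3 distance pairs)")
    dt = pdist(tp)
    dr = pdist(rp)
    r = float(pearsonr(dt, dr)[0])
    err = np.linalg.norm(tp - rp, axis=1)
    return ValidationReport(
        true_points=tp, reconstructed_points=rp,
        true_distances=dt, reconstructed_distances=dr,
        correlation=r, per_point_error_mm=err,
        mean_error_mm=float(err.mean()), max_error_mm=float(err.max()))


def detection_rate(detected: np.ndarray, truth: np.ndarray,
                   tol_mm: float = 2.0) -> float:
    """Percentage of true contacts matched by a detected centroid within
    ``tol_mm``, under an optimal one-to-one assignment."""
    det = np.atleast_2d(np.asarray(detected, float))
    tru = np.atleast_2d(np.asarray(truth, float))
    if len(det) == 0 or len(tru) == 0:
        return 0.0
    from scipy.optimize import linear_sum_assignment
    d = np.linalg.norm(tru[:, None, :] - det[None, :, :], axis=2)
    # out-of-tolerance pairs all cost the same large amount, so the optimal
    # assignment maximizes the number of within-tolerance matches (ties
    # broken by total distance)
    big = tol_mm * (len(tru) + len(det)) * 1e3
    cost = np.where(d <= tol_mm, d, big)
    rows, cols = linear_sum_assignment(cost)
    matched = np.count_nonzero(d[rows, cols] <= tol_mm)
    return 100.0 * matched / len(tru)
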