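"""Subdural-grid (ECoG) segmentation and brain-shift correction.

Stages, in pipeline order:

1. :func:`dual_mask_strip` — the CT is masked twice, once by the basic
   skull-stripped brain mask and once by a slightly dilated copy; both
   masked images are thresholded and clustered, and any cluster whose voxel
   count differs between the two maskings (or that appears only under the
   dilated mask) must straddle the mask boundary into the skull and is
   removed.  Contacts, lying subdurally inside the mask, keep their size.
2. :func:`iterate_segmentation` — the threshold is raised geometrically
   until, after re-clustering and near-neighbor filtering, the cluster
   count lands within a tolerance band (default +/-5%) of the predefined
   contact count.
3. :func:`neighbor_filter` — clusters with fewer than 2 neighbors within
   15 mm are isolated tissue/noise, not part of a 10 mm-pitch array.
4. :func:`edit_contacts` — deterministic programmatic manual correction
   (add / remove / rename) with an audit log.
5. :func:`project_to_surface` — minimal-energy projection compensating
   post-implant brain shift: contacts move onto the smoothed pial surface
   while preserving their initial inter-contact distances as much as
   possible, then snap to the raw pial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .clusters import ClusterSet, connected_components, threshold_volume
from .contacts import Contact, ElectrodeSet, from_points
from .volumes import SurfaceMesh, Volume3D


@dataclass
class EcogSegConfig:
    """Parameters of the grid segmentation.

    The termination band is the published +/-5% rule; "slightly dilated"
    defaults to 2 voxel layers; the initial threshold is a high in-mask
    intensity percentile and grows by 5% per iteration (the method fixes
    only the direction of adjustment, upward).
    """

    n_target: int = 20
    dilation_layers: int = 2
    growth_factor: float = 1.05
    tolerance: float = 0.05
    neighbor_radius: float = 15.0
    min_neighbors: int = 2
    max_iterations: int = 100
    connectivity: int = 26
    size_diff_tol: float = 0.10   # relative size mismatch treated as "different"

    def __post_init__(self) -> None:
        if not (0 < self.tolerance < 0.5):
            raise ValueError("tolerance must be in (0, 0.5)")
        if self.growth_factor <= 1:
            raise ValueError("growth factor must exceed 1")


def _initial_threshold(values: np.ndarray) -> float:
    """Otsu split between tissue and bright structures (skull remnants,
    metal); deliberately permissive — the threshold iteration raises it."""
    from skimage.filters import threshold_otsu
    vals = np.asarray(values, float).ravel()
    if vals.size == 0 or vals.min() == vals.max():
        raise ValueError("cannot pick an initial threshold on a constant image")
    return float(threshold_otsu(vals))


@dataclass
class ProjectionConfig:
    alpha: float = 1.0            # weight of the displacement term
    max_iterations: int = 200
    tol: float = 1e-9
    k_candidates: int = 12        # candidate vertices examined per move

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


# ---------------------------------------------------------------------------
# dual-mask skull strip
# ---------------------------------------------------------------------------

def dual_mask_strip(ct_in_t1: Volume3D, brain_mask: Volume3D,
                    cfg: EcogSegConfig) -> tuple[ClusterSet, Volume3D, float]:
    """Remove skull clusters by comparing basic- and dilated-mask clusterings.

    Returns (candidate clusters, candidate CT restricted to their voxels,
    initial threshold).  The candidate clusters come from the dilated-mask
    image, so boundary contacts are kept whole.
    """
    basic = brain_mask.data > 0
    if not basic.any():
        raise ValueError("brain mask is empty")
    if cfg.dilation_layers > 0:
        dil = ndimage.binary_dilation(
            basic, structure=ndimage.generate_binary_structure(3, 1),
            iterations=cfg.dilation_layers)
    else:
        dil = basic
    ct_d = ct_in_t1.data * dil
    tau0 = _initial_threshold(ct_d[dil])

    vol_d = Volume3D(ct_d, ct_in_t1.affine.copy())
    clus_d = connected_components(threshold_volume(vol_d, tau0),
                                  intensity=vol_d,
                                  connectivity=cfg.connectivity)
    # clustering of the basic-masked image, as a label map for overlap lookup
    vol_b = Volume3D(ct_in_t1.data * basic, ct_in_t1.affine.copy())
    clus_b = connected_components(threshold_volume(vol_b, tau0),
                                  intensity=vol_b,
                                  connectivity=cfg.connectivity)
    label_b = clus_b.label_volume().data

    keep = []
    for c in clus_d:
        ids = label_b[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]]
        ids = np.unique(ids[ids > 0])
        if ids.size == 0:
            continue  # appears only under the dilated mask: skull
        size_b = sum(clus_b[int(i)].size for i in ids)
        if abs(c.size - size_b) > cfg.size_diff_tol * c.size:
            continue  # truncated by the basic mask: straddles into skull
        keep.append(c.id)
    kept = clus_d.subset(keep)

    cand = np.zeros_like(ct_d)
    for c in kept:
        cand[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = \
            ct_d[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]]
    return kept, Volume3D(cand, ct_in_t1.affine.copy()), tau0


# ---------------------------------------------------------------------------
# neighbor filter + threshold iteration
# ---------------------------------------------------------------------------

def neighbor_filter(clusters: ClusterSet, radius: float = 15.0,
                    min_neighbors: int = 2) -> ClusterSet:
    """Keep clusters with at least ``min_neighbors`` other cluster centroids
    within ``radius`` mm — isolated blobs are not part of an electrode array."""
    if len(clusters) == 0:
        return clusters
    cents = clusters.centroids()
    d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
    counts = (d <= radius).sum(axis=1) - 1
    keep = [c.id for c, n in zip(clusters, counts) if n >= min_neighbors]
    return clusters.subset(keep)


def iterate_segmentation(candidates: ClusterSet, candidate_ct: Volume3D,
                         cfg: EcogSegConfig,
                         tau0: float | None = None) -> tuple[ClusterSet, dict]:
    """Raise the threshold until the cluster count is within the band.

    Each round: threshold the candidate CT, re-cluster, apply the
    near-neighbor filter, compare the count with ``cfg.n_target``.  The
    threshold grows by ``cfg.growth_factor`` per round.  If the band
    [N(1-tol), N(1+tol)] is never hit, the best-so-far clustering is
    returned with ``info["converged"] = False``.
    """
    if cfg.n_target < 1:
        raise ValueError("target contact count must be >= 1")
    if len(candidates) == 0:
        raise ValueError("no candidate clusters to segment")
    if tau0 is None:
        tau0 = _initial_threshold(candidate_ct.data[candidate_ct.data > 0])

    lo = cfg.n_target * (1 - cfg.tolerance)
    hi = cfg.n_target * (1 + cfg.tolerance)
    tau = tau0
    best: tuple[int, ClusterSet] | None = None
    info: dict = {"thresholds": [], "counts": [], "converged": False}
    for _ in range(cfg.max_iterations):
        clus = connected_components(threshold_volume(candidate_ct, tau),
                                    intensity=candidate_ct,
                                    connectivity=cfg.connectivity)
        clus = neighbor_filter(clus, cfg.neighbor_radius, cfg.min_neighbors)
        n = len(clus)
        info["thresholds"].append(tau)
        info["counts"].append(n)
        dev = abs(n - cfg.n_target)
        if best is None or dev < best[0]:
            best = (dev, clus)
        if lo <= n <= hi:
            info["converged"] = True
            return clus, info
        if n == 0:
            break  # raising further cannot recover clusters
        tau *= cfg.growth_factor
    info["warning"] = ("threshold iteration did not reach the tolerance band; "
                       "returning the closest clustering")
    return best[1], info


def contacts_from_clusters(clusters: ClusterSet, electrode: str = "G",
                           grid_shape=None) -> ElectrodeSet:
    """Weighted cluster centroids as an electrode's contact list."""
    return from_points(clusters.centroids(weighted=True), electrode,
                       grid_shape=grid_shape)


# ---------------------------------------------------------------------------
# programmatic manual correction
# ---------------------------------------------------------------------------

def edit_contacts(contacts: ElectrodeSet, ops: list[dict]) -> ElectrodeSet:
    """Apply an ordered edit script; returns a new set with an audit log.

    Each op is one of::

        {"op": "add", "electrode": name, "position": [x, y, z]}
        {"op": "remove", "id": "G7"}
        {"op": "rename", "electrode": old, "new": new}
    """
    out = contacts.copy()
    for op in ops:
        kind = op.get("op")
        if kind == "add":
            name = op["electrode"]
            nxt = max((c.index for c in out.by_electrode(name)), default=0) + 1
            out.contacts.append(
                Contact(name, nxt, np.asarray(op["position"], float)))
            out.audit_log.append(f"add {name}{nxt} at {op['position']}")
        elif kind == "remove":
            c = out.get(op["id"])   # KeyError for unknown ids
            out.contacts.remove(c)
            out.audit_log.append(f"remove {op['id']}")
        elif kind == "rename":
            old, new = op["electrode"], op["new"]
            hit = False
            for c in out.contacts:
                if c.electrode == old:
                    c.electrode = new
                    hit = True
            if not hit:
                raise KeyError(f"no electrode named {old!r}")
            out.audit_log.append(f"rename {old} -> {new}")
        else:
            raise ValueError(f"unknown edit op {kind!r}")
    return out


# ---------------------------------------------------------------------------
# minimal-energy surface projection
# ---------------------------------------------------------------------------

def grid_edges(rows: int, cols: int) -> np.ndarray:
    """4-neighborhood edges of a row-major rows x cols grid."""
    edges = []
    for i in range(rows):
        for j in range(cols):
            k = i * cols + j
            if j + 1 < cols:
                edges.append((k, k + 1))
            if i + 1 < rows:
                edges.append((k, k + cols))
    return np.asarray(edges, dtype=int)


def infer_edges(points: np.ndarray, factor: float = 1.35) -> np.ndarray:
    """Neighbor edges from geometry: pairs closer than ``factor`` times the
    median nearest-neighbor distance (fallback when no layout is known)."""
    pts = np.asarray(points, float)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    cutoff = factor * np.median(d.min(axis=1))
    ii, jj = np.where(np.triu(d <= cutoff, k=1))
    return np.stack([ii, jj], axis=1)


def _energy(pos: np.ndarray, pos0: np.ndarray, edges: np.ndarray,
            d0: np.ndarray, alpha: float) -> float:
    disp = np.sum((pos - pos0) ** 2)
    dij = np.linalg.norm(pos[edges[:, 0]] - pos[edges[:, 1]], axis=1)
    return alpha * disp + np.sum((dij - d0) ** 2)


def project_to_surface(contacts: ElectrodeSet, pial: SurfaceMesh,
                       smoothed_pial: SurfaceMesh,
                       cfg: ProjectionConfig | None = None,
                       edges: np.ndarray | None = None,
                       ) -> tuple[ElectrodeSet, dict]:
    """Minimal-energy brain-shift correction for a subdural array.

    Minimizes  E = alpha * sum_i ||p_i - p_i0||^2
                 + sum_(i,j) (||p_i - p_j|| - d0_ij)^2
    with every p_i constrained to the smoothed pial surface (positions live
    on its vertices; moves are accepted only if the total energy drops, so
    the energy is non-increasing).  Final positions are mapped back to the
    raw pial by nearest vertex.  ``d0_ij`` are the pre-projection distances.
    """
    cfg = cfg or ProjectionConfig()
    if edges is None:
        if contacts.grid_shape is not None:
            edges = grid_edges(*contacts.grid_shape)
        else:
            raise ValueError("contacts carry no grid layout; pass explicit "
                             "neighbor edges (or a grid_shape)")
    pos0 = contacts.positions()
    n = len(pos0)
    if edges.size and edges.max() >= n:
        raise ValueError("edge index out of range")
    d0 = np.linalg.norm(pos0[edges[:, 0]] - pos0[edges[:, 1]], axis=1)

    tree_s = cKDTree(smoothed_pial.vertices)
    vidx = tree_s.query(pos0)[1]
    pos = smoothed_pial.vertices[vidx].copy()

    # adjacency for per-contact energy terms
    inc: list[list[int]] = [[] for _ in range(n)]
    for e, (i, j) in enumerate(edges):
        inc[i].append(e)
        inc[j].append(e)

    def local_e(i: int, p: np.ndarray) -> float:
        val = cfg.alpha * np.sum((p - pos0[i]) ** 2)
        for e in inc[i]:
            j = edges[e, 1] if edges[e, 0] == i else edges[e, 0]
            val += (np.linalg.norm(p - pos[j]) - d0[e]) ** 2
        return val

    energies = [_energy(pos, pos0, edges, d0, cfg.alpha)]
    for _ in range(cfg.max_iterations):
        moved = False
        for i in range(n):
            cand_idx = tree_s.query(pos[i], k=cfg.k_candidates)[1]
            cand_idx = np.atleast_1d(cand_idx)
            cur = local_e(i, pos[i])
            vals = [local_e(i, smoothed_pial.vertices[ci]) for ci in cand_idx]
            best = int(np.argmin(vals))
            if vals[best] < cur - cfg.tol:
                pos[i] = smoothed_pial.vertices[cand_idx[best]]
                moved = True
        energies.append(_energy(pos, pos0, edges, d0, cfg.alpha))
        if not moved:
            break

    tree_p = cKDTree(pial.vertices)
    final = pial.vertices[tree_p.query(pos)[1]]

    out = contacts.copy()
    for c, p in zip(out.contacts, final):
        c.position = p.copy()
    out.audit_log.append("projected onto pial surface (minimal energy)")
    return out, {"energy": energies, "smoothed_positions": pos}


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def run_ecog(ct_in_t1: Volume3D, brain_mask: Volume3D, cfg: EcogSegConfig,
             pial: SurfaceMesh | None = None,
             smoothed_pial: SurfaceMesh | None = None,
             project: bool = True, edit_ops: list[dict] | None = None,
             ) -> tuple[ElectrodeSet, dict]:
    """Full ECoG pipeline: dual-mask strip + threshold iteration
    (+ optional edits and surface projection)."""
    cand, cand_ct, tau0 = dual_mask_strip(ct_in_t1, brain_mask, cfg)
    clus, info = iterate_segmentation(cand, cand_ct, cfg, tau0=tau0)
    es = contacts_from_clusters(clus)
    if edit_ops:
        es = edit_contacts(es, edit_ops)
    info["pre_projection"] = es.copy()
    if project and pial is not None and smoothed_pial is not None:
        edges = infer_edges(es.positions())
        es, pinfo = project_to_surface(es, pial, smoothed_pial, edges=edges)
        info["projection"] = pinfo
    return es, info
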