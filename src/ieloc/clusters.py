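"""Thresholding and connected-component clustering shared by both pipelines."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import Volume3D, voxel_to_world

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Cluster:
    id: int
    voxels: np.ndarray            # (n, 3) integer voxel indices
    size: int
    centroid: np.ndarray          # plain centroid, world mm
    weighted_centroid: np.ndarray  # intensity-weighted centroid, world mm


@dataclass
class ClusterSet:
    """Disjoint connected components of a binary volume, ids contiguous from 1."""

    clusters: list[Cluster]
    reference: Volume3D           # grid the voxel indices live on

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, cid: int) -> Cluster:
        for c in self.clusters:
            if c.id == cid:
                return c
        raise KeyError(f"no cluster with id {cid}")

    def centroids(self, weighted: bool = True) -> np.ndarray:
        if not self.clusters:
            return np.zeros((0, 3))
        attr = "weighted_centroid" if weighted else "centroid"
        return np.vstack([getattr(c, attr) for c in self.clusters])

    def total_voxels(self) -> int:
        return sum(c.size for c in self.clusters)

    def subset(self, keep_ids) -> "ClusterSet":
        """New set with the chosen clusters, re-numbered from 1."""
        keep = [c for c in self.clusters if c.id in set(keep_ids)]
        out = [Cluster(i + 1, c.voxels, c.size, c.centroid, c.weighted_centroid)
               for i, c in enumerate(keep)]
        return ClusterSet(out, self.reference)

    def label_volume(self) -> Volume3D:
        """Integer label image (for debugging / NIfTI export)."""
        lab = np.zeros(self.reference.shape, dtype=np.int32)
        for c in self.clusters:
            lab[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]] = c.id
        return Volume3D(lab, self.reference.affine.copy())


def threshold_volume(vol: Volume3D, tau: float) -> Volume3D:
    """Binary mask: voxel true iff intensity >= tau."""
    return Volume3D((vol.data >= tau).astype(np.uint8), vol.affine.copy())


def connected_components(mask: Volume3D, intensity: Volume3D | None = None,
                         connectivity: int = 26) -> ClusterSet:
    """Label connected components of a binary mask.

    ``intensity`` supplies the weights for the intensity-weighted centroids
    (defaults to the mask itself, i.e. unweighted).  Default connectivity is
    26: thin oblique electrodes fragment under 6-connectivity.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    ref = intensity if intensity is not None else mask
    labels, n = ndimage.label(mask.data > 0, structure=_STRUCTS[connectivity])
    clusters: list[Cluster] = []
    if n:
        order = np.argsort(labels.ravel(), kind="stable")
        flat_sorted = labels.ravel()[order]
        starts = np.searchsorted(flat_sorted, np.arange(1, n + 2))
        coords_all = np.unravel_index(order, labels.shape)
        coords_all = np.stack(coords_all, axis=1)
        for cid in range(1, n + 1):
            vox = coords_all[starts[cid - 1]:starts[cid]]
            clusters.append(_make_cluster(cid, vox, ref))
    return ClusterSet(clusters, ref)


def _make_cluster(cid: int, vox: np.ndarray, vol: Volume3D) -> Cluster:
    world = voxel_to_world(vol, vox.astype(float))
    plain = world.mean(axis=0)
    w = np.asarray(vol.data[vox[:, 0], vox[:, 1], vox[:, 2]], dtype=float)
    total = w.sum()
    if total <= 0:
        warnings.warn("nonpositive total intensity in cluster; "
                      "falling back to unweighted centroid", stacklevel=2)
        weighted = plain
    else:
        weighted = (world * w[:, None]).sum(axis=0) / total
    return Cluster(cid, vox, len(vox), plain, weighted)


def weighted_centroid(cluster: Cluster, vol: Volume3D) -> np.ndarray:
    """Intensity-weighted mean world position of a cluster's voxels."""
    if cluster.size == 0:
        raise ValueError("empty cluster")
    return _make_cluster(cluster.id, cluster.voxels, vol).weighted_centroid
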