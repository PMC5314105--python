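"""Subdural-grid pipeline: dual-mask strip, threshold iteration, neighbor
filter, edit scripts, and the minimal-energy surface projection."""

import numpy as np
import pytest

from ieloc import phantom as ph
from ieloc.clusters import connected_components, threshold_volume
from ieloc.contacts import from_points
from ieloc.ecog import (EcogSegConfig, ProjectionConfig, dual_mask_strip,
                        edit_contacts, grid_edges, infer_edges,
                        iterate_segmentation, neighbor_filter,
                        project_to_surface)
from ieloc.validation import detection_rate
from ieloc.volumes import Volume3D


class TestDualMaskStrip:
    def _toy(self):
        """Ball mask with one interior blob, one boundary-straddling blob,
        and one blob only reachable through dilation."""
        n = 40
        x = np.arange(n) - (n - 1) / 2
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        d = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
        mask = Volume3D((d <= 12).astype(np.uint8), np.eye(4))
        ct = np.zeros((n, n, n))
        ct[19:22, 19:22, 19:22] = 1000.0          # interior blob
        # straddling blob centered on the boundary along +x
        ct[29:34, 18:23, 18:23] = 1000.0          # x = 9.5..13.5 vs r=12
        # dilated-only blob just outside the mask
        ct[18:21, 33:35, 19:22] = 1000.0          # y = 13.5..14.5
        return Volume3D(ct, np.eye(4)), mask

    def test_boundary_and_outside_blobs_removed_interior_kept(self):
        ct, mask = self._toy()
        cfg = EcogSegConfig(n_target=1, dilation_layers=2)
        kept, cand_ct, tau0 = dual_mask_strip(ct, mask, cfg)
        assert len(kept) == 1
        np.testing.assert_allclose(kept.clusters[0].centroid, [20, 20, 20],
                                   atol=0.6)

    def test_zero_dilation_removes_nothing(self):
        ct, mask = self._toy()
        cfg = EcogSegConfig(n_target=1, dilation_layers=0)
        kept, _, _ = dual_mask_strip(ct, mask, cfg)
        # identical maskings: every basic-mask cluster is its own counterpart
        basic = connected_components(
            threshold_volume(Volume3D(ct.data * (mask.data > 0), ct.affine),
                             500.0))
        assert len(kept) == len(basic)

    def test_empty_brain_mask_rejected(self):
        ct, mask = self._toy()
        empty = Volume3D(np.zeros_like(mask.data), mask.affine)
        with pytest.raises(ValueError, match="empty"):
            dual_mask_strip(ct, empty, EcogSegConfig(n_target=1))

    def test_all_grid_contacts_survive_strip_noise_free(self, head_ecog):
        ct, truth = ph.implant_ecog(head_ecog, 4, 5, noise_sigma=0)
        cfg = EcogSegConfig(n_target=20)
        kept, _, _ = dual_mask_strip(ct, head_ecog.brain_mask, cfg)
        cents = kept.centroids()
        for c in truth.centers["G"]:
            assert np.linalg.norm(cents - c, axis=1).min() < 2.0


class TestNeighborFilter:
    def _clusters(self, points):
        data = np.zeros((60, 60, 60))
        aff = np.eye(4)
        for p in points:
            data[tuple(np.round(p).astype(int))] = 1.0
        vol = Volume3D(data, aff)
        return connected_components(threshold_volume(vol, 0.5), intensity=vol)

    def test_isolated_blob_removed(self):
        grid = [[10 + 10 * i, 10 + 10 * j, 10] for i in range(2)
                for j in range(3)]
        cs = self._clusters(grid + [[55, 55, 55]])
        kept = neighbor_filter(cs, radius=15.0, min_neighbors=2)
        cents = kept.centroids()
        assert len(kept) == 6
        assert np.linalg.norm(cents - [55, 55, 55], axis=1).min() > 10

    def test_interior_grid_contact_kept(self):
        grid = [[10 + 10 * i, 10 + 10 * j, 10] for i in range(3)
                for j in range(3)]
        kept = neighbor_filter(self._clusters(grid), 15.0, 2)
        assert len(kept) == 9

    def test_pair_with_min_two_neighbors_both_removed(self):
        kept = neighbor_filter(self._clusters([[10, 10, 10], [20, 10, 10]]),
                               15.0, 2)
        assert len(kept) == 0


class TestIterateSegmentation:
    def test_converges_within_5pct_and_detects_80pct(self, ecog_segmentation):
        clus, info, truth = ecog_segmentation
        assert info["converged"]
        n = len(clus)
        assert 19 <= n <= 21      # 20 within +/-5%
        rate = detection_rate(clus.centroids(), truth.centers["G"], 2.0)
        assert rate >= 80.0

    def test_threshold_sequence_strictly_increasing(self, ecog_segmentation):
        _, info, _ = ecog_segmentation
        taus = info["thresholds"]
        assert all(b > a for a, b in zip(taus, taus[1:]))

    def test_counts_non_increasing_on_phantom_run(self, ecog_segmentation):
        _, info, _ = ecog_segmentation
        counts = info["counts"]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_already_converged_returns_without_raising_threshold(self):
        # 3 well-separated bright blobs, N=3: first round must terminate
        data = np.zeros((40, 40, 40))
        for p in [(10, 10, 10), (20, 10, 10), (15, 20, 10)]:
            data[p] = 1000.0
        vol = Volume3D(data, np.eye(4))
        cfg = EcogSegConfig(n_target=3, min_neighbors=1, tolerance=0.05)
        cand = connected_components(threshold_volume(vol, 500.0),
                                    intensity=vol)
        clus, info = iterate_segmentation(cand, vol, cfg, tau0=500.0)
        assert info["converged"] and len(info["thresholds"]) == 1

    def test_merged_pair_split_by_higher_threshold(self):
        # two bright blobs bridged by a dim voxel: the initial threshold
        # sees one cluster, the raised threshold two
        data = np.zeros((30, 30, 30))
        data[10, 10, 10] = data[16, 10, 10] = 1000.0
        for x in range(11, 16):
            data[x, 10, 10] = 600.0
        vol = Volume3D(data, np.eye(4))
        cfg = EcogSegConfig(n_target=2, min_neighbors=0, growth_factor=1.05,
                            tolerance=0.05)
        cand = connected_components(threshold_volume(vol, 500.0),
                                    intensity=vol)
        assert len(cand) == 1
        clus, info = iterate_segmentation(cand, vol, cfg, tau0=500.0)
        assert info["converged"] and len(clus) == 2
        assert abs(len(clus) - 2) < abs(len(cand) - 2) + 1

    def test_empty_candidates_rejected(self):
        vol = Volume3D(np.zeros((10, 10, 10)), np.eye(4))
        cand = connected_components(threshold_volume(vol, 1.0))
        with pytest.raises(ValueError, match="candidate"):
            iterate_segmentation(cand, vol, EcogSegConfig(n_target=5))


class TestEditContacts:
    def _set(self):
        return from_points(np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0.0]]),
                           "G")

    def test_add_then_remove_restores_set(self):
        es = self._set()
        out = edit_contacts(es, [
            {"op": "add", "electrode": "G", "position": [5.0, 5.0, 0.0]},
            {"op": "remove", "id": "G4"},
        ])
        np.testing.assert_allclose(out.positions(), es.positions())
        assert len(out.audit_log) == 2

    def test_empty_ops_identity(self):
        es = self._set()
        out = edit_contacts(es, [])
        np.testing.assert_allclose(out.positions(), es.positions())

    def test_remove_unknown_id_raises(self):
        with pytest.raises(KeyError):
            edit_contacts(self._set(), [{"op": "remove", "id": "G9"}])

    def test_rename_applies_to_all_contacts(self):
        out = edit_contacts(self._set(),
                            [{"op": "rename", "electrode": "G", "new": "LG"}])
        assert out.electrode_names == ["LG"]

    def test_removing_false_positive_raises_precision_keeps_recall(self):
        truth = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0.0]])
        es = from_points(np.vstack([truth, [[40.0, 40.0, 40.0]]]), "G")
        out = edit_contacts(es, [{"op": "remove", "id": "G4"}])
        assert detection_rate(out.positions(), truth) == \
            detection_rate(es.positions(), truth) == 100.0
        # precision: fraction of detections matching truth
        assert len(out) == 3 and len(es) == 4


class TestProjection:
    def test_fixed_point_when_contacts_on_surface(self, head_ecog):
        mesh = head_ecog.smoothed_pial
        # chain of 4 mutually close vertices as a strip already on surface
        idx = [0]
        for _ in range(3):
            d = np.linalg.norm(mesh.vertices - mesh.vertices[idx[-1]], axis=1)
            d[idx] = np.inf
            idx.append(int(np.argmin(d)))
        pts = mesh.vertices[idx]
        es = from_points(pts, "S")
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        out1, info1 = project_to_surface(es, head_ecog.smoothed_pial,
                                         head_ecog.smoothed_pial, edges=edges)
        assert info1["energy"][-1] <= info1["energy"][0] + 1e-9
        np.testing.assert_allclose(info1["smoothed_positions"], pts,
                                   atol=1e-9)
        # doubling alpha with zero displacement: identical output
        out2, _ = project_to_surface(es, head_ecog.smoothed_pial,
                                     head_ecog.smoothed_pial,
                                     cfg=ProjectionConfig(alpha=2.0),
                                     edges=edges)
        np.testing.assert_allclose(out1.positions(), out2.positions())

    def test_inward_shifted_grid_moves_back_toward_surface(self, head_ecog):
        ct, truth = ph.implant_ecog(head_ecog, 4, 5, inward_shift_mm=3.0,
                                    noise_sigma=0)
        es = from_points(truth.centers["G"], "G", grid_shape=(4, 5))
        out, info = project_to_surface(es, head_ecog.pial,
                                       head_ecog.smoothed_pial)
        surf = truth.surface_centers["G"]
        before = np.linalg.norm(truth.centers["G"] - surf, axis=1).mean()
        after = np.linalg.norm(out.positions() - surf, axis=1).mean()
        assert after < before
        energies = info["energy"]
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_output_contacts_on_pial_within_vertex_spacing(self, head_ecog):
        ct, truth = ph.implant_ecog(head_ecog, 3, 4, inward_shift_mm=2.0,
                                    noise_sigma=0)
        es = from_points(truth.centers["G"], "G", grid_shape=(3, 4))
        out, _ = project_to_surface(es, head_ecog.pial,
                                    head_ecog.smoothed_pial)
        from oracles import point_mesh_distance
        d = point_mesh_distance(out.positions(), head_ecog.pial)
        assert d.max() < 1.5  # one vertex spacing of the 1 mm-grid mesh

    def test_missing_layout_rejected(self):
        es = from_points(np.zeros((3, 3)), "G")
        mesh_pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        from ieloc.volumes import SurfaceMesh
        mesh = SurfaceMesh(mesh_pts, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="layout"):
            project_to_surface(es, mesh, mesh)

    def test_grid_edges_and_inferred_edges_agree_on_regular_grid(self):
        pts = np.array([[i * 10.0, j * 10.0, 0.0]
                        for i in range(3) for j in range(4)])
        ge = {tuple(sorted(e)) for e in grid_edges(3, 4)}
        ie = {tuple(sorted(e)) for e in infer_edges(pts)}
        assert ge == ie
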