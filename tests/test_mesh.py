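"""Geometry: tet meshes, braided devices, immersed boundaries, refinement."""

import numpy as np
import pytest

from clotflow.mesh import (MeshingError, TetMesh, generate_tube_mesh,
                           generate_sidewall_aneurysm_mesh,
                           build_braided_device, build_screen_device,
                           compute_immersed_boundary, distance_to_wires,
                           refine_near_wires, _bend_map,
                           TAG_INLET, TAG_OUTLET, TAG_WALL)

D, L = 300e-6, 3e-3
R = D / 2


@pytest.fixture(scope="module")
def tube():
    return generate_tube_mesh(D, L, 30e-6, target_h_axial=100e-6)


@pytest.fixture(scope="module")
def screen():
    return build_screen_device(R, 20e-6, 90.0, pitch=100e-6, x_center=L / 2)


class TestTubeMesh:
    def test_total_volume_matches_cylinder(self, tube):
        vref = np.pi * R * R * L
        assert abs(tube.total_volume() - vref) / vref < 0.02

    def test_inlet_area_matches_disc(self, tube):
        a = tube.face_area[tube.boundary_faces(TAG_INLET)].sum()
        assert abs(a - np.pi * R * R) / (np.pi * R * R) < 0.02

    def test_face_closure(self, tube):
        assert tube.face_closure_residual() < 1e-10

    def test_interior_faces_have_two_elements(self, tube):
        interior = tube.face_elems[:, 1] >= 0
        # boundary faces are exactly those tagged
        assert (tube.face_tag[interior] == 0).all()
        assert (tube.face_tag[~interior] > 0).all()

    def test_positive_volumes_and_spacing(self, tube):
        assert (tube.volumes > 0).all()
        assert (tube.face_ds > 0).all()

    def test_degenerate_resolution_rejected(self):
        with pytest.raises(MeshingError):
            generate_tube_mesh(D, L, D)

    def test_all_tags_present(self, tube):
        for t in (TAG_INLET, TAG_OUTLET, TAG_WALL):
            assert len(tube.boundary_faces(t)) > 0


class TestSidewallMesh:
    def test_sac_volume(self):
        m = generate_sidewall_aneurysm_mesh(4e-3, 8e-3, 4e-2, 4e-3, 0.5e-3)
        c = _bend_map(m.metadata["sac_center_straight"][None, :], 4e-2)[0]
        Ra = m.metadata["sac_radius"]
        d = np.linalg.norm(m.centroids - c, axis=1)
        vin = m.volumes[d < Ra].sum()
        vsph = 4.0 / 3.0 * np.pi * Ra ** 3
        assert abs(vin - vsph) / vsph < 0.10

    def test_straight_variant(self):
        m = generate_sidewall_aneurysm_mesh(4e-3, 8e-3, None, 4e-3, 0.6e-3)
        assert m.metadata["bend"] is None
        assert m.face_closure_residual() < 1e-10
        # vessel axis stays on x
        inlet = m.face_centroid[m.boundary_faces(TAG_INLET)]
        assert np.abs(inlet[:, 0]).max() < 1e-9

    def test_neck_wider_than_sac_rejected(self):
        with pytest.raises(MeshingError):
            generate_sidewall_aneurysm_mesh(4e-3, 8e-3, None, 9e-3, 0.5e-3)

    def test_closure_curved(self):
        m = generate_sidewall_aneurysm_mesh(4e-3, 8e-3, 4e-2, 4e-3, 0.7e-3)
        assert m.face_closure_residual() < 1e-10


class TestBraidedDevice:
    def test_wires_on_deployment_surface(self):
        dev = build_braided_device(48, 32e-6, 90.0, 2.375e-3, 20e-3)
        assert len(dev.wires) == 48
        r = np.linalg.norm(dev.sphere_centers[:, 1:], axis=1)
        assert np.abs(r - 2.375e-3).max() < 2e-6

    def test_helix_pitch_angle(self):
        # 90-degree braid: wires at 45 degrees from the axis on the
        # unrolled cylinder
        dev = build_braided_device(2, 30e-6, 90.0, 1e-3, 5e-3)
        w = dev.wires[0]
        dx = w[-1, 0] - w[0, 0]
        th = np.unwrap(np.arctan2(w[:, 2], w[:, 1]))
        arc = 1e-3 * (th[-1] - th[0])
        assert abs(abs(arc / dx) - np.tan(np.deg2rad(45))) < 1e-6

    def test_sphere_overlap(self):
        dev = build_braided_device(8, 30e-6, 90.0, 1e-3, 5e-3)
        # spacing along each wire must not exceed the sphere radius
        d = np.linalg.norm(np.diff(dev.sphere_centers[:50], axis=0), axis=1)
        assert d.max() <= dev.sphere_radius + 1e-12

    def test_denser_braid_has_smaller_pores(self):
        s90 = build_screen_device(R, 20e-6, 90.0, pitch=100e-6)
        s150 = build_screen_device(R, 20e-6, 150.0, pitch=100e-6)
        assert s150.pore_cell_area() < s90.pore_cell_area()

    def test_coverage_monotone_in_braid_angle(self):
        cov = [build_braided_device(48, 30e-6, a, 1.9e-3, 12e-3)
               .coverage_fraction(2000) for a in (60.0, 90.0, 120.0, 150.0)]
        assert all(b > a for a, b in zip(cov, cov[1:]))

    def test_invalid_angle(self):
        with pytest.raises(ValueError):
            build_braided_device(48, 30e-6, 200.0, 1e-3, 5e-3)
        with pytest.raises(ValueError):
            build_braided_device(47, 30e-6, 90.0, 1e-3, 5e-3)


class TestImmersedBoundary:
    def test_distance_matches_brute_force_segments(self, tube, screen):
        """KD-tree-pruned distances equal the exhaustive point-to-segment
        minimum over every wire segment."""
        pts = tube.centroids[::97]
        d = distance_to_wires(pts, screen)
        # brute force over all segments
        a, b = screen.seg_p0, screen.seg_p1
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        best = np.full(len(pts), np.inf)
        for i, p0 in enumerate(pts):
            t = np.clip(((p0 - a) * ab).sum(1) / denom, 0, 1)
            dd = np.linalg.norm(p0 - (a + t[:, None] * ab), axis=1)
            best[i] = dd.min()
        assert np.abs(d - best).max() < 1e-12

    def test_r_field_floor_and_offset(self, tube, screen):
        ib = compute_immersed_boundary(tube, screen)
        assert (ib.r_field >= 0).all()
        # element centroids on the screen plane are within a wire radius + h
        k = np.argmin(ib.r_field)
        d_center = distance_to_wires(tube.centroids[[k]], screen)[0]
        assert ib.r_field[k] == pytest.approx(
            max(d_center - screen.wire_radius, 0.0), abs=1e-15)

    def test_empty_wireset(self, tube):
        ib = compute_immersed_boundary(tube, None)
        assert np.isinf(ib.r_field).all()
        assert len(ib.cut_edges) == 0 and len(ib.ib_nodes) == 0

    def test_cut_edges_straddle_surface(self, tube, screen):
        ib = compute_immersed_boundary(tube, screen)
        assert len(ib.cut_edges) > 0
        s0 = ib.node_dist[ib.cut_edges[:, 0]] < 0
        s1 = ib.node_dist[ib.cut_edges[:, 1]] < 0
        assert np.all(s0 != s1)
        # every cut edge contributes a tagged node
        tagged = set(ib.ib_nodes.tolist())
        for e in ib.cut_edges[:50]:
            assert e[0] in tagged or e[1] in tagged


@pytest.fixture(scope="module")
def refined(tube, screen):
    ib = compute_immersed_boundary(tube, screen)
    out = refine_near_wires(tube, ib, 1, wires=screen)
    return tube, ib, out


class TestRefinement:
    def test_level_zero_is_identity(self, tube, screen):
        ib = compute_immersed_boundary(tube, screen)
        assert refine_near_wires(tube, ib, 0, wires=screen) is tube

    def test_volume_conserved(self, refined):
        tube, _, out = refined
        assert out.total_volume() == pytest.approx(tube.total_volume(),
                                                   rel=1e-12)

    def test_conforming_and_valid(self, refined):
        _, _, out = refined
        out.validate()            # face pairing + closure checked on build

    def test_h_halves_near_wires(self, refined, screen):
        tube, ib0, out = refined
        cut0 = np.unique(np.concatenate(
            [np.flatnonzero(np.isfinite(ib0.r_field))]))
        ib1 = compute_immersed_boundary(out, screen)
        pre = tube.h[tube.h > 0]
        cut_elems0 = _cut_elements(tube, ib0)
        cut_elems1 = _cut_elements(out, ib1)
        h0 = tube.h[cut_elems0].min()
        h1 = out.h[cut_elems1].min()
        assert h1 <= 0.5 * h0 + 1e-15


def _cut_elements(mesh, ib):
    cut_nodes = set(ib.cut_edges.ravel().tolist())
    mask = np.array([any(n in cut_nodes for n in t) for t in mesh.tets])
    return np.flatnonzero(mask)
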