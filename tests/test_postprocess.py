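import json

import numpy as np
import pytest

from gnawfe.hexfem import build_mesh, solve
from gnawfe.loading import ConstraintSet, LoadCase
from gnawfe.postprocess import (
    LandmarkProfile,
    PostprocessError,
    SamplingError,
    compare_variants,
    corpus_section_dims,
    extract_cross_section,
    place_landmarks,
    sample_mean_von_mises,
    sample_von_mises,
    section_bending_moment,
    section_element_ids,
    ventral_profile_arch,
)
from gnawfe.synthetic_mandible import generate_beam
from gnawfe.variant_builder import AnnotationError


@pytest.fixture(scope="module")
def compressed_block(materials):
    """A beam under uniform uniaxial compression along x (rollers)."""
    grid, _ = generate_beam(4.0, 2.0, 2.0, 0.5)
    mesh = build_mesh(grid)
    sigma = 3.0
    f = np.zeros((mesh.n_nodes, 3))
    face = np.where(mesh.node_ijk[:, 0] == grid.shape[0])[0]
    # consistent nodal forces for uniform traction on the bilinear face mesh
    w = np.ones(len(face))
    for ax in (1, 2):
        edge = (mesh.node_ijk[face, ax] == 0) | (mesh.node_ijk[face, ax] == grid.shape[ax])
        w *= np.where(edge, 0.5, 1.0)
    f[face, 0] = -sigma * (2.0 * 2.0) * w / w.sum()
    rollers = []
    for axis in range(3):
        for n in np.where(mesh.node_ijk[:, axis] == 0)[0]:
            rollers.append(3 * n + axis)
    cons = ConstraintSet(fixed_nodes=np.empty(0, int), extra_dofs=np.array(rollers))
    sol = solve(mesh, materials, LoadCase(forces=f), cons, method="direct")
    return grid, mesh, sol, sigma


class TestPlaceLandmarks:
    def test_two_landmarks_are_the_endpoints(self, coarse_mandible):
        _, ann = coarse_mandible
        prof = place_landmarks(ann, n=2)
        np.testing.assert_allclose(prof.points[0], ann.ventral_path[0])
        np.testing.assert_allclose(prof.points[-1], ann.ventral_path[-1])

    def test_twenty_landmarks_equal_arc_spacing(self, coarse_mandible):
        grid, ann = coarse_mandible
        prof = place_landmarks(ann, n=20)
        assert prof.n == 20
        gaps = np.linalg.norm(np.diff(prof.points, axis=0), axis=1)
        assert np.ptp(gaps) <= grid.spacing / 2.0

    def test_matches_chord_length_oracle(self, coarse_mandible):
        _, ann = coarse_mandible
        prof = place_landmarks(ann, n=9)
        # oracle: independent cumulative chord-length resampling
        path = ann.ventral_path
        d = np.sqrt(((path[1:] - path[:-1]) ** 2).sum(axis=1))
        s = np.concatenate([[0], np.cumsum(d)])
        for k, target in enumerate(np.linspace(0, s[-1], 9)):
            j = np.searchsorted(s, target, side="right") - 1
            j = min(j, len(path) - 2)
            t = (target - s[j]) / max(s[j + 1] - s[j], 1e-300)
            expected = path[j] + t * (path[j + 1] - path[j])
            np.testing.assert_allclose(prof.points[k], expected, atol=1e-9)

    def test_anchor_mismatch_rejected(self, coarse_mandible):
        import dataclasses

        _, ann = coarse_mandible
        bad = dataclasses.replace(ann, ventral_path=ann.ventral_path[5:])
        with pytest.raises(AnnotationError):
            place_landmarks(bad, n=5, anchor_tol=1.0)


class TestSampling:
    def test_uniform_field_reads_uniform(self, compressed_block):
        grid, mesh, sol, sigma = compressed_block
        pts = grid.voxel_centers(np.argwhere(grid.solid_mask())[:10]) + 0.01
        vals = sample_von_mises(sol, pts)
        np.testing.assert_allclose(vals, sigma, rtol=1e-6)

    def test_nearest_surface_element_oracle(self, compressed_block):
        grid, mesh, sol, _ = compressed_block
        surf = np.where(mesh.surface_element_mask())[0]
        centroids = mesh.element_centroids()
        r = np.random.default_rng(2)
        pts = centroids[r.choice(surf, 5)] + r.normal(scale=0.1, size=(5, 3))
        vals = sample_von_mises(sol, pts)
        for p, v in zip(pts, vals):
            d = np.linalg.norm(centroids[surf] - p, axis=1)
            assert v == sol.von_mises[surf[np.argmin(d)]]

    def test_far_point_rejected(self, compressed_block):
        _, _, sol, _ = compressed_block
        with pytest.raises(SamplingError):
            sample_von_mises(sol, np.array([[50.0, 50.0, 50.0]]))

    def test_mean_over_radius_option(self, compressed_block):
        grid, _, sol, sigma = compressed_block
        pts = grid.voxel_centers(np.argwhere(grid.solid_mask())[:3])
        vals = sample_mean_von_mises(sol, pts, radius=1.0)
        np.testing.assert_allclose(vals, sigma, rtol=1e-6)


class TestCrossSection:
    def test_uniaxial_compression_closed_form(self, compressed_block, coarse_mandible):
        import dataclasses

        grid, mesh, sol, sigma = compressed_block
        _, mand_ann = coarse_mandible
        ann = dataclasses.replace(
            mand_ann, molar_posterior_point=np.array([1.75, 1.0, 1.0]), occlusal_frame=np.eye(3)
        )
        sec = extract_cross_section(sol, ann, offset_voxels=1.0)
        E, nu = 17000.0, 0.3
        np.testing.assert_allclose(sec.values("e3"), -sigma / E, rtol=1e-6)
        np.testing.assert_allclose(sec.values("e1"), nu * sigma / E, rtol=1e-6)

    def test_element_count_matches_exhaustive_scan(self, compressed_block):
        grid, mesh, sol, _ = compressed_block
        point = np.array([1.6, 0.0, 0.0])
        normal = np.array([1.0, 0.0, 0.0])
        ids = section_element_ids(mesh, point, normal)
        count = 0
        for c in mesh.element_centroids():
            d = c[0] - 1.6
            if -0.25 <= d < 0.25:
                count += 1
        assert len(ids) == count

    def test_footprint_present_in_model1_absent_hole_in_model5(self, coarse_pipeline):
        res, _ = coarse_pipeline
        s1, s5 = res.sections[1], res.sections[5]
        assert s1.incisor_footprint.any()
        assert not s5.incisor_footprint.any()
        # the crypt is a hole: fewer section elements than the intact model
        assert len(s5.element_ids) < len(s1.element_ids)


class TestCompareVariants:
    def _profile(self, base, **models):
        prof = LandmarkProfile(points=np.zeros((len(base), 3)))
        prof.points[:, 0] = np.arange(len(base))
        prof.von_mises_values[1] = np.asarray(base, dtype=float)
        for idx, vals in models.items():
            prof.von_mises_values[int(idx)] = np.asarray(vals, dtype=float)
        return prof

    def test_identical_profiles_zero_change(self):
        base = [1.0, 2.0, 3.0]
        cmp = compare_variants(self._profile(base, **{"2": base}))
        np.testing.assert_allclose(cmp.percent_change[2], 0.0)

    def test_doubling_is_plus_hundred_percent(self):
        base = np.array([1.0, 2.0, 4.0])
        cmp = compare_variants(self._profile(base, **{"3": 2 * base}))
        np.testing.assert_allclose(cmp.percent_change[3], 100.0)
        assert cmp.max_relative_increase[3] == pytest.approx(100.0)

    def test_tripling_is_plus_two_hundred_percent(self):
        base = [2.0, 2.0]
        cmp = compare_variants(self._profile(base, **{"5": [6.0, 2.0]}))
        assert cmp.percent_change[5][0] == pytest.approx(200.0)

    def test_zero_baseline_flagged_and_excluded(self):
        cmp = compare_variants(self._profile([0.0, 1.0], **{"2": [5.0, 1.5]}))
        assert np.isnan(cmp.percent_change[2][0])
        assert cmp.max_relative_increase[2] == pytest.approx(50.0)

    def test_threshold_index_from_cut_point(self):
        base = [1.0] * 5
        prof = self._profile(base, **{"4": base})
        cmp = compare_variants(prof, cut_points={4: np.array([2.2, 0, 0])})
        assert cmp.threshold_indices[4] == 2


class TestSectionBendingMoment:
    def test_uniform_axial_stress_zero_moment(self, compressed_block):
        grid, mesh, sol, sigma = compressed_block
        M = section_bending_moment(sol, np.array([1.6, 0, 0]), np.array([1.0, 0, 0]))
        scale = sigma * 2.0 * 2.0 * 1.0  # N * typical lever
        assert abs(M) < 1e-4 * scale

    def test_three_point_bending_matches_statics(self, materials):
        h = 0.25
        L, d, w = 16.0, 2.0, 2.0
        grid, ann = generate_beam(L, d, w, h)
        mesh = build_mesh(grid)
        nxp = grid.shape[0]
        ijk = mesh.node_ijk
        ledge = np.where((ijk[:, 0] == 0) & (ijk[:, 2] == 0))[0]
        redge = np.where((ijk[:, 0] == nxp) & (ijk[:, 2] == 0))[0]
        load_nodes = mesh.patch_face_nodes(ann.load_patch, *ann.load_face)
        extra = (
            list(3 * ledge + 2) + list(3 * redge + 2) + list(3 * ledge + 0)
            + list(3 * ledge + 1) + list(3 * redge + 1)
        )
        cons = ConstraintSet(fixed_nodes=np.empty(0, int), extra_dofs=np.array(extra))
        P = 1.0
        f = np.zeros((mesh.n_nodes, 3))
        f[load_nodes, 2] = -P / len(load_nodes)
        sol = solve(mesh, materials, LoadCase(forces=f), cons, tol=1e-9)
        x_sec = L / 4 + h / 2
        M = section_bending_moment(sol, np.array([x_sec, 0, 0]), np.array([1.0, 0, 0]))
        assert M == pytest.approx(P / 2 * x_sec, rel=0.05)

    def test_plane_missing_model_rejected(self, compressed_block):
        _, _, sol, _ = compressed_block
        with pytest.raises(PostprocessError):
            section_bending_moment(sol, np.array([99.0, 0, 0]), np.array([1.0, 0, 0]))


class TestExperimentDriver:
    def test_emits_five_solved_models_and_outputs(self, coarse_pipeline):
        res, outdir = coarse_pipeline
        assert sorted(res.solutions) == [1, 2, 3, 4, 5]
        assert sorted(res.bite_forces) == [1, 2, 3, 4, 5]
        assert (outdir / "landmark_profiles.csv").exists()
        assert (outdir / "comparison.json").exists()
        manifest = json.loads((outdir / "manifest.json").read_text())
        assert len(manifest) == 5
        log = json.loads((outdir / "run_log.json").read_text())
        assert "solver_reports" in log and "bite_forces_N" in log

    def test_landmark_csv_shape(self, coarse_pipeline):
        import pandas as pd

        res, outdir = coarse_pipeline
        df = pd.read_csv(outdir / "landmark_profiles.csv")
        assert len(df) == res.profile.n
        assert [c for c in df.columns if c.endswith("_MPa")] == [
            f"model_{i}_MPa" for i in range(1, 6)
        ]

    def test_ventral_profile_is_mandible_like_arch(self, coarse_mandible):
        grid, ann = coarse_mandible
        prof = ventral_profile_arch(ann)
        assert 0.08 < prof["rise_to_span"] < 0.18
        dims = corpus_section_dims(grid, ann)
        assert 3.0 < dims["depth_mm"] < 9.0
        assert 3.0 < dims["width_mm"] < 7.0
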