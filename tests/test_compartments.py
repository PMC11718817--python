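"""Signed distance, drift correction and compartment classification."""

import numpy as np
import pytest
import trimesh

from spherotrack.compartments import (
    classify,
    count_compartment,
    drift_correct,
    infiltration_percent,
    signed_distance,
)
from spherotrack.motility import summarize_tracks
from spherotrack.simcore import (
    MotilityParams,
    ScenarioConfig,
    simulate_scenario,
)
from spherotrack.trackio import Sphere, SurfaceSeries, Track, ValidationError


class TestSignedDistance:
    def test_sphere_interior_point(self):
        d = signed_distance(Sphere((0, 0, 0), 100.0), np.array([50.0, 0, 0]))
        assert d == pytest.approx(-50.0)

    def test_point_on_surface_counts_as_inside(self):
        sph = Sphere((0, 0, 0), 100.0)
        assert signed_distance(sph, np.array([100.0, 0, 0])) == pytest.approx(0.0)
        track = Track(
            "t", "ctl", "n/a", "n/a", [0.0, 0.5],
            [[100.0, 0, 0], [100.0, 0, 0]],
        )
        labels = classify([track], SurfaceSeries([(0.0, sph), (0.5, sph)]))
        assert (labels.frame_labels["location"] == "infiltrating").all()

    def test_mesh_sign_matches_ray_parity_oracle(
        self, cube_mesh, ray_parity_inside
    ):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1.0, 1.0, (1000, 3))
        d = signed_distance(cube_mesh, pts)
        np.testing.assert_array_equal(d <= 1e-9, ray_parity_inside(cube_mesh, pts))

    def test_mesh_distance_magnitude_on_cube(self, cube_mesh):
        # analytic distance to an axis-aligned unit cube
        rng = np.random.default_rng(4)
        pts = rng.uniform(-1.0, 1.0, (200, 3))
        q = np.abs(pts) - 0.5
        expected = np.linalg.norm(np.maximum(q, 0), axis=1) + np.minimum(
            q.max(axis=1), 0
        )
        np.testing.assert_allclose(
            signed_distance(cube_mesh, pts), expected, atol=1e-12
        )

    def test_fine_sphere_mesh_agrees_with_analytic_sphere(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=100.0)
        assert len(mesh.faces) >= 2000
        rng = np.random.default_rng(5)
        pts = rng.uniform(-130, 130, (1000, 3))
        r = np.linalg.norm(pts, axis=1)
        pts, r = pts[np.abs(r - 100) >= 1.0], r[np.abs(r - 100) >= 1.0]
        disagree = (signed_distance(mesh, pts) <= 0) != (r <= 100.0)
        assert disagree.mean() <= 0.001


def _simulate_small(seed=3, **kw):
    cfg = ScenarioConfig(
        seed=seed, n_frames=16, n_tumor=60, n_macrophage=8, n_ctl=40, **kw
    )
    return simulate_scenario(cfg)


def _add_drift(tracks, surfaces, per_frame):
    per_frame = np.asarray(per_frame, dtype=float)
    n = tracks[0].n_samples
    drift = np.vstack([np.zeros(3), np.cumsum(np.tile(per_frame, (n - 1, 1)), axis=0)])
    shifted = [
        Track(
            t.track_id, t.cell_type, t.genotype, t.treatment,
            t.times, t.positions + drift, apoptotic=t.apoptotic,
        )
        for t in tracks
    ]
    frames = [
        (t, Sphere(tuple(g.center_array + drift[k]), g.radius))
        for k, (t, g) in enumerate(surfaces.frames)
    ]
    return shifted, SurfaceSeries(frames)


class TestDriftCorrection:
    def test_pure_translation_removed_exactly(self):
        # stationary tumor cells make the drift estimate exact
        out = _simulate_small(
            tumor_params=MotilityParams(mean_speed=0.0, speed_cv=0.0)
        )
        shifted, shifted_surf = _add_drift(
            out.tracks, out.surfaces, (1.0, 0.0, 0.0)
        )
        corrected, corr_surf = drift_correct(shifted, shifted_surf)
        for orig, corr in zip(out.tracks, corrected):
            np.testing.assert_allclose(corr.positions, orig.positions, atol=1e-9)
        for (_, g0), (_, g1) in zip(out.surfaces.frames, corr_surf.frames):
            np.testing.assert_allclose(g1.center_array, g0.center_array, atol=1e-9)

    def test_known_drift_leaves_speeds_unchanged(self):
        # correction commutes with adding rigid drift, so corrected
        # kinematics match the corrected no-drift run to round-off
        out = _simulate_small()
        base, _ = drift_correct(out.tracks, out.surfaces)
        shifted, shifted_surf = _add_drift(out.tracks, out.surfaces, (0.5, -0.2, 0.1))
        corrected, _ = drift_correct(shifted, shifted_surf)
        s0 = summarize_tracks(base)
        s1 = summarize_tracks(corrected)
        np.testing.assert_allclose(
            s1.average_speed.to_numpy(), s0.average_speed.to_numpy(), atol=1e-9
        )

    def test_drift_free_input_with_static_reference_is_identity(self):
        out = _simulate_small(
            tumor_params=MotilityParams(mean_speed=0.0, speed_cv=0.0)
        )
        corrected, _ = drift_correct(out.tracks, out.surfaces)
        for orig, corr in zip(out.tracks, corrected):
            np.testing.assert_allclose(corr.positions, orig.positions, atol=1e-12)

    def test_surface_centroid_fallback(self):
        sph = [
            (k * 0.5, Sphere((1.0 * k, 0.0, 0.0), 50.0)) for k in range(4)
        ]
        track = Track(
            "c", "ctl", "n/a", "n/a", np.arange(4) * 0.5,
            np.tile([10.0, 0, 0], (4, 1)) + np.outer(np.arange(4), [1.0, 0, 0]),
        )
        corrected, corr_surf = drift_correct([track], SurfaceSeries(sph))
        np.testing.assert_allclose(
            corrected[0].positions, np.tile([10.0, 0, 0], (4, 1))
        )
        for _, g in corr_surf.frames:
            np.testing.assert_allclose(g.center_array, [0, 0, 0])

    def test_no_reference_objects_raises(self):
        track = Track("c", "ctl", "n/a", "n/a", [0, 0.5], [[0] * 3] * 2)
        with pytest.raises(ValidationError, match="drift"):
            drift_correct([track], None)


class TestClassify:
    def test_track_inside_sphere_all_infiltrating(self):
        sph = Sphere((0, 0, 0), 150.0)
        track = Track(
            "t", "ctl", "n/a", "n/a", [0, 0.5, 1.0],
            [[50, 0, 0], [0, 50, 0], [0, 0, 50]],
        )
        surfaces = SurfaceSeries([(0.0, sph), (0.5, sph), (1.0, sph)])
        labels = classify([track], surfaces)
        assert (labels.frame_labels["location"] == "infiltrating").all()
        assert labels.track_labels["track_location"].iloc[0] == "infiltrating"

    def test_majority_rule_two_in_one_out(self):
        sph = Sphere((0, 0, 0), 100.0)
        track = Track(
            "t", "ctl", "n/a", "n/a", [0, 0.5, 1.0],
            [[50, 0, 0], [60, 0, 0], [150, 0, 0]],
        )
        surfaces = SurfaceSeries([(0.0, sph), (0.5, sph), (1.0, sph)])
        labels = classify([track], surfaces)
        assert labels.track_labels["track_location"].iloc[0] == "infiltrating"

    def test_tie_counts_as_infiltrating(self):
        sph = Sphere((0, 0, 0), 100.0)
        track = Track(
            "t", "ctl", "n/a", "n/a", [0, 0.5], [[50, 0, 0], [150, 0, 0]]
        )
        labels = classify([track], SurfaceSeries([(0.0, sph), (0.5, sph)]))
        assert labels.track_labels["track_location"].iloc[0] == "infiltrating"

    def test_frame_labels_match_bruteforce_on_simulation(self):
        out = _simulate_small(seed=9)
        labels = classify(out.tracks, out.surfaces)
        radii = {float(t): g.radius for t, g in out.surfaces.frames}
        by_track = {t.track_id: t for t in out.tracks}
        for _, row in labels.frame_labels.iterrows():
            tr = by_track[row.track_id]
            i = int(row.frame_index)
            inside = np.linalg.norm(tr.positions[i]) <= radii[float(tr.times[i])]
            assert (row.location == "infiltrating") == inside

    def test_time_mismatch_raises(self):
        sph = Sphere((0, 0, 0), 100.0)
        track = Track("t", "ctl", "n/a", "n/a", [0, 0.5], [[0] * 3] * 2)
        with pytest.raises(ValidationError, match="surface frame"):
            classify([track], SurfaceSeries([(10.0, sph), (10.5, sph)]))


class TestCountsAndPercent:
    def _labels(self, n_in, n_out):
        sph = Sphere((0, 0, 0), 100.0)
        tracks = []
        for i in range(n_in + n_out):
            r = 50.0 if i < n_in else 200.0
            tracks.append(
                Track(
                    f"c{i:02d}", "ctl", "n/a", "n/a", [0, 0.5],
                    [[r, 0, 0], [r, 0, 0]],
                )
            )
        return classify(tracks, SurfaceSeries([(0.0, sph), (0.5, sph)]))

    def test_three_of_twelve_inside_is_25_percent(self):
        assert infiltration_percent(self._labels(3, 9), "ctl") == pytest.approx(25.0)

    def test_all_inside_is_100_percent(self):
        assert infiltration_percent(self._labels(4, 0), "ctl") == pytest.approx(100.0)

    def test_zero_cells_raises(self):
        with pytest.raises(ValidationError, match="undefined"):
            infiltration_percent(self._labels(2, 2), "macrophage")

    def test_counts(self):
        labels = self._labels(5, 3)
        assert count_compartment(labels, "ctl", "infiltrating") == 5
        assert count_compartment(labels, "ctl", "peripheral") == 3
        assert count_compartment(labels, "tumor", "infiltrating") == 0

    def test_partition_conservation_on_simulation(self):
        out = _simulate_small(seed=21)
        labels = classify(out.tracks, out.surfaces)
        cfg = out.config
        totals = {"tumor": cfg.n_tumor, "macrophage": cfg.n_macrophage,
                  "ctl": cfg.n_ctl}
        for frame in (0, cfg.n_frames - 1):
            for ctype, total in totals.items():
                n_in = count_compartment(labels, ctype, "infiltrating", frame)
                n_out = count_compartment(labels, ctype, "peripheral", frame)
                assert n_in + n_out == total
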