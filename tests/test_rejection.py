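"""Spheroid volume, fold changes, fragment counting, apoptosis proximity."""

import math

import numpy as np
import pytest
import trimesh

from spherotrack.rejection import (
    apoptosis_proximity,
    count_fragments,
    default_link_radius,
    fold_change,
    percent_increase,
    rejection_summary,
    spheroid_volume,
)
from spherotrack.simcore import ScenarioConfig, simulate_scenario
from spherotrack.trackio import Sphere, ValidationError


class TestVolume:
    def test_sphere_closed_form(self):
        v = spheroid_volume(Sphere((0, 0, 0), 150.0))
        assert v == pytest.approx(4.0 / 3.0 * math.pi * 150.0**3)
        assert v == pytest.approx(1.4137e7, rel=1e-4)

    def test_unit_cube_mesh(self, cube_mesh):
        assert spheroid_volume(cube_mesh) == pytest.approx(1.0)

    def test_icosphere_refinement_converges(self):
        errors = {}
        for sub in (1, 2, 3, 4):
            mesh = trimesh.creation.icosphere(subdivisions=sub, radius=100.0)
            v = spheroid_volume(mesh)
            errors[len(mesh.faces)] = abs(v - 4 / 3 * math.pi * 1e6) / (
                4 / 3 * math.pi * 1e6
            )
            # divergence-theorem sum agrees with the library volume
            assert v == pytest.approx(abs(mesh.volume), rel=1e-12)
        faces = sorted(errors)
        assert all(errors[a] > errors[b] for a, b in zip(faces, faces[1:]))
        # inscribed-vertex icosphere volume deficit: ~0.9% at 1280 faces,
        # under 0.5% from 5120 faces on
        assert faces[-1] >= 1280 and errors[faces[-1]] < 0.005

    def test_open_mesh_rejected(self, cube_mesh):
        open_mesh = trimesh.Trimesh(
            vertices=cube_mesh.vertices,
            faces=np.asarray(cube_mesh.faces)[:-1],
            process=False,
        )
        with pytest.raises(ValidationError, match="watertight"):
            spheroid_volume(open_mesh)


class TestFoldChange:
    def test_examples(self):
        assert fold_change(200.0, 100.0) == pytest.approx(0.5)
        assert fold_change(7.3, 7.3) == pytest.approx(1.0)

    def test_halved_radius_gives_eighth_volume(self):
        v0 = spheroid_volume(Sphere((0, 0, 0), 150.0))
        v1 = spheroid_volume(Sphere((0, 0, 0), 75.0))
        assert fold_change(v0, v1) == pytest.approx(0.125)

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValidationError):
            fold_change(0.0, 1.0)

    def test_random_pairs_match_division(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b = rng.uniform(0.1, 100, 2)
            assert fold_change(a, b) == pytest.approx(b / a, rel=1e-12)


class TestPercentIncrease:
    def test_reported_macrophage_infiltration_rise(self):
        # 5.55 -> 11.95 macrophages is a 115% increase to the nearest integer
        assert round(percent_increase(5.55, 11.95)) == 115

    def test_identity_and_doubling(self):
        assert percent_increase(4.2, 4.2) == pytest.approx(0.0)
        assert percent_increase(1.0, 2.0) == pytest.approx(100.0)

    def test_nonpositive_early_rejected(self):
        with pytest.raises(ValidationError):
            percent_increase(0.0, 5.0)


def _bruteforce_components(points, link_radius, min_cells):
    """O(n^2) union-find oracle for fragment counting."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= link_radius:
                parent[find(i)] = find(j)
    from collections import Counter

    sizes = Counter(find(i) for i in range(n))
    return sum(1 for c in sizes.values() if c >= min_cells)


class TestFragments:
    def test_single_compact_cluster(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 5, (50, 3))
        assert count_fragments(pts, link_radius=10.0, min_cells=5) == 1

    def test_two_separated_clusters(self):
        rng = np.random.default_rng(4)
        pts = np.vstack(
            [rng.normal(0, 3, (30, 3)), rng.normal(200, 3, (30, 3))]
        )
        assert count_fragments(pts, link_radius=15.0, min_cells=5) == 2

    def test_matches_bruteforce_union_find(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.uniform(0, 60, (rng.integers(10, 60), 3))
            radius = rng.uniform(5, 25)
            min_cells = int(rng.integers(1, 6))
            assert count_fragments(pts, radius, min_cells) == (
                _bruteforce_components(pts, radius, min_cells)
            )

    def test_monotone_in_link_radius_and_permutation_invariant(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 50, (80, 3))
        counts = [
            count_fragments(pts, r, min_cells=1) for r in (2, 5, 10, 20, 50)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        perm = rng.permutation(len(pts))
        assert count_fragments(pts[perm], 10.0, 1) == count_fragments(pts, 10.0, 1)

    def test_empty_and_default_radius(self):
        assert count_fragments(np.empty((0, 3))) == 0
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 5, (30, 3))
        assert count_fragments(pts) >= 1  # default radius from NN scale
        assert default_link_radius(pts) > 0


class TestProximity:
    def test_apoptotic_at_ctl_positions(self):
        ctls = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        apoptotic_cells = ctls.copy()
        alive_cells = ctls + np.array([0.0, 100.0, 0.0])
        tumor = np.vstack([apoptotic_cells, alive_cells])
        flags = np.array([True, True, False, False])
        res = apoptosis_proximity(tumor, flags, ctls)
        assert res.mean_distance_apoptotic == pytest.approx(0.0)
        assert res.mean_distance_alive == pytest.approx(100.0)
        assert res.n_apoptotic == 2 and res.n_alive == 2

    def test_nearest_ctl_distances(self):
        res = apoptosis_proximity(
            np.array([[3.0, 0, 0], [0, 4.0, 0]]),
            np.array([False, True]),
            np.array([[0.0, 0, 0]]),
        )
        assert res.mean_distance_alive == pytest.approx(3.0)
        assert res.mean_distance_apoptotic == pytest.approx(4.0)

    def test_empty_flag_class_reports_nan_not_error(self):
        res = apoptosis_proximity(
            np.array([[1.0, 0, 0]]), np.array([False]), np.array([[0.0, 0, 0]])
        )
        assert math.isnan(res.mean_distance_apoptotic)
        assert res.n_apoptotic == 0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        tumor = rng.normal(0, 30, (40, 3))
        flags = rng.uniform(size=40) < 0.3
        ctls = rng.normal(0, 30, (20, 3))
        base = apoptosis_proximity(tumor, flags, ctls)
        # random rotation + translation applied jointly
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([10.0, -20.0, 5.0])
        moved = apoptosis_proximity(tumor @ q.T + shift, flags, ctls @ q.T + shift)
        assert moved.mean_distance_alive == pytest.approx(
            base.mean_distance_alive, rel=1e-9
        )
        assert moved.mean_distance_apoptotic == pytest.approx(
            base.mean_distance_apoptotic, rel=1e-9
        )

    def test_contact_killing_couples_apoptosis_to_ctl_proximity(self):
        # the generative model kills only tumor cells adjacent to an
        # arrested CTL, so apoptotic cells must sit closer to CTLs
        wins = 0
        for seed in range(20):
            cfg = ScenarioConfig(
                seed=seed, n_frames=31, n_tumor=120, n_macrophage=0,
                n_ctl=120, ctl_inside_fraction=0.5,
                kill_prob_per_arrest_min=0.5,
            )
            out = simulate_scenario(cfg)
            final = {
                t.cell_type: [] for t in out.tracks
            }
            flags = []
            for t in out.tracks:
                final[t.cell_type].append(t.positions[-1])
                if t.cell_type == "tumor":
                    flags.append(bool(t.apoptotic[-1]))
            res = apoptosis_proximity(
                np.asarray(final["tumor"]), np.asarray(flags),
                np.asarray(final["ctl"]),
            )
            if res.n_apoptotic and res.mean_distance_apoptotic < res.mean_distance_alive:
                wins += 1
        assert wins >= 18


class TestRejectionSummary:
    def test_volume_and_fragment_fold_changes(self):
        rng = np.random.default_rng(10)
        initial = rng.normal(0, 10, (60, 3))
        final = np.vstack(
            [rng.normal(0, 10, (30, 3)), rng.normal(300, 10, (30, 3))]
        )
        summary = rejection_summary(
            Sphere((0, 0, 0), 100.0), Sphere((0, 0, 0), 50.0),
            initial, final, link_radius=15.0,
        )
        assert summary.volume_fold_change == pytest.approx(0.125)
        assert summary.fragments_initial == 1
        assert summary.fragments_final == 2
        assert summary.fragment_fold_change == pytest.approx(2.0)
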