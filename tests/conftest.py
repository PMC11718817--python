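import numpy as np
import pytest
import trimesh

from spherotrack.trackio import Track


@pytest.fixture
def make_track():
    """Factory for a minimal valid CTL track from a position array."""

    def _make(positions, dt=0.5, track_id="t0", cell_type="ctl", **kw):
        positions = np.asarray(positions, dtype=float)
        times = np.arange(len(positions)) * dt
        return Track(
            track_id=track_id,
            cell_type=cell_type,
            genotype=kw.pop("genotype", "n/a"),
            treatment=kw.pop("treatment", "n/a"),
            times=times,
            positions=positions,
            **kw,
        )

    return _make


@pytest.fixture
def cube_mesh():
    """Unit cube centered at the origin (8 vertices, 12 triangles)."""
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


@pytest.fixture
def ray_parity_inside():
    """Independent brute-force point-in-mesh oracle.

    Casts a ray in a fixed irrational direction from each point and
    counts Moller-Trumbore triangle intersections; odd parity means
    inside.  Shares no code with the library's containment test.
    """

    def _inside(mesh, points):
        direction = np.array([0.57735027, 0.26726124, 0.77151675])
        direction /= np.linalg.norm(direction)
        tri = np.asarray(mesh.vertices)[np.asarray(mesh.faces)]
        out = np.zeros(len(points), dtype=bool)
        for i, p in enumerate(np.atleast_2d(points)):
            hits = 0
            for a, b, c in tri:
                e1, e2 = b - a, c - a
                h = np.cross(direction, e2)
                det = e1 @ h
                if abs(det) < 1e-12:
                    continue
                s = p - a
                u = (s @ h) / det
                if u < 0 or u > 1:
                    continue
                q = np.cross(s, e1)
                v = (direction @ q) / det
                if v < 0 or u + v > 1:
                    continue
                t = (e2 @ q) / det
                if t > 1e-12:
                    hits += 1
            out[i] = hits % 2 == 1
        return out

    return _inside


@pytest.fixture(scope="session")
def occupancy_cohort():
    """500 CTL tracks x 120 steps with exact stationary arrest occupancy 0.30.

    Rates are chosen analytically so the simulated per-frame chain
    (switch probability 1 - exp(-rate * dt)) has stationary occupancy
    exactly 0.30; no tumor contact, so the chain is homogeneous.
    """
    from spherotrack.simcore import (
        MotilityParams,
        ScenarioConfig,
        simulate_scenario,
    )

    dt, pi, k_on = 0.5, 0.30, 0.3
    p_on = -np.expm1(-k_on * dt)
    k_off = -np.log1p(-p_on * (1.0 - pi) / pi) / dt
    params = MotilityParams(
        mean_speed=4.5,
        speed_cv=0.35,
        persistence_kappa=7.0,
        arrest_on_rate=k_on,
        arrest_off_rate=k_off,
    )
    cfg = ScenarioConfig(
        seed=7,
        frame_interval=dt,
        n_frames=121,
        n_tumor=0,
        n_macrophage=0,
        n_ctl=500,
        ctl_params=params,
        kill_prob_per_arrest_min=0.0,
    )
    assert abs(params.discrete_stationary_arrest_fraction(dt) - pi) < 1e-12
    return simulate_scenario(cfg), pi
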