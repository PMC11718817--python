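"""Drift correction and infiltrating/peripheral compartment classification.

A cell is *infiltrating* at a frame when it lies inside (or exactly on)
the spheroid surface and *peripheral* otherwise; the track-level label is
the majority of its frame labels, with ties counted as infiltrating.
Signed distances are negative inside.  Rigid stage/sample drift shared by
all objects is removed before classification using the tumor-cell
centroid as the reference (falling back to the surface centroid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .trackio import Geometry, Sphere, SurfaceSeries, Track, ValidationError

__all__ = [
    "CompartmentLabels",
    "signed_distance",
    "drift_correct",
    "classify",
    "infiltration_percent",
    "count_compartment",
]

#: |signed distance| below this counts as exactly on the surface (inside)
BOUNDARY_TOLERANCE_UM = 1e-9


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact unsigned distances for matched (point, triangle) pairs.

    The closest feature is either the projection onto the face plane
    (when its barycentric coordinates are inside) or a clamped projection
    onto one of the three edges; taking the minimum over both covers
    every Voronoi region of the triangle.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    best = np.full(len(points), np.inf)
    for p0, p1 in ((a, b), (b, c), (c, a)):
        e = p1 - p0
        t = np.einsum("ij,ij->i", points - p0, e) / np.einsum("ij,ij->i", e, e)
        t = np.clip(t, 0.0, 1.0)
        best = np.minimum(
            best, np.linalg.norm(points - (p0 + t[:, None] * e), axis=1)
        )
    n = np.cross(b - a, c - a)
    nn = np.einsum("ij,ij->i", n, n)
    ok = nn > 0
    if np.any(ok):
        ap = points - a
        dist_plane = np.einsum("ij,ij->i", ap, n)
        proj = points - (dist_plane / np.where(ok, nn, 1.0))[:, None] * n
        # barycentric test of the projected point
        v0, v1, v2 = c - a, b - a, proj - a
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        denom = d00 * d11 - d01 * d01
        safe = ok & (np.abs(denom) > 0)
        denom = np.where(safe, denom, 1.0)
        u = (d11 * d20 - d01 * d21) / denom
        v = (d00 * d21 - d01 * d20) / denom
        in_face = safe & (u >= 0) & (v >= 0) & (u + v <= 1)
        best = np.where(
            in_face, np.minimum(best, np.abs(dist_plane) / np.sqrt(np.where(ok, nn, 1.0))),
            best,
        )
    return best


def _mesh_unsigned_distance(
    mesh: trimesh.Trimesh, points: np.ndarray, k: int = 64
) -> np.ndarray:
    """Distance to the nearest face, pruning candidates by centroid KD-tree."""
    from scipy.spatial import cKDTree

    tri = mesh.vertices[mesh.faces]  # (n_faces, 3, 3)
    centroids = tri.mean(axis=1)
    k = min(k, len(tri))
    _, idx = cKDTree(centroids).query(points, k=k)
    idx = np.atleast_2d(idx.T).T  # (n_points, k) even for k == 1
    out = np.full(len(points), np.inf)
    for col in range(idx.shape[1]):
        out = np.minimum(
            out, _point_triangle_distance(points, tri[idx[:, col]])
        )
    return out


def _mesh_contains(
    mesh: trimesh.Trimesh, points: np.ndarray, chunk: int = 128
) -> np.ndarray:
    """Containment by generalized winding number (Van Oosterom-Strackee).

    For a watertight mesh the summed signed solid angle is ±4π inside
    and 0 outside; the threshold at 2π makes the test robust to
    floating-point noise.
    """
    tri = mesh.vertices[mesh.faces]
    inside = np.empty(len(points), dtype=bool)
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk]
        r = tri[None, :, :, :] - p[:, None, None, :]  # (chunk, faces, 3, 3)
        a, b, c = r[:, :, 0], r[:, :, 1], r[:, :, 2]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("pfi,pfi->pf", a, b) * lc
            + np.einsum("pfi,pfi->pf", b, c) * la
            + np.einsum("pfi,pfi->pf", c, a) * lb
        )
        omega = 2.0 * np.arctan2(num, den)
        inside[lo : lo + chunk] = np.abs(omega.sum(axis=1)) > 2.0 * np.pi
    return inside


def signed_distance(geometry: Geometry, points: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance from points to the surface, µm.

    Negative inside, positive outside, 0 on the surface.  Spheres use the
    closed form ``|p - c| - R``; watertight meshes use exact distance to
    the nearest face with the sign decided by winding-number containment.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if isinstance(geometry, Sphere):
        if geometry.radius <= 0:
            raise ValidationError("degenerate sphere (radius <= 0)")
        d = np.linalg.norm(pts - geometry.center_array, axis=1) - geometry.radius
    else:
        d = _mesh_unsigned_distance(geometry, pts)
        d = np.where(_mesh_contains(geometry, pts), -d, d)
    return d if np.asarray(points).ndim == 2 else d[0]


@dataclass
class CompartmentLabels:
    """Per-frame and per-track infiltrating/peripheral assignment.

    ``frame_labels`` has one row per (track_id, frame_index) with the
    signed distance (µm, negative inside) and location; ``track_labels``
    one row per track with the majority-rule location.
    """

    frame_labels: pd.DataFrame
    track_labels: pd.DataFrame

    def location_at(self, frame_index: int) -> pd.DataFrame:
        return self.frame_labels[self.frame_labels["frame_index"] == frame_index]


def drift_correct(
    tracks: list[Track], surfaces: SurfaceSeries | None = None
) -> tuple[list[Track], SurfaceSeries | None]:
    """Remove rigid per-frame translation shared by all objects.

    The per-frame drift is the median (componentwise) frame-to-frame
    displacement of tumor-cell positions; with no tumor tracks the
    surface centroid displacement is used.  Cumulative drift is
    subtracted from every spot and surface frame; frame 0 is unchanged.
    """
    tumor = [t for t in tracks if t.cell_type == "tumor"]
    if tumor:
        n_frames = tumor[0].n_samples
        P = np.stack([t.positions for t in tumor])  # (n_tumor, n_frames, 3)
        step_drift = np.median(np.diff(P, axis=1), axis=0)  # (n_frames-1, 3)
    elif surfaces is not None and len(surfaces.frames) >= 2:
        centers = []
        for _, geom in surfaces.frames:
            if isinstance(geom, Sphere):
                centers.append(geom.center_array)
            else:
                centers.append(np.asarray(geom.centroid))
        centers = np.asarray(centers)
        n_frames = len(centers)
        step_drift = np.diff(centers, axis=0)
    else:
        raise ValidationError(
            "no tumor tracks or multi-frame surface series to estimate drift "
            "from; disable drift correction for this input"
        )
    drift = np.vstack([np.zeros(3), np.cumsum(step_drift, axis=0)])

    corrected = []
    for t in tracks:
        if t.n_samples != n_frames:
            raise ValidationError(
                f"track {t.track_id!r} has {t.n_samples} frames, reference "
                f"has {n_frames}"
            )
        corrected.append(
            Track(
                track_id=t.track_id,
                cell_type=t.cell_type,
                genotype=t.genotype,
                treatment=t.treatment,
                times=t.times.copy(),
                positions=t.positions - drift,
                apoptotic=None if t.apoptotic is None else t.apoptotic.copy(),
            )
        )
    if surfaces is None:
        return corrected, None
    new_frames = []
    for k, (time, geom) in enumerate(surfaces.frames):
        if isinstance(geom, Sphere):
            new_frames.append(
                (time, Sphere(tuple(geom.center_array - drift[k]), geom.radius))
            )
        else:
            new_frames.append(
                (
                    time,
                    trimesh.Trimesh(
                        vertices=geom.vertices - drift[k],
                        faces=geom.faces.copy(),
                        process=False,
                    ),
                )
            )
    return corrected, SurfaceSeries(new_frames)


def classify(tracks: list[Track], surfaces: SurfaceSeries) -> CompartmentLabels:
    """Label every (track, frame) as infiltrating or peripheral.

    Surface frames are matched to track times by nearest time within half
    a frame interval.  Signed distance <= 0 (boundary included) counts as
    infiltrating; the track label is the per-frame majority with ties
    infiltrating.
    """
    frame_rows = []
    track_rows = []
    for tr in tracks:
        tol = tr.frame_interval / 2.0
        dists = np.empty(tr.n_samples)
        for i, t in enumerate(tr.times):
            geom = surfaces.geometry_at(float(t), tolerance=tol)
            dists[i] = signed_distance(geom, tr.positions[i])
        inside = dists <= BOUNDARY_TOLERANCE_UM
        for i in range(tr.n_samples):
            frame_rows.append(
                (
                    tr.track_id,
                    tr.cell_type,
                    i,
                    dists[i],
                    "infiltrating" if inside[i] else "peripheral",
                )
            )
        majority_inside = inside.sum() * 2 >= tr.n_samples  # ties -> infiltrating
        track_rows.append(
            (
                tr.track_id,
                tr.cell_type,
                "infiltrating" if majority_inside else "peripheral",
            )
        )
    frame_labels = pd.DataFrame(
        frame_rows,
        columns=["track_id", "cell_type", "frame_index", "signed_distance", "location"],
    )
    track_labels = pd.DataFrame(
        track_rows, columns=["track_id", "cell_type", "track_location"]
    )
    return CompartmentLabels(frame_labels=frame_labels, track_labels=track_labels)


def infiltration_percent(
    labels: CompartmentLabels, cell_type: str, frame: int = 0
) -> float:
    """Percent of cells of ``cell_type`` infiltrating at the given frame.

    Defaults to the first frame of the video, the convention used for
    per-video infiltration readouts.
    """
    sub = labels.frame_labels
    sub = sub[(sub["cell_type"] == cell_type) & (sub["frame_index"] == frame)]
    n = len(sub)
    if n == 0:
        raise ValidationError(
            f"no {cell_type} cells at frame {frame}: infiltration percent undefined"
        )
    return 100.0 * float((sub["location"] == "infiltrating").sum()) / n


def count_compartment(
    labels: CompartmentLabels, cell_type: str, location: str, frame: int = 0
) -> int:
    """Number of cells of ``cell_type`` with the given per-frame location."""
    sub = labels.frame_labels
    sub = sub[
        (sub["cell_type"] == cell_type)
        & (sub["frame_index"] == frame)
        & (sub["location"] == location)
    ]
    return int(len(sub))
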