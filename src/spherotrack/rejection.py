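"""Tumor-rejection readouts: spheroid volume, fragmentation and
apoptosis-proximity statistics.

Rejection of the spheroid by cytotoxic T cells shows up as shrinking
spheroid volume, break-up into fragments, and apoptotic tumor cells
sitting closer to CTLs than surviving ones.  Volumes come from the
analytic sphere or a watertight mesh; fragments are connected components
of the tumor-cell position graph under single linkage; proximity is the
centroid-to-centroid distance from each tumor cell to its nearest CTL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .trackio import Geometry, Sphere, ValidationError, boundary_edge_count

__all__ = [
    "RejectionSummary",
    "ProximityResult",
    "spheroid_volume",
    "fold_change",
    "percent_increase",
    "default_link_radius",
    "count_fragments",
    "apoptosis_proximity",
    "rejection_summary",
]


@dataclass
class RejectionSummary:
    """Initial/final spheroid volume and fragment counts with fold changes."""

    experiment_id: str
    volume_initial: float
    volume_final: float
    volume_fold_change: float
    fragments_initial: int
    fragments_final: int
    fragment_fold_change: float


@dataclass
class ProximityResult:
    """Mean nearest-CTL distance of alive vs apoptotic tumor cells, µm.

    A mean is NaN when its flag class is empty (reported as unavailable,
    never an exception).
    """

    experiment_id: str
    mean_distance_alive: float
    mean_distance_apoptotic: float
    n_alive: int
    n_apoptotic: int


def spheroid_volume(geometry: Geometry) -> float:
    """Enclosed volume in µm³: (4/3)πR³ for spheres, signed
    tetrahedron sum (divergence theorem) for watertight meshes."""
    if isinstance(geometry, Sphere):
        return 4.0 / 3.0 * math.pi * geometry.radius**3
    bad = boundary_edge_count(geometry)
    if bad:
        raise ValidationError(
            f"cannot compute volume: mesh not watertight ({bad} boundary edges)"
        )
    v = geometry.vertices
    tri = v[geometry.faces]  # (n_faces, 3, 3)
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


def fold_change(initial: float, final: float) -> float:
    """final / initial (e.g. overnight change in spheroid volume)."""
    if initial <= 0:
        raise ValidationError(f"initial value must be > 0, got {initial}")
    return final / initial


def percent_increase(early: float, late: float) -> float:
    """100 x (late - early) / early."""
    if early <= 0:
        raise ValidationError(f"early value must be > 0, got {early}")
    return 100.0 * (late - early) / early


def default_link_radius(positions: np.ndarray) -> float:
    """2x the mean nearest-neighbor distance of a point set."""
    pts = np.asarray(positions, dtype=float)
    if len(pts) < 2:
        raise ValidationError("need >= 2 points for a nearest-neighbor scale")
    d, _ = cKDTree(pts).query(pts, k=2)
    return 2.0 * float(d[:, 1].mean())


def count_fragments(
    positions: np.ndarray,
    link_radius: float | None = None,
    min_cells: int = 5,
) -> int:
    """Number of spheroid fragments among tumor-cell positions at one frame.

    Fragments are connected components of the graph joining cells within
    ``link_radius`` (single linkage); components with fewer than
    ``min_cells`` cells are discarded as debris.  ``link_radius``
    defaults to twice the mean nearest-neighbor distance of the given
    positions.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.size == 0:
        return 0
    pts = np.atleast_2d(pts)
    if link_radius is None:
        link_radius = default_link_radius(pts)
    if link_radius <= 0:
        raise ValidationError("link_radius must be > 0")
    n = len(pts)
    pairs = cKDTree(pts).query_pairs(link_radius, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, label = sparse.csgraph.connected_components(adj, directed=False)
    sizes = np.bincount(label, minlength=n_comp)
    return int(np.count_nonzero(sizes >= min_cells))


def apoptosis_proximity(
    tumor_positions: np.ndarray,
    apoptotic: np.ndarray,
    ctl_positions: np.ndarray,
    experiment_id: str = "",
) -> ProximityResult:
    """Mean distance from alive vs apoptotic tumor cells to the nearest CTL.

    Distances are centroid to centroid at one (typically the final)
    frame.  An empty flag class yields a NaN mean for that class.
    """
    tumor = np.atleast_2d(np.asarray(tumor_positions, dtype=float))
    ctls = np.atleast_2d(np.asarray(ctl_positions, dtype=float))
    flags = np.asarray(apoptotic, dtype=bool)
    if len(ctls) == 0:
        raise ValidationError("need >= 1 CTL position")
    if len(tumor) != len(flags):
        raise ValidationError("apoptotic flags do not match tumor positions")
    d, _ = cKDTree(ctls).query(tumor)
    n_apo = int(flags.sum())
    n_alive = int(len(flags) - n_apo)
    return ProximityResult(
        experiment_id=experiment_id,
        mean_distance_alive=float(d[~flags].mean()) if n_alive else math.nan,
        mean_distance_apoptotic=float(d[flags].mean()) if n_apo else math.nan,
        n_alive=n_alive,
        n_apoptotic=n_apo,
    )


def rejection_summary(
    geometry_initial: Geometry,
    geometry_final: Geometry,
    tumor_positions_initial: np.ndarray,
    tumor_positions_final: np.ndarray,
    experiment_id: str = "",
    link_radius: float | None = None,
    min_cells: int = 5,
) -> RejectionSummary:
    """Volume and fragment fold changes between two observations.

    The linking radius is derived from the initial frame (unless given)
    and reused for the final frame so both counts share one scale.
    """
    if link_radius is None:
        link_radius = default_link_radius(tumor_positions_initial)
    v0 = spheroid_volume(geometry_initial)
    v1 = spheroid_volume(geometry_final)
    f0 = count_fragments(tumor_positions_initial, link_radius, min_cells)
    f1 = count_fragments(tumor_positions_final, link_radius, min_cells)
    if f0 < 1:
        raise ValidationError("initial frame has no fragment (empty spheroid?)")
    return RejectionSummary(
        experiment_id=experiment_id,
        volume_initial=v0,
        volume_final=v1,
        volume_fold_change=fold_change(v0, v1),
        fragments_initial=f0,
        fragments_final=f1,
        fragment_fold_change=fold_change(f0, f1),
    )
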