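"""Arrest-phase statistics from instantaneous velocity.

A cell is *arrested* whenever its instantaneous velocity falls strictly
below a threshold (2 µm/min by default).  The arrest coefficient of a
track is the fraction of its velocity samples below the threshold — the
fraction of observed time the cell stays in arrest — and arrest
durations are the lengths of maximal below-threshold runs.  Distribution
displays use a Gaussian kernel density on [0, 1] with boundary
reflection, since arrest coefficients live on the unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motility import VelocitySeries
from .simcore import ARREST_THRESHOLD_UM_PER_MIN
from .trackio import ValidationError

__all__ = [
    "ArrestProfile",
    "DensityCurve",
    "arrest_profile",
    "arrest_density",
    "pause_timeline",
]


@dataclass
class ArrestProfile:
    """Arrest mask, coefficient and maximal-run durations of one track."""

    track_id: str
    threshold: float
    arrest_mask: np.ndarray
    arrest_coefficient: float
    arrest_durations: np.ndarray  # minutes, one per maximal below-threshold run


@dataclass
class DensityCurve:
    """Kernel density of a bounded metric on an evaluation grid."""

    metric: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True, in samples."""
    if mask.size == 0 or not mask.any():
        return np.array([], dtype=int)
    padded = np.concatenate([[0], mask.astype(int), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def arrest_profile(
    velocities: VelocitySeries,
    threshold: float = ARREST_THRESHOLD_UM_PER_MIN,
) -> ArrestProfile:
    """Threshold a velocity series into an arrest profile.

    Arrest is strict: ``v < threshold``; a sample exactly at the
    threshold counts as motile.  There is no minimum arrest duration — a
    single below-threshold sample is a (frame-interval-long) arrest.
    """
    v = np.asarray(velocities.values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty velocity series")
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    mask = v < threshold
    runs = _run_lengths(mask)
    return ArrestProfile(
        track_id=velocities.track_id,
        threshold=threshold,
        arrest_mask=mask,
        arrest_coefficient=float(mask.mean()),
        arrest_durations=runs * velocities.frame_interval,
    )


def arrest_density(
    coefficients: np.ndarray,
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> DensityCurve:
    """Boundary-reflected Gaussian KDE of arrest coefficients on [0, 1].

    The kernel estimate is reflected at both boundaries (density(x) =
    k(x) + k(-x) + k(2-x) for x in [0, 1]) so that no probability mass
    leaks outside the unit interval.  Default bandwidth is Silverman's
    rule; all-identical samples make that degenerate and raise an error
    suggesting an explicit bandwidth.
    """
    x = np.asarray(coefficients, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValidationError("need >= 2 finite coefficients for a density")
    if bandwidth is None:
        if np.all(x == x[0]):
            raise ValidationError(
                "all coefficients identical: Silverman bandwidth degenerates; "
                "pass an explicit bandwidth"
            )
        bandwidth = 1.06 * np.std(x, ddof=1) * x.size ** (-1.0 / 5.0)  # Silverman
    if bandwidth <= 0:
        raise ValidationError("bandwidth must be > 0")
    grid = np.linspace(0.0, 1.0, grid_size)

    def k(points: np.ndarray) -> np.ndarray:
        z = (points[:, None] - x[None, :]) / bandwidth
        return stats.norm.pdf(z).sum(axis=1) / (x.size * bandwidth)

    # reflect about both boundaries; second-order images (shifts by ±2)
    # matter once the bandwidth is an appreciable fraction of the interval
    density = np.zeros_like(grid)
    for shift in (-2.0, 0.0, 2.0):
        density += k(shift + grid) + k(shift - grid)
    return DensityCurve(
        metric="arrest_coefficient", grid=grid, density=density, bandwidth=bandwidth
    )


def pause_timeline(
    velocities: VelocitySeries,
    threshold: float = ARREST_THRESHOLD_UM_PER_MIN,
) -> pd.DataFrame:
    """Plot-ready instantaneous-velocity timeline with the arrest flag.

    One row per velocity sample: midpoint time of the frame pair, the
    velocity, and whether it falls strictly below the threshold (the
    pausing phases marked by the dashed threshold line in velocity
    plots).  ``threshold`` may be 0 here, in which case no sample is
    flagged.
    """
    v = np.asarray(velocities.values, dtype=float)
    return pd.DataFrame(
        {
            "track_id": velocities.track_id,
            "t_min": velocities.midpoint_times,
            "velocity_um_per_min": v,
            "below_threshold": v < threshold,
        }
    )
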