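"""Per-track kinematic metrics for 3D cell tracks.

The metrics mirror the standard tracking-software export: instantaneous
velocity (per-step speed from forward differences), average speed, track
displacement (start-to-end vector distance), track length (summed step
norms), straightness (displacement / length, 1 for directional and 0 for
confined motion) and track duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trackio import Track, ValidationError

__all__ = [
    "VelocitySeries",
    "MotilitySummary",
    "instantaneous_velocity",
    "summarize_track",
    "summarize_tracks",
    "cohort_summary",
]

METRICS = [
    "average_speed",
    "track_displacement",
    "track_length",
    "straightness",
    "track_duration",
]


@dataclass
class VelocitySeries:
    """Instantaneous velocity samples of one track, µm/min.

    ``values[i] = |r_{i+1} - r_i| / frame_interval`` — one sample per
    consecutive frame pair (forward differences, so sample ``i`` is
    aligned with the step leaving frame ``i``).
    """

    track_id: str
    values: np.ndarray
    frame_interval: float

    @property
    def midpoint_times(self) -> np.ndarray:
        """Midpoint time of each frame pair, minutes from track start."""
        return (np.arange(len(self.values)) + 0.5) * self.frame_interval


@dataclass
class MotilitySummary:
    """Whole-track kinematics.  ``straightness`` is NaN when undefined
    (zero track length); such tracks are excluded from cohort means."""

    track_id: str
    average_speed: float
    track_displacement: float
    track_length: float
    straightness: float
    track_duration: float


def instantaneous_velocity(track: Track) -> VelocitySeries:
    """Per-step speed from forward differences, µm/min."""
    if track.n_samples < 2:
        raise ValidationError(
            f"track {track.track_id!r}: need >= 2 samples for velocities"
        )
    steps = np.diff(track.positions, axis=0)
    dt = track.frame_interval
    return VelocitySeries(
        track_id=track.track_id,
        values=np.linalg.norm(steps, axis=1) / dt,
        frame_interval=dt,
    )


def summarize_track(track: Track) -> MotilitySummary:
    """Whole-track kinematic summary.

    track_length = sum of step norms; track_displacement = |r_last -
    r_first|; average_speed = track_length / track_duration (equal to the
    mean instantaneous velocity under uniform sampling); straightness =
    displacement / length, NaN for a zero-length track.
    """
    steps = np.diff(track.positions, axis=0)
    length = float(np.linalg.norm(steps, axis=1).sum())
    displacement = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    duration = track.duration
    straightness = displacement / length if length > 0 else math.nan
    return MotilitySummary(
        track_id=track.track_id,
        average_speed=length / duration,
        track_displacement=displacement,
        track_length=length,
        straightness=straightness,
        track_duration=duration,
    )


def summarize_tracks(tracks: list[Track]) -> pd.DataFrame:
    """Summaries for a collection of tracks, one row per track."""
    rows = [vars(summarize_track(t)) for t in tracks]
    return pd.DataFrame(rows, columns=["track_id"] + METRICS)


def cohort_summary(
    summaries: pd.DataFrame, group_keys: list[str], metrics: list[str] | None = None
) -> pd.DataFrame:
    """Mean +/- SD per group per metric.

    SD uses the n-1 denominator; groups of one report SD 0 with
    ``sd_defined = False``.  Tracks with undefined (NaN) straightness are
    excluded from the straightness row and counted in ``n_excluded``.
    """
    if metrics is None:
        metrics = [m for m in METRICS if m in summaries.columns]
    rows = []
    for keys, grp in summaries.groupby(group_keys, sort=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for metric in metrics:
            if metric not in grp.columns:
                continue
            vals = grp[metric].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            n = len(finite)
            if n == 0:
                continue
            rows.append(
                keys
                + (
                    metric,
                    float(np.mean(finite)),
                    float(np.std(finite, ddof=1)) if n > 1 else 0.0,
                    n,
                    n > 1,
                    len(vals) - n,
                )
            )
    return pd.DataFrame(
        rows,
        columns=list(group_keys)
        + ["metric", "mean", "sd", "n", "sd_defined", "n_excluded"],
    )
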