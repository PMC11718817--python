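"""Readers, writers and validators for cell-track tables and spheroid surface series.

The on-disk formats are plain delimited text (comma-separated, UTF-8,
``.`` decimal) so that every analysis input and output is diff-able and
version-controllable:

* **native track table** — one row per cell per frame with columns
  ``track_id, cell_type, genotype, treatment, frame_index, t_min, x_um,
  y_um, z_um, apoptotic``.  ``frame_index`` is the authoritative ordering
  key; time is stored in decimal minutes and coordinates in physical µm
  (never voxel indices).
* **imaris_position_export dialect** — the conventional column layout of a
  microscope-software position export (``Position X/Y/Z``, ``Unit``,
  ``Time`` as a 1-based frame number, ``TrackID``), mapped onto the native
  schema on read.  A ``Unit`` of ``mm`` is converted to µm (×1000).
* **surface series** — a line-based block format holding, per frame,
  either an analytic sphere (center + radius) or a closed triangle mesh in
  OFF-style vertex/face layout.

Validation is total: malformed input raises a typed error
(:class:`SchemaError` or :class:`ValidationError`) and never yields a
partially constructed object.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "Track",
    "Sphere",
    "SurfaceSeries",
    "SchemaError",
    "ValidationError",
    "read_track_table",
    "write_track_table",
    "tracks_to_table",
    "table_to_tracks",
    "read_surface_series",
    "write_surface_series",
    "boundary_edge_count",
]

CELL_TYPES = ("tumor", "ctl", "macrophage")
GENOTYPES = ("WT", "Il18r_ko", "n/a")
TREATMENTS = ("none", "untreated_mph", "lps_nigericin_mph", "n/a")

#: tolerance on uniform frame spacing, minutes
TIME_TOLERANCE_MIN = 1e-6

NATIVE_COLUMNS = [
    "track_id",
    "cell_type",
    "genotype",
    "treatment",
    "frame_index",
    "t_min",
    "x_um",
    "y_um",
    "z_um",
    "apoptotic",
]


class SchemaError(ValueError):
    """A table is missing mandatory columns or uses unknown vocabulary."""


class ValidationError(ValueError):
    """A structurally complete input violates a data-model invariant."""


@dataclass
class Track:
    """Time-ordered 3D positions of a single tracked cell.

    ``times`` are minutes, ``positions`` µm in a right-handed Cartesian
    frame.  ``apoptotic`` is a per-sample flag carried only by tumor
    cells (``None`` otherwise).
    """

    track_id: str
    cell_type: str
    genotype: str
    treatment: str
    times: np.ndarray
    positions: np.ndarray
    apoptotic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.apoptotic is not None:
            self.apoptotic = np.asarray(self.apoptotic, dtype=bool)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(
                f"track {self.track_id!r}: unknown cell_type {self.cell_type!r}"
            )
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"track {self.track_id!r}: unknown genotype {self.genotype!r}"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"track {self.track_id!r}: unknown treatment {self.treatment!r}"
            )
        n = len(self.times)
        if n < 2:
            raise ValidationError(
                f"track {self.track_id!r}: needs >= 2 samples, got {n}"
            )
        if self.positions.shape != (n, 3):
            raise ValidationError(
                f"track {self.track_id!r}: positions shape {self.positions.shape} "
                f"does not match {n} time samples"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.positions)
        ):
            raise ValidationError(f"track {self.track_id!r}: non-finite values")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValidationError(
                f"track {self.track_id!r}: time not strictly increasing"
            )
        if np.max(dt) - np.min(dt) > TIME_TOLERANCE_MIN:
            raise ValidationError(
                f"track {self.track_id!r}: non-uniform frame spacing "
                f"(range {np.min(dt):.6g}..{np.max(dt):.6g} min)"
            )
        if self.apoptotic is not None and len(self.apoptotic) != n:
            raise ValidationError(
                f"track {self.track_id!r}: apoptotic flag length mismatch"
            )

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Track duration in minutes: (n_samples - 1) x frame interval."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class Sphere:
    """Analytic sphere geometry: center in µm, radius in µm (> 0)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError(f"sphere radius must be > 0, got {self.radius}")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


Geometry = Union[Sphere, trimesh.Trimesh]


def boundary_edge_count(mesh: trimesh.Trimesh) -> int:
    """Number of edges not shared by exactly two faces (0 for watertight)."""
    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.count_nonzero(counts != 2))


def _validate_geometry(geom: Geometry, where: str = "") -> None:
    if isinstance(geom, Sphere):
        return  # radius checked at construction
    bad = boundary_edge_count(geom)
    if bad:
        raise ValidationError(
            f"mesh{where} is not watertight: {bad} edge(s) not shared by "
            "exactly 2 faces"
        )


@dataclass
class SurfaceSeries:
    """Per-frame closed spheroid geometry: list of (t_minutes, geometry)."""

    frames: list[tuple[float, Geometry]]

    def __post_init__(self) -> None:
        for i, (t, geom) in enumerate(self.frames):
            _validate_geometry(geom, where=f" at frame {i} (t={t})")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.frames], dtype=float)

    def geometry_at(self, t: float, tolerance: float) -> Geometry:
        """Geometry of the frame nearest to ``t``, within ``tolerance`` minutes."""
        times = self.times
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) > tolerance:
            raise ValidationError(
                f"no surface frame within {tolerance} min of t={t} "
                f"(nearest at t={times[i]})"
            )
        return self.frames[i][1]


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------

def tracks_to_table(tracks: Iterable[Track]) -> pd.DataFrame:
    """Flatten tracks to the native row-per-frame table.

    Rows are ordered by (track_id, frame_index); ``apoptotic`` is empty
    for cell types that carry no flag.
    """
    records = []
    for tr in tracks:
        # flags stored as 0.0/1.0 (empty when the type carries no flag)
        flags = (
            tr.apoptotic.astype(float)
            if tr.apoptotic is not None
            else np.full(tr.n_samples, np.nan)
        )
        for i in range(tr.n_samples):
            records.append(
                (
                    tr.track_id,
                    tr.cell_type,
                    tr.genotype,
                    tr.treatment,
                    i,
                    tr.times[i],
                    tr.positions[i, 0],
                    tr.positions[i, 1],
                    tr.positions[i, 2],
                    flags[i],
                )
            )
    df = pd.DataFrame.from_records(records, columns=NATIVE_COLUMNS)
    df = df.sort_values(["track_id", "frame_index"], kind="stable").reset_index(
        drop=True
    )
    return df


def table_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Group a native table into validated :class:`Track` objects."""
    missing = [c for c in NATIVE_COLUMNS if c not in df.columns and c != "apoptotic"]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["track_id", "frame_index"])
    if dup.any():
        tid = df.loc[dup, "track_id"].iloc[0]
        raise ValidationError(f"duplicate (track_id, frame_index) in track {tid!r}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame_index", kind="stable")
        apo_flags = None
        if "apoptotic" in grp.columns and grp["apoptotic"].notna().any():
            apo_flags = grp["apoptotic"].astype(float).to_numpy() > 0.5
        tracks.append(
            Track(
                track_id=str(tid),
                cell_type=str(grp["cell_type"].iloc[0]),
                genotype=str(grp["genotype"].iloc[0]),
                treatment=str(grp["treatment"].iloc[0]),
                times=grp["t_min"].to_numpy(dtype=float),
                positions=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                apoptotic=apo_flags,
            )
        )
    return tracks


_IMARIS_REQUIRED = ["Position X", "Position Y", "Position Z", "Unit", "Time", "TrackID"]


def _read_imaris(
    df: pd.DataFrame,
    frame_interval: float,
    cell_type: str,
    genotype: str,
    treatment: str,
) -> pd.DataFrame:
    missing = [c for c in _IMARIS_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    units = df["Unit"].astype(str).str.strip().str.lower().unique()
    scale = {}
    for u in units:
        if u in ("um", "µm", "micrometer", "micrometers"):
            scale[u] = 1.0
        elif u == "mm":
            scale[u] = 1000.0
        else:
            raise SchemaError(f"unknown unit {u!r} (expected um or mm)")
    fac = df["Unit"].astype(str).str.strip().str.lower().map(scale).to_numpy()
    frame = df["Time"].astype(int).to_numpy() - 1  # Time is a 1-based frame number
    out = pd.DataFrame(
        {
            "track_id": df["TrackID"].astype(str),
            "cell_type": cell_type,
            "genotype": genotype,
            "treatment": treatment,
            "frame_index": frame,
            "t_min": frame * frame_interval,
            "x_um": df["Position X"].astype(float).to_numpy() * fac,
            "y_um": df["Position Y"].astype(float).to_numpy() * fac,
            "z_um": df["Position Z"].astype(float).to_numpy() * fac,
            "apoptotic": np.nan,
        }
    )
    return out


def read_track_table(
    path: str | Path,
    dialect: str = "native",
    *,
    frame_interval: float = 0.5,
    cell_type: str = "ctl",
    genotype: str = "n/a",
    treatment: str = "n/a",
) -> list[Track]:
    """Read a track table and return validated tracks.

    Parameters
    ----------
    path
        Delimited-text file.
    dialect
        ``"native"`` for the package's own schema, or
        ``"imaris_position_export"`` for the conventional position-export
        layout (``Position X/Y/Z``, ``Unit``, ``Time``, ``TrackID``).
        The imaris dialect carries no timestamps or cell annotations, so
        ``frame_interval`` (minutes) and the label arguments supply them.
    """
    # "n/a" is a legitimate genotype/treatment label, not missing data;
    # round_trip parsing keeps write -> read lossless
    df = pd.read_csv(
        path, keep_default_na=False, na_values=[""],
        float_precision="round_trip",
    )
    if dialect == "native":
        pass
    elif dialect == "imaris_position_export":
        df = _read_imaris(df, frame_interval, cell_type, genotype, treatment)
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")
    return table_to_tracks(df)


def write_track_table(tracks: Sequence[Track], path: str | Path) -> None:
    """Write tracks as a native table: deterministic row and column order.

    Floats are written with shortest round-trip precision so that
    write -> read is lossless.
    """
    df = tracks_to_table(tracks)
    df.to_csv(
        path,
        index=False,
        lineterminator="\n",
        na_rep="",
        float_format=lambda v: repr(float(v)),
    )


# ---------------------------------------------------------------------------
# surface series
# ---------------------------------------------------------------------------
# Block format, one frame per block:
#   FRAME t=<minutes> kind=sphere
#   <cx> <cy> <cz> <radius>
#   FRAME t=<minutes> kind=mesh nv=<n_vertices> nf=<n_faces>
#   <x> <y> <z>          (nv lines)
#   3 <i> <j> <k>        (nf lines, OFF-style face records)

_MAGIC = "SPHEROTRACK_SURFACES v1"


def write_surface_series(series: SurfaceSeries, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write(_MAGIC + "\n")
    for t, geom in series.frames:
        t = float(t)
        if isinstance(geom, Sphere):
            buf.write(f"FRAME t={t!r} kind=sphere\n")
            cx, cy, cz = (float(v) for v in geom.center)
            buf.write(f"{cx!r} {cy!r} {cz!r} {float(geom.radius)!r}\n")
        else:
            v, f = geom.vertices, geom.faces
            buf.write(f"FRAME t={t!r} kind=mesh nv={len(v)} nf={len(f)}\n")
            for row in v:
                buf.write(
                    f"{float(row[0])!r} {float(row[1])!r} {float(row[2])!r}\n"
                )
            for row in f:
                buf.write(f"3 {row[0]} {row[1]} {row[2]}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_surface_series(path: str | Path) -> SurfaceSeries:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise SchemaError(f"{path}: not a surface-series file (bad magic line)")
    frames: list[tuple[float, Geometry]] = []
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.startswith("FRAME "):
            raise SchemaError(f"{path}: expected FRAME header, got {line!r}")
        fields = dict(kv.split("=", 1) for kv in line.split()[1:])
        t = float(fields["t"])
        if fields["kind"] == "sphere":
            cx, cy, cz, r = (float(v) for v in lines[i].split())
            i += 1
            frames.append((t, Sphere((cx, cy, cz), r)))
        elif fields["kind"] == "mesh":
            nv, nf = int(fields["nv"]), int(fields["nf"])
            verts = np.array(
                [[float(v) for v in lines[i + k].split()] for k in range(nv)]
            )
            i += nv
            faces = []
            for k in range(nf):
                rec = lines[i + k].split()
                if rec[0] != "3":
                    raise SchemaError(f"{path}: only triangle faces supported")
                faces.append([int(rec[1]), int(rec[2]), int(rec[3])])
            i += nf
            mesh = trimesh.Trimesh(
                vertices=verts, faces=np.array(faces), process=False
            )
            frames.append((t, mesh))
        else:
            raise SchemaError(f"{path}: unknown geometry kind {fields['kind']!r}")
    return SurfaceSeries(frames)
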