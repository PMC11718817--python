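"""Seeded agent-based generator of synthetic spheroid cocultures.

The generator emulates 30-min light-sheet videos of a pancreatic-cancer
spheroid coculture: tumor cells packed inside a spherical spheroid, CD8+
cytotoxic T lymphocytes (CTLs) split between an infiltrating and a
peripheral population, and macrophages in both compartments.  It emits the
same artifacts a tracking-software export would — a track table and a
per-frame spheroid surface — plus the generative ground truth that real
imaging never provides (true motile/arrested state per frame, true
apoptosis times), so that the downstream estimators can be tested for
parameter recovery.

Generative model
----------------
Each motile cell follows a persistent random walk: per step the speed is
drawn from a log-normal with configured mean and coefficient of
variation, and the direction is a von Mises-Fisher perturbation of the
previous direction with concentration ``persistence_kappa`` (isotropic
when kappa = 0).  Independently, each cell switches between a *motile*
and an *arrested* state as a discrete-time Markov chain with per-frame
transition probabilities ``1 - exp(-rate * frame_interval)``; while
arrested the cell holds an anchor position plus Gaussian jitter small
enough that its instantaneous velocity stays below the 2 µm/min arrest
threshold with probability >= 0.99.  Contact with a tumor cell (within
``contact_radius``) multiplies the arrest-on rate, and a CTL arrested in
tumor contact kills its target with a configured per-minute probability;
each kill shrinks the spheroid volume by a fixed fraction.  Apoptotic
tumor cells stop moving and keep their apoptosis flag raised for the
remaining frames, mirroring the accumulation of a caspase-3/7 dye.

Reproducibility: one root seed; every cell draws from its own substream
keyed by (seed, cell-type, index), so enlarging one population never
perturbs the random draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .trackio import Sphere, SurfaceSeries, Track

__all__ = [
    "MotilityParams",
    "ScenarioConfig",
    "GroundTruth",
    "SimulationOutput",
    "simulate_scenario",
    "default_scenario",
    "ARREST_THRESHOLD_UM_PER_MIN",
    "TIMEPOINTS",
    "CTL_GENOTYPES",
    "MACROPHAGE_TREATMENTS",
]

#: velocity threshold (µm/min) below which a cell counts as arrested
ARREST_THRESHOLD_UM_PER_MIN = 2.0

TIMEPOINTS = ("early_4h", "late_18h")
CTL_GENOTYPES = ("WT", "Il18r_ko")
MACROPHAGE_TREATMENTS = ("none", "untreated_mph", "lps_nigericin_mph")

_TYPE_CODES = {"tumor": 0, "macrophage": 1, "ctl": 2}


@dataclass(frozen=True)
class MotilityParams:
    """Per-cell-type motility parameters.

    mean_speed : µm/min, mean of the per-step log-normal speed draw.
    speed_cv : coefficient of variation of the speed draw.
    persistence_kappa : von Mises-Fisher concentration of the direction
        update; 0 gives an isotropic random walk, large values a nearly
        ballistic one.
    arrest_on_rate, arrest_off_rate : per-minute Markov switching rates;
        stationary arrested occupancy is on/(on+off).
    arrest_jitter_sd : µm, per-axis positional noise while arrested.
    contact_arrest_multiplier : factor on arrest_on_rate while within
        ``contact_radius`` of a live tumor cell.
    infiltration_bias : µm/min inward radial drift applied to cells
        outside the spheroid surface.
    """

    mean_speed: float
    speed_cv: float = 0.35
    persistence_kappa: float = 0.0
    arrest_on_rate: float = 0.0
    arrest_off_rate: float = 1.0
    arrest_jitter_sd: float = 0.15
    contact_arrest_multiplier: float = 1.0
    infiltration_bias: float = 0.0

    def validate(self, frame_interval: float) -> None:
        if self.mean_speed < 0 or self.speed_cv < 0:
            raise ValueError("speed parameters must be >= 0")
        if self.persistence_kappa < 0:
            raise ValueError("persistence_kappa must be >= 0")
        if self.arrest_on_rate < 0 or self.arrest_off_rate < 0:
            raise ValueError("arrest rates must be >= 0")
        if self.contact_arrest_multiplier < 0:
            raise ValueError("contact_arrest_multiplier must be >= 0")
        if self.arrest_jitter_sd < 0:
            raise ValueError("arrest_jitter_sd must be >= 0")
        if self.arrest_on_rate > 0 and self.arrest_jitter_sd > 0:
            # arrested steps are differences of two independent N(0, sd^2 I)
            # jitters; require P(|step|/dt < threshold) >= 0.99 so simulated
            # arrests are detectable at the 2 µm/min threshold
            q = (
                ARREST_THRESHOLD_UM_PER_MIN
                * frame_interval
                / (self.arrest_jitter_sd * np.sqrt(2.0))
            )
            p_below = stats.chi2.cdf(q * q, df=3)
            if p_below < 0.99:
                raise ValueError(
                    f"arrest_jitter_sd={self.arrest_jitter_sd} too large: "
                    f"arrested velocity < {ARREST_THRESHOLD_UM_PER_MIN} µm/min "
                    f"only with probability {p_below:.3f} (< 0.99)"
                )

    @property
    def stationary_arrest_fraction(self) -> float:
        """Continuous-time stationary occupancy on/(on+off) of the arrest state."""
        tot = self.arrest_on_rate + self.arrest_off_rate
        return self.arrest_on_rate / tot if tot > 0 else 0.0

    def discrete_stationary_arrest_fraction(self, frame_interval: float) -> float:
        """Exact stationary occupancy of the simulated per-frame chain.

        The chain switches with per-frame probabilities
        ``p = 1 - exp(-rate * frame_interval)``, whose stationary arrest
        occupancy is ``p_on / (p_on + p_off)``.  This converges to the
        continuous-time ratio on/(on+off) as the frame interval shrinks
        but differs from it at finite sampling.
        """
        p_on = -np.expm1(-self.arrest_on_rate * frame_interval)
        p_off = -np.expm1(-self.arrest_off_rate * frame_interval)
        tot = p_on + p_off
        return p_on / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic coculture video.

    Defaults preserve the study's 60,000 tumor : 8,000 macrophage :
    120,000 CTL seeding ratio scaled down 200x, a 150 µm spheroid, and a
    30-min video sampled every 0.5 min (61 frames).
    """

    seed: int = 0
    frame_interval: float = 0.5
    n_frames: int = 61
    timepoint: str = "early_4h"
    spheroid_radius: float = 150.0
    n_tumor: int = 300
    n_macrophage: int = 40
    n_ctl: int = 600
    tumor_params: MotilityParams = field(
        default_factory=lambda: MotilityParams(mean_speed=0.4, speed_cv=0.3)
    )
    macrophage_params: MotilityParams = field(
        default_factory=lambda: MotilityParams(
            mean_speed=3.0, persistence_kappa=2.0,
            arrest_on_rate=0.3, arrest_off_rate=0.9,
        )
    )
    ctl_params: MotilityParams = field(
        default_factory=lambda: MotilityParams(
            mean_speed=4.5, persistence_kappa=7.0,
            arrest_on_rate=0.35, arrest_off_rate=1.0,
            contact_arrest_multiplier=2.5, infiltration_bias=0.5,
        )
    )
    ctl_genotype: str = "WT"
    macrophage_treatment: str = "none"
    ctl_inside_fraction: float = 0.253
    macrophage_inside_fraction: float = 0.3
    kill_prob_per_arrest_min: float = 0.02
    contact_radius: float = 12.0
    volume_decay_per_kill: float = 0.002

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError(
                "n_frames must be >= 2 (frame interval must not reach the "
                "video length)"
            )
        for n in (self.n_tumor, self.n_macrophage, self.n_ctl):
            if n < 0:
                raise ValueError("cell counts must be >= 0")
        if self.spheroid_radius <= 0:
            raise ValueError("spheroid_radius must be > 0")
        for p in (
            self.ctl_inside_fraction,
            self.macrophage_inside_fraction,
            self.kill_prob_per_arrest_min,
            self.volume_decay_per_kill,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability/fraction {p} outside [0, 1]")
        if self.contact_radius <= 0:
            raise ValueError("contact_radius must be > 0")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.ctl_genotype not in CTL_GENOTYPES:
            raise ValueError(f"unknown ctl_genotype {self.ctl_genotype!r}")
        if self.macrophage_treatment not in MACROPHAGE_TREATMENTS:
            raise ValueError(
                f"unknown macrophage_treatment {self.macrophage_treatment!r}"
            )
        for p in (self.tumor_params, self.macrophage_params, self.ctl_params):
            p.validate(self.frame_interval)

    # -- flat key-value config I/O ------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for key, val in asdict(self).items():
            if isinstance(val, dict):  # nested MotilityParams
                prefix = key.replace("_params", "")
                for k2, v2 in val.items():
                    d[f"{prefix}.{k2}"] = v2
            else:
                d[key] = val
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        plain: dict = {}
        nested: dict[str, dict] = {"tumor": {}, "macrophage": {}, "ctl": {}}
        for key, val in d.items():
            if "." in key:
                prefix, sub = key.split(".", 1)
                nested[prefix][sub] = val
            else:
                plain[key] = val
        for prefix, sub in nested.items():
            if sub:
                plain[f"{prefix}_params"] = MotilityParams(**sub)
        cfg = cls(**plain)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclass
class GroundTruth:
    """Generative truth withheld from the analysis layer.

    states : one row per (track_id, frame) with the true state label;
        state ``i`` governs the step from frame ``i`` to ``i+1`` (the
        final row repeats the post-video state, so a track with n frames
        has n state rows = (n-1) velocity samples + 1).
    apoptosis_times : per tumor track, minutes at which the cell became
        apoptotic (NaN if it stayed alive).
    """

    states: pd.DataFrame
    apoptosis_times: pd.DataFrame

    def arrested_fraction(self, track_id: str) -> float:
        """True fraction of velocity samples spent arrested for one track."""
        s = self.states.loc[self.states["track_id"] == track_id, "state"]
        s = s.iloc[:-1]  # last row is the post-video state
        return float((s == "arrested").mean())


@dataclass
class SimulationOutput:
    tracks: list[Track]
    surfaces: SurfaceSeries
    ground_truth: GroundTruth
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _sample_vmf_w(u: np.ndarray, kappa: float) -> np.ndarray:
    """Cosine of the deflection angle for a von Mises-Fisher step on S2.

    Inverse-CDF sampling: W = 1 + log(u + (1-u) e^{-2k}) / k; isotropic
    (W = 2u - 1) when kappa = 0.
    """
    if kappa == 0.0:
        return 2.0 * u - 1.0
    # log(u + (1-u)exp(-2k)) computed stably for large kappa
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def _perturb_directions(
    mu: np.ndarray, w: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Rotate unit vectors ``mu`` by deflection cosine ``w`` and azimuth ``phi``."""
    # orthonormal frame around each mu; pick the helper axis per row to
    # avoid degeneracy when mu is nearly axis-aligned
    helper = np.zeros_like(mu)
    smallest = np.argmin(np.abs(mu), axis=1)
    helper[np.arange(len(mu)), smallest] = 1.0
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    out = (
        w[:, None] * mu
        + (s * np.cos(phi))[:, None] * e1
        + (s * np.sin(phi))[:, None] * e2
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _cell_rng(seed: int, type_code: int, index: int) -> np.random.Generator:
    # substream keyed by (seed, type, index): stable under population growth
    return np.random.default_rng(np.random.SeedSequence([seed, type_code, index]))


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig) -> SimulationOutput:
    """Run one synthetic coculture video.

    Returns tracks for every cell (gap-free, ``n_frames`` samples each),
    the per-frame spheroid sphere, and the generative ground truth.
    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    dt = config.frame_interval
    n_frames = config.n_frames
    n_steps = n_frames - 1
    R0 = config.spheroid_radius

    cell_types: list[str] = (
        ["tumor"] * config.n_tumor
        + ["macrophage"] * config.n_macrophage
        + ["ctl"] * config.n_ctl
    )
    n_cells = len(cell_types)
    params_of = {
        "tumor": config.tumor_params,
        "macrophage": config.macrophage_params,
        "ctl": config.ctl_params,
    }
    inside_fraction = {
        "tumor": 1.0,
        "macrophage": config.macrophage_inside_fraction,
        "ctl": config.ctl_inside_fraction,
    }

    # ---- per-cell initialization and pre-drawn random tables ----------
    pos = np.zeros((n_cells, 3))
    direction = np.zeros((n_cells, 3))
    arrested = np.zeros(n_cells, dtype=bool)
    speeds_tab = np.zeros((n_cells, n_steps))
    w_tab = np.zeros((n_cells, n_steps))
    phi_tab = np.zeros((n_cells, n_steps))
    u_state_tab = np.zeros((n_cells, n_steps))
    jitter_tab = np.zeros((n_cells, n_steps, 3))
    type_index: dict[str, int] = {t: 0 for t in _TYPE_CODES}
    track_ids: list[str] = []

    for i, ctype in enumerate(cell_types):
        idx = type_index[ctype]
        type_index[ctype] += 1
        track_ids.append(f"{ctype}_{idx:04d}")
        p = params_of[ctype]
        rng = _cell_rng(config.seed, _TYPE_CODES[ctype], idx)
        # placement: inside = uniform in a slightly shrunken ball; outside =
        # uniform in a shell just beyond the surface
        u_inside = rng.uniform()
        r_frac = rng.uniform() ** (1.0 / 3.0)
        unit = _random_unit_vectors(rng, 1)[0]
        if u_inside < inside_fraction[ctype]:
            pos[i] = unit * (0.92 * R0) * r_frac
        else:
            pos[i] = unit * rng.uniform(1.05 * R0, 1.35 * R0)
        direction[i] = _random_unit_vectors(rng, 1)[0]
        # start each chain in its exact stationary law so occupancy is
        # unbiased from frame 0
        arrested[i] = rng.uniform() < p.discrete_stationary_arrest_fraction(dt)
        mu, sigma = _lognormal_params(max(p.mean_speed, 1e-300), p.speed_cv)
        speeds_tab[i] = (
            np.exp(rng.normal(mu, sigma, n_steps)) if p.mean_speed > 0 else 0.0
        )
        w_tab[i] = _sample_vmf_w(rng.uniform(size=n_steps), p.persistence_kappa)
        phi_tab[i] = rng.uniform(0.0, 2.0 * np.pi, n_steps)
        u_state_tab[i] = rng.uniform(size=n_steps)
        jitter_tab[i] = rng.normal(0.0, 1.0, (n_steps, 3)) * p.arrest_jitter_sd

    is_tumor = np.array([t == "tumor" for t in cell_types])
    is_ctl = np.array([t == "ctl" for t in cell_types])
    p_on_base = np.array(
        [1.0 - np.exp(-params_of[t].arrest_on_rate * dt) for t in cell_types]
    )
    contact_mult = np.array(
        [params_of[t].contact_arrest_multiplier for t in cell_types]
    )
    on_rate = np.array([params_of[t].arrest_on_rate for t in cell_types])
    p_off = np.array(
        [1.0 - np.exp(-params_of[t].arrest_off_rate * dt) for t in cell_types]
    )
    bias = np.array([params_of[t].infiltration_bias for t in cell_types])
    needs_contact = np.any(contact_mult != 1.0) or config.kill_prob_per_arrest_min > 0

    interaction_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 3, 0])
    )

    anchor = pos.copy()
    alive = np.ones(n_cells, dtype=bool)  # tumor apoptosis status
    apoptosis_time = np.full(n_cells, np.nan)
    radius = np.empty(n_frames)
    radius[0] = R0
    positions_out = np.empty((n_cells, n_frames, 3))
    positions_out[:, 0] = pos
    # states_out[:, i] is the state governing the step from frame i to
    # i+1; the final column repeats the post-video state
    states_out = np.empty((n_cells, n_frames), dtype=bool)
    kill_p = min(config.kill_prob_per_arrest_min * dt, 1.0)

    from scipy.spatial import cKDTree

    for step in range(n_steps):
        R = radius[step]
        # tumor contact (live tumor cells only)
        if needs_contact and alive[is_tumor].sum() > 0:
            tree = cKDTree(pos[is_tumor & alive])
            d_near, i_near = tree.query(pos)
            in_contact = d_near <= config.contact_radius
        else:
            in_contact = np.zeros(n_cells, dtype=bool)
            i_near = None

        # state switching (frozen apoptotic cells keep their last state)
        mult = np.where(in_contact, contact_mult, 1.0)
        p_on = np.where(
            mult == 1.0, p_on_base, 1.0 - np.exp(-on_rate * mult * dt)
        )
        u = u_state_tab[:, step]
        switch_on = (~arrested) & (u < p_on)
        switch_off = arrested & (u < p_off)
        new_arrested = arrested.copy()
        new_arrested[switch_on] = True
        new_arrested[switch_off] = False
        frozen = is_tumor & ~alive
        new_arrested[frozen] = arrested[frozen]
        anchor[switch_on] = pos[switch_on]
        arrested = new_arrested

        # movement
        moving = ~arrested & ~frozen
        if np.any(moving):
            direction[moving] = _perturb_directions(
                direction[moving], w_tab[moving, step], phi_tab[moving, step]
            )
            new_pos = pos.copy()
            new_pos[moving] = (
                pos[moving]
                + speeds_tab[moving, step, None] * dt * direction[moving]
            )
            # inward radial drift for cells outside the surface
            r_norm = np.linalg.norm(pos, axis=1)
            outside = moving & (r_norm > R) & (bias > 0)
            if np.any(outside):
                new_pos[outside] -= (
                    (bias[outside] * dt / r_norm[outside])[:, None] * pos[outside]
                )
            pos = new_pos
        paused = arrested & ~frozen
        pos[paused] = anchor[paused] + jitter_tab[paused, step]

        # contact killing by arrested CTLs
        n_kills = 0
        if kill_p > 0 and i_near is not None:
            u_kill = interaction_rng.uniform(size=n_cells)
            killers = is_ctl & arrested & in_contact & (u_kill < kill_p)
            if np.any(killers):
                live_idx = np.flatnonzero(is_tumor & alive)
                targets = np.unique(live_idx[i_near[killers]])
                alive[targets] = False
                apoptosis_time[targets] = (step + 1) * dt
                n_kills = len(targets)
        radius[step + 1] = radius[step] * (
            (1.0 - config.volume_decay_per_kill) ** (n_kills / 3.0)
        )

        positions_out[:, step + 1] = pos
        states_out[:, step] = arrested
    states_out[:, n_frames - 1] = states_out[:, n_frames - 2]

    # ---- package outputs ---------------------------------------------
    times = np.arange(n_frames) * dt
    tracks: list[Track] = []
    for i, ctype in enumerate(cell_types):
        apo = None
        if ctype == "tumor":
            apo = (
                times >= apoptosis_time[i]
                if np.isfinite(apoptosis_time[i])
                else np.zeros(n_frames, dtype=bool)
            )
        tracks.append(
            Track(
                track_id=track_ids[i],
                cell_type=ctype,
                genotype=config.ctl_genotype if ctype == "ctl" else "n/a",
                treatment=(
                    config.macrophage_treatment if ctype != "tumor" else "n/a"
                ),
                times=times,
                positions=positions_out[i],
                apoptotic=apo,
            )
        )
    surfaces = SurfaceSeries(
        [(float(times[k]), Sphere((0.0, 0.0, 0.0), float(radius[k])))
         for k in range(n_frames)]
    )
    states = pd.DataFrame(
        {
            "track_id": np.repeat(track_ids, n_frames),
            "frame": np.tile(np.arange(n_frames), n_cells),
            "state": np.where(states_out.ravel(), "arrested", "motile"),
        }
    )
    apoptosis = pd.DataFrame(
        {
            "track_id": [track_ids[i] for i in np.flatnonzero(is_tumor)],
            "apoptosis_time_min": apoptosis_time[is_tumor],
        }
    )
    return SimulationOutput(
        tracks=tracks,
        surfaces=surfaces,
        ground_truth=GroundTruth(states=states, apoptosis_times=apoptosis),
        config=config,
    )


# ---------------------------------------------------------------------------
# shipped default scenarios
# ---------------------------------------------------------------------------

# Calibration anchors for the WT / untreated / early defaults: mean CTL
# track straightness in [0.4, 0.5] and ~25.3% of CTLs infiltrating at the
# early timepoint, rising to ~30.2% at the late one.  Condition effects
# are qualitative orderings: IL-18R-deficient CTLs run faster and arrest
# more often than WT; LPS/nigericin-activated macrophages speed CTLs up
# and lower their arrest coefficient relative to untreated macrophages.

_EARLY_INSIDE_FRACTION = 0.253
_LATE_INSIDE_FRACTION = 0.3022


def default_scenario(
    timepoint: str = "early_4h",
    ctl_genotype: str = "WT",
    macrophage_treatment: str = "none",
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """Shipped parameter set for one cell-culture condition.

    ``overrides`` are forwarded to :class:`ScenarioConfig` (e.g. smaller
    cell counts for quick runs).  Raises ``ValueError`` for unknown
    enumeration values.
    """
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    if ctl_genotype not in CTL_GENOTYPES:
        raise ValueError(f"unknown ctl_genotype {ctl_genotype!r}")
    if macrophage_treatment not in MACROPHAGE_TREATMENTS:
        raise ValueError(f"unknown macrophage_treatment {macrophage_treatment!r}")

    late = timepoint == "late_18h"
    speed = 4.5
    kappa = 7.0
    k_on = 0.35
    k_off = 1.0
    if ctl_genotype == "Il18r_ko":
        speed *= 1.15
        k_on *= 1.45
    if macrophage_treatment == "lps_nigericin_mph":
        speed *= 1.2
        k_on *= 0.72
    if late:
        k_on *= 1.5  # late videos show more frequent / longer arrests

    ctl = MotilityParams(
        mean_speed=speed,
        speed_cv=0.35,
        persistence_kappa=kappa,
        arrest_on_rate=k_on,
        arrest_off_rate=k_off,
        arrest_jitter_sd=0.15,
        contact_arrest_multiplier=2.5,
        infiltration_bias=0.5,
    )
    mph = MotilityParams(
        mean_speed=3.0 * (1.1 if macrophage_treatment == "lps_nigericin_mph" else 1.0),
        speed_cv=0.35,
        persistence_kappa=2.0,
        arrest_on_rate=0.3,
        arrest_off_rate=0.9,
    )
    kwargs = dict(
        seed=seed,
        timepoint=timepoint,
        ctl_genotype=ctl_genotype,
        macrophage_treatment=macrophage_treatment,
        n_macrophage=0 if macrophage_treatment == "none" else 40,
        ctl_params=ctl,
        macrophage_params=mph,
        ctl_inside_fraction=(
            _LATE_INSIDE_FRACTION if late else _EARLY_INSIDE_FRACTION
        ),
        macrophage_inside_fraction=0.45 if late else 0.3,
        kill_prob_per_arrest_min=0.05 if late else 0.02,
    )
    kwargs.update(overrides)
    cfg = ScenarioConfig(**kwargs)
    cfg.validate()
    return cfg


def write_ground_truth(gt: GroundTruth, states_path, apoptosis_path) -> None:
    """Write ground truth as two delimited tables."""
    gt.states.to_csv(states_path, index=False, lineterminator="\n")
    gt.apoptosis_times.to_csv(apoptosis_path, index=False, lineterminator="\n")
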