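"""Statistical layer and pipeline orchestration.

Implements the statistics used for bar-graph comparisons of motility
metrics — Grubbs outlier screening (alpha 0.05, one removal per pass),
Welch's unpaired two-tailed t-test, ordinary one-way ANOVA followed by
Tukey's HSD over all pairs, and the usual significance stars
(* p <= 0.05, ** p < 0.01, *** p < 0.001) — plus :func:`run_pipeline`,
which chains simulation or file input through drift correction,
compartment classification, kinematics, arrest statistics and group
summaries into a deterministic, diff-able report bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .arrest import arrest_density, arrest_profile
from .compartments import classify, drift_correct, infiltration_percent
from .motility import cohort_summary, instantaneous_velocity, summarize_tracks
from .simcore import (
    ARREST_THRESHOLD_UM_PER_MIN,
    ScenarioConfig,
    default_scenario,
    simulate_scenario,
)
from .trackio import (
    SurfaceSeries,
    Track,
    ValidationError,
    read_surface_series,
    read_track_table,
    write_track_table,
)

__all__ = [
    "GroupComparison",
    "OutlierReport",
    "grubbs_test",
    "welch_t_test",
    "anova_tukey",
    "stars",
    "run_pipeline",
]


@dataclass
class GroupComparison:
    """Result of a two-group or multi-group test.

    ``pairwise`` is filled for Tukey comparisons: one row per group pair
    with mean difference, adjusted p and stars.
    """

    groups: list[str]
    statistic_name: str
    statistic: float
    p_value: float
    stars: str
    df: float = float("nan")
    pairwise: pd.DataFrame | None = None


@dataclass
class OutlierReport:
    """Single-pass Grubbs screen: at most one removal."""

    values: np.ndarray
    kept: np.ndarray
    removed: float | None
    g_statistic: float
    critical_value: float
    alpha: float
    zero_variance: bool = False


def stars(p: float) -> str:
    """Significance label: *** p < 0.001, ** p < 0.01, * p <= 0.05, else ns."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value at level ``alpha``.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValidationError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05) -> OutlierReport:
    """Two-sided single-outlier Grubbs test (one removal per pass).

    G = max|x_i - mean| / sd; the most extreme point is removed iff
    G exceeds the critical value.  Zero-variance input yields a flagged
    no-outlier result rather than an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("Grubbs test needs n >= 3 values")
    sd = float(np.std(x, ddof=1))
    crit = grubbs_critical_value(x.size, alpha)
    if sd == 0.0:
        return OutlierReport(
            values=x, kept=x.copy(), removed=None, g_statistic=0.0,
            critical_value=crit, alpha=alpha, zero_variance=True,
        )
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / sd)
    if g > crit:
        return OutlierReport(
            values=x, kept=np.delete(x, i), removed=float(x[i]),
            g_statistic=g, critical_value=crit, alpha=alpha,
        )
    return OutlierReport(
        values=x, kept=x.copy(), removed=None, g_statistic=g,
        critical_value=crit, alpha=alpha,
    )


def welch_t_test(a, b, labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Unpaired two-tailed t-test with Welch's correction.

    Uses the Welch statistic with Welch-Satterthwaite degrees of freedom
    (reported conservatively whether or not the variances differ).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("samples must be finite")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate constant samples: identical means are a null result,
        # different means a certain one
        equal = a.mean() == b.mean()
        t_stat = 0.0 if equal else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if equal else 0.0
        df = float(a.size + b.size - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return GroupComparison(
        groups=list(labels),
        statistic_name="welch_t",
        statistic=t_stat,
        p_value=p,
        stars=stars(p),
        df=df,
    )


def anova_tukey(
    groups: dict[str, np.ndarray], include_pairwise: bool = True
) -> GroupComparison:
    """Ordinary one-way ANOVA followed by Tukey's HSD over all pairs.

    Adjusted pairwise p-values come from the studentized-range
    distribution.  Degenerate all-equal data report F = 0, p = 1.
    """
    names = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    if len(samples) < 3:
        raise ValidationError("one-way ANOVA here expects >= 3 groups")
    for name, s in zip(names, samples):
        if s.size < 2:
            raise ValidationError(f"group {name!r} needs n >= 2")
    grand = np.concatenate(samples)
    degenerate = bool(np.all(grand == grand[0]))
    if degenerate:
        f_stat, p = 0.0, 1.0
    else:
        res = stats.f_oneway(*samples)
        f_stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # zero within-group variance with equal means
            f_stat, p = 0.0, 1.0
    pairwise = None
    if include_pairwise:
        hsd = None if degenerate else stats.tukey_hsd(*samples)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                adj = 1.0 if hsd is None else float(
                    np.clip(hsd.pvalue[i, j], 0.0, 1.0)
                )
                rows.append(
                    (
                        names[i],
                        names[j],
                        float(np.mean(samples[i]) - np.mean(samples[j])),
                        adj,
                        stars(adj),
                    )
                )
        pairwise = pd.DataFrame(
            rows, columns=["group_a", "group_b", "mean_difference", "p_adjusted", "stars"]
        )
    return GroupComparison(
        groups=names,
        statistic_name="anova_F",
        statistic=f_stat,
        p_value=p,
        stars=stars(p),
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONDITION_GRID = [
    {"timepoint": tp, "ctl_genotype": g, "macrophage_treatment": mt}
    for tp in ("early_4h", "late_18h")
    for g in ("WT", "Il18r_ko")
    for mt in ("untreated_mph", "lps_nigericin_mph")
]


def _condition_label(timepoint: str, genotype: str, treatment: str) -> str:
    return f"{timepoint}|{genotype}|{treatment}"


def _analyze_video(
    tracks: list[Track],
    surfaces: SurfaceSeries,
    condition: str,
    video_id: str,
    arrest_threshold: float,
    apply_drift_correction: bool,
) -> pd.DataFrame:
    """Per-track metric table for one video."""
    if apply_drift_correction:
        tracks, surfaces = drift_correct(tracks, surfaces)
    labels = classify(tracks, surfaces)
    per_track = summarize_tracks(tracks)
    loc = labels.track_labels.set_index("track_id")["track_location"]
    meta = pd.DataFrame(
        {
            "track_id": [t.track_id for t in tracks],
            "cell_type": [t.cell_type for t in tracks],
            "genotype": [t.genotype for t in tracks],
            "treatment": [t.treatment for t in tracks],
        }
    )
    coeffs, n_arrests, arrest_total = [], [], []
    for t in tracks:
        prof = arrest_profile(instantaneous_velocity(t), arrest_threshold)
        coeffs.append(prof.arrest_coefficient)
        n_arrests.append(len(prof.arrest_durations))
        arrest_total.append(float(prof.arrest_durations.sum()))
    out = meta.merge(per_track, on="track_id")
    out.insert(0, "condition", condition)
    out.insert(1, "video_id", video_id)
    out["track_location"] = out["track_id"].map(loc)
    out["arrest_coefficient"] = coeffs
    out["n_arrests"] = n_arrests
    out["arrest_minutes"] = arrest_total
    ctl_pct = infiltration_percent(labels, "ctl", frame=0) if any(
        t.cell_type == "ctl" for t in tracks
    ) else np.nan
    out["video_ctl_infiltration_pct"] = ctl_pct
    return out


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the full analysis chain and write a report bundle.

    ``config`` is a plain mapping (typically loaded from YAML) with keys:

    * ``seed`` — root seed for simulated inputs (default 0);
    * ``arrest_threshold`` — µm/min (default 2.0);
    * ``drift_correction`` — apply rigid drift removal (default False);
    * either ``simulate`` (``conditions``: list of condition mappings,
      ``n_replicates`` videos per condition, ``overrides`` forwarded to
      the scenario) or ``inputs`` (``tracks``/``surfaces`` paths and
      ``dialect``).

    Writes ``per_track.csv``, ``group_summary.csv``,
    ``arrest_density.csv``, ``comparisons.csv`` and ``manifest.json`` to
    ``out_dir``; output is byte-identical for identical config + seed.
    Returns the tables in memory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    threshold = float(config.get("arrest_threshold", ARREST_THRESHOLD_UM_PER_MIN))
    do_drift = bool(config.get("drift_correction", False))

    videos: list[tuple[list[Track], SurfaceSeries, str, str]] = []
    if "simulate" in config:
        sim = config["simulate"]
        conditions = sim.get("conditions", DEFAULT_CONDITION_GRID)
        n_rep = int(sim.get("n_replicates", 1))
        overrides = dict(sim.get("overrides", {}))
        for cond in conditions:
            label = _condition_label(
                cond["timepoint"], cond["ctl_genotype"], cond["macrophage_treatment"]
            )
            for rep in range(n_rep):
                cfg = default_scenario(
                    seed=seed + rep, **cond, **overrides
                )
                sim_out = simulate_scenario(cfg)
                videos.append(
                    (sim_out.tracks, sim_out.surfaces, label, f"{label}#r{rep}")
                )
    elif "inputs" in config:
        inp = config["inputs"]
        tracks = read_track_table(
            inp["tracks"], dialect=inp.get("dialect", "native"),
            frame_interval=float(inp.get("frame_interval", 0.5)),
        )
        surfaces = read_surface_series(inp["surfaces"])
        videos.append((tracks, surfaces, inp.get("condition", "external"), "external#r0"))
    else:
        raise ValidationError("config needs either a 'simulate' or an 'inputs' section")

    frames = []
    for tracks, surfaces, label, vid in videos:
        try:
            frames.append(
                _analyze_video(tracks, surfaces, label, vid, threshold, do_drift)
            )
        except ValidationError as err:
            raise ValidationError(f"video {vid!r}: {err}") from err
    per_track = pd.concat(frames, ignore_index=True)
    per_track = per_track.sort_values(
        ["condition", "video_id", "track_id"], kind="stable"
    ).reset_index(drop=True)

    metric_cols = [
        "average_speed", "track_displacement", "track_length",
        "straightness", "track_duration", "arrest_coefficient",
    ]
    group_summary = (
        cohort_summary(
            per_track, ["condition", "cell_type", "track_location"], metric_cols
        )
        .sort_values(["condition", "cell_type", "track_location", "metric"],
                     kind="stable")
        .reset_index(drop=True)
    )

    # pooled density of CTL arrest coefficients per condition
    dens_rows = []
    for cond, grp in per_track[per_track["cell_type"] == "ctl"].groupby(
        "condition", sort=True
    ):
        vals = grp["arrest_coefficient"].to_numpy()
        if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
            curve = arrest_density(vals)
            dens_rows.append(
                pd.DataFrame(
                    {
                        "condition": cond,
                        "arrest_coefficient": curve.grid,
                        "density": curve.density,
                        "bandwidth": curve.bandwidth,
                    }
                )
            )
    density = (
        pd.concat(dens_rows, ignore_index=True)
        if dens_rows
        else pd.DataFrame(
            columns=["condition", "arrest_coefficient", "density", "bandwidth"]
        )
    )

    # group comparisons on per-video replicate means of CTL metrics
    comp_rows = []
    ctl = per_track[per_track["cell_type"] == "ctl"]
    per_video = ctl.groupby(["condition", "video_id"], sort=True)[
        metric_cols
    ].mean().reset_index()
    conditions = sorted(per_video["condition"].unique())
    enough = (
        per_video.groupby("condition")["video_id"].nunique().ge(2).all()
        and len(conditions) >= 2
    )
    if enough:
        for metric in metric_cols:
            samples = {
                c: per_video.loc[per_video["condition"] == c, metric].to_numpy()
                for c in conditions
            }
            if len(conditions) == 2:
                cmp = welch_t_test(
                    samples[conditions[0]], samples[conditions[1]],
                    labels=(conditions[0], conditions[1]),
                )
                comp_rows.append(
                    (metric, cmp.statistic_name, conditions[0], conditions[1],
                     cmp.statistic, cmp.p_value, cmp.stars)
                )
            else:
                cmp = anova_tukey(samples)
                comp_rows.append(
                    (metric, cmp.statistic_name, "all", "all",
                     cmp.statistic, cmp.p_value, cmp.stars)
                )
                for _, row in cmp.pairwise.iterrows():
                    comp_rows.append(
                        (metric, "tukey_hsd", row["group_a"], row["group_b"],
                         row["mean_difference"], row["p_adjusted"], row["stars"])
                    )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["metric", "test", "group_a", "group_b", "statistic",
                 "p_value", "stars"],
    )

    per_track.to_csv(out_dir / "per_track.csv", index=False, lineterminator="\n")
    group_summary.to_csv(
        out_dir / "group_summary.csv", index=False, lineterminator="\n"
    )
    density.to_csv(out_dir / "arrest_density.csv", index=False, lineterminator="\n")
    comparisons.to_csv(out_dir / "comparisons.csv", index=False, lineterminator="\n")

    canon = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": seed,
        "arrest_threshold_um_per_min": threshold,
        "drift_correction": do_drift,
        "n_videos": len(videos),
        "config": json.loads(canon),
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {
        "per_track": per_track,
        "group_summary": group_summary,
        "arrest_density": density,
        "comparisons": comparisons,
        "manifest": manifest,
    }
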