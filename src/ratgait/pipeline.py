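"""Orchestration: simulate -> spatiotemporal -> dynamics -> behavior -> stats.

Every stage is a pure function of (inputs, config, seed); a full run
writes diffable CSVs plus a JSON manifest (config hash, seed, versions)
that suffices to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import UpDownSeries, updown_threshold, weight_distribution
from .config import RunConfig
from .dynamics import (
    ForceTrace,
    body_weight_mN,
    detect_stance,
    ensemble_average,
    extract_force_metrics,
    lowpass_filter,
)
from .simulate import (
    child_rng,
    generate_force_trace,
    generate_updown_responses,
    generate_weight_readings,
    simulate_trial_events,
)
from .spatiotemporal import trial_metrics
from .stats import (
    deviation_test,
    fit_velocity_adjusted,
    oneway_anova,
    snk_posthoc,
    two_factor_anova,
)

__all__ = [
    "simulate_dataset",
    "analyze_spatiotemporal",
    "analyze_dynamics",
    "analyze_behavior",
    "run_stats",
    "run",
]

FORCE_METRIC_COLUMNS = [
    "max_fz_mN", "iz_mN_s", "max_f_neg_x_mN", "max_fx_mN", "i_neg_x_mN_s",
    "ix_mN_s", "t_neg_x_pct", "max_fy_first_mN", "max_fy_second_mN", "iy_mN_s",
]


# ---------------------------------------------------------------- simulate

def simulate_dataset(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Generate the full synthetic dataset for one run configuration.

    Returns a dict of DataFrames (``events``, ``forces``, ``updown``,
    ``weights``) plus the ground-truth record; when ``outdir`` is given
    the tables are also written as CSV alongside ``ground_truth.json``.
    """
    design = cfg.design.to_design(cfg.seed)
    effects = {g: e.to_effect() for g, e in cfg.effects.items()}

    # footfall events
    event_frames = []
    for gi, group in enumerate(design.groups):
        for a in range(design.n_per_group):
            animal = f"{group}_{a:02d}"
            for t in range(design.trials_per_animal):
                rng = child_rng(cfg.seed, "gait", gi, a, t)
                v = float(np.clip(
                    rng.normal(design.velocity_mean_cm_s[group], design.velocity_sd_cm_s),
                    5.0, 80.0,
                ))
                ev = simulate_trial_events(
                    rng, v, effects[group],
                    n_strides=design.strides_per_limb,
                    affected=cfg.analysis.affected_limb,
                )
                ev.insert(0, "trial_id", t)
                ev.insert(0, "group", group)
                ev.insert(0, "animal_id", animal)
                event_frames.append(ev)
    events = pd.concat(event_frames, ignore_index=True)

    # force traces (long format, one row per sample)
    force_frames = []
    for gi, group in enumerate(design.groups):
        for a in range(design.n_per_group):
            animal = f"{group}_{a:02d}"
            mass_rng = child_rng(cfg.seed, "force", gi, a)
            mass = float(mass_rng.normal(cfg.force.body_mass_g[group], cfg.force.body_mass_sd_g))
            for li, limb in enumerate(("LH", "RH")):
                affected = limb == cfg.analysis.affected_limb
                shape = cfg.force.to_shape(group, affected)
                for t in range(cfg.force.trials_per_limb):
                    rng = child_rng(cfg.seed, "force", gi, a, li, t)
                    stance = float(np.clip(
                        rng.normal(cfg.force.stance_mean_s, cfg.force.stance_sd_s),
                        0.15, 0.6,
                    ))
                    tr = generate_force_trace(
                        shape, stance, mass, fs_hz=cfg.analysis.fps, rng=rng,
                        limb=limb, group=group, animal_id=animal, trial_id=t,
                    )
                    force_frames.append(pd.DataFrame({
                        "animal_id": animal, "group": group, "limb": limb,
                        "trial_id": t, "t_s": tr.t_s, "fx_mN": tr.fx_mN,
                        "fy_mN": tr.fy_mN, "fz_mN": tr.fz_mN,
                        "body_weight_g": mass,
                    }))
    forces = pd.concat(force_frames, ignore_index=True)

    # up-down series
    updown_rows = []
    for gi, group in enumerate(design.groups):
        for a in range(design.n_per_group):
            animal = f"{group}_{a:02d}"
            for li, limb_role in enumerate(("affected", "contra")):
                rng = child_rng(cfg.seed, "updown", gi, a, li)
                series = generate_updown_responses(
                    cfg.behavior.thresholds_gF[group][limb_role],
                    steepness=cfg.behavior.psychometric_steepness,
                    rng=rng,
                )
                for k, (f, w) in enumerate(series.presentations):
                    updown_rows.append({
                        "animal_id": animal, "group": group, "limb": limb_role,
                        "presentation_idx": k, "filament_gF": f,
                        "withdrawal": int(w),
                        "boundary": series.boundary or "",
                    })
    updown = pd.DataFrame(updown_rows)

    # incapacitance readings
    weight_rows = []
    for gi, group in enumerate(design.groups):
        for a in range(design.n_per_group):
            animal = f"{group}_{a:02d}"
            rng = child_rng(cfg.seed, "weight", gi, a)
            readings = generate_weight_readings(
                cfg.behavior.weight_fraction[group],
                noise_sd=cfg.behavior.weight_noise_sd,
                n_trials=cfg.behavior.weight_trials,
                rng=rng,
            )
            for t, (lg, rg) in enumerate(readings):
                weight_rows.append({
                    "animal_id": animal, "group": group, "trial_idx": t,
                    "left_g": lg, "right_g": rg,
                })
    weights = pd.DataFrame(weight_rows)

    truth = {
        "seed": cfg.seed,
        "groups": list(design.groups),
        "effects": {g: cfg.effects[g].model_dump() for g in design.groups},
        "weight_fraction": dict(cfg.behavior.weight_fraction),
        "thresholds_gF": {g: dict(v) for g, v in cfg.behavior.thresholds_gF.items()},
    }
    data = {"events": events, "forces": forces, "updown": updown,
            "weights": weights, "ground_truth": truth}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("events", "forces", "updown", "weights"):
            data[name].to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return data


# ----------------------------------------------------------------- analyze

def analyze_spatiotemporal(events: pd.DataFrame, affected: str = "RH") -> pd.DataFrame:
    """Per-trial spatiotemporal descriptors from a study event table."""
    rows = []
    for (animal, group, trial), ev in events.groupby(
        ["animal_id", "group", "trial_id"], sort=False
    ):
        rec = trial_metrics(ev, affected=affected)
        rows.append({"animal_id": animal, "group": group, "trial_id": trial, **rec})
    return pd.DataFrame(rows)


def analyze_dynamics(
    forces: pd.DataFrame,
    cutoff_hz: float = 25.0,
    n_bins: int = 100,
    stance_threshold: float = 0.02,
    fs_hz: float = 200.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Force descriptors per contact and ensemble curves per group.

    Returns ``(metrics, curves)``: one metrics row per contact with both
    raw (mN) and body-weight-normalized (``_bw`` suffix) descriptors, and
    normalized ensemble mean +- 95% CI curves per (group, axis) for the
    affected-limb contacts.
    """
    metric_rows = []
    traces_by_group: dict[str, list[ForceTrace]] = {}
    for (animal, group, limb, trial), sub in forces.groupby(
        ["animal_id", "group", "limb", "trial_id"], sort=False
    ):
        sub = sub.sort_values("t_s")
        tr = ForceTrace(
            t_s=sub["t_s"].to_numpy(), fx_mN=sub["fx_mN"].to_numpy(),
            fy_mN=sub["fy_mN"].to_numpy(), fz_mN=sub["fz_mN"].to_numpy(),
            body_weight_g=float(sub["body_weight_g"].iloc[0]), fs_hz=fs_hz,
            limb=limb, group=group, animal_id=animal, trial_id=trial,
        )
        filt = lowpass_filter(tr, cutoff_hz)
        try:
            stance = detect_stance(filt.fz_mN, filt.body_weight_g, stance_threshold)
        except ValueError as exc:
            warnings.warn(f"{animal} {limb} trial {trial}: {exc}", stacklevel=2)
            continue
        m = extract_force_metrics(filt, stance)
        norm = m.normalized(filt.body_weight_g)
        row = {"animal_id": animal, "group": group, "limb": limb,
               "trial_id": trial, "stance_s": m.stance_s}
        for col in FORCE_METRIC_COLUMNS:
            row[col] = getattr(m, col)
            row[col.replace("_mN", "_bw") if "_mN" in col else col + "_bw"] = getattr(norm, col)
        metric_rows.append(row)
        if limb == "RH":
            traces_by_group.setdefault(group, []).append(filt)
    metrics = pd.DataFrame(metric_rows)

    curve_frames = []
    for group, traces in traces_by_group.items():
        for axis in ("fx", "fy", "fz"):
            try:
                c = ensemble_average(traces, n_bins=n_bins, axis=axis)
            except ValueError:
                continue
            c.insert(0, "axis", axis)
            c.insert(0, "group", group)
            curve_frames.append(c)
    curves = (
        pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["group", "axis", "pct_stance", "mean", "ci_low", "ci_high"])
    )
    return metrics, curves


def analyze_behavior(updown: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Per-animal withdrawal thresholds and weight distribution."""
    rows: dict[tuple, dict] = {}
    for (animal, group, limb), sub in updown.groupby(
        ["animal_id", "group", "limb"], sort=False
    ):
        sub = sub.sort_values("presentation_idx")
        series = UpDownSeries(
            presentations=[
                (float(f), bool(w))
                for f, w in zip(sub["filament_gF"], sub["withdrawal"])
            ],
            boundary=(sub["boundary"].iloc[0] or None)
            if sub["boundary"].iloc[0] != ""
            else None,
        )
        key = (animal, group)
        rows.setdefault(key, {"animal_id": animal, "group": group})
        rows[key][f"threshold_{limb}_gF"] = updown_threshold(series)
    for (animal, group), sub in weights.groupby(["animal_id", "group"], sort=False):
        key = (animal, group)
        rows.setdefault(key, {"animal_id": animal, "group": group})
        rows[key]["weight_right_pct"] = weight_distribution(
            sub[["left_g", "right_g"]].to_numpy()
        )
    return pd.DataFrame(list(rows.values()))


# ------------------------------------------------------------------- stats

def _animal_means(df: pd.DataFrame, value: str) -> pd.DataFrame:
    return (
        df.groupby(["group", "animal_id"], sort=False)[value].mean().reset_index()
    )


def run_stats(
    spatio: pd.DataFrame,
    force_metrics: pd.DataFrame,
    behavior_df: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int | None = None,
    unit: str = "animal",
) -> tuple[pd.DataFrame, dict]:
    """All inference for one run; returns (tidy report rows, results dict)."""
    groups = list(dict.fromkeys(spatio["group"]))
    fam = family_size if family_size is not None else len(groups)
    rows: list[dict] = []
    results: dict = {"deviation": {}, "ancova": {}, "anova": {}, "two_factor": {}}

    def add(section, metric, term, estimate, stat, p, sig):
        rows.append({
            "section": section, "metric": metric, "term": term,
            "estimate": estimate, "statistic": stat, "p": p, "significant": sig,
        })

    # velocity: one-way ANOVA + SNK on animal means
    vel = _animal_means(spatio, "velocity_cm_s")
    F, p, mse, dfr = oneway_anova(vel["velocity_cm_s"], vel["group"])
    add("oneway", "velocity_cm_s", "group", np.nan, F, p, p < alpha)
    sizes = vel.groupby("group").size().to_dict()
    means = vel.groupby("group")["velocity_cm_s"].mean().to_dict()
    ph = snk_posthoc(means, mse, dfr, sizes, alpha=alpha)
    for _, c in ph.comparisons.iterrows():
        add("snk:velocity_cm_s", "velocity_cm_s", f"{c.group_a} vs {c.group_b}",
            c["diff"], c["q"], c["p"], bool(c["significant"]))

    # velocity-covariate ANCOVA on trial-level data
    for metric in ("duty_affected_pct", "duty_contra_pct",
                   "stride_length_cm", "step_width_cm"):
        model = fit_velocity_adjusted(
            spatio[metric], spatio["group"], spatio["velocity_cm_s"],
            response=metric,
        )
        results["ancova"][metric] = model
        add("ancova", metric, "group", np.nan, model.anova_F, model.anova_p,
            model.anova_p < alpha)
        add("ancova", metric, "velocity_slope", model.slope,
            model.slope / model.slope_se if model.slope_se > 0 else np.nan,
            np.nan, False)
        ph = snk_posthoc(model.adjusted_means, model.mse, model.df_resid,
                         model.group_sizes, alpha=alpha)
        for _, c in ph.comparisons.iterrows():
            add(f"snk:{metric}", metric, f"{c.group_a} vs {c.group_b}",
                c["diff"], c["q"], c["p"], bool(c["significant"]))

    # deviation from balanced, symmetric gait / even weight bearing
    targets = [("imbalance_pp", 0.0, spatio), ("symmetry", 0.5, spatio)]
    if "weight_right_pct" in behavior_df:
        targets.append(("weight_right_pct", 50.0, behavior_df))
    for metric, theo, src in targets:
        per_animal = _animal_means(src, metric) if unit == "animal" else src
        for g in groups:
            vals = per_animal.loc[per_animal["group"] == g, metric]
            dt = deviation_test(vals, theo, family_size=fam)
            results["deviation"][(metric, g)] = dt
            add("deviation", metric, g, dt.mean, dt.t, dt.p_adjusted, dt.significant)
        F, p, mse, dfr = oneway_anova(per_animal[metric], per_animal["group"])
        add("oneway", metric, "group", np.nan, F, p, p < alpha)
        sizes = per_animal.groupby("group").size().to_dict()
        means = per_animal.groupby("group")[metric].mean().to_dict()
        ph = snk_posthoc(means, mse, dfr, sizes, alpha=alpha)
        for _, c in ph.comparisons.iterrows():
            add(f"snk:{metric}", metric, f"{c.group_a} vs {c.group_b}",
                c["diff"], c["q"], c["p"], bool(c["significant"]))

    # two-factor (group x limb) ANOVA on normalized force metrics
    if len(force_metrics):
        for col in FORCE_METRIC_COLUMNS:
            bw = col.replace("_mN", "_bw") if "_mN" in col else col + "_bw"
            agg = (
                force_metrics.groupby(["group", "limb", "animal_id"], sort=False)[bw]
                .mean().reset_index()
                if unit == "animal" else force_metrics
            )
            table, ph = two_factor_anova(agg[bw], agg["group"], agg["limb"], alpha=alpha)
            results["two_factor"][col] = (table, ph)
            for term in table.index[:-1]:
                add("two_factor", col, term, np.nan,
                    float(table.loc[term, "F"]), float(table.loc[term, "PR(>F)"]),
                    float(table.loc[term, "PR(>F)"]) < alpha)

    # two-factor ANOVA on withdrawal thresholds
    if {"threshold_affected_gF", "threshold_contra_gF"} <= set(behavior_df.columns):
        long = behavior_df.melt(
            id_vars=["animal_id", "group"],
            value_vars=["threshold_affected_gF", "threshold_contra_gF"],
            var_name="limb", value_name="threshold_gF",
        )
        long["limb"] = long["limb"].str.replace("threshold_", "").str.replace("_gF", "")
        table, ph = two_factor_anova(
            long["threshold_gF"], long["group"], long["limb"], alpha=alpha
        )
        results["two_factor"]["threshold_gF"] = (table, ph)
        for term in table.index[:-1]:
            add("two_factor", "threshold_gF", term, np.nan,
                float(table.loc[term, "F"]), float(table.loc[term, "PR(>F)"]),
                float(table.loc[term, "PR(>F)"]) < alpha)

    return pd.DataFrame(rows), results


def _render_report(report: pd.DataFrame, force_metrics: pd.DataFrame) -> str:
    """Plain-text report with Table-1-like and Table-2-like layouts."""
    lines = ["ratgait statistical report", "=" * 60, ""]
    if len(force_metrics):
        lines.append("Generalized gait dynamics descriptors (raw mN; mean +/- SE)")
        for limb in ("RH", "LH"):
            sub = force_metrics[force_metrics["limb"] == limb]
            if not len(sub):
                continue
            lines.append(f"-- limb {limb}")
            agg = sub.groupby("group")[FORCE_METRIC_COLUMNS].agg(["mean", "sem"])
            for col in FORCE_METRIC_COLUMNS:
                vals = "  ".join(
                    f"{g}: {agg.loc[g, (col, 'mean')]:.1f}+/-{agg.loc[g, (col, 'sem')]:.1f}"
                    for g in agg.index
                )
                lines.append(f"   {col:<18s} {vals}")
        lines.append("")
    lines.append("Deviation from balanced, symmetric gait (Bonferroni-adjusted)")
    dev = report[report["section"] == "deviation"]
    for _, r in dev.iterrows():
        flag = "*" if r["significant"] else " "
        lines.append(
            f"  {r['metric']:<18s} {r['term']:<14s} mean={r['estimate']:8.3f}"
            f"  t={r['statistic']:7.2f}  p_adj={r['p']:.4f} {flag}"
        )
    lines.append("")
    lines.append("Group effects (ANCOVA / ANOVA / two-factor)")
    for _, r in report[report["section"].isin(["ancova", "oneway", "two_factor"])].iterrows():
        if r["term"] == "velocity_slope":
            lines.append(f"  {r['metric']:<18s} velocity slope = {r['estimate']:.4f}")
            continue
        flag = "*" if r["significant"] else " "
        lines.append(
            f"  {r['section']:<10s} {r['metric']:<18s} {str(r['term']):<22s}"
            f" F={r['statistic']:9.3f}  p={r['p']:.4f} {flag}"
        )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------- run

def run(cfg: RunConfig, outdir: str | Path) -> dict:
    """Simulate-and-analyze a full study; write all outputs and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(cfg, outdir)

    spatio = analyze_spatiotemporal(data["events"], affected=cfg.analysis.affected_limb)
    spatio.to_csv(outdir / "spatiotemporal.csv", index=False)

    metrics, curves = analyze_dynamics(
        data["forces"], cutoff_hz=cfg.analysis.cutoff_hz,
        n_bins=cfg.analysis.n_bins,
        stance_threshold=cfg.analysis.stance_threshold_fraction,
        fs_hz=cfg.analysis.fps,
    )
    metrics.to_csv(outdir / "force_metrics.csv", index=False)
    curves.to_csv(outdir / "ensemble_curves.csv", index=False)

    behav = analyze_behavior(data["updown"], data["weights"])
    behav.to_csv(outdir / "behavior_metrics.csv", index=False)

    report, results = run_stats(
        spatio, metrics, behav, alpha=cfg.analysis.alpha,
        family_size=cfg.analysis.family_size, unit=cfg.analysis.unit,
    )
    report.to_csv(outdir / "stats_report.csv", index=False)
    (outdir / "report.txt").write_text(_render_report(report, metrics))

    config_json = cfg.model_dump_json()
    manifest = {
        "package": "ratgait",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": json.loads(config_json),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.suffix == ".csv"),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"spatiotemporal": spatio, "force_metrics": metrics,
            "ensemble_curves": curves, "behavior": behav,
            "report": report, "results": results, "manifest": manifest}
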