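"""End-to-end configured pipeline on fully synthetic data.

One call simulates a longitudinal cohort (two age groups x subjects x
scan sessions), conditions the signals, builds thresholded graphs, computes
graph metrics, rich-club curves and ACC-seed connectivity, simulates maze
behavior and catFISH cell populations, and runs the group statistics:
the group x session mixed ANOVA on ACC-DS connectivity, the per-k rich-club
comparison, the within-group-z-scored bias-connectivity correlation, and the
age x task comparison of Arc-positive fractions.

The planted effects mirror the phenomenon under study: in the "aged" group
the ACC-DS correlation and the hub-hub (rich club) correlation increase
across sessions while the "young" group stays flat, and aged rats keep an
elevated lateral response bias.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

import json
import platform
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .behavior import mean_bias
from .catfish import ensemble_counts, epoch_to_task, similarity_score
from .connectome import (
    correlation_matrix,
    graph_metrics,
    high_strength_subnetwork,
    rich_club_curve,
    seed_connectivity,
    threshold_density,
)
from .preprocess import preprocess_series
from .stats import (
    MixedAnovaResult,
    mixed_anova,
    pooled_correlation,
    richclub_group_comparison,
    within_group_zscore,
)
from .synth import (
    BehaviorSimConfig,
    CellSimConfig,
    TimeSeriesSimConfig,
    gen_cell_population,
    gen_roi_timeseries,
    gen_trial_log,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


def _sub_seed(base: int, tag: str) -> int:
    """Deterministic per-unit seed below 2**31, independent of call order."""
    return int(np.random.SeedSequence([base, zlib.crc32(tag.encode())]).generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """All tunable parameters of a demonstration run."""

    # cohort
    groups: tuple[str, str] = ("young", "aged")
    n_subjects_per_group: int = 5
    n_sessions: int = 3
    # acquisition
    n_rois: int = 150
    n_volumes: int = 300
    dt: float = 2.0
    # preprocessing
    band_low: float = 0.01
    band_high: float = 0.1
    n_drop: int = 9
    # graph construction / metrics
    density: float = 0.15
    s_min: float = 15.0
    k_min: float = 40.0
    e_undir_display: float = 0.3
    n_smallworld_nulls: int = 0
    richclub_k_max: int = 40
    # planted connectivity conditions (per session)
    seed_region: str = "ACC"
    target_regions: tuple[str, ...] = ("DLS", "DMS")
    seed_pair_r: dict = field(default_factory=lambda: {
        "young": (0.35, 0.28, 0.20), "aged": (0.20, 0.45, 0.65)})
    hub_r: dict = field(default_factory=lambda: {
        "young": (0.45, 0.45, 0.45), "aged": (0.35, 0.55, 0.65)})
    n_hubs: int = 16
    noise_sd: float = 0.5
    # behavior
    n_trials_per_day: int = 32
    n_days_per_session: int = 3
    side_bias: dict = field(default_factory=lambda: {
        "young": (0.70, 0.60, 0.50), "aged": (0.80, 0.85, 0.90)})
    p_correct: dict = field(default_factory=lambda: {
        "young": (0.60, 0.75, 0.85), "aged": (0.55, 0.60, 0.60)})
    p_wme: float = 0.1
    # catFISH
    n_cells_per_image: int = 120
    n_images_per_region: int = 4
    n_planes: int = 20
    arc_fractions: dict = field(default_factory=lambda: {
        # region-> group -> (nuclear, cytoplasmic, double)
        "ACC": {"young": (0.05, 0.04, 0.015), "aged": (0.05, 0.04, 0.015)},
        "DLS": {"young": (0.02, 0.02, 0.005), "aged": (0.04, 0.035, 0.012)},
        "DMS": {"young": (0.02, 0.02, 0.005), "aged": (0.04, 0.035, 0.012)},
    })
    # stage toggles
    run_behavior: bool = True
    run_catfish: bool = True
    # statistics
    alpha: float = 0.05
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.density <= 1 and 0 < self.band_low < self.band_high):
            raise ValueError("density/band parameters out of range")
        for name in ("seed_pair_r", "hub_r", "side_bias", "p_correct"):
            d = getattr(self, name)
            for g in self.groups:
                if g not in d or len(d[g]) != self.n_sessions:
                    raise ValueError(f"{name} needs one value per session for group {g!r}")


@dataclass
class PipelineResult:
    """Report bundle of one pipeline run."""

    config: PipelineConfig
    metrics_table: pd.DataFrame
    seed_table: pd.DataFrame
    behavior_table: pd.DataFrame
    richclub_long: pd.DataFrame
    richclub_comparison: pd.DataFrame
    seed_anova: MixedAnovaResult
    bias_connectivity: tuple[float, float, float]  # (R, F, p)
    subnetworks: dict
    catfish_counts: pd.DataFrame
    catfish_task: pd.DataFrame
    catfish_anova: dict
    similarity_table: pd.DataFrame


def _simulate_graph_stage(config: PipelineConfig):
    """Simulate + preprocess + graph every subject/session."""
    labels = None
    metric_rows, seed_rows, rc_rows = [], [], []
    graphs_by_cell: dict[tuple[str, int], list] = {}
    for group in config.groups:
        for s in range(config.n_subjects_per_group):
            subject = f"{group}{s}"
            for session in range(config.n_sessions):
                ts_cfg = TimeSeriesSimConfig(
                    n_rois=config.n_rois,
                    n_volumes=config.n_volumes,
                    dt=config.dt,
                    hub_set=tuple(range(config.n_hubs)),
                    hub_r=config.hub_r[group][session],
                    noise_sd=config.noise_sd,
                    rng_seed=_sub_seed(config.seed, f"ts/{subject}/{session}"),
                )
                pairs = [(f"{config.seed_region}_{h}", f"{t}_{h}")
                         for t in config.target_regions for h in ("L", "R")]
                ts_cfg.seed_pair = pairs
                ts_cfg.seed_pair_r = config.seed_pair_r[group][session]
                series = gen_roi_timeseries(ts_cfg)
                labels = series.roi_labels
                clean = preprocess_series(series, low=config.band_low, high=config.band_high)
                cm = correlation_matrix(clean, n_drop=config.n_drop)
                graph = threshold_density(cm, density=config.density)
                graphs_by_cell.setdefault((group, session), []).append(graph)
                gm = graph_metrics(
                    graph,
                    n_nulls=config.n_smallworld_nulls,
                    rng_seed=_sub_seed(config.seed, f"null/{subject}/{session}"),
                )
                metric_rows.append({
                    "subject": subject, "group": group, "session": session,
                    "strength_mean": float(gm.strength.mean()),
                    "degree_mean": float(gm.degree.mean()),
                    "clustering": gm.clustering,
                    "path_length": gm.path_length,
                    "small_worldness": gm.small_worldness,
                })
                k_max = min(config.richclub_k_max, int(graph.degree().max()))
                rc = rich_club_curve(graph, k_max=k_max)
                for k, phi, defined in zip(rc.k_values, rc.phi, rc.defined):
                    rc_rows.append({"subject": subject, "group": group,
                                    "session": session, "k": int(k),
                                    "value": float(phi) if defined else np.nan})
                for res in seed_connectivity(cm, config.seed_region,
                                             config.target_regions):
                    seed_rows.append({
                        "subject": subject, "group": group, "session": session,
                        "target": res.target_label, "z_left": res.z_left,
                        "z_right": res.z_right, "z_mean": res.z_mean,
                    })
    return (pd.DataFrame(metric_rows), pd.DataFrame(seed_rows),
            pd.DataFrame(rc_rows), graphs_by_cell, labels)


def _simulate_behavior(config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for group in config.groups:
        for s in range(config.n_subjects_per_group):
            subject = f"{group}{s}"
            for session in range(config.n_sessions):
                bcfg = BehaviorSimConfig(
                    n_trials_per_day=config.n_trials_per_day,
                    n_days=config.n_days_per_session,
                    side_bias=config.side_bias[group][session],
                    p_correct=[config.p_correct[group][session]] * config.n_days_per_session,
                    p_wme=config.p_wme,
                    rng_seed=_sub_seed(config.seed, f"beh/{subject}/{session}"),
                )
                log = gen_trial_log(bcfg)
                rows.append({"subject": subject, "group": group, "session": session,
                             "mean_bias": mean_bias(log)})
    return pd.DataFrame(rows)


def _simulate_catfish(config: PipelineConfig):
    cells = []
    orders = {}
    for gi, group in enumerate(config.groups):
        for s in range(config.n_subjects_per_group):
            rat = f"{group}{s}"
            orders[rat] = "task_first" if s % 2 == 0 else "task_second"
            rat_rng = np.random.default_rng(_sub_seed(config.seed, f"rat/{rat}"))
            for region, by_group in config.arc_fractions.items():
                # between-animal biological variability on the planted rates
                nuc, cyt, dbl = (
                    float(np.clip(v * rat_rng.lognormal(0.0, 0.2), 0.0, 0.3))
                    for v in by_group[group]
                )
                for img in range(config.n_images_per_region):
                    ccfg = CellSimConfig(
                        n_cells=config.n_cells_per_image,
                        n_planes=config.n_planes,
                        frac_nuclear=nuc, frac_cytoplasmic=cyt, frac_double=dbl,
                        frac_negative=1.0 - nuc - cyt - dbl,
                        region=region,
                        hemisphere="left" if img % 2 == 0 else "right",
                        rat_id=rat, image_id=f"{rat}_{region}_{img}",
                        rng_seed=_sub_seed(config.seed, f"cell/{rat}/{region}/{img}"),
                    )
                    cells.extend(rec.cell for rec in gen_cell_population(ccfg))
    counts = ensemble_counts(cells)
    count_rows, task_rows, sim_rows = [], [], []
    for ec in counts:
        count_rows.append({
            "rat_id": ec.rat_id, "region": ec.region, "n_cells": ec.n_cells,
            "frac_nuclear": ec.frac_nuclear, "frac_cytoplasmic": ec.frac_cytoplasmic,
            "frac_double": ec.frac_double, "frac_negative": ec.frac_negative,
        })
        group = "aged" if ec.rat_id.startswith("aged") else "young"
        by_task = epoch_to_task(ec, orders[ec.rat_id])
        for task, frac in by_task.items():
            task_rows.append({"rat_id": ec.rat_id, "group": group,
                              "region": ec.region, "task": task,
                              "pct_positive": 100.0 * frac})
        p_a = ec.frac_nuclear + ec.frac_double
        p_b = ec.frac_cytoplasmic + ec.frac_double
        try:
            sim = similarity_score(p_a, p_b, ec.frac_double)
        except ValueError:
            sim = np.nan
        sim_rows.append({"rat_id": ec.rat_id, "group": group,
                         "region": ec.region, "similarity": sim})
    return (pd.DataFrame(count_rows), pd.DataFrame(task_rows),
            pd.DataFrame(sim_rows))


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute simulate -> preprocess -> graph -> behavior/catFISH -> stats.

    When ``out_dir`` is given, all result tables, the resolved config and a
    run log (library versions + seed) are written there as delimited text.
    """
    config = config or PipelineConfig()
    config.validate()
    cfg_hash = cio.config_hash(config)

    metrics, seeds, rc_long, graphs_by_cell, _ = _simulate_graph_stage(config)

    # ACC-DS connectivity: mean over targets and hemispheres per subject/session
    acc_ds = (seeds.groupby(["subject", "group", "session"], as_index=False)
              ["z_mean"].mean().rename(columns={"z_mean": "value"}))
    seed_anova = mixed_anova(acc_ds)

    rc_comparison = richclub_group_comparison(rc_long, alpha=config.alpha)

    behavior = pd.DataFrame()
    bias_conn = (np.nan, np.nan, np.nan)
    if config.run_behavior:
        behavior = _simulate_behavior(config)
        # pooled bias-connectivity correlation after within-group z-scoring
        merged = acc_ds.merge(behavior, on=["subject", "group", "session"])
        zconn = within_group_zscore(merged["value"], merged["group"])
        zbias = within_group_zscore(merged["mean_bias"], merged["group"])
        bias_conn = pooled_correlation(zconn, zbias)

    subnetworks = {}
    for (group, session), graphs in sorted(graphs_by_cell.items()):
        nodes, _ = high_strength_subnetwork(graphs, s_min=config.s_min, mode="mean")
        subnetworks[f"{group}/session{session}"] = nodes

    counts = task_table = sim_table = pd.DataFrame()
    catfish_anova = {}
    if config.run_catfish:
        counts, task_table, sim_table = _simulate_catfish(config)
        ds_task = task_table[task_table["region"].isin(("DLS", "DMS"))]
        ds_mean = (ds_task.groupby(["rat_id", "group", "task"], as_index=False)
                   ["pct_positive"].mean()
                   .rename(columns={"task": "session", "pct_positive": "value",
                                    "rat_id": "subject"}))
        cat_res = mixed_anova(ds_mean)
        catfish_anova = {
            "f_age": cat_res.f_between, "p_age": cat_res.p_between,
            "f_task": cat_res.f_within, "p_task": cat_res.p_within,
            "f_age_x_task": cat_res.f_interaction, "p_age_x_task": cat_res.p_interaction,
        }

    result = PipelineResult(
        config=config, metrics_table=metrics, seed_table=seeds,
        behavior_table=behavior, richclub_long=rc_long,
        richclub_comparison=rc_comparison, seed_anova=seed_anova,
        bias_connectivity=bias_conn, subnetworks=subnetworks,
        catfish_counts=counts, catfish_task=task_table,
        catfish_anova=catfish_anova, similarity_table=sim_table,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), cfg_hash)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, cfg_hash: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = result.config.seed
    tables = {
        "graph_metrics.tsv": (result.metrics_table, "graph"),
        "seed_connectivity.tsv": (result.seed_table, "seed"),
        "behavior_summary.tsv": (result.behavior_table, "behavior"),
        "richclub_curves.tsv": (result.richclub_long, "richclub"),
        "richclub_comparison.tsv": (result.richclub_comparison, "stats"),
        "catfish_counts.tsv": (result.catfish_counts, "catfish"),
        "catfish_task_fractions.tsv": (result.catfish_task, "catfish"),
        "similarity_scores.tsv": (result.similarity_table, "catfish"),
    }
    for name, (df, stage) in tables.items():
        if not df.empty:
            cio.write_table(df, out_dir / name, stage=stage, seed=seed, cfg_hash=cfg_hash)
    report = {
        "seed_anova": asdict(result.seed_anova),
        "bias_connectivity": dict(zip(("R", "F", "p"), result.bias_connectivity)),
        "catfish_anova": result.catfish_anova,
        "subnetworks": result.subnetworks,
    }
    (out_dir / "summary_report.json").write_text(json.dumps(report, indent=2, default=str))
    (out_dir / "resolved_config.json").write_text(
        json.dumps(asdict(result.config), indent=2, default=str))
    log = {
        "config_hash": cfg_hash,
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
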