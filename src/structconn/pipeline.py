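"""End-to-end analysis: manifest -> thresholded metric curves -> AUC ->
group comparisons -> volumetrics -> clinical associations -> report.

A single global seed fans out to stage-specific seeds through
``numpy.random.SeedSequence([seed, stage_index])`` (stage indices are
fixed and logged), so a run is reproducible end to end and no two
stages share a random stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import volumetrics as vol
from .io import Cohort, VOLUME_REGIONS, default_parcellation, load_cohort, load_parcellation
from .stats import (
    CurveConfig,
    TESTED_NODAL_METRICS,
    auc_table,
    compare_groups,
    compute_metric_curves,
    covariate_adjusted_association,
)
from .thresholding import RangeSelection, ThresholdRange, default_range, select_threshold_range

log = logging.getLogger(__name__)

_STAGE = {"range_selection": 0, "curves": 1, "permutation": 2, "partition": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([global_seed, _STAGE[stage]]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    manifest: str | None = None
    parcellation: str | None = None  # None = bundled 84-region table
    out_dir: str = "structconn_results"
    seed: int = 0
    # thresholds.*
    grid: tuple[float, ...] | None = None  # None = 0.10..0.55 step 0.05
    auto_select: bool = False
    candidates: tuple[float, ...] | None = None
    sigma_fraction: float = 1.0
    step: float = 0.05
    # nulls.*
    n_nulls: int = 20
    swaps_per_edge: int = 10
    # stats.*
    n_iter: int = 10_000
    alpha: float = 0.05
    apl_policy: str = "strict"
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("manifest", "parcellation", "out_dir", "seed", "plots"):
            if key in raw:
                kwargs[key] = raw[key]
        thr = raw.get("thresholds", {})
        for src, dst in (("grid", "grid"), ("auto_select", "auto_select"),
                         ("candidates", "candidates"), ("sigma_fraction", "sigma_fraction"),
                         ("step", "step")):
            if src in thr:
                val = thr[src]
                kwargs[dst] = tuple(val) if isinstance(val, (list, tuple)) else val
        nulls = raw.get("nulls", {})
        if "n" in nulls:
            kwargs["n_nulls"] = nulls["n"]
        if "swaps_per_edge" in nulls:
            kwargs["swaps_per_edge"] = nulls["swaps_per_edge"]
        stats = raw.get("stats", {})
        if "n_iter" in stats:
            kwargs["n_iter"] = stats["n_iter"]
        if "alpha" in stats:
            kwargs["alpha"] = stats["alpha"]
        return cls(**kwargs)


@dataclass
class AnalysisResults:
    config: RunConfig
    thr_range: ThresholdRange
    range_selection: RangeSelection | None
    aucs: pd.DataFrame
    comparisons: pd.DataFrame
    volume_table: pd.DataFrame
    volume_tests: pd.DataFrame
    volume_correlations: pd.DataFrame
    associations: pd.DataFrame
    seeds: dict = field(default_factory=dict)


def _volumetrics_stage(cohort: Cohort, aucs: pd.DataFrame, alpha: float):
    """ICV adjustment, Welch group tests, and volume-strength correlations."""
    subj_ids = [s.subject_id for s in cohort.subjects]
    icvs = np.array([s.icv for s in cohort.subjects])
    is_patient = cohort.groups == "patient"
    vol_rows, test_rows = [], []
    adjusted_by_region = {}
    for region in VOLUME_REGIONS:
        observed = np.array(
            [s.regional_volumes.get(region, np.nan) for s in cohort.subjects]
        )
        if not np.all(np.isfinite(observed)):
            log.info("region %s: missing volumes; skipped", region)
            continue
        adj = vol.icv_adjust(observed, icvs)
        adjusted_by_region[region] = adj.adjusted
        for sid, o, a in zip(subj_ids, observed, adj.adjusted):
            vol_rows.append((sid, region, o, a))
        t = vol.group_volume_test(adj.adjusted, is_patient)
        test_rows.append(
            (region, adj.beta, adj.icv_mean, t.mean_patient, t.mean_control,
             t.t_statistic, t.p_value, t.p_value < alpha)
        )
    volume_table = pd.DataFrame(
        vol_rows, columns=["subject_id", "region", "volume_observed", "volume_adjusted"]
    )
    volume_tests = pd.DataFrame(
        test_rows,
        columns=["region", "beta", "icv_mean", "mean_patient", "mean_control",
                 "t_statistic", "p_value", "significant"],
    )

    # hippocampal volume vs own-hemisphere hippocampal strength AUC, in patients
    corr_rows = []
    strength = aucs[(aucs["scope_type"] == "node") & (aucs["metric"] == "strength")]
    for region, label in (
        ("left_hippocampus", "Left-Hippocampus"),
        ("right_hippocampus", "Right-Hippocampus"),
    ):
        if region not in adjusted_by_region:
            continue
        sa = strength[strength["scope"] == label].set_index("subject_id")["auc"]
        if sa.empty:
            continue
        adj = pd.Series(adjusted_by_region[region], index=subj_ids)
        pat_ids = [sid for sid, p in zip(subj_ids, is_patient) if p]
        r = vol.volume_metric_correlation(adj.loc[pat_ids].to_numpy(), sa.loc[pat_ids].to_numpy())
        corr_rows.append((region, label, "strength", r.r, r.p_value, r.n))
    volume_correlations = pd.DataFrame(
        corr_rows, columns=["region", "scope", "metric", "r", "p_value", "n"]
    )
    return volume_table, volume_tests, volume_correlations


def _associations_stage(
    cohort: Cohort, aucs: pd.DataFrame, comparisons: pd.DataFrame, alpha: float
) -> pd.DataFrame:
    """Covariate-adjusted associations for significantly altered nodal metrics.

    Predictors are the nodal comparisons below alpha; outcomes the
    clinical and cognitive scores; covariates age and years of
    education; patients only, listwise-complete cases.
    """
    from .io import SCORE_NAMES

    sig = comparisons[
        (comparisons["scope_type"] == "node") & (comparisons["p_value"] < alpha)
    ]
    patients = cohort.by_group("patient")
    covs = np.column_stack(
        [[s.age for s in patients], [s.education for s in patients]]
    )
    rows = []
    for _, pred in sig.iterrows():
        x = (
            aucs[
                (aucs["scope_type"] == "node")
                & (aucs["scope"] == pred["scope"])
                & (aucs["metric"] == pred["metric"])
            ]
            .set_index("subject_id")["auc"]
            .reindex([s.subject_id for s in patients])
            .to_numpy()
        )
        for score in SCORE_NAMES:
            y = np.array([s.scores.get(score, np.nan) for s in patients])
            if np.isfinite(y).sum() < 5:
                continue
            try:
                a = covariate_adjusted_association(
                    x, y, covs,
                    predictor=f"{pred['scope']}:{pred['metric']}", outcome=score,
                )
            except ValueError:
                continue
            rows.append(
                (a.predictor, a.outcome, a.partial_r, a.p_value, a.n_complete,
                 (a.p_value < alpha) if np.isfinite(a.p_value) else False)
            )
    return pd.DataFrame(
        rows, columns=["predictor", "outcome", "partial_r", "p_value", "n_complete", "significant"]
    )


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> AnalysisResults:
    """Execute the full analysis; any stage failure raises with the stage name."""
    if cohort is None:
        if config.manifest is None:
            raise ValueError("either a cohort or a manifest path is required")
        parc = (
            load_parcellation(config.parcellation)
            if config.parcellation
            else default_parcellation()
        )
        cohort = load_cohort(config.manifest, parc)

    seeds = {stage: stage_seed(config.seed, stage) for stage in _STAGE}

    range_selection = None
    if config.auto_select:
        range_selection = select_threshold_range(
            cohort,
            config.candidates,
            step=config.step,
            sigma_fraction=config.sigma_fraction,
            n_nulls=config.n_nulls,
            swaps_per_edge=config.swaps_per_edge,
            seed=seeds["range_selection"],
        )
        thr_range = range_selection.range
    elif config.grid is not None:
        thr_range = ThresholdRange(tuple(config.grid))
    else:
        thr_range = default_range()

    curve_cfg = CurveConfig(
        n_nulls=config.n_nulls,
        swaps_per_edge=config.swaps_per_edge,
        apl_policy=config.apl_policy,
        seed=seeds["curves"],
    )
    curves = compute_metric_curves(cohort, thr_range, curve_cfg)
    aucs = auc_table(curves)

    parc = cohort.parcellation
    tested_nodes = np.concatenate([parc.nodes_in("MTL"), parc.nodes_in("DMN")])
    tested_labels = [parc.labels[i] for i in tested_nodes]
    comparisons = compare_groups(
        aucs, n_iter=config.n_iter, seed=seeds["permutation"], tested_nodes=tested_labels
    )
    comparisons["significant"] = comparisons["p_value"] < config.alpha

    volume_table, volume_tests, volume_correlations = _volumetrics_stage(
        cohort, aucs, config.alpha
    )
    associations = _associations_stage(cohort, aucs, comparisons, config.alpha)

    return AnalysisResults(
        config=config,
        thr_range=thr_range,
        range_selection=range_selection,
        aucs=aucs,
        comparisons=comparisons,
        volume_table=volume_table,
        volume_tests=volume_tests,
        volume_correlations=volume_correlations,
        associations=associations,
        seeds=seeds,
    )


_FLOAT_FMT = "%.17g"


def write_report(results: AnalysisResults, out_dir: str | Path, plots: bool | None = None) -> Path:
    """Write tidy result CSVs, a run log, and a human-readable summary.

    Tables are sorted by (scope_type, metric, scope) so identical runs
    produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    comp = results.comparisons.sort_values(
        ["scope_type", "metric", "scope"], kind="stable"
    )
    for scope_type, name in (("node", "nodal"), ("module", "modular"), ("global", "global")):
        sub = comp[comp["scope_type"] == scope_type]
        sub.to_csv(out / f"comparisons_{name}.csv", index=False, float_format=_FLOAT_FMT)
    results.aucs.sort_values(
        ["scope_type", "metric", "scope", "subject_id"], kind="stable"
    ).to_csv(out / "auc_values.csv", index=False, float_format=_FLOAT_FMT)
    results.volume_table.sort_values(["region", "subject_id"]).to_csv(
        out / "volumes_adjusted.csv", index=False, float_format=_FLOAT_FMT
    )
    results.volume_tests.sort_values("region").to_csv(
        out / "volume_tests.csv", index=False, float_format=_FLOAT_FMT
    )
    results.volume_correlations.sort_values("region").to_csv(
        out / "volume_correlations.csv", index=False, float_format=_FLOAT_FMT
    )
    results.associations.sort_values(["predictor", "outcome"]).to_csv(
        out / "associations.csv", index=False, float_format=_FLOAT_FMT
    )
    if results.range_selection is not None:
        results.range_selection.diagnostics.to_csv(
            out / "threshold_diagnostics.csv", index=False, float_format=_FLOAT_FMT
        )

    cfg = results.config
    log_lines = [
        "structconn run log",
        f"global seed: {cfg.seed}",
        *[f"stage seed [{k}]: {v}" for k, v in sorted(results.seeds.items())],
        f"threshold grid: {list(results.thr_range.densities)}",
        f"null ensemble: n={cfg.n_nulls}, swaps_per_edge={cfg.swaps_per_edge}",
        f"permutation iterations: {cfg.n_iter}",
        f"alpha: {cfg.alpha}",
        f"APL policy: {cfg.apl_policy}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    sig = comp[comp["p_value"] < cfg.alpha]
    lines = [
        "# Analysis summary",
        "",
        "**No correction for multiple testing was applied; all p-values are",
        "reported as-is and comparisons are exploratory.**",
        "",
        f"Threshold range: {results.thr_range.densities[0]:.2f}-"
        f"{results.thr_range.densities[-1]:.2f} "
        f"(step {results.thr_range.step:.2f}, {len(results.thr_range)} densities), "
        "metrics integrated as area under the metric-vs-density curve.",
        "",
        f"## Group comparisons below alpha = {cfg.alpha}",
        "",
    ]
    if sig.empty:
        lines.append("(none)")
    else:
        for _, row in sig.iterrows():
            lines.append(
                f"- {row['scope_type']} | {row['scope']} | {row['metric']}: "
                f"diff (patient - control) = {row['observed_diff']:.4g}, p = {row['p_value']:.4g}"
            )
    lines += ["", "## Volume group tests (Welch, ICV-adjusted)", ""]
    for _, row in results.volume_tests.iterrows():
        lines.append(
            f"- {row['region']}: t = {row['t_statistic']:.3f}, p = {row['p_value']:.4g}"
        )
    lines += ["", "## Volume-strength correlations (patients)", ""]
    for _, row in results.volume_correlations.iterrows():
        lines.append(f"- {row['region']} vs {row['scope']}: r = {row['r']:.3f}, p = {row['p_value']:.4g}")
    if not results.associations.empty:
        lines += ["", "## Covariate-adjusted clinical associations (patients)", ""]
        for _, row in results.associations.iterrows():
            lines.append(
                f"- {row['predictor']} vs {row['outcome']}: partial r = {row['partial_r']:.3f}, "
                f"p = {row['p_value']:.4g} (n = {row['n_complete']})"
            )
    (out / "summary.md").write_text("\n".join(lines) + "\n")

    if plots if plots is not None else cfg.plots:
        _write_plots(results, out / "plots")
    return out


def _write_plots(results: AnalysisResults, plot_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    comp = results.comparisons
    sig = comp[(comp["scope_type"] == "node") & (comp["p_value"] < results.config.alpha)]
    aucs = results.aucs
    for _, row in sig.iterrows():
        sub = aucs[
            (aucs["scope_type"] == "node")
            & (aucs["scope"] == row["scope"])
            & (aucs["metric"] == row["metric"])
        ]
        fig, ax = plt.subplots(figsize=(4, 4))
        data = [sub.loc[sub["group"] == g, "auc"] for g in ("control", "patient")]
        ax.boxplot(data, tick_labels=["control", "patient"])
        ax.set_title(f"{row['scope']} {row['metric']} (p={row['p_value']:.3g})")
        ax.set_ylabel("AUC")
        fig.tight_layout()
        safe = row["scope"].replace(".", "_").replace("-", "_")
        fig.savefig(plot_dir / f"box_{safe}_{row['metric']}.png", dpi=100)
        plt.close(fig)
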