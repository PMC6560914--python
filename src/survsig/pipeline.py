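"""End-to-end orchestration of the subgroup-specific prognostic analysis.

Per subgroup with enough death events the pipeline runs: preprocessing
(probe collapse, full-cohort relative rescaling, gene filters, stratified
split) -> genome-wide univariable Cox on the exploratory split (with an
optional proportional-hazards diagnostic) -> pre-ranked GSEA on the log-HR
ordering (positive and negative directions at nominal p < 0.05) ->
leading-edge core scores evaluated on both splits plus the bootstrap
robustness percentage -> arm-level aberration screening and successive
stratification.  Subgroups below the event threshold are skipped with a
logged reason (the WNT-style low-event rule).

Everything is a thin composition of the stage modules; results are returned
in memory and optionally written as TSV/JSON with a run manifest recording
seeds and parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import preprocess as pp
from .cna import screen_aberrations, successive_stratify
from .gsea import (
    GeneSetCollection,
    filter_gene_sets,
    rank_by_loghr,
    results_to_frame,
    run_gsea,
)
from .preprocess import ExpressionMatrix
from .signature import bootstrap_robustness, core_average_score, evaluate_score
from .survival import cox_screen, ph_test

logger = logging.getLogger("survsig")


@dataclass
class RunConfig:
    """All stage parameters of a pipeline run."""

    subgroups: list[str] | None = None  # None = all with enough events
    max_age: float | None = 18.0
    split_fraction: float = 0.7
    min_events_per_subgroup: int = 5
    gene_min_max_expr: float = 7.0
    gene_min_range: float = 1.5
    gset_max_size: int = 50
    gset_min_size: int = 5
    databases: list[str] | None = None
    n_perm: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    cna_min_freq: float = 0.10
    delta_r2_min: float = 0.01
    min_node: int = 20
    include_i17q: bool = False
    run_ph_test: bool = False
    seed: int = 0


@dataclass
class SubgroupReport:
    subgroup: str
    skipped_reason: str | None = None
    n: int = 0
    n_events: int = 0
    n_genes_analyzed: int = 0
    gene_cox: pd.DataFrame | None = None
    gsea: pd.DataFrame | None = None
    pathways: pd.DataFrame | None = None
    cna_screen: pd.DataFrame | None = None
    tree: dict | None = None


@dataclass
class RunReport:
    subgroup_reports: dict[str, SubgroupReport]
    manifest: dict


def run_subgroup_analysis(
    expression: ExpressionMatrix,
    samples: pd.DataFrame,
    gene_sets: GeneSetCollection,
    config: RunConfig,
    probe_map: pd.Series | None = None,
    arm_calls: pd.DataFrame | None = None,
    out_dir=None,
) -> RunReport:
    """Run the full analysis; see the module docstring for the stage order."""
    t0 = time.time()
    # ---- cohort-level preprocessing -------------------------------------
    samples = pp.filter_samples(samples, max_age=config.max_age)
    samples = samples.loc[[s for s in samples.index if s in expression.sample_ids]]
    expression = expression.subset_samples(samples.index)
    if probe_map is not None:
        gene_log2 = pp.collapse_probes(expression, probe_map)
    else:
        gene_log2 = expression
    relative = pp.rescale_relative(gene_log2)  # full retained cohort scaling
    samples = samples.copy()
    samples["two_year_status"] = pp.two_year_status(samples["os_years"],
                                                    samples["os_event"])
    samples = pp.stratified_split(samples, fraction=config.split_fraction,
                                  seed=config.seed)
    logger.info("cohort: %d samples, %d genes after collapse",
                len(samples), len(gene_log2.feature_ids))

    subgroups = config.subgroups or sorted(samples["subgroup"].unique())
    reports: dict[str, SubgroupReport] = {}
    for k, sg in enumerate(subgroups):
        sg_seed = int((config.seed + 7919 * (k + 1)) % (2**31))
        reports[sg] = _analyze_subgroup(
            sg, gene_log2, relative, samples, gene_sets, arm_calls,
            config, sg_seed,
        )
    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "n_samples": int(len(samples)),
        "n_genes": int(len(gene_log2.feature_ids)),
        "subgroups": list(subgroups),
        "elapsed_s": round(time.time() - t0, 2),
    }
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    report = RunReport(subgroup_reports=reports, manifest=manifest)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _analyze_subgroup(sg, gene_log2, relative, samples, gene_sets, arm_calls,
                      config: RunConfig, seed: int) -> SubgroupReport:
    sub = samples[samples["subgroup"] == sg]
    rep = SubgroupReport(subgroup=sg, n=len(sub),
                         n_events=int(sub["os_event"].sum()))
    if rep.n_events < config.min_events_per_subgroup:
        rep.skipped_reason = (
            f"only {rep.n_events} death events out of {rep.n} samples "
            f"(threshold {config.min_events_per_subgroup})"
        )
        logger.info("subgroup %s skipped: %s", sg, rep.skipped_reason)
        return rep

    # gene filters on all subgroup samples (log2 scale)
    genes = pp.filter_genes(gene_log2, sub.index,
                            min_max_expr=config.gene_min_max_expr,
                            min_range=config.gene_min_range)
    genes = [g for g in genes if g in relative.values.index]
    rep.n_genes_analyzed = len(genes)
    logger.info("subgroup %s: n=%d, events=%d, genes=%d",
                sg, rep.n, rep.n_events, len(genes))
    if not genes:
        rep.skipped_reason = "no gene passed the expression filters"
        return rep

    expl = sub[sub["split"] == pp.SPLIT_EXPLORATORY]
    X_expl = relative.values.loc[genes, expl.index].T
    t_screen = time.time()
    gene_cox = cox_screen(expl["os_years"], expl["os_event"], X_expl)
    logger.info("subgroup %s: Cox screen on %d genes in %.1fs", sg,
                len(genes), time.time() - t_screen)
    if config.run_ph_test:
        ok = gene_cox.index[~gene_cox["degenerate"]]
        ph = {}
        for g in ok:
            ph[g] = ph_test(expl["os_years"], expl["os_event"],
                            X_expl[g].to_numpy(), names=(g,))[0]
        gene_cox["ph_p"] = pd.Series(ph)
    rep.gene_cox = gene_cox

    ranked = rank_by_loghr(gene_cox["beta"].dropna())
    filtered, _dropped = filter_gene_sets(
        gene_sets, universe=list(ranked.genes),
        max_size=config.gset_max_size, min_size=config.gset_min_size,
        databases=config.databases,
    )
    enr = run_gsea(ranked, filtered, n_perm=config.n_perm, seed=seed)
    rep.gsea = results_to_frame(enr)

    # core-gene signature stage for sets passing nominal p < alpha
    rows = []
    boot_root = np.random.default_rng(seed + 1)
    whole_cox = None
    for r in sorted(enr, key=lambda r: (r.nominal_p, r.set_name)):
        if r.nominal_p >= config.alpha or not r.leading_edge:
            continue
        score = core_average_score(relative.subset_samples(sub.index),
                                   r.leading_edge, pathway=r.set_name)
        fits = evaluate_score(score, sub)
        boot = bootstrap_robustness(score, sub, n_boot=config.n_boot,
                                    seed=int(boot_root.integers(2**31)),
                                    alpha=config.alpha)
        if whole_cox is None:
            whole_cox = cox_screen(sub["os_years"], sub["os_event"],
                                   relative.values.loc[genes, sub.index].T)
        rep_core = [g for g in r.leading_edge
                    if g in whole_cox.index
                    and whole_cox.loc[g, "wald_p"] < config.alpha]
        fe = fits[pp.SPLIT_EXPLORATORY]
        fv = fits[pp.SPLIT_VALIDATION]
        rows.append({
            "pathway": r.set_name,
            "db": r.database,
            "direction": r.direction,
            "es": r.es,
            "nominal_p": r.nominal_p,
            "n_core": len(score.core_genes),
            "expl_hr_per_0.1": np.nan if fe is None else fe.hr_per_01[0],
            "expl_p": np.nan if fe is None else fe.wald_p[0],
            "valid_hr_per_0.1": np.nan if fv is None else fv.hr_per_01[0],
            "valid_p": np.nan if fv is None else fv.wald_p[0],
            "bootstrap_pct": boot.pct_significant,
            "representative_core_genes": ",".join(rep_core),
            "core_genes": ",".join(score.core_genes),
        })
    pathways = pd.DataFrame(rows)
    if not pathways.empty:
        pathways = pathways.sort_values(
            ["bootstrap_pct", "es"], ascending=[False, False]
        ).reset_index(drop=True)
    rep.pathways = pathways

    # arm-level CNA stage
    if arm_calls is not None:
        calls = arm_calls.loc[sub.index]
        events = screen_aberrations(calls, sub, min_freq=config.cna_min_freq,
                                    alpha=config.alpha,
                                    include_i17q=config.include_i17q)
        rep.cna_screen = pd.DataFrame(
            {
                "event": [e.label for e in events],
                "frequency": [e.frequency for e in events],
                "hr": [np.nan if e.cox is None else e.cox.hr_per_unit[0]
                       for e in events],
                "p": [e.p for e in events],
                "designation": [e.designation or "" for e in events],
            }
        )
        score = None
        if not pathways.empty:
            top = pathways.iloc[0]
            score = core_average_score(relative.subset_samples(sub.index),
                                       top["core_genes"].split(","),
                                       pathway=top["pathway"])
        tree = successive_stratify(calls, sub, score=score,
                                   min_freq=config.cna_min_freq,
                                   alpha=config.alpha,
                                   min_node=config.min_node,
                                   include_i17q=config.include_i17q)
        rep.tree = tree.to_dict()
    return rep


def gene_level_report(
    relative: ExpressionMatrix,
    samples: pd.DataFrame,
    genes: list[str],
    gene_pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-gene prognostic table plus gene–gene Pearson correlations.

    Returns (gene table, correlation table, skipped genes). The gene table
    has the per-0.1 hazard ratio and Wald p over the given samples and the
    per-subgroup median relative expression.
    """
    known = [g for g in genes if g in relative.values.index]
    skipped = [g for g in genes if g not in relative.values.index]
    X = relative.values.loc[known, samples.index].T
    cox = cox_screen(samples["os_years"], samples["os_event"], X)
    table = cox[["hr_per_0.1", "wald_p"]].copy()
    for sg in sorted(samples["subgroup"].unique()):
        ids = samples.index[samples["subgroup"] == sg]
        table[f"median_{sg}"] = relative.values.loc[known, ids].median(axis=1)
    corr_rows = []
    for a, b in gene_pairs or []:
        if a not in relative.values.index or b not in relative.values.index:
            skipped += [g for g in (a, b) if g not in relative.values.index]
            continue
        xa = relative.values.loc[a, samples.index].to_numpy()
        xb = relative.values.loc[b, samples.index].to_numpy()
        r, p = sps.pearsonr(xa, xb)
        corr_rows.append((a, b, float(r), float(p)))
    corr = pd.DataFrame(corr_rows, columns=["gene_a", "gene_b", "pearson_r", "p"])
    return table, corr, sorted(set(skipped))


def write_report(report: RunReport, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sg, rep in report.subgroup_reports.items():
        d = out_dir / sg
        d.mkdir(exist_ok=True)
        if rep.skipped_reason:
            (d / "SKIPPED.txt").write_text(rep.skipped_reason + "\n")
            continue
        for name, df in [("gene_cox", rep.gene_cox), ("gsea", rep.gsea),
                         ("pathways", rep.pathways),
                         ("cna_screen", rep.cna_screen)]:
            if df is not None:
                df.to_csv(d / f"{name}.tsv", sep="\t",
                          float_format="%.6g")
        if rep.tree is not None:
            with open(d / "stratification_tree.json", "w") as fh:
                json.dump(rep.tree, fh, indent=1)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=1)
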