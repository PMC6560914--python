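"""Core-gene average prognostic scores and their evaluation.

A pathway's core genes are the leading edge of its enrichment; the per-sample
score is the unweighted mean of their relative ([0, 1]) expression values.
The score's prognostic power is assessed by univariable Cox fits on the
exploratory and validation splits (HR reported per 0.1 score increment),
by Q1/Q3 quantile stratification feeding Kaplan–Meier/log-rank comparisons,
and by a bootstrap robustness percentage: the share of with-replacement
cohort resamples in which the score's Cox p-value is below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, SPLIT_EXPLORATORY, SPLIT_VALIDATION
from .survival import (
    CoxResult,
    DegenerateCovariateError,
    InsufficientEventsError,
    fit_cox,
)


@dataclass
class CoreScore:
    pathway: str
    core_genes: list[str]       # genes actually contributing
    missing_genes: list[str]    # requested but absent from the matrix
    scores: pd.Series           # per-sample mean relative expression

    def subset(self, sample_ids) -> pd.Series:
        return self.scores.loc[list(sample_ids)]


def core_average_score(matrix: ExpressionMatrix, core_genes,
                       pathway: str = "") -> CoreScore:
    """Per-sample unweighted mean relative expression of the core genes."""
    if matrix.scale != "relative":
        raise ValueError("core scores are defined on the relative scale")
    core_genes = list(core_genes)
    present = [g for g in core_genes if g in matrix.values.index]
    missing = [g for g in core_genes if g not in matrix.values.index]
    if not present:
        raise ValueError(f"no core gene of {pathway!r} present in the matrix")
    scores = matrix.values.loc[present].mean(axis=0)
    return CoreScore(pathway=pathway, core_genes=present,
                     missing_genes=missing, scores=scores)


def evaluate_score(score: CoreScore, samples: pd.DataFrame) -> dict[str, CoxResult | None]:
    """Univariable Cox fit of the score on each split.

    Returns ``{"exploratory": CoxResult|None, "validation": ...}``; a split
    with fewer than two events or a degenerate score is flagged
    not-evaluable (None).
    """
    out: dict[str, CoxResult | None] = {}
    for split in (SPLIT_EXPLORATORY, SPLIT_VALIDATION):
        sub = samples[samples["split"] == split]
        x = score.subset(sub.index)
        try:
            out[split] = fit_cox(sub["os_years"], sub["os_event"], x,
                                 names=(score.pathway or "score",))
        except (InsufficientEventsError, DegenerateCovariateError):
            out[split] = None
    return out


def quantile_stratify(scores) -> tuple[pd.Series, bool]:
    """Label samples low/mid/high by the Q1 and Q3 score quantiles.

    low: score < Q1; mid: Q1 <= score <= Q3; high: score > Q3 (linear-
    interpolation quantiles). Returns (labels, degenerate); when all scores
    are equal the stratification is flagged degenerate and every sample is
    labelled mid.
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 4:
        raise ValueError("quantile stratification needs n >= 4")
    q1, q3 = np.percentile(scores.to_numpy(), [25, 75])
    if scores.nunique() == 1:
        return pd.Series("mid", index=scores.index), True
    labels = pd.Series("mid", index=scores.index)
    labels[scores < q1] = "low"
    labels[scores > q3] = "high"
    return labels, False


@dataclass
class BootstrapSummary:
    pathway: str
    n_replicates: int
    pct_significant: float  # percentage of replicates with Wald p < 0.05
    n_redrawn: int
    seed: int


def bootstrap_robustness(score: CoreScore, samples: pd.DataFrame,
                         n_boot: int = 1000, seed: int = 0,
                         alpha: float = 0.05) -> BootstrapSummary:
    """Bootstrap robustness percentage of the score's prognostic effect.

    Each replicate resamples the full cohort with replacement and refits the
    univariable Cox model on the score. Replicates with fewer than two
    events or a zero-variance score are redrawn (count reported) so the
    denominator stays ``n_boot``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    times = samples["os_years"].to_numpy(dtype=float)
    events = samples["os_event"].to_numpy(dtype=int)
    x = score.subset(samples.index).to_numpy(dtype=float)
    n = len(times)
    n_sig = 0
    n_redrawn = 0
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        ev = events[idx]
        xv = x[idx]
        if ev.sum() < 2 or xv.std() == 0:
            n_redrawn += 1
            continue
        res = fit_cox(times[idx], ev, xv)
        if res.wald_p[0] < alpha:
            n_sig += 1
        done += 1
    return BootstrapSummary(
        pathway=score.pathway,
        n_replicates=n_boot,
        pct_significant=100.0 * n_sig / n_boot,
        n_redrawn=n_redrawn,
        seed=seed,
    )
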