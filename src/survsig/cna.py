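"""Arm-level copy-number prognostic screening and successive stratification.

Each chromosome arm contributes up to two candidate aberration events (gain
and loss, screened separately as binary carrier indicators).  Events carried
by at least ``min_freq`` of the cohort are tested by univariable Cox;
significant ones are designated *risk* (HR > 1) or *protective* (HR < 1).
The i(17q) proxy marks samples with simultaneous 17p loss and 17q gain.

``select_by_r2`` performs forward selection of jointly informative events by
the increment in Nagelkerke's R^2 of the multivariable Cox model, and
``successive_stratify`` formalises the exclude-and-rescreen procedure: split
off carriers of the strongest significant event, re-screen the remainder,
and stop when nothing is significant or the remainder is too small; the
terminal stratum is then split by score quantiles.  No multiple-testing
correction is applied across arms or steps by default (an optional
Benjamini–Hochberg flag is available per screening round).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signature import CoreScore, quantile_stratify
from .survival import (
    CoxResult,
    DegenerateCovariateError,
    InsufficientEventsError,
    KMCurve,
    LogRankResult,
    fit_cox,
    km_estimate,
    logrank,
    mann_whitney,
)

I17Q = "i17q"


def validate_arm_calls(calls: pd.DataFrame) -> pd.DataFrame:
    if calls.columns.duplicated().any():
        raise ValueError("duplicate arm labels")
    if not calls.isin([-1, 0, 1]).all(axis=None):
        raise ValueError("arm calls must be -1, 0 or 1")
    return calls


@dataclass
class AberrationEvent:
    arm: str
    direction: str  # "gain" | "loss" | "i17q"
    indicator: pd.Series  # boolean carrier indicator over screened samples
    frequency: float
    cox: CoxResult | None
    p: float
    designation: str | None  # "risk" | "protective" | None if not significant

    @property
    def label(self) -> str:
        return self.arm if self.direction == I17Q else f"{self.arm}_{self.direction}"


def derive_i17q(calls: pd.DataFrame) -> pd.Series:
    """Isochromosome-17q proxy: 17p loss together with 17q gain."""
    for arm in ("17p", "17q"):
        if arm not in calls.columns:
            raise ValueError(f"arm {arm!r} missing from call matrix")
    return (calls["17p"] == -1) & (calls["17q"] == 1)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        i = m - rank_from_last  # 1-based rank
        prev = min(prev, p[idx] * m / i)
        adj[idx] = prev
    return adj


def screen_aberrations(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    min_freq: float = 0.10,
    alpha: float = 0.05,
    include_i17q: bool = False,
    bh_correct: bool = False,
) -> list[AberrationEvent]:
    """Screen every arm x direction event with carrier frequency >= min_freq.

    Fits a univariable Cox model on the binary carrier indicator; events
    with p < alpha get a risk/protective designation by HR direction.
    Returns all tested events (significant or not), sorted by p.
    """
    if not 0 < min_freq < 1:
        raise ValueError("min_freq must be in (0, 1)")
    calls = validate_arm_calls(calls.loc[samples.index])
    times = samples["os_years"].to_numpy(dtype=float)
    ev = samples["os_event"].to_numpy(dtype=int)
    n = len(samples)
    candidates: list[tuple[str, str, pd.Series]] = []
    for arm in calls.columns:
        candidates.append((arm, "gain", calls[arm] == 1))
        candidates.append((arm, "loss", calls[arm] == -1))
    if include_i17q and "17p" in calls.columns and "17q" in calls.columns:
        candidates.append((I17Q, I17Q, derive_i17q(calls)))
    events: list[AberrationEvent] = []
    for arm, direction, ind in candidates:
        freq = float(ind.mean())
        if freq < min_freq or freq == 1.0:
            continue
        try:
            res = fit_cox(times, ev, ind.to_numpy(dtype=float),
                          names=(f"{arm}_{direction}",))
            p = float(res.wald_p[0])
        except (InsufficientEventsError, DegenerateCovariateError):
            res, p = None, np.nan
        events.append(AberrationEvent(arm=arm, direction=direction,
                                      indicator=ind, frequency=freq,
                                      cox=res, p=p, designation=None))
    pvals = np.array([e.p for e in events])
    eff_p = _bh_adjust(np.nan_to_num(pvals, nan=1.0)) if bh_correct else pvals
    for e, pe in zip(events, eff_p):
        if np.isfinite(pe) and pe < alpha and e.cox is not None:
            hr = float(e.cox.hr_per_unit[0])
            e.designation = "risk" if hr > 1 else "protective"
    events.sort(key=lambda e: (np.nan_to_num(e.p, nan=1.0), e.label))
    return events


def select_by_r2(
    candidates: list[AberrationEvent],
    samples: pd.DataFrame,
    delta_r2_min: float = 0.01,
) -> tuple[list[AberrationEvent], pd.DataFrame]:
    """Forward selection of aberration events by Nagelkerke R^2 increment.

    Candidates are considered in ascending univariable-p order; one is kept
    iff adding its indicator raises the multivariable model's R^2 by at
    least ``delta_r2_min``. Indicators identical to an already-selected one
    are dropped as collinear. Returns (selected, trace) where the trace
    records, per candidate, the R^2 before/after and the per-covariate Wald
    p-values of the joint model (exposing "no longer significant" checks).
    """
    if not candidates:
        raise ValueError("no candidate events")
    times = samples["os_years"].to_numpy(dtype=float)
    ev = samples["os_event"].to_numpy(dtype=int)
    order = sorted(candidates, key=lambda e: (np.nan_to_num(e.p, nan=1.0), e.label))
    selected: list[AberrationEvent] = []
    rows = []
    r2_prev = 0.0
    for cand in order:
        x_cand = cand.indicator.loc[samples.index].to_numpy(dtype=float)
        dup = any(
            np.array_equal(x_cand, s.indicator.loc[samples.index].to_numpy(dtype=float))
            for s in selected
        )
        if dup:
            rows.append((cand.label, r2_prev, r2_prev, 0.0, "collinear", ""))
            continue
        X = np.column_stack(
            [s.indicator.loc[samples.index].to_numpy(dtype=float) for s in selected]
            + [x_cand]
        )
        names = [s.label for s in selected] + [cand.label]
        try:
            fit = fit_cox(times, ev, X, names=names, compute_r2=True)
        except (InsufficientEventsError, DegenerateCovariateError):
            rows.append((cand.label, r2_prev, r2_prev, 0.0, "unfittable", ""))
            continue
        r2_new = fit.r2_nagelkerke or 0.0
        delta = r2_new - r2_prev
        joint_p = ";".join(f"{nm}={p:.4g}" for nm, p in zip(names, fit.wald_p))
        if delta >= delta_r2_min:
            selected.append(cand)
            rows.append((cand.label, r2_prev, r2_new, delta, "kept", joint_p))
            r2_prev = r2_new
        else:
            rows.append((cand.label, r2_prev, r2_new, delta, "rejected", joint_p))
    trace = pd.DataFrame(rows, columns=["event", "r2_before", "r2_after",
                                        "delta_r2", "decision", "joint_wald_p"])
    return selected, trace


@dataclass
class StratumNode:
    condition: str
    members: list[str]
    n: int
    n_events: int
    km: KMCurve | None = None
    logrank_vs_rest: LogRankResult | None = None
    mean_score: float = np.nan
    sibling_mean_score: float = np.nan
    mannwhitney_p: float = np.nan
    depth: int = 0

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n": self.n,
            "n_events": self.n_events,
            "depth": self.depth,
            "median_survival": None if self.km is None or not np.isfinite(self.km.median)
            else float(self.km.median),
            "logrank_p": None if self.logrank_vs_rest is None
            else float(self.logrank_vs_rest.p),
            "mean_score": None if not np.isfinite(self.mean_score)
            else float(self.mean_score),
            "sibling_mean_score": None if not np.isfinite(self.sibling_mean_score)
            else float(self.sibling_mean_score),
            "mannwhitney_p": None if not np.isfinite(self.mannwhitney_p)
            else float(self.mannwhitney_p),
            "members": list(self.members),
        }


@dataclass
class StratificationTree:
    nodes: list[StratumNode] = field(default_factory=list)  # carrier splits, in order
    terminal: list[StratumNode] = field(default_factory=list)  # score-quantile leaves
    cohort: list[str] = field(default_factory=list)

    @property
    def split_labels(self) -> list[str]:
        return [n.condition for n in self.nodes]

    def leaves(self) -> list[StratumNode]:
        return self.nodes + self.terminal

    def to_dict(self) -> dict:
        return {
            "cohort_n": len(self.cohort),
            "splits": [n.to_dict() for n in self.nodes],
            "terminal": [n.to_dict() for n in self.terminal],
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [n.to_dict() for n in self.leaves()]
        for r in rows:
            r.pop("members")
        return pd.DataFrame(rows)


def successive_stratify(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    score: CoreScore | None = None,
    min_freq: float = 0.10,
    alpha: float = 0.05,
    min_node: int = 20,
    include_i17q: bool = False,
    bh_correct: bool = False,
) -> StratificationTree:
    """Exclude-and-rescreen stratification by arm-level aberrations.

    At each step the strongest significant aberration (smallest p) defines a
    carrier stratum that is split off; screening is repeated on the
    remainder until no event is significant or fewer than ``min_node``
    samples remain. The terminal remainder is split by score quantiles when
    a score is supplied. Every split is annotated with the carriers-vs-rest
    log-rank test and a Mann–Whitney comparison of mean core scores.
    """
    tree = StratificationTree(cohort=list(samples.index))
    remaining = samples.copy()
    depth = 0
    while len(remaining) >= min_node:
        events = screen_aberrations(calls, remaining, min_freq=min_freq,
                                    alpha=alpha, include_i17q=include_i17q,
                                    bh_correct=bh_correct)
        sig = [e for e in events if e.designation is not None]
        if not sig:
            break
        best = sig[0]  # events are p-sorted
        carriers = remaining.index[best.indicator.loc[remaining.index]]
        rest = remaining.index[~best.indicator.loc[remaining.index]]
        if len(carriers) == 0 or len(rest) == 0:
            break
        node = _annotate_node(
            condition=f"{best.label}:{best.designation}",
            member_ids=list(carriers), sibling_ids=list(rest),
            samples=remaining, score=score, depth=depth,
        )
        tree.nodes.append(node)
        remaining = remaining.loc[rest]
        depth += 1
    # terminal stratum: quantile split on the core score (single node if no
    # score or too few samples)
    if score is not None and len(remaining) >= 4:
        labels, degenerate = quantile_stratify(score.subset(remaining.index))
        groups = ["low", "mid", "high"] if not degenerate else ["mid"]
        for g in groups:
            ids = list(labels.index[labels == g])
            if not ids:
                continue
            sib = list(labels.index[labels != g])
            tree.terminal.append(
                _annotate_node(condition=f"score:{g}", member_ids=ids,
                               sibling_ids=sib, samples=remaining,
                               score=score, depth=depth)
            )
    elif len(remaining) > 0:
        tree.terminal.append(
            _annotate_node(condition="remainder", member_ids=list(remaining.index),
                           sibling_ids=[], samples=remaining, score=score,
                           depth=depth)
        )
    return tree


def _annotate_node(condition, member_ids, sibling_ids, samples, score, depth) -> StratumNode:
    sub = samples.loc[member_ids]
    node = StratumNode(
        condition=condition,
        members=list(member_ids),
        n=len(member_ids),
        n_events=int(sub["os_event"].sum()),
        depth=depth,
    )
    node.km = km_estimate(sub["os_years"], sub["os_event"])
    if sibling_ids:
        both = samples.loc[list(member_ids) + list(sibling_ids)]
        labels = np.array(["in"] * len(member_ids) + ["out"] * len(sibling_ids))
        try:
            node.logrank_vs_rest = logrank(both["os_years"], both["os_event"], labels)
        except ValueError:
            node.logrank_vs_rest = None
    if score is not None:
        s_in = score.subset(member_ids)
        node.mean_score = float(s_in.mean())
        if sibling_ids:
            s_out = score.subset(sibling_ids)
            node.sibling_mean_score = float(s_out.mean())
            try:
                _, node.mannwhitney_p = mann_whitney(s_in.to_numpy(), s_out.to_numpy())
            except ValueError:
                pass
    return node
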