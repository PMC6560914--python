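"""Expression and clinical preprocessing.

Covers the steps between a processed log2 expression matrix and the survival
screens: many-to-one probe collapse by inter-quartile range, min–max
rescaling to [0, 1] relative expression across the full cohort, expression
and variability gene filters, the dead/alive/censored status at two years,
age/overall-survival sample filtering, and the stratified 70/30
exploratory/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATUS_DEAD = "dead"
STATUS_ALIVE = "alive"
STATUS_CENSORED = "censored"
SPLIT_EXPLORATORY = "exploratory"
SPLIT_VALIDATION = "validation"


@dataclass
class ExpressionMatrix:
    """Expression values, rows = features (probes or genes), cols = samples.

    ``scale`` is ``"log2"`` or ``"relative"``.  A relative matrix keeps the
    per-gene min/max used for rescaling so that sample subsets inherit the
    full-cohort scaling instead of being re-min-maxed.
    """

    values: pd.DataFrame
    scale: str = "log2"
    gene_min: pd.Series | None = None
    gene_max: pd.Series | None = None
    zero_range_genes: list[str] = field(default_factory=list)
    probe_provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in ("log2", "relative"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Column subset; relative values are NOT rescaled (contract)."""
        return ExpressionMatrix(
            values=self.values.loc[:, list(sample_ids)],
            scale=self.scale,
            gene_min=self.gene_min,
            gene_max=self.gene_max,
            zero_range_genes=list(self.zero_range_genes),
            probe_provenance=dict(self.probe_provenance),
        )

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(feature_ids)],
            scale=self.scale,
            gene_min=None if self.gene_min is None else self.gene_min.loc[list(feature_ids)],
            gene_max=None if self.gene_max is None else self.gene_max.loc[list(feature_ids)],
            zero_range_genes=list(self.zero_range_genes),
            probe_provenance=dict(self.probe_provenance),
        )


class UnmappedProbeError(ValueError):
    def __init__(self, probes):
        self.probes = list(probes)
        super().__init__(f"probes missing from probe map: {self.probes[:10]}"
                         + ("..." if len(self.probes) > 10 else ""))


def collapse_probes(matrix: ExpressionMatrix, probe_map: pd.Series) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene by maximal IQR.

    ``probe_map`` maps probe id -> gene symbol (many-to-one).  The IQR is
    Q3 - Q1 with linear-interpolation quantiles; exact IQR ties are broken
    by the lexicographically smallest probe id.  The winning probe id per
    gene is recorded in ``probe_provenance``.
    """
    if matrix.scale != "log2":
        raise ValueError("probe collapse expects a log2-scale matrix")
    probe_map = pd.Series(probe_map)
    missing = [p for p in matrix.values.index if p not in probe_map.index]
    if missing:
        raise UnmappedProbeError(missing)
    vals = matrix.values
    q1, q3 = np.percentile(vals.to_numpy(), [25, 75], axis=1)
    iqr = pd.Series(q3 - q1, index=vals.index)
    choice = (
        pd.DataFrame({"probe": vals.index, "gene": probe_map.loc[vals.index].to_numpy(),
                      "iqr": iqr.to_numpy()})
        .sort_values(["gene", "iqr", "probe"], ascending=[True, False, True],
                     kind="stable")
        .drop_duplicates("gene", keep="first")
    )
    out = vals.loc[choice["probe"]]
    out.index = choice["gene"].to_numpy()
    provenance = dict(zip(choice["gene"], choice["probe"]))
    return ExpressionMatrix(values=out.sort_index(), scale="log2",
                            probe_provenance=provenance)


def rescale_relative(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene min–max rescaling to [0, 1] across all samples present.

    Zero-range genes are excluded from the relative view and reported via
    ``zero_range_genes``. The min/max are stored so later sample subsets
    reuse this cohort's scaling.
    """
    if matrix.scale != "log2":
        raise ValueError("expected a log2-scale matrix")
    vals = matrix.values
    gmin = vals.min(axis=1)
    gmax = vals.max(axis=1)
    rng = gmax - gmin
    zero = rng == 0
    keep = vals.index[~zero]
    rel = vals.loc[keep].sub(gmin.loc[keep], axis=0).div(rng.loc[keep], axis=0)
    return ExpressionMatrix(
        values=rel,
        scale="relative",
        gene_min=gmin.loc[keep],
        gene_max=gmax.loc[keep],
        zero_range_genes=list(vals.index[zero]),
        probe_provenance=dict(matrix.probe_provenance),
    )


def filter_genes(
    matrix: ExpressionMatrix,
    sample_ids=None,
    min_max_expr: float = 7.0,
    min_range: float = 1.5,
) -> list[str]:
    """Genes with high expression and large variation over the given samples.

    Keeps genes with log2 maximum >= ``min_max_expr`` AND range (max - min)
    >= ``min_range``; both boundaries inclusive.
    """
    if matrix.scale != "log2":
        raise ValueError("gene filters operate on the log2 scale")
    vals = matrix.values if sample_ids is None else matrix.values.loc[:, list(sample_ids)]
    if vals.shape[1] == 0:
        raise ValueError("empty sample subset")
    gmax = vals.max(axis=1)
    rng = gmax - vals.min(axis=1)
    keep = (gmax >= min_max_expr) & (rng >= min_range)
    return list(vals.index[keep])


def two_year_status(os_years, os_event) -> np.ndarray:
    """Survival status at two years: dead, alive, or censored.

    Death at exactly 2 years counts as dead; any follow-up reaching 2 years
    (event or not) counts as alive-at-2y; censoring strictly before 2 years
    is censored.
    """
    os_years = np.asarray(os_years, dtype=float)
    os_event = np.asarray(os_event, dtype=int)
    if np.any(os_years < 0) or np.any(np.isnan(os_years)):
        raise ValueError("survival times must be non-negative and present")
    out = np.where(
        (os_event == 1) & (os_years <= 2.0), STATUS_DEAD,
        np.where(os_years >= 2.0, STATUS_ALIVE, STATUS_CENSORED),
    )
    return out.astype(object)


def filter_samples(samples: pd.DataFrame, max_age: float | None = 18.0,
                   require_os: bool = True) -> pd.DataFrame:
    """Keep patients below ``max_age`` (strict) with overall-survival data."""
    out = samples
    if require_os:
        out = out[out["os_years"].notna() & out["os_event"].notna()]
    if max_age is not None:
        if "age_years" not in out.columns:
            raise ValueError("age filtering requested but no age_years column")
        out = out[out["age_years"].notna() & (out["age_years"] < max_age)]
    return out.copy()


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(samples: pd.DataFrame, fraction: float = 0.7,
                     seed: int = 0) -> pd.DataFrame:
    """Assign exploratory/validation split stratified by subgroup and
    two-year status.

    Within each (subgroup x two_year_status) stratum, round(fraction * size)
    samples (half-up) go to exploratory, drawn by a seeded RNG; a stratum of
    size 1 goes to exploratory. Adds/overwrites a ``split`` column; also
    derives ``two_year_status`` if absent.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    out = samples.copy()
    if "two_year_status" not in out.columns:
        out["two_year_status"] = two_year_status(out["os_years"], out["os_event"])
    rng = np.random.default_rng(seed)
    out["split"] = SPLIT_VALIDATION
    for (_, _), idx in sorted(
        out.groupby(["subgroup", "two_year_status"], sort=True).groups.items(),
        key=lambda kv: (str(kv[0][0]), str(kv[0][1])),
    ):
        ids = sorted(idx)
        k = len(ids)
        n_exp = 1 if k == 1 else _round_half_up(fraction * k)
        chosen = rng.permutation(k)[:n_exp]
        out.loc[np.asarray(ids, dtype=object)[chosen], "split"] = SPLIT_EXPLORATORY
    return out
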