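"""Pre-ranked gene-set enrichment on Cox log-hazard-ratio rankings.

Genes are ordered by descending log hazard ratio (``beta`` from a univariable
Cox screen), so the top of the list is the poor-prognosis end.  The
enrichment score is the classic weighted Kolmogorov–Smirnov-like running-sum
statistic with weight exponent 1: set members ("hits") increment the sum by
``|r_i| / sum_hits |r_j|`` and non-members decrement it by ``1/(N - N_hits)``;
the ES is the running-sum value of maximal absolute deviation from zero.
Significance uses gene-tag permutation: null scores from random same-size
gene draws, with a one-sided add-one-smoothed p-value within the sign class
of the observed ES.  Leading-edge ("core") genes are the set members at or
before the peak (positive ES) or at or after it (negative ES).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_KNOWN_DATABASES = ("PID", "KEGG", "BIOCARTA")


class GMTParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    @property
    def database(self) -> str:
        prefix = self.name.split("_", 1)[0].upper()
        return prefix if prefix in _KNOWN_DATABASES else "other"


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        d: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in d:
                raise ValueError(f"duplicate gene set name {s.name!r}")
            d[s.name] = s
        return cls(sets=d)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def sizes(self) -> dict[str, int]:
        return {s.name: len(s.genes) for s in self}


def read_gmt(path) -> GeneSetCollection:
    """Parse an MSigDB GMT file (name TAB description TAB members...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise GMTParseError(f"{path}: line {lineno}: set {name!r} empty")
            sets.append(GeneSet(name=name, description=desc, genes=tuple(genes)))
    return GeneSetCollection.from_sets(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


@dataclass
class RankedGeneList:
    """Genes in descending rank-metric order (metric = Cox beta = ln HR)."""

    genes: np.ndarray  # object array of gene ids
    metric: np.ndarray  # aligned metric values, descending

    def __post_init__(self):
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric must align")
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        if len(self.index) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_loghr(betas: Mapping[str, float] | pd.Series) -> RankedGeneList:
    """Order genes by descending Cox log-HR; exact ties by ascending gene id."""
    if isinstance(betas, pd.Series):
        if betas.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        items = list(betas.items())
    else:
        items = list(betas.items())
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    genes = np.array([k for k, _ in items], dtype=object)
    metric = np.array([v for _, v in items], dtype=float)
    return RankedGeneList(genes=genes, metric=metric)


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray
    peak_index: int
    hit_positions: np.ndarray


def enrichment_score(
    ranked: RankedGeneList, members: Iterable[str], exponent: float = 1.0
) -> ESResult:
    """Weighted running-sum enrichment score of ``members`` in ``ranked``.

    ``exponent=0`` gives the unweighted statistic (equal hit increments),
    in which case the running sum returns exactly to 0 at the end.
    """
    positions = sorted(ranked.index[g] for g in members if g in ranked.index)
    if not positions:
        raise ValueError("gene set has no member in the ranked universe")
    n = len(ranked)
    hit = np.zeros(n, dtype=bool)
    hit[positions] = True
    nh = hit.sum()
    w = np.abs(ranked.metric[hit]) ** exponent
    total = w.sum()
    if total == 0:  # all-zero hit metrics: fall back to equal weights
        w = np.full(nh, 1.0)
        total = float(nh)
    incr = np.zeros(n)
    incr[hit] = w / total
    if n > nh:
        incr[~hit] = -1.0 / (n - nh)
    rs = np.cumsum(incr)
    imax = int(np.argmax(rs))
    imin = int(np.argmin(rs))
    # maximal absolute deviation; exact tie resolved toward the positive peak
    if rs[imax] >= -rs[imin]:
        es, peak = float(rs[imax]), imax
    else:
        es, peak = float(rs[imin]), imin
    return ESResult(es=es, running_sum=rs, peak_index=peak,
                    hit_positions=np.asarray(positions))


def leading_edge(ranked: RankedGeneList, es_result: ESResult) -> list[str]:
    """Core genes: members at ranks <= peak (ES > 0) or >= peak (ES < 0)."""
    pos = es_result.hit_positions
    if es_result.es >= 0:
        keep = pos[pos <= es_result.peak_index]
    else:
        keep = pos[pos >= es_result.peak_index]
    return [str(ranked.genes[i]) for i in keep]


def _null_es(metric_abs: np.ndarray, k: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Null enrichment scores for random k-gene draws from the universe.

    Uses the fact that the running-sum maximum is attained at a hit and the
    minimum just before a hit (or 0 at the end), so only hit positions are
    needed — O(k log k) per permutation instead of O(N).
    """
    n = len(metric_abs)
    pos = np.empty((n_perm, k), dtype=np.int64)
    for i in range(n_perm):
        pos[i] = rng.choice(n, size=k, replace=False)
    pos.sort(axis=1)
    w = metric_abs[pos]
    totals = w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1)
    zero = (totals[:, 0] == 0)
    if zero.any():  # equal-weight fallback per permutation
        cw[zero] = np.arange(1, k + 1, dtype=float)
        totals[zero] = float(k)
    cw = cw / totals
    j = np.arange(k)
    if n == k:
        return cw[:, -1]  # no misses: ES = 1
    miss_den = n - k
    at_hit = cw - (pos - j) / miss_den  # after the j-th hit
    # misses processed before hit j (0-based) = pos_j - j
    before_hit = np.concatenate([np.zeros((n_perm, 1)), cw[:, :-1]], axis=1) \
        - (pos - j) / miss_den
    max_dev = at_hit.max(axis=1)
    min_dev = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def permutation_p(
    ranked: RankedGeneList,
    members: Iterable[str],
    n_perm: int,
    rng: np.random.Generator | int,
    exponent: float = 1.0,
) -> tuple[float, str, ESResult]:
    """Gene-tag permutation p-value for a set's enrichment score.

    One-sided within the observed ES's sign class with add-one smoothing:
    ``p = (1 + #{null of same sign with |null| >= |obs|}) / (1 + #{null of
    same sign})``.  Returns (nominal p, direction, observed ESResult).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    obs = enrichment_score(ranked, members, exponent=exponent)
    k = len(obs.hit_positions)
    null = _null_es(np.abs(ranked.metric) ** exponent if exponent != 1.0
                    else np.abs(ranked.metric), k, n_perm, rng)
    if obs.es >= 0:
        same = null[null >= 0]
        extreme = int((same >= obs.es).sum())
        direction = "positive"
    else:
        same = null[null < 0]
        extreme = int((same <= obs.es).sum())
        direction = "negative"
    p = (1 + extreme) / (1 + len(same))
    return float(min(p, 1.0)), direction, obs


@dataclass
class EnrichmentResult:
    set_name: str
    database: str
    size: int  # effective (universe-intersected) size
    es: float
    direction: str
    nominal_p: float
    leading_edge: list[str]
    peak_index: int


def filter_gene_sets(
    collection: GeneSetCollection,
    universe: Sequence[str],
    max_size: int = 50,
    min_size: int = 5,
    databases: Sequence[str] | None = None,
) -> tuple[GeneSetCollection, list[str]]:
    """Restrict a collection to sets usable against a gene universe.

    Members are intersected with ``universe``; sets outside
    ``[min_size, max_size]`` (inclusive) after intersection, or from a
    database not in ``databases`` (when given), are dropped. Returns the
    filtered collection (intersected membership, original order preserved)
    and the names of dropped sets.
    """
    uni = set(universe)
    allowed = {d.upper() for d in databases} if databases else None
    kept, dropped = [], []
    for s in collection:
        if allowed is not None and s.database.upper() not in allowed:
            dropped.append(s.name)
            continue
        inter = tuple(g for g in s.genes if g in uni)
        if not (min_size <= len(inter) <= max_size):
            dropped.append(s.name)
            continue
        kept.append(GeneSet(name=s.name, description=s.description, genes=inter))
    return GeneSetCollection.from_sets(kept), dropped


def run_gsea(
    ranked: RankedGeneList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Score every set in ``collection`` against ``ranked``.

    Sets are processed in sorted-name order with one child RNG stream each,
    so results are reproducible and independent of collection ordering.
    """
    root = (np.random.default_rng(seed) if isinstance(seed, (int, np.integer))
            else seed)
    results = []
    for name in sorted(collection.sets):
        s = collection[name]
        members = [g for g in s.genes if g in ranked.index]
        if not members:
            continue
        p, direction, obs = permutation_p(
            ranked, members, n_perm=n_perm, rng=np.random.default_rng(root.integers(2**31)),
            exponent=exponent,
        )
        results.append(
            EnrichmentResult(
                set_name=s.name,
                database=s.database,
                size=len(members),
                es=obs.es,
                direction=direction,
                nominal_p=p,
                leading_edge=leading_edge(ranked, obs),
                peak_index=obs.peak_index,
            )
        )
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "db": [r.database for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "direction": [r.direction for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
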