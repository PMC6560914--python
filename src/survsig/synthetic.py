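"""Synthetic multi-subgroup cohorts with known prognostic structure.

The generator emulates the statistical structure the downstream analysis
assumes: a proportional-hazards survival model in which the log hazard is a
linear function of the average relative expression of one or more planted
gene sets, and arm-level copy-number aberrations that act in *cis* on the
log2 expression of the genes assigned to the arm (gain: +delta, loss:
-delta).  Because arm aberrations shift planted-set expression, they acquire
an indirect survival effect, which is what the arm-level screening stage is
meant to recover.

Members of a planted set additionally share a per-sample latent activity
term (``set_latent_sd`` log2 units), giving the within-set co-expression
that real pathways show; without it the mean of k independent genes has
vanishing variance and no realistic planted effect size is detectable.

Event times are Weibull with the per-sample hazard multiplier applied to
the cumulative hazard; censoring is an independent uniform draw capped at an
administrative follow-up horizon.  One designated probe per gene carries the
signal; extra probes are pure noise with a smaller IQR, making the
IQR-based probe collapse verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gsea import GeneSet, GeneSetCollection
from .preprocess import ExpressionMatrix


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSet:
    """A gene set with a planted proportional-hazards effect.

    ``beta`` is the log-hazard-ratio per unit of the set's average relative
    expression; a mapping gives subgroup-specific coefficients (absent
    subgroups get 0).
    """

    name: str
    genes: tuple[str, ...]
    beta: float | Mapping[str, float]

    def beta_for(self, subgroup: str) -> float:
        if isinstance(self.beta, Mapping):
            return float(self.beta.get(subgroup, 0.0))
        return float(self.beta)


@dataclass(frozen=True)
class ArmDef:
    """Chromosome arm: member genes, aberration frequencies, cis effect.

    ``cooccur_arm``/``cooccur_freqs`` model co-occurring aberrations (as
    isochromosome 17q couples 17p loss to 17q gain): among carriers of any
    aberration of ``cooccur_arm``, this arm's (gain, loss) frequencies are
    replaced by ``cooccur_freqs``. The referenced arm must itself be
    uncoupled.
    """

    genes: tuple[str, ...]
    gain_freq: float = 0.0
    loss_freq: float = 0.0
    cis_effect_delta: float = 0.0
    cooccur_arm: str | None = None
    cooccur_freqs: tuple[float, float] = (0.0, 0.0)


@dataclass
class SimulationConfig:
    n_samples_per_subgroup: dict[str, int]
    n_genes: int = 2000
    n_probes_per_gene: int = 1
    planted_sets: list[PlantedSet] = field(default_factory=list)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    set_latent_sd: float = 1.3
    arm_defs: dict[str, ArmDef] = field(default_factory=dict)
    subgroup_hazard_multiplier: dict[str, float] = field(default_factory=dict)
    weibull_shape: float = 1.2
    weibull_scale: float = 20.0
    censor_uniform_max: float = 20.0
    followup_cap: float = 15.0
    n_decoy_sets: int = 0
    decoy_set_size: int = 20
    seed: int = 0

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> None:
        if not self.n_samples_per_subgroup:
            raise SimulationConfigError("n_samples_per_subgroup: empty")
        for sg, n in self.n_samples_per_subgroup.items():
            if n <= 0:
                raise SimulationConfigError(
                    f"n_samples_per_subgroup[{sg!r}]: must be positive")
        for name, val in [("n_genes", self.n_genes),
                          ("n_probes_per_gene", self.n_probes_per_gene),
                          ("baseline_log2_sd", self.baseline_log2_sd),
                          ("weibull_shape", self.weibull_shape),
                          ("weibull_scale", self.weibull_scale),
                          ("censor_uniform_max", self.censor_uniform_max),
                          ("followup_cap", self.followup_cap)]:
            if val <= 0:
                raise SimulationConfigError(f"{name}: must be positive")
        known = set(self.gene_ids())
        for ps in self.planted_sets:
            unknown = [g for g in ps.genes if g not in known]
            if unknown:
                raise SimulationConfigError(
                    f"planted_sets[{ps.name!r}]: unknown gene ids {unknown[:5]}")
        for arm, d in self.arm_defs.items():
            if not (0 <= d.gain_freq <= 1 and 0 <= d.loss_freq <= 1):
                raise SimulationConfigError(f"arm_defs[{arm!r}]: frequencies in [0,1]")
            if d.gain_freq + d.loss_freq > 1:
                raise SimulationConfigError(
                    f"arm_defs[{arm!r}]: gain_freq + loss_freq > 1")
            if d.cooccur_arm is not None:
                if d.cooccur_arm not in self.arm_defs:
                    raise SimulationConfigError(
                        f"arm_defs[{arm!r}]: unknown cooccur_arm {d.cooccur_arm!r}")
                if self.arm_defs[d.cooccur_arm].cooccur_arm is not None:
                    raise SimulationConfigError(
                        f"arm_defs[{arm!r}]: cooccur_arm must be uncoupled")
                cg, cl = d.cooccur_freqs
                if not (0 <= cg <= 1 and 0 <= cl <= 1 and cg + cl <= 1):
                    raise SimulationConfigError(
                        f"arm_defs[{arm!r}]: invalid cooccur_freqs")
            unknown = [g for g in d.genes if g not in known]
            if unknown:
                raise SimulationConfigError(
                    f"arm_defs[{arm!r}]: unknown gene ids {unknown[:5]}")


@dataclass
class CohortBundle:
    expression: ExpressionMatrix  # probe-level, log2
    samples: pd.DataFrame
    arm_calls: pd.DataFrame
    gene_sets: GeneSetCollection
    probe_map: pd.Series
    ground_truth: dict


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Draw one cohort from the generative model described in the module doc.

    Identical config + seed gives a bit-identical bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    gene_idx = {g: i for i, g in enumerate(genes)}
    subgroups = sorted(config.n_samples_per_subgroup)
    sample_ids, sample_sg = [], []
    for sg in subgroups:
        n = config.n_samples_per_subgroup[sg]
        sample_ids += [f"{sg}_s{i:04d}" for i in range(1, n + 1)]
        sample_sg += [sg] * n
    n_samples = len(sample_ids)
    n_genes = config.n_genes

    # arm calls: iid per sample per arm; coupled arms drawn after their
    # reference arm with conditional frequencies among its carriers
    arms = sorted(config.arm_defs)
    calls = pd.DataFrame(0, index=sample_ids, columns=arms, dtype=int)
    draw_order = ([a for a in arms if config.arm_defs[a].cooccur_arm is None]
                  + [a for a in arms if config.arm_defs[a].cooccur_arm is not None])
    for arm in draw_order:
        d = config.arm_defs[arm]
        u = rng.random(n_samples)
        gain = np.full(n_samples, d.gain_freq)
        loss = np.full(n_samples, d.loss_freq)
        if d.cooccur_arm is not None:
            ref = calls[d.cooccur_arm].to_numpy() != 0
            gain[ref], loss[ref] = d.cooccur_freqs
        calls[arm] = np.where(u < gain, 1, np.where(u < gain + loss, -1, 0))

    # gene-level signal expression
    expr = np.full((n_genes, n_samples), config.baseline_log2_mean)
    for arm in arms:
        d = config.arm_defs[arm]
        if d.cis_effect_delta == 0 or not d.genes:
            continue
        rows = [gene_idx[g] for g in d.genes]
        expr[np.ix_(rows, range(n_samples))] += (
            d.cis_effect_delta * calls[arm].to_numpy()[None, :]
        )
    if config.set_latent_sd > 0:
        for ps in config.planted_sets:
            latent = rng.normal(0.0, config.set_latent_sd, size=n_samples)
            rows = [gene_idx[g] for g in ps.genes]
            expr[rows, :] += latent[None, :]
    expr += rng.normal(0.0, config.baseline_log2_sd, size=expr.shape)

    # relative expression of the signal matrix -> true planted-set scores
    gmin = expr.min(axis=1, keepdims=True)
    gmax = expr.max(axis=1, keepdims=True)
    rel = (expr - gmin) / np.where(gmax - gmin == 0, 1.0, gmax - gmin)
    sg_arr = np.asarray(sample_sg, dtype=object)
    log_mult = np.zeros(n_samples)
    true_scores = {}
    for ps in config.planted_sets:
        rows = [gene_idx[g] for g in ps.genes]
        score = rel[rows, :].mean(axis=0)
        true_scores[ps.name] = score
        betas = np.array([ps.beta_for(sg) for sg in sg_arr])
        # centering is a baseline-hazard reparameterization: it leaves every
        # Cox estimate untouched but keeps the event rate at its null level
        log_mult += betas * (score - 0.5)

    # per-subgroup baseline hazard multiplier (e.g. an excellent-prognosis
    # subgroup); multiplies the PH hazard like any other log-linear term
    for sg, m in config.subgroup_hazard_multiplier.items():
        if m <= 0:
            raise SimulationConfigError(
                f"subgroup_hazard_multiplier[{sg!r}]: must be positive")
        log_mult[sg_arr == sg] += np.log(m)

    # Weibull PH event times: T = scale * (E / mult)^(1/shape), E ~ Exp(1)
    mult = np.exp(log_mult)
    e = rng.exponential(1.0, size=n_samples)
    t_event = config.weibull_scale * (e / mult) ** (1.0 / config.weibull_shape)
    t_cens = np.minimum(rng.uniform(0, config.censor_uniform_max, size=n_samples),
                        config.followup_cap)
    os_years = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "os_years": os_years,
            "os_event": os_event,
            "subgroup": sample_sg,
            "age_years": rng.uniform(0.5, 17.5, size=n_samples).round(2),
            "histology": rng.choice(["classic", "desmoplastic", "LCA"],
                                    size=n_samples, p=[0.7, 0.2, 0.1]),
            "metastasis": rng.integers(0, 2, size=n_samples),
        }
    ).set_index("sample_id")

    # probe-level matrix: probe 1 carries the signal, the rest are noise
    # with a smaller spread so the IQR collapse picks the signal probe
    probe_rows, probe_ids, probe_genes = [], [], []
    for gi, g in enumerate(genes):
        probe_ids.append(f"{g}_p1")
        probe_genes.append(g)
        probe_rows.append(expr[gi])
    for extra in range(2, config.n_probes_per_gene + 1):
        noise = rng.normal(config.baseline_log2_mean,
                           0.3 * config.baseline_log2_sd,
                           size=(n_genes, n_samples))
        for gi, g in enumerate(genes):
            probe_ids.append(f"{g}_p{extra}")
            probe_genes.append(g)
            probe_rows.append(noise[gi])
    expression = ExpressionMatrix(
        values=pd.DataFrame(np.vstack(probe_rows), index=probe_ids,
                            columns=sample_ids).sort_index(),
        scale="log2",
    )
    probe_map = pd.Series(probe_genes, index=probe_ids).sort_index()

    sets = [GeneSet(name=ps.name, description="planted", genes=ps.genes)
            for ps in config.planted_sets]
    taken = {s.name for s in sets}
    for i in range(config.n_decoy_sets):
        name = f"DECOY_SET_{i + 1:03d}"
        if name in taken:
            continue
        members = tuple(sorted(rng.choice(genes, size=config.decoy_set_size,
                                          replace=False)))
        sets.append(GeneSet(name=name, description="decoy", genes=members))
    gene_sets = GeneSetCollection.from_sets(sets)

    ground_truth = {
        "seed": config.seed,
        "planted_sets": [
            {"name": ps.name, "genes": list(ps.genes),
             "beta": (dict(ps.beta) if isinstance(ps.beta, Mapping)
                      else ps.beta)}
            for ps in config.planted_sets
        ],
        "arm_effects": {
            arm: {"genes": list(d.genes), "gain_freq": d.gain_freq,
                  "loss_freq": d.loss_freq,
                  "cis_effect_delta": d.cis_effect_delta}
            for arm, d in config.arm_defs.items()
        },
        "true_scores": {k: v.tolist() for k, v in true_scores.items()},
        "signal_probes": {g: f"{g}_p1" for g in genes},
        "sample_ids": sample_ids,
    }
    return CohortBundle(expression=expression, samples=samples,
                        arm_calls=calls, gene_sets=gene_sets,
                        probe_map=probe_map, ground_truth=ground_truth)


def null_cohort_config(seed: int, n: int = 300, n_genes: int = 2000,
                       subgroup: str = "SHH") -> SimulationConfig:
    """Null study condition: no planted effects, no arm aberrations."""
    return SimulationConfig(n_samples_per_subgroup={subgroup: n},
                            n_genes=n_genes, seed=seed)


def planted_pathway_config(seed: int, n: int = 300, n_genes: int = 1000,
                           set_size: int = 20, hr_per_01: float = 1.5,
                           subgroup: str = "SHH") -> SimulationConfig:
    """One planted prognostic pathway at a given per-0.1 hazard ratio.

    The planted coefficient is ``10 * ln(hr_per_01)`` per unit of the set's
    average relative expression, so a fitted core-score Cox model should
    recover ``hr_per_0.1 = hr_per_01``.
    """
    cfg = SimulationConfig(n_samples_per_subgroup={subgroup: n},
                           n_genes=n_genes, seed=seed)
    genes = cfg.gene_ids()
    cfg.planted_sets = [PlantedSet("PID_PLANTED_PATHWAY",
                                   tuple(genes[:set_size]),
                                   10.0 * np.log(hr_per_01))]
    return cfg


def nested_arm_config(seed: int, n: int = 500, n_genes: int = 1000,
                      subgroup: str = "G3") -> SimulationConfig:
    """Two-level nested arm-aberration structure over two planted pathways.

    Arm ``8q`` loss (~30% of samples) lowers the first planted pathway's
    expression in cis and is protective.  Arm ``9p`` gain raises the second
    planted pathway and is the nested risk marker: it preferentially
    co-occurs with 8q loss (as i(17q)-style coupled aberrations do), so its
    marginal survival effect is masked by the protective carriers and only
    emerges after they are excluded — the structure the successive
    exclude-and-rescreen procedure is built to recover.  Two neutral arms
    with common aberrations but no cis effect give the screen true
    negatives.
    """
    cfg = planted_pathway_config(seed, n=n, n_genes=n_genes, subgroup=subgroup)
    genes = cfg.gene_ids()
    set1 = cfg.planted_sets[0].genes
    set2 = tuple(genes[40:60])
    cfg.planted_sets = [
        PlantedSet(cfg.planted_sets[0].name, set1, cfg.planted_sets[0].beta),
        PlantedSet("KEGG_NESTED_RISK", set2, 10.0 * np.log(1.8)),
    ]
    # the protective aberration is planted deliberately strong so that the
    # intended discovery order is identified; the nested risk marker's
    # marginal effect is masked by its co-occurrence with the protective arm
    cfg.arm_defs = {
        "8q": ArmDef(genes=set1, loss_freq=0.30, cis_effect_delta=5.0),
        "9p": ArmDef(genes=set2, gain_freq=0.14, cis_effect_delta=1.8,
                     cooccur_arm="8q", cooccur_freqs=(0.28, 0.0)),
        "5p": ArmDef(genes=tuple(genes[-20:]), gain_freq=0.15, loss_freq=0.10),
        "10q": ArmDef(genes=tuple(genes[-40:-20]), loss_freq=0.15),
    }
    return cfg


def demo_multisubgroup_config(seed: int, scale: float = 1.0) -> SimulationConfig:
    """A four-subgroup cohort shaped like a pediatric medulloblastoma study.

    Subgroup sizes mirror a 530-sample cohort (WNT 49, SHH 121, G3 107,
    G4 253, scalable); each non-WNT subgroup carries its own planted
    prognostic pathway, WNT carries none (and its low event count triggers
    the skip rule downstream). One shared arm with a cis effect on the G3
    pathway gives the copy-number stage something to find.
    """
    sizes = {"WNT": 49, "SHH": 121, "G3": 107, "G4": 253}
    cfg = SimulationConfig(
        n_samples_per_subgroup={k: max(10, int(round(v * scale)))
                                for k, v in sizes.items()},
        n_genes=1500, n_probes_per_gene=2, n_decoy_sets=25, seed=seed,
    )
    genes = cfg.gene_ids()
    beta = 10.0 * np.log(1.5)
    cfg.planted_sets = [
        PlantedSet("PID_SHH_PATHWAY", tuple(genes[0:20]), {"SHH": beta}),
        PlantedSet("KEGG_G3_PATHWAY", tuple(genes[20:40]), {"G3": beta}),
        PlantedSet("BIOCARTA_G4_PATHWAY", tuple(genes[40:60]), {"G4": beta}),
    ]
    cfg.subgroup_hazard_multiplier = {"WNT": 0.12}  # excellent prognosis
    cfg.arm_defs = {
        "17p": ArmDef(genes=tuple(genes[20:40]), loss_freq=0.25,
                      cis_effect_delta=3.5),
        "17q": ArmDef(genes=tuple(genes[200:220]), gain_freq=0.30),
        "7p": ArmDef(genes=tuple(genes[220:240]), gain_freq=0.15, loss_freq=0.10),
    }
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(bundle: CohortBundle, directory) -> dict:
    """Write a cohort bundle as plain-text files; return a manifest.

    Files: expression.tsv, samples.tsv, arm_calls.tsv, probe_map.tsv,
    gene_sets.gmt, ground_truth.json, manifest.json.  Reals are written with
    6 decimals, which the round-trip tests treat as the stated precision.
    """
    from . import io as sio
    from .gsea import write_gmt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sio.write_expression_tsv(bundle.expression, directory / "expression.tsv")
    sio.write_sample_tsv(bundle.samples, directory / "samples.tsv")
    sio.write_arm_calls_tsv(bundle.arm_calls, directory / "arm_calls.tsv")
    sio.write_probe_map_tsv(bundle.probe_map, directory / "probe_map.tsv")
    write_gmt(bundle.gene_sets, directory / "gene_sets.gmt")
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1)
    files = ["expression.tsv", "samples.tsv", "arm_calls.tsv",
             "probe_map.tsv", "gene_sets.gmt", "ground_truth.json"]
    manifest = {
        "seed": bundle.ground_truth["seed"],
        "files": {f: _sha256(directory / f) for f in files},
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_fixture_bundle(directory) -> CohortBundle:
    """Read back a bundle written by :func:`write_fixture_bundle`."""
    from . import io as sio
    from .gsea import read_gmt

    directory = Path(directory)
    with open(directory / "ground_truth.json") as fh:
        ground_truth = json.load(fh)
    return CohortBundle(
        expression=sio.read_expression_tsv(directory / "expression.tsv"),
        samples=sio.read_sample_tsv(directory / "samples.tsv"),
        arm_calls=sio.read_arm_calls_tsv(directory / "arm_calls.tsv"),
        gene_sets=read_gmt(directory / "gene_sets.gmt"),
        probe_map=sio.read_probe_map_tsv(directory / "probe_map.tsv"),
        ground_truth=ground_truth,
    )
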