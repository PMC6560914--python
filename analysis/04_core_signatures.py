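#!/usr/bin/env python
"""Core-gene prognostic scores: split evaluation and bootstrap robustness.

For every gene set significant in the enrichment stage, the leading-edge
(core) genes define a per-sample score (mean relative expression).  The
score is evaluated by Cox regression on the exploratory and validation
splits (hazard ratio per 0.1 increment) and by the percentage of 1000
with-replacement cohort resamples in which it stays significant.  Also
stratifies each subgroup by the score's Q1/Q3 quantiles with a log-rank
test, the whole-cohort analogue of the published survival figures.
"""

from pathlib import Path

import pandas as pd

from survsig import io as sio
from survsig.signature import (
    bootstrap_robustness,
    core_average_score,
    evaluate_score,
    quantile_stratify,
)
from survsig.survival import logrank

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 4
N_BOOT = 1000


def main():
    rel = sio.read_expression_tsv(ROOT / "preprocessed" / "expression_relative.tsv",
                                  scale="relative")
    samples = sio.read_sample_tsv(ROOT / "preprocessed" / "samples_split.tsv")
    out = ROOT / "signatures"
    out.mkdir(parents=True, exist_ok=True)
    for gsea_file in sorted((ROOT / "gsea").glob("*_gsea.tsv")):
        sg = gsea_file.name.rsplit("_gsea.tsv", 1)[0]
        grp = samples[samples["subgroup"] == sg]
        tab = pd.read_csv(gsea_file, sep="\t")
        rows = []
        for i, r in tab[tab["nominal_p"] < 0.05].reset_index().iterrows():
            core = str(r["leading_edge"]).split(",")
            score = core_average_score(rel.subset_samples(grp.index), core,
                                       pathway=r["set"])
            fits = evaluate_score(score, grp)
            boot = bootstrap_robustness(score, grp, n_boot=N_BOOT,
                                        seed=SEED + i)
            labels, degenerate = quantile_stratify(score.scores)
            lr = (None if degenerate else
                  logrank(grp["os_years"], grp["os_event"], labels.to_numpy()))
            fe, fv = fits["exploratory"], fits["validation"]
            rows.append({
                "pathway": r["set"], "direction": r["direction"],
                "nominal_p": r["nominal_p"], "n_core": len(score.core_genes),
                "expl_hr_per_0.1": None if fe is None else round(fe.hr_per_01[0], 3),
                "expl_p": None if fe is None else fe.wald_p[0],
                "valid_hr_per_0.1": None if fv is None else round(fv.hr_per_01[0], 3),
                "valid_p": None if fv is None else fv.wald_p[0],
                "bootstrap_pct": boot.pct_significant,
                "q1q3_logrank_p": None if lr is None else lr.p,
            })
        res = pd.DataFrame(rows).sort_values("bootstrap_pct", ascending=False) \
            if rows else pd.DataFrame()
        res.to_csv(out / f"{sg}_pathways.tsv", sep="\t", index=False,
                   float_format="%.6g")
        print(f"{sg}: {len(res)} significant pathways")
        if not res.empty:
            print(res[["pathway", "expl_hr_per_0.1", "valid_hr_per_0.1",
                       "bootstrap_pct"]].to_string(index=False))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
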