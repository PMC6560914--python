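#!/usr/bin/env python
"""Preprocess the simulated cohort: collapse, rescale, filter, split.

Collapses probes to genes by maximal inter-quartile range, rescales each
gene to [0, 1] relative expression across the full cohort, derives the
two-year survival status, and assigns the 70/30 exploratory/validation
split stratified by subgroup and two-year status.  Reports the per-subgroup
gene-filter counts (log2 max >= 7, range >= 1.5).
"""

from pathlib import Path

from survsig import io as sio
from survsig.preprocess import (
    collapse_probes,
    filter_genes,
    rescale_relative,
    stratified_split,
    two_year_status,
)
from survsig.synthetic import read_fixture_bundle

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 4


def main():
    bundle = read_fixture_bundle(ROOT / "cohort")
    gene = collapse_probes(bundle.expression, bundle.probe_map)
    n_signal = sum(p.endswith("_p1") for p in gene.probe_provenance.values())
    print(f"probe collapse: {len(gene.feature_ids)} genes; "
          f"{n_signal} signal probes chosen by IQR")
    rel = rescale_relative(gene)
    if rel.zero_range_genes:
        print(f"  zero-range genes excluded: {len(rel.zero_range_genes)}")
    samples = bundle.samples.copy()
    samples["two_year_status"] = two_year_status(samples["os_years"],
                                                 samples["os_event"])
    samples = stratified_split(samples, fraction=0.7, seed=SEED)
    for sg, grp in samples.groupby("subgroup"):
        kept = filter_genes(gene, grp.index)
        n_exp = (grp["split"] == "exploratory").sum()
        print(f"  {sg}: {len(kept)} genes pass filters; "
              f"split {n_exp}/{len(grp) - n_exp}")
    out = ROOT / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    sio.write_expression_tsv(gene, out / "expression_log2.tsv")
    sio.write_expression_tsv(rel, out / "expression_relative.tsv")
    sio.write_sample_tsv(samples, out / "samples_split.tsv")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
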