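#!/usr/bin/env python
"""Arm-level copy-number screening and successive patient stratification.

Per analyzable subgroup: screens every arm gain/loss carried by >=10% of
patients with univariable Cox (risk = HR > 1, protective = HR < 1), applies
forward selection by Nagelkerke R^2 increment to the significant events,
then builds the exclude-and-rescreen stratification tree, annotating each
split with the carriers-vs-rest log-rank test and the Mann-Whitney
comparison of the top pathway's core score.
"""

import json
from pathlib import Path

import pandas as pd

from survsig import io as sio
from survsig.cna import screen_aberrations, select_by_r2, successive_stratify
from survsig.signature import core_average_score
from survsig.synthetic import read_fixture_bundle

ROOT = Path(__file__).resolve().parents[1] / "results"
MIN_EVENTS = 5


def main():
    bundle = read_fixture_bundle(ROOT / "cohort")
    rel = sio.read_expression_tsv(ROOT / "preprocessed" / "expression_relative.tsv",
                                  scale="relative")
    samples = sio.read_sample_tsv(ROOT / "preprocessed" / "samples_split.tsv")
    out = ROOT / "cna"
    out.mkdir(parents=True, exist_ok=True)
    for sg, grp in samples.groupby("subgroup"):
        if int(grp["os_event"].sum()) < MIN_EVENTS:
            print(f"{sg}: skipped (too few events)")
            continue
        events = screen_aberrations(bundle.arm_calls, grp, min_freq=0.10)
        screen = pd.DataFrame(
            {"event": [e.label for e in events],
             "frequency": [round(e.frequency, 3) for e in events],
             "hr": [None if e.cox is None else round(float(e.cox.hr_per_unit[0]), 3)
                    for e in events],
             "p": [e.p for e in events],
             "designation": [e.designation or "" for e in events]})
        screen.to_csv(out / f"{sg}_screen.tsv", sep="\t", index=False,
                      float_format="%.6g")
        sig = [e for e in events if e.designation is not None]
        print(f"{sg}: {len(events)} events tested, {len(sig)} significant")
        if sig:
            selected, trace = select_by_r2(sig, grp)
            print("  R^2 forward selection kept: "
                  f"{[e.label for e in selected]}")
            trace.to_csv(out / f"{sg}_r2_trace.tsv", sep="\t", index=False,
                         float_format="%.6g")
        score = None
        path_file = ROOT / "signatures" / f"{sg}_pathways.tsv"
        if path_file.exists():
            paths = pd.read_csv(path_file, sep="\t")
            if not paths.empty:
                gsea = pd.read_csv(ROOT / "gsea" / f"{sg}_gsea.tsv", sep="\t")
                top = paths.iloc[0]["pathway"]
                core = gsea.set_index("set").loc[top, "leading_edge"].split(",")
                score = core_average_score(rel.subset_samples(grp.index),
                                           core, pathway=top)
        tree = successive_stratify(bundle.arm_calls, grp, score=score)
        (out / f"{sg}_tree.json").write_text(json.dumps(tree.to_dict(), indent=1))
        tree.to_frame().to_csv(out / f"{sg}_tree.tsv", sep="\t", index=False,
                               float_format="%.6g")
        for node in tree.leaves():
            lr = ("" if node.logrank_vs_rest is None
                  else f", logrank p={node.logrank_vs_rest.p:.3g}")
            print(f"  [{node.depth}] {node.condition}: n={node.n}, "
                  f"events={node.n_events}{lr}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
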