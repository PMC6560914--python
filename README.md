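# survsig

Subgroup-specific prognostic **pathway** discovery from tumor expression,
survival and arm-level copy-number data.

Molecularly defined tumor subgroups (the motivating case is pediatric
medulloblastoma with its WNT / SHH / Group 3 / Group 4 consensus subgroups)
are internally heterogeneous: within one subgroup, survival varies with the
activity of particular biological programs and with recurrent chromosome-arm
gains and losses. `survsig` implements, as a tested and reusable pipeline,
the discovery procedure for such *within-subgroup* prognostic structure:

1. **Genome-wide Cox screen.** For each gene *g*, a univariable Cox
   proportional-hazards model on overall survival with the gene's relative
   expression x<sub>g</sub> ∈ [0, 1] (per-gene min–max rescaling across the
   full cohort) as covariate: h(t|x) = h₀(t)·exp(β<sub>g</sub>x). Fitting
   maximizes the Efron-ties partial likelihood by Newton–Raphson; hazard
   ratios are reported per unit and per 0.1 increment (exp(0.1 β)).
2. **Pre-ranked GSEA.** Genes are ranked by ln HR = β and gene sets (MSigDB
   GMT, size ≤ 50, optionally restricted to the PID/KEGG/BIOCARTA databases)
   are scored with the weighted running-sum enrichment statistic; nominal
   p-values come from gene-tag permutations, one-sided within the observed
   direction. Leading-edge members are the pathway's **core genes**.
3. **Core-gene signature.** Each pathway's per-sample score is the mean
   relative expression of its core genes. The score is evaluated by Cox
   regression separately on a 70/30 exploratory/validation split (stratified
   by subgroup and two-year survival status), by Q1/Q3 quantile
   stratification with log-rank tests, and by a **bootstrap robustness
   percentage**: the share of with-replacement cohort resamples in which the
   score stays significant at p < 0.05.
4. **Arm-level copy-number stratification.** Every arm gain/loss carried by
   ≥ 10% of a subgroup is screened by univariable Cox (risk: HR > 1,
   protective: HR < 1, at p < 0.05), jointly informative events are chosen
   by forward selection on the Nagelkerke R² increment, and patients are
   partitioned by **successive stratification**: split off carriers of the
   strongest significant aberration, re-screen the remainder, repeat;
   terminal strata are split by core-score quantiles. An i(17q) proxy
   (17p loss together with 17q gain) is available as a derived marker.

A first-class synthetic-cohort generator (`survsig.synthetic`) draws
multi-subgroup cohorts with *known* planted structure — proportional-hazards
effects on planted pathway scores, arm aberrations acting in cis on member
genes, co-occurring aberration pairs, Weibull baseline with uniform-plus-cap
censoring — so every stage is testable end-to-end against ground truth
without any external download.

## Worked example

The `analysis/` scripts run the whole pipeline on a simulated 530-sample,
four-subgroup cohort (sizes 49/121/107/253, one planted pathway per non-WNT
subgroup at HR 1.5 per 0.1 score increment, a 17p-loss arm cis-linked to the
Group 3 pathway, and a WNT-like subgroup with near-perfect survival):

```
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_cox_screen_and_gsea.py
python analysis/04_core_signatures.py
python analysis/05_cna_stratification.py
```

Selected output (seed 4):

```
cohort: 530 samples, 3000 probes (1500 genes x 2 probes)
  G3: n=107, deaths=55 ... WNT: n=49, deaths=1

SHH: 1500 genes screened (expl n=84, events=18); 1/28 sets at nominal p<0.05
            set direction      es  nominal_p
PID_SHH_PATHWAY  positive 0.92293   0.001739
WNT: skipped (1 events < 5)

SHH: 1 significant pathways
        pathway  expl_hr_per_0.1  valid_hr_per_0.1  bootstrap_pct
PID_SHH_PATHWAY            1.884             1.03            95.1

G3: R^2 forward selection kept: ['17p_loss']
  [0] 17p_loss:protective: n=22, events=5, logrank p=0.00568
```

Reading this: the planted SHH pathway is recovered in the positive (poor
prognosis) direction with ES 0.92; its core-gene score carries an
exploratory hazard ratio of 1.88 per 0.1 increment and stays significant in
95.1% of 1000 bootstrap resamples. In Group 3 the cis-linked 17p loss is
recovered as a protective aberration and heads the stratification tree.
The WNT-like subgroup is skipped by the low-event rule, and occasional
neutral-arm splits elsewhere (e.g. a spurious 17q gain in SHH) illustrate
that the screening is deliberately uncorrected for multiple testing — see
`docs/methods.md`.

The same stages are available as a CLI
(`survsig simulate | preprocess | cox-screen | gsea | core-score |
cna-strat | run-all`) and as library calls
(`survsig.pipeline.run_subgroup_analysis`).

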