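# Methods

## Statistical model

All prognostic claims rest on the Cox proportional-hazards model
h(t|x) = h₀(t)·exp(βᵀx). Covariates are either a gene's relative
expression (per-gene min–max rescaling of log2 values to [0, 1] across the
full retained cohort), a pathway score (mean relative expression of the
pathway's core genes, hence also in [0, 1]), or a binary aberration-carrier
indicator. Because a unit change of a [0, 1] covariate is the entire
dynamic range, hazard ratios are additionally reported per 0.1 increment,
exp(0.1β), which is the scale on which pathway effects are quoted.

### Cox fitting

The partial likelihood uses the Efron correction for tied event times and
is maximized by Newton–Raphson with step halving (convergence when the log
partial likelihood changes by < 1e-9, at most 100 iterations). The
gradient and Hessian are computed by segment reductions over the
descending-time order, so a genome-wide screen of thousands of genes costs
a few milliseconds per gene. Monotone likelihoods (e.g. a carrier group
with no events) have no interior maximum; such fits are capped at
|β| = 15, flagged `degenerate`, and retain their (extreme) rank in the
downstream ordering rather than aborting the screen — pre-ranked
enrichment needs a total order. Zero-variance covariates and cohorts with
fewer than two events raise typed errors. Wald p-values (two-sided) are
used throughout the per-gene screens; Nagelkerke's R²
(Cox–Snell rescaled, with n = number of samples) quantifies multivariable
model fit in the aberration-selection stage. The proportional-hazards
diagnostic is the Grambsch–Therneau score test on scaled Schoenfeld
residuals with the Kaplan–Meier time transform, the standard default
configuration; it is a diagnostic, not a gate — genes are not excluded on
its account.

### Pre-ranked enrichment

Genes are ranked by descending β (= ln HR); exact ties break by ascending
gene id so the order is total and deterministic. The enrichment score of a
set is the classic weighted Kolmogorov–Smirnov-like statistic with weight
exponent 1: walking down the ranking, members increment the running sum by
|r_i| / Σ_hits |r_j| and non-members decrement it by 1/(N − N_hits); the ES
is the running-sum value of maximal absolute deviation (an exact tie
between the positive and negative extreme resolves to the positive one;
the first index attaining the extreme is the peak). If all member metrics
are exactly zero the hit weights fall back to equal. Leading-edge (core)
genes are the members at or before the peak for positive ES, at or after
it for negative ES; for positive ES the peak is itself a hit, so the
leading edge is never empty.

Significance uses gene-tag permutation — random same-size draws from the
ranked universe — which is the only null available to pre-ranked input.
The p-value is one-sided within the sign class of the observed ES with
add-one smoothing, p = (1 + #{same-sign null with |ES★| ≥ |ES|}) /
(1 + #{same-sign null}), so p is never zero and −log₁₀ p is stable.
Null scores are computed from hit positions only (the running-sum maximum
is attained at a hit, the minimum just before one), making 1000
permutations of genome-sized rankings cheap. Normalized enrichment scores
and FDR q-values are deliberately not computed: the procedure thresholds
on the nominal p-value in each direction, and the bootstrap stage, not an
FDR, carries the robustness burden.

### Core-gene signature evaluation

Core genes are extracted from enrichment run on the exploratory split
only; the score is then evaluated on exploratory and validation splits
separately (the discovery/validation asymmetry is preserved deliberately —
the exploratory estimate is selection-biased, the validation estimate is
not). The bootstrap robustness percentage resamples the *entire* subgroup
(both splits pooled) with replacement, refits the univariable Cox model on
the score, and reports the percentage of replicates with p < 0.05.
Replicates with fewer than two events or zero score variance are redrawn,
not dropped, so the denominator stays fixed and percentages are comparable
across pathways. Q1/Q3 stratification uses linear-interpolation quantiles
with the mid group closed on both ends (low: s < Q1; mid: Q1 ≤ s ≤ Q3;
high: s > Q3); all-equal scores are flagged degenerate instead of being
split.

### Arm-level screening and successive stratification

Gain and loss of the same arm are separate candidate events (binary
indicators). Events carried by at least 10% of the screened cohort
(inclusive) are tested; significant ones (p < 0.05) are designated risk
(HR > 1) or protective (HR < 1). Forward selection orders candidates by
univariable p and keeps one iff the joint model's Nagelkerke R² rises by
at least 0.01 (configurable); indicator vectors identical to an already
selected one are dropped as collinear, and the per-step joint Wald
p-values are exposed so "no longer significant once X is included"
statements can be read off the trace. Successive stratification repeatedly
splits off the carriers of the strongest significant event and re-screens
the remainder, stopping when nothing is significant or fewer than 20
samples remain (the smallest subsets worth screening in cohorts of this
size); the terminal remainder is stratified by the core score's quantiles.
Each split is annotated with a carriers-vs-rest log-rank test and a
Mann–Whitney comparison of mean core scores. No multiple-testing
correction is applied across arms or steps — this mirrors the published
procedure the pipeline formalizes, and on a null cohort the chance of at
least one spurious split is inflated accordingly (the worked example in
the README shows such a split). A Benjamini–Hochberg option per screening
round exists for users who want control.

### Other conventions

Probe collapse keeps, per gene, the probe with the largest IQR
(linear-interpolation quartiles, "type 7"); IQR ties break on the
lexicographically smallest probe id. Gene filters (log2 maximum ≥ 7 and
range ≥ 1.5, both inclusive) are computed on all samples of a subgroup,
not the exploratory split only. Relative rescaling is computed once on the
full retained cohort before splitting, and sample subsets inherit that
scaling. Two-year status: death at ≤ 2 years is `dead` (boundary
inclusive), follow-up reaching 2 years is `alive`, censoring before 2
years is `censored`. The stratified split assigns round(0.7·k) samples
(half-up) of each subgroup × two-year-status stratum to the exploratory
set; singleton strata go to exploratory. Subgroups with fewer than 5 death
events are skipped entirely, with the reason logged. The Mann–Whitney test
is exact when both groups have n ≤ 8 and no ties, otherwise the normal
approximation with midranks and tie correction.

## The synthetic-cohort generator

The generator draws the data-generating process the analysis assumes, so
that recovery of planted truth is a meaningful end-to-end check.

* **Expression.** Genes share a baseline log2 level (default mean 8, noise
  sd 1). Members of a planted set additionally share a per-sample latent
  activity (sd 1.3 log2 units, ≈ 63% within-set shared variance). This
  co-expression is essential, not cosmetic: the mean of k independent
  min–max-scaled genes has sd ≈ 0.17/√k, and no biologically plausible
  hazard coefficient makes such a score a strong marker; real pathway
  modules (cell-cycle/proliferation programs above all) are strongly
  co-expressed, with first-component variance shares well above 50%.
  Optional extra probes per gene are pure noise at 0.3× the baseline sd,
  so the IQR collapse verifiably picks the signal probe.
* **Copy number.** Arm calls are −1/0/+1, drawn iid per arm with
  configured gain/loss frequencies; a coupled arm can have different
  frequencies among carriers of a reference arm, modeling co-occurring
  aberration pairs of the i(17q) type. Aberrations act in cis: ±δ log2 on
  the arm's member genes. Survival effects of arms are therefore always
  *indirect*, mediated by planted-set expression — exactly the causal
  structure the screening stage assumes.
* **Survival.** Event times are Weibull (shape 1.2, scale 20 years) with
  the per-sample hazard multiplied by exp(Σ β_s·(score_s − 0.5)); the
  centering is a baseline reparameterization that leaves every Cox
  estimate unchanged while keeping the event rate at its null level.
  Censoring is min(Uniform(0, 20), 15) years. These defaults give ≈ 33%
  death events, matching long-follow-up pediatric brain-tumor cohorts. A
  per-subgroup hazard multiplier models systematically favorable subgroups
  (the WNT-like subgroup in the demo uses 0.12, yielding the ~3-events-
  in-49 pattern that triggers the skip rule).

What the generator does *not* emulate: batch effects, probe-level
intensity artifacts, subgroup-specific expression signatures (subgroups
differ only through their planted sets and hazard multipliers), focal
amplifications, and methylation data. Passing tests therefore demonstrate
that the *procedure* recovers the structure it assumes at realistic effect
sizes and censoring — not that it is robust to the technical artifacts of
any particular platform.

## Verification strategy and problem sizes

Every numerically nontrivial primitive is checked against an independent
oracle: the Cox fitter against brute-force grid maximization of a
hand-written partial likelihood on ~100 tiny cohorts (and against an
independent survival library on larger ones, including ties), the
enrichment score and leading edge against exhaustive step-by-step
running-sum enumeration on 200 random rankings, the log-rank statistic
against a hand-enumerated risk-table computation, and the exact
Mann–Whitney p against complete enumeration of assignments. Calibration
and recovery checks run at the study conditions the generator encodes:
null calibration on a 300-sample, 2000-gene effect-free cohort; planted
pathway recovery (HR 1.5 per 0.1, n = 300, 20-gene set) over 20 seeds with
1000 permutations and 1000 bootstrap replicates; nested two-level
stratification recovery (protective arm, 30% carriers, with a co-occurring
masked risk arm, n = 500) over 20 seeds. These sizes keep the full suite
and the acceptance script to a few minutes on one CPU while leaving the
binomial noise of the recovery rates well inside the asserted margins.

## Known limitations

* The bootstrap percentage is a stability measure, not an error rate; it
  inherits the selection bias of bootstrapping after discovery.
* Degenerate (capped) Cox fits give the affected gene an extreme rank by
  construction; with very small cohorts this can push rare monotone
  patterns to the top of a ranking.
* The successive stratification is greedy and sequential: it formalizes a
  narrative procedure, and its uncorrected per-step screening means tree
  depth grows with the number of arms tested under the null.
* The Grambsch–Therneau test is one specific proportional-hazards
  diagnostic; other transforms (rank, identity) can disagree near the
  boundary.
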