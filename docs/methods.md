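# Methods

This note documents the statistical machinery implemented in `pvhmr`, the
assumptions baked into the synthetic-cohort generator, and the numerical
choices a user should know before trusting or extending the results.

## Variant retention and the mutation matrix

Three inclusive thresholds govern retention, all configurable
(`filters.min_vaf`, `filters.common_maf`, `filters.rare_vus_maf`; defaults
2%, 1%, 0.01%): a variant is dropped when its VAF is below 2%, when its
general-population minor allele frequency is at least 1% (common
polymorphism), or when it is a VUS with population MAF of at least 0.01%
(rare polymorphism). Prognostic analyses then use pathogenic and
likely-pathogenic variants only. Whether the VAF floor is applied before or
after pathogenicity restriction does not change the retained set (the two
filters commute); both counts are logged.

Gene-level aggregation uses the **maximum** VAF across a patient's variants
in a gene category. Rationale: VAF proxies clone size, and the classifier's
TET2 ≥ 5% rule asks whether *any* TET2 clone has reached that size. For
TET2 and DNMT3A, categories are split into truncating (nonsense/frameshift)
vs missense(-like) because their two lesion types behave differently;
splice and in-frame lesions fall in the missense-like bucket. "Additional
mutations" count *variants*, not genes — two TET2 hits contribute 2 — since
multi-hit patients are biologically distinct (biallelic inactivation).
The matrix drops categories mutated in fewer than `min_patients` patients
(default 7 for network input) but `n_additional` is computed before that
filter and is unaffected by it.

The default panel ships the 15 genes with recurrent pathogenic PV variants;
the full capture design is wider and the panel is a config key
(`panel.genes`). The DNA source (whole blood vs granulocytes) is carried as
optional metadata and never used in computation.

## Association testing

Test choice is by variable type: binary x binary pairs get the two-sided
Fisher exact test with the odds ratio; binary x continuous pairs get the
two-sided Mann-Whitney test with direction from the median shift;
continuous x continuous (VAF-VAF) pairs get Spearman rank correlation.
Degenerate pairs (constant margins, too few pairwise-complete observations)
are emitted with p = 1 and a `degenerate` flag rather than dropped, so the
table shape is deterministic. Benjamini-Hochberg q-values are computed over
the *whole* table; the reporting flag `p < 0.05` mirrors common practice of
displaying only nominally significant associations, but the full table is
always written.

## Bayesian network over mutation indicators

Structure learning is score-based: greedy hill-climbing over single-edge
additions, deletions and reversals, maximizing the BIC of a discrete
Bayesian network with Bernoulli nodes and tabular conditional distributions
(one free parameter per parent configuration; the penalty counts all
2^|parents| representable configurations, not only the observed ones, so
adding a parent is never free on sparse data). The search starts from the
empty graph, breaks equal-score moves lexicographically, and runs 5 seeded
random restarts. Edge confidence is the fraction of bootstrap resamples
(default 50) whose learned structure contains the edge in its *skeleton* —
direction is not scored, because observational co-occurrence data identify
DAGs only up to Markov equivalence. Everything is deterministic given
`random_state`.

Learning runs on binary presence; VAF dependence is reported separately as
rank correlations and through the gene clustering (average linkage on
1 − |Spearman ρ| of per-patient maximum-VAF profiles, lexicographic column
order for deterministic ties, constant columns assigned distance 1 and
flagged).

## PV-HMR classification

The classifier is sequential: high (HMR-gene mutation, ≥ 2 additional
mutations, or a non-chromosome-9 CNV), else intermediate (TET2 max VAF
≥ 5%), else low. Three deliberate readings of the rules:

- "non-9p CNV" means *no abnormality of chromosome 9 at all* — 9pUPD and 9p
  trisomy both fail to trigger the rule, matching how chromosome-9
  abnormalities are tallied separately from other CNVs.
- The intermediate patient's TET2 variant *does* count toward the ≥ 2 rule
  (any non-driver mutation counts), so TET2+DNMT3A at low VAFs is high.
- CBL is **not** in the default high-risk gene set: the classifier
  definition names SRSF2/IDH1/IDH2/EZH2/NFE2, even though CBL sometimes
  appears in broader "high-risk mutation" groupings. The set is a
  constructor parameter for sensitivity analyses.

The JAK2 driver never counts toward any rule. The comparator scores
(IWG-PV, MIPSS-PV) are a generic points engine driven by YAML configs; the
shipped component weights come from the scores' own publications and are
marked "verify against cited source" — the engine, not the weights, is what
this package vouches for.

## Multistate model

Clock-forward Markov illness-death model: all three transitions are modelled
on time since diagnosis, with the 2→3 transition entering its risk set at
the transformation time via left truncation. Competing events are censored
cause-specifically (the 1→2 record is censored at death without
transformation, and vice versa); intervals are half-open (entry, exit].

The Cox solver maximizes the Breslow-ties partial likelihood by
Newton-Raphson with step halving. Convergence requires the maximum absolute
score component below 1e-8 *or* a stationary parameter step below 1e-10 —
the second criterion exists because at n in the thousands the summed score
hits floating-point cancellation around 1e-8 before the step does. Efron
ties are available behind `ties="efron"`. A |log HR| exceeding 15 is
diagnosed as a monotone likelihood (perfect separation) and raised as an
error naming the covariate; standard errors are Wald from the inverse
observed information, and the baseline cumulative hazard is the Breslow
estimator (which reduces to Nelson-Aalen when no covariates are fitted).
Stepwise downward selection drops the covariate with the largest Wald
p > 0.05 (ties broken by name, lexicographically first), refits, and stops
when all remaining p ≤ 0.05.

Aalen-Johansen state occupation is the product integral of the empirical
transition-intensity matrix over event times; occupation probabilities sum
to one by construction and the chronic-state curve reduces to Kaplan-Meier
when no transformations occur.

## Performance metrics

- **Harrell's C** over censoring-usable pairs (an event subject with the
  earlier time vs any subject with a later time), 0.5 credit for tied risks.
- **IPCW Brier score** (Graf): subjects with events by the horizon weighted
  by 1/G(t⁻), subjects at risk past it by 1/G(t), subjects censored before
  it weight 0, with G the Kaplan-Meier estimate of the censoring
  distribution on the whole sample (events processed before censorings at
  tied times).
- **Cumulative/dynamic IPCW AUC**: cases are events by the horizon,
  controls are subjects at risk past it; the weighted proportion of
  correctly ordered case-control pairs, ties 0.5.

These are the estimators implemented across the standard survival-metrics
ecosystem; the C-index implementation is cross-checked against
scikit-survival in the test suite, and all three are checked against
exhaustive pair/weight enumeration on small fixtures. For the
transformation endpoint, death before transformation is treated as
cause-specific censoring (an Aalen-Johansen competing-risk variant of the
predicted probabilities can be built from the multistate module, but the
default report uses cause-specific censoring). Horizons where G(t) = 0 are
reported as unevaluable rather than extrapolated. Horizons default to
6/10/14 years.

## Synthetic-cohort generator

The generator emulates the statistical structure of a PV sequencing cohort;
it is the package's test bed and parameter-recovery engine, not a patient
simulator. Components, with provenance flags:

- **Mutation model**: a DAG over genes with tabular Bernoulli conditionals,
  sampled ancestrally. Marginal prevalences put TET2 (0.25), DNMT3A (0.15)
  and ASXL1 on top [ASSUMED, ordered to match observed gene rankings]; the
  co-occurrence table makes ASXL1 central (enriched given TET2, and
  enriching EZH2/SRSF2/IDH2), with a DNMT3A-BCOR link [ASSUMED sparse
  structure]. Given a TET2 mutation, a second TET2 variant occurs with
  probability 0.25, reproducing the observed ~6% multi-TET2 patients.
- **VAF model**: per gene, a two-component beta mixture on the percent
  scale — a low-clone component (Beta(2,18), mean 10%) and a high-clone
  component (Beta(8,12) or Beta(10,12), mean ~40-45%). Mixture weights give
  DNMT3A/NFE2 mostly low VAFs, IDH2/SRSF2 mostly high, TET2/ASXL1 bimodal
  [ASSUMED shapes; qualitative pattern from the observed distributions].
- **CNV**: 9pUPD at 45% [PAPER-reported rate], 9p trisomy 1.8% [PAPER], and
  seven non-9p regions totalling ~1.6% [PAPER].
- **Clinical covariates**: age Normal(66, 15.5) clipped to [20, 95]
  (median 66, IQR ≈ [55, 76] [PAPER]); 59% male [PAPER]; prior venous /
  arterial thrombosis 23% / 20% [PAPER]; lognormal blood counts and NLR,
  constitutional symptoms 20%, pruritus 30% [ASSUMED]. Driver VAF is drawn
  higher for 9pUPD carriers (UPD amplifies the driver clone).
- **Outcomes**: competing 1→2 / 1→3 times by inversion of each
  cause-specific cumulative hazard; on transformation, the 2→3 time is
  drawn clock-forward from the transformation time (memoryless under the
  default constant hazards; a Weibull baseline is available via
  `weibull_shape`, sampled through the inverse cumulative hazard). Baseline
  rates 0.004 / 0.025 / 0.20 per year for 1→2 / 1→3 / 2→3 in the low-risk
  group [ASSUMED, chosen to give event proportions of the right order over
  a ~16-year horizon]; group log-hazard effects are the final multistate
  model's published estimates (HR 5.42 and 3.51 on 1→2 for high and
  intermediate, 1.92 on 1→3 for high) and age effects 1.07 / 1.09 per year
  [PAPER]. Censoring = min(administrative 16 years, Exp(0.04) dropout)
  [ASSUMED].
- **Noise**: sub-threshold-VAF, VUS and common-polymorphism variant rows
  are emitted at small Poisson rates so the retention filters have real
  work to do in end-to-end runs.

Random streams are split per component (mutations / clinical / outcomes) via
`SeedSequence.spawn`, so toggling one block does not shift the others; a
given (config, seed) is byte-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not establish about real cohorts: clonal evolution over time, correlation
between mutations and blood counts beyond the group effect on hazards,
informative censoring, treatment effects, inter-center heterogeneity, and
measurement error in VAF. Parameter-recovery results validate the
*estimators* under the generating model, not the published cohort-specific
estimates.

## Problem sizes in the checks

The recovery experiments use 100 replicates of n = 1500 with ~15% high-risk
(and, where relevant, 20% intermediate) patients, constant baselines
(1→2: 0.012, 1→3: 0.03, 2→3: 0.20 per year), a 15-year administrative
horizon and Exp(0.04) dropout, giving roughly 30% randomly censored
subjects and a few hundred events per transition — enough that the mean
fitted HR estimates the generating HR to a few percent. Closed-form
Aalen-Johansen checks use n = 10,000 constant-hazard cohorts; oracle
equivalences (brute-force partial likelihood, exhaustive DAG search,
enumeration-based metrics) use fixtures of ≤ 10 subjects or 3 nodes where
exhaustive computation is exact.

## Known limitations

- The Cox solver handles the moderate covariate counts of this design
  (tens), not high-dimensional regression; there is no penalization.
- The Bayesian network learner assumes complete binary data and is
  exponential in the parent-set size through its 2^|parents| penalty;
  with the ≥ 7-mutated-patients filter the node count stays small.
- The IPCW metrics estimate censoring marginally (no covariate-dependent
  censoring model).
- `CategoricalRiskModel` probabilities are in-sample Kaplan-Meier estimates
  per category, matching how categorical scores are usually evaluated on a
  development cohort; no cross-validation is built in.
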