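# pvhmr

Molecular-prognostic analysis of polycythemia vera (PV) cohorts: variant
filtering, mutation-landscape and co-occurrence analysis, the 3-tier PV-HMR
genomic classifier, an illness-death multistate survival model, and
time-dependent prognostic performance metrics — with a synthetic
clinical-genomic cohort generator so every stage is testable without access
to patient-level data.

## Who this is for

Biostatisticians and hematology researchers who want to stratify PV patients
by their *additional* somatic mutations (everything beyond the canonical
*JAK2* driver) and quantify how well a genomic classification predicts
hematologic transformation (secondary myelofibrosis or MDS/AML) and death.

## The model

**Variant retention.** Panel variants are kept when VAF ≥ 2% and the variant
is not a common polymorphism (population MAF ≥ 1%); variants of unknown
significance with population MAF ≥ 0.01% are treated as rare polymorphisms
and removed. Only pathogenic and likely-pathogenic variants enter the
prognostic analysis.

**PV-HMR classification** (sequential, per patient):

1. **high** — any mutation in *SRSF2*, *IDH1*, *IDH2*, *EZH2* or *NFE2*,
   OR ≥ 2 additional (non-driver) mutations, OR ≥ 1 CNV outside
   chromosome 9;
2. **intermediate** — otherwise, a *TET2* mutation with VAF ≥ 5%;
3. **low** — everything else.

**Illness-death multistate model.** States 1 = chronic phase,
2 = hematologic transformation, 3 = death, with transitions 1→2, 1→3, 2→3.
Each transition gets its own Cox proportional-hazards model

&nbsp;&nbsp;&nbsp;&nbsp;λ<sub>hj</sub>(t | x) = λ<sub>hj,0</sub>(t) · exp(xᵀβ<sub>hj</sub>)

fitted on the clock-forward time scale (years since diagnosis), with left
truncation for 2→3 entry at the transformation time, Breslow ties and a
Breslow baseline. Backward ("stepwise downward") covariate elimination on
Wald p-values selects the final model per transition. State-occupation
probabilities come from the Aalen-Johansen product integral.

**Performance metrics.** Harrell's C (0.5 credit for risk ties), IPCW
cumulative/dynamic AUC(t) and the Graf IPCW Brier score BS(t), all with
Kaplan-Meier censoring weights, evaluated at 6/10/14-year horizons for the
overall-survival and transformation endpoints.

**Co-occurrence structure.** A Bayesian network over binary gene-mutation
indicators, learned by BIC hill-climbing (add/delete/reverse moves, seeded
restarts) with bootstrap skeleton-edge confidence, plus average-linkage
hierarchical clustering of genes on 1 − |Spearman ρ| of VAF profiles.

## Worked example

```python
from pvhmr import (simulate_cohort, filter_variants, prognostic_subset,
                   classify_pv_hmr, to_multistate, fit_cox_transition,
                   summarize_landscape, build_mutation_matrix)

variants, cnvs, clinical = simulate_cohort(seed=1)     # 500 patients
prog = prognostic_subset(filter_variants(variants))
matrix = build_mutation_matrix(prog, clinical["patient_id"])
summary = summarize_landscape(matrix, prog, cnvs)
print("patients with >=1 additional mutation:",
      f"{summary['pct_additional']['ge1']}%")

groups = classify_pv_hmr(prog, cnvs, clinical["patient_id"])
print(groups["genomic_group"].value_counts().to_dict())

clin = clinical.merge(groups[["patient_id", "genomic_group"]], on="patient_id")
clin["group_high"] = (clin["genomic_group"] == "high").astype(float)
clin["group_intermediate"] = (clin["genomic_group"] == "intermediate").astype(float)
clin["age_c"] = clin["age_dx"] - 66.0

dataset = to_multistate(clin, covariates=["group_high", "group_intermediate",
                                          "age_c"])
fit = fit_cox_transition(dataset, "1->2",
                         ["group_high", "group_intermediate", "age_c"])
print(fit.summary().round(3))
```

prints

```
patients with >=1 additional mutation: 49.6%
{'low': 324, 'high': 139, 'intermediate': 37}
                     coef     HR     se      p  HR_lower  HR_upper
group_high          1.369  3.931  0.340  0.000     2.019     7.652
group_intermediate  0.669  1.953  0.560  0.232     0.652     5.848
age_c               0.076  1.079  0.014  0.000     1.049     1.109
```

Half the simulated patients carry at least one additional mutation; the
high-molecular-risk group's chronic→transformation hazard ratio is estimated
at 3.9 (the single-cohort estimate of a generating HR of 5.42 — at 500
patients the transformation transition carries few events, so the
replicate-averaged recovery below is the calibrated check), and age increases
the transformation hazard by ~8%/year in this cohort.

## Command line

```sh
pvhmr simulate  --seed 42 --out run/ --n 500      # synthetic cohort TSVs
pvhmr landscape --in run/ --out run/ --seed 42    # summary, network, clusters
pvhmr classify  --in run/ --out run/              # groups.tsv + comparators
pvhmr fit       --in run/ --groups run/groups.tsv --out run/
pvhmr evaluate  --in run/ --groups run/groups.tsv --out run/ --horizons 6,10,14
pvhmr all       --seed 42 --out run/ --n 500      # everything above
```

Every run writes a YAML manifest (seed, config hash, input digests) and a
log recording dropped-row counts from each filter.

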