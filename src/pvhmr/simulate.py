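"""Synthetic clinical-genomic cohort generator.

Emulates the statistical structure of a polycythemia vera sequencing cohort:
gene mutation prevalences with TET2/DNMT3A/ASXL1 most frequent and non-random
co-occurrence (a DAG with tabular Bernoulli conditionals), per-gene VAF
distributions as two-component beta mixtures (low-clone vs high-clone, giving
the observed bimodality for TET2/ASXL1, low VAF for DNMT3A/NFE2 and high VAF
for IDH2/SRSF2), 9pUPD and rare non-9p CNVs, clinical covariates, and
illness-death event histories with covariate log-hazard effects plus
administrative and random censoring.

Values flagged [PAPER] in the default config are read off the study being
emulated; values flagged [ASSUMED] are documented choices (see
docs/methods.md). Random streams are split per component (mutations /
clinical / outcomes) so toggling one block does not shift the others.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd


def default_config() -> dict:
    """Default simulation config; every leaf is overridable."""
    return {
        "n_patients": 500,
        # gene -> marginal prevalence ([ASSUMED], ordered to put TET2 /
        # DNMT3A / ASXL1 on top as in real PV cohorts) and VAF mixture:
        # weight of the low-clone component, Beta(a, b) shapes for the low
        # and high components on the percent scale.
        "genes": {
            "TET2":   {"prevalence": 0.25, "w_low": 0.50,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.70, "p_second_variant": 0.25},
            "DNMT3A": {"prevalence": 0.15, "w_low": 0.90,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.30, "p_second_variant": 0.05},
            "ASXL1":  {"prevalence": 0.05, "w_low": 0.50,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.90, "p_second_variant": 0.05},
            "SRSF2":  {"prevalence": 0.025, "w_low": 0.15,
                       "low": [2.0, 18.0], "high": [10.0, 12.0],
                       "truncating_frac": 0.05, "p_second_variant": 0.0},
            "IDH1":   {"prevalence": 0.01, "w_low": 0.15,
                       "low": [2.0, 18.0], "high": [10.0, 12.0],
                       "truncating_frac": 0.0, "p_second_variant": 0.0},
            "IDH2":   {"prevalence": 0.02, "w_low": 0.15,
                       "low": [2.0, 18.0], "high": [10.0, 12.0],
                       "truncating_frac": 0.0, "p_second_variant": 0.0},
            "EZH2":   {"prevalence": 0.015, "w_low": 0.40,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.60, "p_second_variant": 0.0},
            "NFE2":   {"prevalence": 0.03, "w_low": 0.90,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.90, "p_second_variant": 0.0},
            "CBL":    {"prevalence": 0.02, "w_low": 0.40,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.05, "p_second_variant": 0.0},
            "TP53":   {"prevalence": 0.03, "w_low": 0.80,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.20, "p_second_variant": 0.05},
            "PPM1D":  {"prevalence": 0.02, "w_low": 0.85,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.90, "p_second_variant": 0.0},
            "BCOR":   {"prevalence": 0.02, "w_low": 0.60,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.80, "p_second_variant": 0.0},
            "SF3B1":  {"prevalence": 0.02, "w_low": 0.30,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.05, "p_second_variant": 0.0},
            "U2AF1":  {"prevalence": 0.01, "w_low": 0.30,
                       "low": [2.0, 18.0], "high": [8.0, 12.0],
                       "truncating_frac": 0.05, "p_second_variant": 0.0},
        },
        # co-occurrence DAG ([ASSUMED] sparse structure with ASXL1 central):
        # child -> {parent gene: odds multiplier on the prevalence-odds}.
        "cooccurrence": {
            "ASXL1": {"TET2": 3.0},
            "EZH2": {"ASXL1": 8.0},
            "SRSF2": {"ASXL1": 5.0},
            "IDH2": {"ASXL1": 4.0, "SRSF2": 6.0},
            "BCOR": {"DNMT3A": 5.0},
        },
        # contamination emitted upstream of the retention filters:
        # per-patient expected counts of sub-threshold and VUS rows [ASSUMED]
        "noise": {"low_vaf_rate": 0.05, "vus_rate": 0.15,
                  "common_poly_rate": 0.05},
        "cnv": {
            "9p_upd": 0.45,          # [PAPER] 45% 9pUPD
            "9p_gain": 0.018,        # [PAPER] 9p trisomy 1.8%
            "non9p": {"20q": 0.007, "1q": 0.005, "7": 0.005, "8": 0.002,
                      "13q": 0.002, "17p": 0.002, "5": 0.001},  # [PAPER] ~1.6% total
        },
        "clinical": {
            "age_median": 66.0, "age_sigma": 15.5,   # [PAPER] median 66, IQR 55-76
            "age_range": [20.0, 95.0],
            "male_frac": 0.59,                        # [PAPER]
            "leukocytes_logmed": np.log(10.5), "leukocytes_sigma": 0.45,  # [ASSUMED]
            "platelets_logmed": np.log(450.0), "platelets_sigma": 0.35,   # [ASSUMED]
            "nlr_logmed": np.log(4.0), "nlr_sigma": 0.5,                  # [ASSUMED]
            "prior_venous": 0.23, "prior_arterial": 0.20,  # [PAPER]
            "constitutional_symptoms": 0.20, "pruritus": 0.30,  # [ASSUMED]
            "exon12_frac": 0.02,                      # [PAPER] 2% exon 12
        },
        "hazards": {
            # constant baseline rates per year for the low-risk group [ASSUMED]
            "baseline": {"1->2": 0.004, "1->3": 0.025, "2->3": 0.20},
            # log hazard ratios; group effects are the final-model
            # estimates [PAPER], age effects per year, centred at 66 [PAPER]
            "effects": {
                "1->2": {"group_high": np.log(5.42),
                         "group_intermediate": np.log(3.51),
                         "age_c": np.log(1.07)},
                "1->3": {"group_high": np.log(1.92), "age_c": np.log(1.09)},
                "2->3": {},
            },
            "weibull_shape": None,   # None -> constant (exponential) hazards
        },
        "censoring": {"admin_horizon": 16.0, "dropout_rate": 0.04},  # [ASSUMED]
    }


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def make_config(**overrides) -> dict:
    """Default config with nested overrides applied."""
    return _merge(default_config(), overrides)


def _validate_config(cfg: dict) -> None:
    for gene, g in cfg["genes"].items():
        for key in ("prevalence", "w_low", "truncating_frac",
                    "p_second_variant"):
            v = g[key]
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"genes.{gene}.{key}: {v} outside [0, 1]")
    for tr, lam in cfg["hazards"]["baseline"].items():
        if lam < 0:
            raise ValueError(f"hazards.baseline.{tr}: negative rate")
    for child, parents in cfg["cooccurrence"].items():
        if child not in cfg["genes"]:
            raise ValueError(f"cooccurrence.{child}: unknown gene")
        for p in parents:
            if p not in cfg["genes"]:
                raise ValueError(f"cooccurrence.{child}.{p}: unknown gene")


def _topo_order(genes, cooccurrence) -> list:
    order, seen = [], set()

    def visit(g, stack=()):
        if g in seen:
            return
        if g in stack:
            raise ValueError("cooccurrence graph must be acyclic")
        for p in cooccurrence.get(g, {}):
            visit(p, stack + (g,))
        seen.add(g)
        order.append(g)

    for g in genes:
        visit(g)
    return order


def _sample_vaf(gcfg, rng) -> float:
    low = rng.random() < gcfg["w_low"]
    a, b = gcfg["low"] if low else gcfg["high"]
    vaf = 100.0 * rng.beta(a, b)
    return float(np.clip(vaf, 2.0, 98.0))


def simulate_mutations(cfg: dict, rng) -> pd.DataFrame:
    """Variant rows (including filter-fodder noise) for all patients."""
    n = cfg["n_patients"]
    genes = cfg["genes"]
    order = _topo_order(genes, cfg["cooccurrence"])
    present = {g: np.zeros(n, dtype=bool) for g in genes}
    for g in order:
        base_p = genes[g]["prevalence"]
        if base_p <= 0:
            continue
        odds = np.full(n, base_p / (1.0 - base_p) if base_p < 1 else np.inf)
        for parent, mult in cfg["cooccurrence"].get(g, {}).items():
            odds = np.where(present[parent], odds * mult, odds)
        p = odds / (1.0 + odds)
        present[g] = rng.random(n) < p

    rows = []
    for i in range(n):
        pid = f"P{i:04d}"
        for g in order:
            if not present[g][i]:
                continue
            n_var = 1 + int(rng.random() < genes[g]["p_second_variant"])
            for _ in range(n_var):
                trunc = rng.random() < genes[g]["truncating_frac"]
                effect = ("frameshift" if trunc and rng.random() < 0.6
                          else "nonsense" if trunc else "missense")
                rows.append({
                    "patient_id": pid, "gene": g, "effect": effect,
                    "vaf": round(_sample_vaf(genes[g], rng), 2),
                    "pathogenicity": "pathogenic" if rng.random() < 0.7
                    else "likely_pathogenic",
                    "pop_maf": 0.0, "is_driver": 0,
                })
        # noise rows removed by the retention filters
        noise = cfg["noise"]
        gene_list = list(genes)
        for _ in range(rng.poisson(noise["low_vaf_rate"])):
            rows.append({"patient_id": pid,
                         "gene": gene_list[rng.integers(len(gene_list))],
                         "effect": "missense",
                         "vaf": round(float(rng.uniform(0.3, 1.9)), 2),
                         "pathogenicity": "likely_pathogenic",
                         "pop_maf": 0.0, "is_driver": 0})
        for _ in range(rng.poisson(noise["vus_rate"])):
            rows.append({"patient_id": pid,
                         "gene": gene_list[rng.integers(len(gene_list))],
                         "effect": "missense",
                         "vaf": round(float(rng.uniform(2.0, 50.0)), 2),
                         "pathogenicity": "VUS",
                         "pop_maf": round(float(rng.uniform(0.01, 0.5)), 4),
                         "is_driver": 0})
        for _ in range(rng.poisson(noise["common_poly_rate"])):
            rows.append({"patient_id": pid,
                         "gene": gene_list[rng.integers(len(gene_list))],
                         "effect": "missense",
                         "vaf": round(float(rng.uniform(30.0, 60.0)), 2),
                         "pathogenicity": "likely_pathogenic",
                         "pop_maf": round(float(rng.uniform(1.0, 40.0)), 2),
                         "is_driver": 0})
    return pd.DataFrame(rows, columns=["patient_id", "gene", "effect", "vaf",
                                       "pathogenicity", "pop_maf", "is_driver"])


def simulate_cnv(cfg: dict, rng) -> pd.DataFrame:
    n = cfg["n_patients"]
    rows = []
    cnv = cfg["cnv"]
    for i in range(n):
        pid = f"P{i:04d}"
        if rng.random() < cnv["9p_upd"]:
            rows.append({"patient_id": pid, "region": "9p", "kind": "UPD"})
        elif rng.random() < cnv["9p_gain"]:
            rows.append({"patient_id": pid, "region": "9p", "kind": "gain"})
        for region, p in cnv["non9p"].items():
            if rng.random() < p:
                kind = "loss" if region in ("20q", "13q", "17p", "7") else "gain"
                rows.append({"patient_id": pid, "region": region, "kind": kind})
    return pd.DataFrame(rows, columns=["patient_id", "region", "kind"])


def simulate_clinical_covariates(cfg: dict, rng, cnvs=None) -> pd.DataFrame:
    n = cfg["n_patients"]
    c = cfg["clinical"]
    lo, hi = c["age_range"]
    age = np.clip(rng.normal(c["age_median"], c["age_sigma"], n), lo, hi)
    upd = np.zeros(n, dtype=bool)
    if cnvs is not None and len(cnvs):
        pats = set(cnvs.loc[cnvs["region"] == "9p", "patient_id"])
        upd = np.array([f"P{i:04d}" in pats for i in range(n)])
    # 9pUPD amplifies the driver clone -> higher JAK2 VAF
    driver_vaf = np.where(upd, 100 * rng.beta(3.0, 1.8, n),
                          100 * rng.beta(1.6, 3.4, n))
    exon12 = rng.random(n) < c["exon12_frac"]
    return pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "age_dx": np.round(age, 1),
        "sex": np.where(rng.random(n) < c["male_frac"], "male", "female"),
        "prior_arterial_thrombosis": (rng.random(n) < c["prior_arterial"]).astype(int),
        "prior_venous_thrombosis": (rng.random(n) < c["prior_venous"]).astype(int),
        "constitutional_symptoms": (rng.random(n) < c["constitutional_symptoms"]).astype(int),
        "pruritus": (rng.random(n) < c["pruritus"]).astype(int),
        "leukocytes": np.round(rng.lognormal(c["leukocytes_logmed"],
                                             c["leukocytes_sigma"], n), 1),
        "platelets": np.round(rng.lognormal(c["platelets_logmed"],
                                            c["platelets_sigma"], n), 0),
        "neutrophil_lymphocyte_ratio": np.round(
            rng.lognormal(c["nlr_logmed"], c["nlr_sigma"], n), 2),
        "driver": np.where(exon12, "exon12", "V617F"),
        "driver_vaf": np.round(driver_vaf, 1),
    })


def _draw_event_time(rate, rng_exp, shape=None, scale=None):
    """Inverse-cumulative-hazard sampling; constant hazard unless Weibull."""
    if shape is None:
        with np.errstate(divide="ignore"):
            return np.where(rate > 0, rng_exp / rate, np.inf)
    # Weibull baseline: Lambda(t) = (t/scale)^shape * exp(lp) folded into rate
    with np.errstate(divide="ignore"):
        return np.where(rate > 0,
                        scale * np.divide(rng_exp, np.maximum(rate, 1e-300))
                        ** (1.0 / shape), np.inf)


def simulate_event_histories(covariates: pd.DataFrame, hazards: dict,
                             censoring: dict, seed) -> pd.DataFrame:
    """Per-patient illness-death outcomes by cause-specific hazard inversion.

    ``covariates`` columns are matched against the effect names in
    ``hazards['effects'][transition]``; the two competing 1->2 / 1->3 times
    are drawn first, and on transformation the 2->3 time is drawn
    clock-forward (left truncated at the transformation time for constant
    hazards this is memoryless). Administrative and exponential random
    censoring are applied last.
    """
    rng = np.random.default_rng(seed)
    n = len(covariates)

    def rate(transition):
        lam = hazards["baseline"][transition]
        lp = np.zeros(n)
        for name, beta in hazards["effects"].get(transition, {}).items():
            lp += beta * covariates[name].to_numpy(dtype=float)
        return lam * np.exp(lp)

    shape = hazards.get("weibull_shape")
    t12 = _draw_event_time(rate("1->2"), rng.exponential(size=n), shape, 1.0)
    t13 = _draw_event_time(rate("1->3"), rng.exponential(size=n), shape, 1.0)
    t23_extra = _draw_event_time(rate("2->3"), rng.exponential(size=n),
                                 shape, 1.0)

    transform_first = t12 < t13
    death_time = np.where(transform_first, t12 + t23_extra, t13)
    transform_time = np.where(transform_first, t12, np.inf)

    admin = censoring.get("admin_horizon", np.inf)
    drop_rate = censoring.get("dropout_rate", 0.0)
    drop = (rng.exponential(size=n) / drop_rate if drop_rate > 0
            else np.full(n, np.inf))
    censor = np.minimum(admin, drop)

    event_tr = transform_time < censor
    event_death = death_time <= censor

    out = pd.DataFrame(index=covariates.index)
    out["time_transformation"] = np.where(event_tr, transform_time, np.nan)
    out["event_transformation"] = event_tr.astype(int)
    out["time_death"] = np.where(event_death, death_time, np.nan)
    out["event_death"] = event_death.astype(int)
    out["time_censor"] = censor
    return out.round({"time_transformation": 6, "time_death": 6,
                      "time_censor": 6})


def group_effect_recovery(transition: str, hr_high: float | None = None,
                          hr_intermediate: float | None = None,
                          n_patients: int = 1500, n_reps: int = 100,
                          seed: int = 0, frac_high: float = 0.15,
                          frac_intermediate: float = 0.0,
                          baseline: dict | None = None,
                          censoring: dict | None = None) -> pd.DataFrame:
    """Parameter-recovery experiment for a genomic-group hazard effect.

    Simulates ``n_reps`` seeded illness-death cohorts with constant baseline
    hazards where the chosen ``transition``'s hazard is multiplied by
    ``hr_high`` for a ``frac_high`` high-risk group (and ``hr_intermediate``
    for a ``frac_intermediate`` intermediate group when given), fits the
    transition-specific Cox model per cohort, and returns one row per
    replicate with the fitted HRs and 95% Wald confidence bounds.
    """
    from .multistate import fit_cox_transition, to_multistate

    baseline = baseline or {"1->2": 0.012, "1->3": 0.03, "2->3": 0.20}
    censoring = censoring or {"admin_horizon": 15.0, "dropout_rate": 0.04}
    effects = {}
    covs = []
    if hr_high is not None:
        effects["group_high"] = float(np.log(hr_high))
        covs.append("group_high")
    if hr_intermediate is not None:
        effects["group_intermediate"] = float(np.log(hr_intermediate))
        covs.append("group_intermediate")
    if not covs:
        raise ValueError("need at least one group effect")
    hazards = {"baseline": baseline, "effects": {transition: effects}}

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_reps)
    rows = []
    for s in rep_seeds:
        r = np.random.default_rng(int(s))
        u = r.random(n_patients)
        high = u < frac_high
        inter = (u >= frac_high) & (u < frac_high + frac_intermediate)
        cov = pd.DataFrame({"group_high": high.astype(float),
                            "group_intermediate": inter.astype(float)})
        out = simulate_event_histories(cov, hazards, censoring,
                                       seed=int(s) + 1)
        clin = pd.concat([pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n_patients)]}),
            cov, out], axis=1)
        fit = fit_cox_transition(to_multistate(clin, covariates=covs),
                                 transition, covs)
        row = {}
        for c in covs:
            row[f"hr_{c}"] = float(fit.hazard_ratios_[c])
            row[f"lo_{c}"] = float(fit.confidence_intervals_.loc[c, "lower"])
            row[f"hi_{c}"] = float(fit.confidence_intervals_.loc[c, "upper"])
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(config: dict | None = None, seed: int = 0):
    """Full cohort: returns ``(variants, cnvs, clinical)`` DataFrames.

    Deterministic for a given (config, seed); random streams are split per
    component. Genomic group effects on the hazards are computed from the
    generated variants with the same sequential rules as the classifier, so
    the generating model and the analysis model agree.
    """
    from .riskclass import classify_pv_hmr
    from .cohort_io import filter_variants, prognostic_subset

    cfg = config or default_config()
    _validate_config(cfg)
    ss = np.random.SeedSequence(seed)
    s_mut, s_clin, s_out = ss.spawn(3)

    variants = simulate_mutations(cfg, np.random.default_rng(s_mut))
    cnvs = simulate_cnv(cfg, np.random.default_rng(s_mut.spawn(1)[0]))
    clinical = simulate_clinical_covariates(cfg, np.random.default_rng(s_clin),
                                            cnvs)

    # driver rows (one per patient; JAK2 always mutated)
    rng_d = np.random.default_rng(s_clin.spawn(1)[0])
    drivers = pd.DataFrame({
        "patient_id": clinical["patient_id"],
        "gene": "JAK2", "effect": "missense",
        "vaf": np.maximum(clinical["driver_vaf"], 2.0),
        "pathogenicity": "pathogenic", "pop_maf": 0.0, "is_driver": 1,
    })
    variants = (drivers.copy() if variants.empty
                else pd.concat([drivers, variants], ignore_index=True))

    # genomic group drives the hazards, exactly as the classifier defines it
    prog = prognostic_subset(filter_variants(variants))
    groups = classify_pv_hmr(prog, cnvs, clinical["patient_id"])
    gg = groups.set_index("patient_id")["genomic_group"].reindex(
        clinical["patient_id"]).to_numpy()
    cov = pd.DataFrame({
        "group_high": (gg == "high").astype(float),
        "group_intermediate": (gg == "intermediate").astype(float),
        "age_c": clinical["age_dx"].to_numpy() - cfg["clinical"]["age_median"],
    })
    outcomes = simulate_event_histories(cov, cfg["hazards"], cfg["censoring"],
                                        s_out)
    clinical = pd.concat([clinical.reset_index(drop=True),
                          outcomes.reset_index(drop=True)], axis=1)
    return variants, cnvs, clinical
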