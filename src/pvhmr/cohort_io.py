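"""Cohort tables: reading, validation, variant filtering and the mutation matrix.

The package works on three patient-level tab-separated tables:

``variants.tsv``
    one row per annotated somatic variant
    (patient_id, gene, effect, vaf, pathogenicity, pop_maf, is_driver)
``cnv.tsv``
    one row per copy-number / copy-neutral call (patient_id, region, kind)
``clinical.tsv``
    one row per patient with covariates and outcome times/indicators.

VAF and population MAF are stored in percent (0-100); all times are years
from diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger("pvhmr")

#: Genes of the default myeloid panel. The full capture panel is wider; these
#: are the genes that carry recurrent pathogenic variants in polycythemia vera
#: cohorts. Override through a YAML config (``panel.genes``).
DEFAULT_PANEL = (
    "JAK2", "TET2", "DNMT3A", "ASXL1", "SRSF2", "SF3B1", "U2AF1",
    "IDH1", "IDH2", "EZH2", "NFE2", "CBL", "TP53", "PPM1D", "BCOR",
)

EFFECTS = ("missense", "nonsense", "frameshift", "splice", "inframe")
TRUNCATING_EFFECTS = ("nonsense", "frameshift")
PATHOGENICITIES = ("pathogenic", "likely_pathogenic", "VUS")
CNV_REGIONS = ("1q", "5", "7", "8", "9p", "13q", "17p", "20q")
CNV_KINDS = ("UPD", "gain", "loss")

VARIANT_COLUMNS = ("patient_id", "gene", "effect", "vaf", "pathogenicity",
                   "pop_maf", "is_driver")
CNV_COLUMNS = ("patient_id", "region", "kind")
CLINICAL_COLUMNS = (
    "patient_id", "age_dx", "sex", "prior_arterial_thrombosis",
    "prior_venous_thrombosis", "constitutional_symptoms", "pruritus",
    "leukocytes", "platelets", "neutrophil_lymphocyte_ratio",
    "driver", "driver_vaf", "time_transformation", "event_transformation",
    "time_death", "event_death", "time_censor",
)


class CohortError(ValueError):
    """Fatal cohort-validation error; the message carries line numbers."""


@dataclass
class MutationMatrix:
    """Patients x gene-category mutation matrix after prognostic filtering.

    Attributes
    ----------
    presence : binary patients x categories DataFrame.
    max_vaf : same shape; per-category maximum VAF in percent (0 where absent).
    n_additional : per-patient count of retained non-driver variants.
        Counts variants, not categories: two TET2 hits contribute 2.
    """

    presence: pd.DataFrame
    max_vaf: pd.DataFrame
    n_additional: pd.Series

    @property
    def patients(self) -> pd.Index:
        return self.presence.index

    @property
    def categories(self) -> pd.Index:
        return self.presence.columns


def load_config(path: str | Path) -> dict:
    """Load a YAML analysis config (keys ``panel.genes``, ``filters.*``)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    filters = cfg.get("filters", {})
    for key, default in (("min_vaf", 2.0), ("common_maf", 1.0),
                         ("rare_vus_maf", 0.01)):
        filters.setdefault(key, default)
    cfg["filters"] = filters
    cfg.setdefault("panel", {}).setdefault("genes", list(DEFAULT_PANEL))
    return cfg


def _require_columns(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{name}: missing required column(s) {missing}")


def _line(df_index: int) -> int:
    # +2: 1-based counting plus the header row
    return int(df_index) + 2


def read_variants(path: str | Path, panel=DEFAULT_PANEL) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    _require_columns(df, VARIANT_COLUMNS, "variants")
    if len(df) == 0:
        return df

    bad_vaf = df.index[(df["vaf"] < 0) | (df["vaf"] > 100) | df["vaf"].isna()]
    if len(bad_vaf):
        raise CohortError(
            f"variants: vaf outside [0,100] at line {_line(bad_vaf[0])}")
    bad_maf = df.index[(df["pop_maf"] < 0) | (df["pop_maf"] > 100)]
    if len(bad_maf):
        raise CohortError(
            f"variants: pop_maf outside [0,100] at line {_line(bad_maf[0])}")
    bad_eff = df.index[~df["effect"].isin(EFFECTS)]
    if len(bad_eff):
        raise CohortError(
            f"variants: unknown effect {df.loc[bad_eff[0], 'effect']!r} "
            f"at line {_line(bad_eff[0])}")
    bad_path = df.index[~df["pathogenicity"].isin(PATHOGENICITIES)]
    if len(bad_path):
        raise CohortError(
            f"variants: unknown pathogenicity at line {_line(bad_path[0])}")

    unknown = ~df["gene"].isin(panel)
    if unknown.any():
        n = int(unknown.sum())
        logger.warning("variants: dropped %d row(s) with genes outside the "
                       "panel: %s", n, sorted(df.loc[unknown, "gene"].unique()))
        df = df.loc[~unknown].reset_index(drop=True)
    df["is_driver"] = df["is_driver"].astype(int).astype(bool)
    return df


def read_cnv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    _require_columns(df, CNV_COLUMNS, "cnv")
    if len(df) == 0:
        return df
    df["region"] = df["region"].astype(str)
    bad = df.index[~df["region"].isin(CNV_REGIONS)]
    if len(bad):
        raise CohortError(
            f"cnv: unknown region {df.loc[bad[0], 'region']!r} at line "
            f"{_line(bad[0])} (expected one of {CNV_REGIONS})")
    bad = df.index[~df["kind"].isin(CNV_KINDS)]
    if len(bad):
        raise CohortError(f"cnv: unknown kind at line {_line(bad[0])}")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    _require_columns(df, CLINICAL_COLUMNS, "clinical")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortError(f"clinical: duplicated patient_id {dup!r}")
    for flag in ("prior_arterial_thrombosis", "prior_venous_thrombosis",
                 "constitutional_symptoms", "pruritus",
                 "event_transformation", "event_death"):
        df[flag] = df[flag].fillna(0).astype(int)
    validate_clinical(df)
    return df


def validate_clinical(df: pd.DataFrame) -> None:
    """Check outcome-time invariants; raise CohortError with line numbers."""
    for col in ("time_transformation", "time_death", "time_censor", "age_dx"):
        neg = df.index[(df[col] < 0).fillna(False)]
        if len(neg):
            raise CohortError(
                f"clinical: negative {col} at line {_line(neg[0])}")
    limit = df[["time_death", "time_censor"]].min(axis=1, skipna=True)
    transformed = df["event_transformation"].astype(bool)
    bad = df.index[transformed & df["time_transformation"].isna()]
    if len(bad):
        raise CohortError(
            "clinical: event_transformation=1 without time_transformation "
            f"at line {_line(bad[0])}")
    bad = df.index[transformed & (df["time_transformation"] > limit + 1e-12)]
    if len(bad):
        raise CohortError(
            "clinical: event_transformation=1 but time_transformation exceeds "
            f"min(time_death, time_censor) at line {_line(bad[0])}")
    dead = df["event_death"].astype(bool)
    bad = df.index[dead & df["time_death"].isna()]
    if len(bad):
        raise CohortError(
            f"clinical: event_death=1 without time_death at line {_line(bad[0])}")


def read_cohort(variant_path, cnv_path, clinical_path, panel=DEFAULT_PANEL):
    """Read and validate the three cohort tables.

    Returns ``(variants, cnvs, clinical)`` DataFrames. Patients referenced by
    the variant or CNV table must exist in the clinical table.
    """
    variants = read_variants(variant_path, panel=panel)
    cnvs = read_cnv(cnv_path)
    clinical = read_clinical(clinical_path)
    known = set(clinical["patient_id"])
    for name, df in (("variants", variants), ("cnv", cnvs)):
        if len(df):
            orphan = ~df["patient_id"].isin(known)
            if orphan.any():
                idx = df.index[orphan][0]
                raise CohortError(
                    f"{name}: patient {df.loc[idx, 'patient_id']!r} at line "
                    f"{_line(idx)} absent from the clinical table")
    return variants, cnvs, clinical


def filter_variants(variants: pd.DataFrame, min_vaf: float = 2.0,
                    common_maf: float = 1.0,
                    rare_vus_maf: float = 0.01) -> pd.DataFrame:
    """Apply the variant-retention rules, preserving row order.

    A variant is retained when its VAF is at least ``min_vaf`` percent, it is
    not a common polymorphism (population MAF >= ``common_maf`` percent), and —
    if it is a VUS — its population MAF is below ``rare_vus_maf`` percent
    (VUS at or above that frequency are treated as rare polymorphisms).
    All three thresholds are inclusive on the removal side of >=.
    """
    if len(variants) == 0:
        return variants.copy()
    keep = (variants["vaf"] >= min_vaf)
    keep &= ~(variants["pop_maf"] >= common_maf)
    keep &= ~((variants["pathogenicity"] == "VUS")
              & (variants["pop_maf"] >= rare_vus_maf))
    n_before, n_after = len(variants), int(keep.sum())
    logger.info("filter_variants: retained %d/%d variants", n_after, n_before)
    return variants.loc[keep].copy()


def prognostic_subset(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep pathogenic / likely-pathogenic variants only.

    Drivers (canonical JAK2) remain in the output but are flagged and are
    excluded later from 'additional mutation' counts and matrix categories.
    """
    if len(variants) == 0:
        return variants.copy()
    keep = variants["pathogenicity"].isin(("pathogenic", "likely_pathogenic"))
    return variants.loc[keep].copy()


def _category(gene: str, effect: str, split_genes) -> str:
    if gene in split_genes:
        kind = "truncating" if effect in TRUNCATING_EFFECTS else "missense"
        return f"{gene}_{kind}"
    return gene


def build_mutation_matrix(variants: pd.DataFrame, patients,
                          split_effect_genes=("TET2", "DNMT3A"),
                          min_patients: int = 0) -> MutationMatrix:
    """Build the patients x gene-category matrix from prognostic variants.

    Category VAF is the maximum VAF over the patient's variants in that
    category (clone-size interpretation). Categories mutated in fewer than
    ``min_patients`` patients are dropped. ``n_additional`` counts retained
    non-driver variants per patient and is unaffected by the category filter.
    """
    patients = pd.Index(patients, name="patient_id").astype(str)
    if patients.has_duplicates:
        raise CohortError("build_mutation_matrix: duplicated patient ids")
    nondriver = variants.loc[~variants["is_driver"].astype(bool)].copy()
    if len(nondriver):
        missing = set(nondriver["patient_id"].astype(str)) - set(patients)
        if missing:
            raise CohortError(
                f"build_mutation_matrix: variant patients {sorted(missing)} "
                "absent from the patient list")

    n_additional = pd.Series(0, index=patients, name="n_additional")
    if len(nondriver):
        counts = nondriver.groupby(nondriver["patient_id"].astype(str)).size()
        n_additional = n_additional.add(counts, fill_value=0).astype(int)
        n_additional = n_additional.reindex(patients, fill_value=0)

    if len(nondriver) == 0:
        empty = pd.DataFrame(index=patients, dtype=float)
        return MutationMatrix(empty.astype(int), empty.astype(float),
                              n_additional)

    nondriver["category"] = [
        _category(g, e, split_effect_genes)
        for g, e in zip(nondriver["gene"], nondriver["effect"])
    ]
    max_vaf = (nondriver.pivot_table(index=nondriver["patient_id"].astype(str),
                                     columns="category", values="vaf",
                                     aggfunc="max")
               .reindex(patients).fillna(0.0))
    max_vaf = max_vaf[sorted(max_vaf.columns)]
    presence = (max_vaf > 0).astype(int)
    if min_patients > 0:
        keep = presence.sum(axis=0) >= min_patients
        presence, max_vaf = presence.loc[:, keep], max_vaf.loc[:, keep]
    return MutationMatrix(presence, max_vaf, n_additional)


def write_tables(out_dir, variants=None, cnvs=None, clinical=None,
                 **named_frames) -> dict:
    """Write DataFrames as TSV under ``out_dir``; returns {name: path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = dict(named_frames)
    if variants is not None:
        frames["variants"] = variants
    if cnvs is not None:
        frames["cnv"] = cnvs
    if clinical is not None:
        frames["clinical"] = clinical
    paths = {}
    for name, df in frames.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
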