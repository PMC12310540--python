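"""Genomic risk classification.

The 3-tier PV-HMR classifier assigns each polycythemia vera patient to one of
three groups by sequential rules over the prognostic (pathogenic /
likely-pathogenic, VAF-filtered) non-driver variants and CNV calls:

``high``
    any mutation in the high-molecular-risk genes (SRSF2, IDH1, IDH2, EZH2,
    NFE2 by default), OR two or more additional (non-driver) mutations, OR at
    least one CNV outside chromosome 9;
``intermediate``
    otherwise, a TET2 mutation with VAF >= 5%;
``low``
    everything else. The canonical JAK2 driver never counts toward any rule.

A generic, config-driven points engine (:class:`RuleBasedScore`) hosts the
IWG-PV and MIPSS-PV comparator scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

DEFAULT_HMR_GENES = ("SRSF2", "IDH1", "IDH2", "EZH2", "NFE2")
GROUPS = ("low", "intermediate", "high")


def genomic_features(variants: pd.DataFrame, cnvs: pd.DataFrame,
                     patients) -> pd.DataFrame:
    """Per-patient features consumed by :class:`PVHMRClassifier`.

    ``variants`` must already be the prognostic subset. Columns of the
    result: ``n_additional``, ``max_tet2_vaf``, ``has_non9_cnv`` and one
    ``has_<GENE>`` indicator per mutated gene.
    """
    patients = pd.Index(pd.Series(patients).astype(str), name="patient_id")
    feats = pd.DataFrame(index=patients)
    nondriver = variants.loc[~variants["is_driver"].astype(bool)] \
        if len(variants) else variants
    counts = pd.Series(0, index=patients, dtype=int)
    tet2 = pd.Series(0.0, index=patients)
    if len(nondriver):
        pid = nondriver["patient_id"].astype(str)
        counts = counts.add(nondriver.groupby(pid).size(), fill_value=0)
        t = nondriver.loc[nondriver["gene"] == "TET2"]
        if len(t):
            tet2 = tet2.add(t.groupby(t["patient_id"].astype(str))["vaf"].max(),
                            fill_value=0.0)
        for gene in sorted(nondriver["gene"].unique()):
            pats = set(nondriver.loc[nondriver["gene"] == gene,
                                     "patient_id"].astype(str))
            feats[f"has_{gene}"] = [int(p in pats) for p in patients]
    feats["n_additional"] = counts.reindex(patients, fill_value=0).astype(int)
    feats["max_tet2_vaf"] = tet2.reindex(patients, fill_value=0.0)
    non9 = pd.Series(0, index=patients, dtype=int)
    if cnvs is not None and len(cnvs):
        pats = set(cnvs.loc[cnvs["region"] != "9p", "patient_id"].astype(str))
        non9 = pd.Series([int(p in pats) for p in patients], index=patients)
    feats["has_non9_cnv"] = non9
    return feats


class PVHMRClassifier(BaseEstimator):
    """Sequential 3-tier genomic classifier (high / intermediate / low).

    Stateless rule set: ``fit`` only validates parameters. ``predict`` takes
    the feature frame from :func:`genomic_features` and returns the group per
    patient; ``predict_frame`` adds the triggering rule and the feature
    columns, matching the ``groups.tsv`` output layout.
    """

    def __init__(self, hmr_genes=DEFAULT_HMR_GENES,
                 tet2_vaf_threshold: float = 5.0,
                 n_additional_threshold: int | None = 2,
                 use_cnv_rule: bool = True):
        self.hmr_genes = hmr_genes
        self.tet2_vaf_threshold = tet2_vaf_threshold
        self.n_additional_threshold = n_additional_threshold
        self.use_cnv_rule = use_cnv_rule

    def fit(self, X=None, y=None):
        if self.tet2_vaf_threshold is not None and self.tet2_vaf_threshold < 0:
            raise ValueError("tet2_vaf_threshold must be >= 0")
        self.is_fitted_ = True
        return self

    def predict_frame(self, features: pd.DataFrame) -> pd.DataFrame:
        groups, triggers = [], []
        hmr_cols = [f"has_{g}" for g in self.hmr_genes]
        for _, row in features.iterrows():
            has_hmr = any(bool(row.get(c, 0)) for c in hmr_cols)
            many = (self.n_additional_threshold is not None
                    and row["n_additional"] >= self.n_additional_threshold)
            cnv = self.use_cnv_rule and bool(row.get("has_non9_cnv", 0))
            if has_hmr:
                groups.append("high"); triggers.append("hmr_gene")
            elif many:
                groups.append("high"); triggers.append("n_additional")
            elif cnv:
                groups.append("high"); triggers.append("non9_cnv")
            elif (np.isfinite(self.tet2_vaf_threshold)
                  and row.get("max_tet2_vaf", 0.0) >= self.tet2_vaf_threshold):
                groups.append("intermediate"); triggers.append("tet2_vaf")
            else:
                groups.append("low"); triggers.append("none")
        out = features.copy()
        out["genomic_group"] = pd.Categorical(groups, categories=GROUPS,
                                              ordered=True)
        out["trigger_rule"] = triggers
        return out

    def predict(self, features: pd.DataFrame) -> pd.Series:
        return self.predict_frame(features)["genomic_group"]


def classify_pv_hmr(variants: pd.DataFrame, cnvs: pd.DataFrame, patients,
                    hmr_genes=DEFAULT_HMR_GENES,
                    tet2_vaf_threshold: float = 5.0) -> pd.DataFrame:
    """Classify every patient; returns the ``groups.tsv`` frame."""
    feats = genomic_features(variants, cnvs, patients)
    clf = PVHMRClassifier(hmr_genes=hmr_genes,
                          tet2_vaf_threshold=tet2_vaf_threshold).fit()
    out = clf.predict_frame(feats)
    cols = ["n_additional", "max_tet2_vaf", "has_non9_cnv",
            "genomic_group", "trigger_rule"]
    return out[cols].reset_index()


# ---------------------------------------------------------------------------
# Generic rule-based comparator scores (IWG-PV, MIPSS-PV, ...)
# ---------------------------------------------------------------------------

_OPS = {
    "ge": lambda x, v: x >= v,
    "gt": lambda x, v: x > v,
    "le": lambda x, v: x <= v,
    "lt": lambda x, v: x < v,
    "eq": lambda x, v: x == v,
    "in_range": lambda x, v: (x >= v[0]) & (x < v[1]),
}


@dataclass
class ScoreConfig:
    """A named points-based score: criteria over patient fields + cut-points."""

    name: str
    criteria: list      # [{field, op, value, points}, ...]
    cutpoints: list     # [{min_points, category}, ...] strictly increasing

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(name=raw["name"], criteria=raw.get("criteria", []),
                   cutpoints=raw["cutpoints"])

    def validate(self, known_fields) -> None:
        for crit in self.criteria:
            if crit["field"] not in known_fields:
                raise ValueError(
                    f"score {self.name!r}: unknown field {crit['field']!r}")
            if crit.get("op", "ge") not in _OPS:
                raise ValueError(
                    f"score {self.name!r}: unknown op {crit.get('op')!r}")
        mins = [c["min_points"] for c in self.cutpoints]
        if mins != sorted(mins) or len(set(mins)) != len(mins):
            raise ValueError(
                f"score {self.name!r}: cut-points must be strictly increasing")
        if len(self.cutpoints) < 2:
            raise ValueError(f"score {self.name!r}: need >= 2 categories")


class RuleBasedScore(BaseEstimator):
    """Points engine over patient-level fields, bucketed into categories.

    ``predict`` returns the category per patient; rows with a missing value in
    any referenced field get ``"unevaluable"``. ``transform`` returns the raw
    point totals.
    """

    def __init__(self, config: ScoreConfig | None = None):
        self.config = config

    def fit(self, X: pd.DataFrame, y=None):
        if self.config is None:
            raise ValueError("RuleBasedScore needs a ScoreConfig")
        self.config.validate(set(X.columns))
        self.fields_ = sorted({c["field"] for c in self.config.criteria})
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        pts = pd.Series(0.0, index=X.index)
        for crit in self.config.criteria:
            field = X[crit["field"]]
            hit = _OPS[crit.get("op", "ge")](field, crit["value"])
            pts = pts + hit.fillna(False).astype(float) * crit["points"]
        return pts

    def predict(self, X: pd.DataFrame) -> pd.Series:
        pts = self.transform(X)
        cats = []
        order = sorted(self.config.cutpoints, key=lambda c: c["min_points"])
        missing = X[self.fields_].isna().any(axis=1) if self.fields_ \
            else pd.Series(False, index=X.index)
        for total, miss in zip(pts, missing):
            if miss:
                cats.append("unevaluable")
                continue
            cat = order[0]["category"]
            for cp in order:
                if total >= cp["min_points"]:
                    cat = cp["category"]
            cats.append(cat)
        return pd.Series(cats, index=X.index, name=self.config.name)


def score_rule_based(patients: pd.DataFrame, config: ScoreConfig) -> pd.Series:
    """Apply a points-based score config to a patient table."""
    return RuleBasedScore(config).fit(patients).predict(patients)
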