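"""Mutation-landscape analyses.

Per-gene mutation summaries, pairwise mutation-mutation and mutation-clinical
association tests with Benjamini-Hochberg correction, Bayesian-network
structure learning over gene co-occurrence (BIC hill-climbing with bootstrap
edge confidence), and hierarchical clustering of genes by VAF profile.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cohort_io import MutationMatrix, TRUNCATING_EFFECTS

logger = logging.getLogger("pvhmr")


# ---------------------------------------------------------------------------
# Landscape summaries
# ---------------------------------------------------------------------------

def summarize_landscape(matrix: MutationMatrix, variants: pd.DataFrame | None = None,
                        cnvs: pd.DataFrame | None = None) -> dict:
    """Cohort-level mutation summary.

    Returns a dict with

    ``n_patients``
    ``n_additional_distribution`` : count of patients by number of additional
        (non-driver, retained) mutations, with bins 0, 1, 2 and ``3+``.
    ``pct_additional`` : the same bins as percentages of all patients, to one
        decimal, plus ``ge1`` and ``ge2`` (``ge2`` is the sum of the rounded
        2 and 3+ bins, which is how such headline figures are quoted).
    ``category_counts`` : mutated-patient count per gene category.
    ``effect_counts`` : per gene, number of variants by truncating vs SNV
        (requires ``variants``).
    ``multiple_per_gene`` : patients carrying >=2 variants of the same gene.
    ``isolated_pct`` : per gene, percent of its mutated patients whose only
        additional mutations are in that gene.
    ``cnv`` : per-region counts and percentages over patients with CNV data
        (requires ``cnvs``; a patient with no row counts as CNV-evaluated
        only if present in ``cnvs.attrs['evaluated']`` — otherwise the
        denominator is all cohort patients).
    """
    n = len(matrix.patients)
    summary: dict = {"n_patients": n}

    n_add = matrix.n_additional
    dist = {
        "0": int((n_add == 0).sum()),
        "1": int((n_add == 1).sum()),
        "2": int((n_add == 2).sum()),
        "3+": int((n_add >= 3).sum()),
    }
    summary["n_additional_distribution"] = dist
    if n > 0:
        pct = {k: round(100.0 * v / n, 1) for k, v in dist.items()}
        pct["ge1"] = round(100.0 * int((n_add >= 1).sum()) / n, 1)
        pct["ge2"] = round(pct["2"] + pct["3+"], 1)
    else:
        pct = {k: 0.0 for k in ("0", "1", "2", "3+", "ge1", "ge2")}
    summary["pct_additional"] = pct
    summary["category_counts"] = matrix.presence.sum(axis=0).to_dict()

    if variants is not None and len(variants):
        nondriver = variants.loc[~variants["is_driver"].astype(bool)]
        eff = {}
        for gene, grp in nondriver.groupby("gene"):
            trunc = int(grp["effect"].isin(TRUNCATING_EFFECTS).sum())
            eff[gene] = {"truncating": trunc, "snv": len(grp) - trunc}
        summary["effect_counts"] = eff

        per = nondriver.groupby([nondriver["patient_id"].astype(str), "gene"]).size()
        multi = per[per >= 2].reset_index().groupby("gene")["patient_id"].nunique()
        summary["multiple_per_gene"] = {
            g: {"n": int(c), "pct": round(100.0 * c / n, 1) if n else 0.0}
            for g, c in multi.items()
        }

        gene_patients = nondriver.groupby("gene")["patient_id"].apply(
            lambda s: set(s.astype(str)))
        counts = nondriver.groupby(nondriver["patient_id"].astype(str)).size()
        other = {}
        for gene, pats in gene_patients.items():
            own = nondriver.loc[nondriver["gene"] == gene]
            own_counts = own.groupby(own["patient_id"].astype(str)).size()
            isolated = sum(1 for p in pats if counts[p] == own_counts[p])
            other[gene] = {"n_mutated": len(pats), "n_isolated": isolated,
                           "pct_isolated": round(100.0 * isolated / len(pats), 1)}
        summary["isolated_pct"] = other

    if cnvs is not None:
        evaluated = cnvs.attrs.get("evaluated")
        denom = len(evaluated) if evaluated is not None else n
        out = {}
        if len(cnvs):
            for region, grp in cnvs.groupby("region"):
                c = grp["patient_id"].nunique()
                out[str(region)] = {"n": int(c), "denominator": denom,
                                    "pct": round(100.0 * c / denom, 1) if denom else 0.0}
            non9 = cnvs.loc[cnvs["region"] != "9p", "patient_id"].nunique()
        else:
            non9 = 0
        out["non_9p_any"] = {"n": int(non9), "denominator": denom,
                             "pct": round(100.0 * non9 / denom, 1) if denom else 0.0}
        summary["cnv"] = out
    return summary


# ---------------------------------------------------------------------------
# Pairwise associations + multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _is_binary(x: pd.Series) -> bool:
    vals = set(pd.unique(x.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def _assoc_one(a: pd.Series, b: pd.Series) -> dict:
    """One pairwise test on pairwise-complete observations."""
    ok = a.notna() & b.notna()
    a, b = a[ok].astype(float), b[ok].astype(float)
    row = {"estimate": np.nan, "p_value": 1.0, "direction": "undefined",
           "degenerate": False, "n": int(ok.sum())}
    if len(a) == 0:
        row["degenerate"] = True
        return row
    bin_a, bin_b = _is_binary(a), _is_binary(b)
    if bin_a and bin_b:
        row["statistic_kind"] = "odds_ratio"
        if a.nunique() < 2 or b.nunique() < 2:
            row["degenerate"] = True
            return row
        table = pd.crosstab(a, b).reindex(index=[0, 1], columns=[0, 1],
                                          fill_value=0).to_numpy()
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        row.update(estimate=float(odds), p_value=float(p),
                   direction="positive" if odds > 1
                   else ("negative" if odds < 1 else "undefined"))
    elif bin_a or bin_b:
        flag, value = (a, b) if bin_a else (b, a)
        row["statistic_kind"] = "mean_shift"
        g0, g1 = value[flag == 0], value[flag == 1]
        if len(g0) == 0 or len(g1) == 0 or value.nunique() < 2:
            row["degenerate"] = True
            return row
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided")
        shift = float(np.median(g1) - np.median(g0))
        row.update(estimate=shift, p_value=float(res.pvalue),
                   direction="positive" if shift > 0
                   else ("negative" if shift < 0 else "undefined"))
    else:
        row["statistic_kind"] = "rank_correlation"
        if a.nunique() < 2 or b.nunique() < 2:
            row["degenerate"] = True
            return row
        rho, p = stats.spearmanr(a, b)
        row.update(estimate=float(rho), p_value=float(p),
                   direction="positive" if rho > 0
                   else ("negative" if rho < 0 else "undefined"))
    if not np.isfinite(row["p_value"]):
        # too few pairwise-complete observations for a defined test
        row.update(p_value=1.0, degenerate=True)
    return row


def pairwise_association(matrix: MutationMatrix, clinical: pd.DataFrame,
                         features, mutation_features=None,
                         report_alpha: float = 0.05) -> pd.DataFrame:
    """Mutation x clinical and mutation x mutation association table.

    Binary x binary pairs use the two-sided Fisher exact test with an odds
    ratio; binary x continuous use the two-sided Mann-Whitney test with the
    median shift as direction; continuous x continuous (VAF-VAF) use Spearman
    rank correlation. q-values are BH-adjusted over the whole table. Rows
    with ``p < report_alpha`` carry ``reported=True``; degenerate pairs
    (constant margins) are emitted with p = 1 and ``degenerate=True``.
    """
    clin = clinical.set_index(clinical["patient_id"].astype(str)) \
        if "patient_id" in clinical else clinical
    clin = clin.reindex(matrix.patients)
    muts = list(mutation_features) if mutation_features is not None \
        else list(matrix.categories)

    rows = []
    for cat, feat in itertools.product(muts, features):
        r = _assoc_one(matrix.presence[cat].astype(float), clin[feat])
        rows.append({"feature_a": cat, "feature_b": feat, **r})
    for ca, cb in itertools.combinations(muts, 2):
        r = _assoc_one(matrix.max_vaf[ca].replace(0, np.nan),
                       matrix.max_vaf[cb].replace(0, np.nan))
        pres = _assoc_one(matrix.presence[ca].astype(float),
                          matrix.presence[cb].astype(float))
        rows.append({"feature_a": ca, "feature_b": cb, **pres})
        r["statistic_kind"] = "rank_correlation"
        rows.append({"feature_a": f"{ca}:vaf", "feature_b": f"{cb}:vaf", **r})

    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["reported"] = table["p_value"] < report_alpha
    return table


# ---------------------------------------------------------------------------
# Bayesian-network structure learning
# ---------------------------------------------------------------------------

def _local_bic(x: np.ndarray, parents: np.ndarray | None, n: int) -> float:
    """BIC contribution of one Bernoulli node with tabular conditionals.

    ``loglik - (k/2) log n`` with one free parameter per parent configuration.
    """
    if parents is None or parents.shape[1] == 0:
        k1 = x.sum()
        k0 = x.size - k1
        ll = 0.0
        for c, tot in ((k1, x.size), (k0, x.size)):
            if c > 0:
                ll += c * np.log(c / tot)
        return ll - 0.5 * np.log(n)
    # encode parent configuration as an integer
    code = parents @ (1 << np.arange(parents.shape[1]))
    ll = 0.0
    n_cfg = 0
    for cfg in np.unique(code):
        sel = x[code == cfg]
        k1 = sel.sum()
        k0 = sel.size - k1
        for c in (k1, k0):
            if c > 0:
                ll += c * np.log(c / sel.size)
        n_cfg += 1
    # penalise all representable configurations, not only observed ones
    return ll - 0.5 * (2 ** parents.shape[1]) * np.log(n)


class GeneNetworkLearner(BaseEstimator):
    """Score-based Bayesian-network learner for binary mutation indicators.

    Greedy hill-climbing over single-edge additions, deletions and reversals,
    maximizing the BIC of Bernoulli nodes with tabular conditional
    distributions; seeded restarts; bootstrap resampling for skeleton edge
    confidence. Deterministic given ``random_state``.

    Parameters
    ----------
    min_patients : drop categories mutated in fewer patients than this.
    n_boot : bootstrap resamples for edge confidence.
    n_restarts : random restarts (random edge perturbations of the empty
        start graph) per structure search.
    random_state : seed; mandatory for reproducibility.

    Attributes (after ``fit``)
    ----------
    nodes_, edges_ : selected DAG; ``edges_`` is a sorted list of (u, v).
    confidence_ : {frozenset skeleton edge: bootstrap fraction}.
    score_ : BIC of the selected structure.
    """

    def __init__(self, min_patients: int = 7, n_boot: int = 50,
                 n_restarts: int = 5, random_state: int = 0):
        self.min_patients = min_patients
        self.n_boot = n_boot
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- search machinery ---------------------------------------------------
    def _score_node(self, data, node, parents, cache):
        key = (node, tuple(sorted(parents)))
        if key not in cache:
            cols = sorted(parents)
            pmat = data[:, cols] if cols else None
            cache[key] = _local_bic(data[:, node], pmat, data.shape[0])
        return cache[key]

    def _hill_climb(self, data, n_nodes, rng):
        best_dag, best_score = None, -np.inf
        for restart in range(max(1, self.n_restarts)):
            parents = [set() for _ in range(n_nodes)]
            if restart > 0:
                for _ in range(rng.integers(1, n_nodes + 1)):
                    u, v = rng.choice(n_nodes, size=2, replace=False)
                    if not self._creates_cycle(parents, int(u), int(v)):
                        parents[int(v)].add(int(u))
            cache: dict = {}
            score = sum(self._score_node(data, v, parents[v], cache)
                        for v in range(n_nodes))
            improved = True
            while improved:
                improved = False
                best_move, best_delta = None, 1e-10
                for u, v in itertools.permutations(range(n_nodes), 2):
                    if u in parents[v]:
                        # deletion
                        new = parents[v] - {u}
                        delta = (self._score_node(data, v, new, cache)
                                 - self._score_node(data, v, parents[v], cache))
                        move = ("del", u, v)
                        if self._better(delta, move, best_delta, best_move):
                            best_move, best_delta = move, delta
                        # reversal u->v  =>  v->u
                        if not self._creates_cycle(
                                [p - {u} if i == v else p
                                 for i, p in enumerate(parents)], v, u):
                            d = (self._score_node(data, v, parents[v] - {u}, cache)
                                 - self._score_node(data, v, parents[v], cache)
                                 + self._score_node(data, u, parents[u] | {v}, cache)
                                 - self._score_node(data, u, parents[u], cache))
                            move = ("rev", u, v)
                            if self._better(d, move, best_delta, best_move):
                                best_move, best_delta = move, d
                    else:
                        if self._creates_cycle(parents, u, v):
                            continue
                        delta = (self._score_node(data, v, parents[v] | {u}, cache)
                                 - self._score_node(data, v, parents[v], cache))
                        move = ("add", u, v)
                        if self._better(delta, move, best_delta, best_move):
                            best_move, best_delta = move, delta
                if best_move is not None:
                    op, u, v = best_move
                    if op == "add":
                        parents[v].add(u)
                    elif op == "del":
                        parents[v].discard(u)
                    else:
                        parents[v].discard(u)
                        parents[u].add(v)
                    score += best_delta
                    improved = True
            if score > best_score + 1e-12 or best_dag is None:
                best_dag, best_score = [set(p) for p in parents], score
        return best_dag, best_score

    @staticmethod
    def _better(delta, move, best_delta, best_move):
        if delta > best_delta + 1e-12:
            return True
        # lexicographic tie-break between equal-score moves
        if best_move is not None and abs(delta - best_delta) <= 1e-12:
            return move < best_move
        return False

    @staticmethod
    def _creates_cycle(parents, u, v) -> bool:
        """Would adding u -> v create a cycle? (is u reachable from v)"""
        stack, seen = [u], set()
        while stack:
            node = stack.pop()
            if node == v:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(parents[node])
        return False

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        """Learn the structure from a binary patients x categories DataFrame."""
        X = pd.DataFrame(X)
        keep = X.sum(axis=0) >= self.min_patients
        X = X.loc[:, keep]
        X = X[sorted(X.columns, key=str)]
        self.nodes_ = [str(c) for c in X.columns]
        self.confidence_ = {}
        self.edges_ = []
        self.score_ = 0.0
        if len(self.nodes_) < 2:
            logger.warning("learn_network: fewer than 2 qualifying categories"
                           " — returning an empty network")
            return self

        data = X.to_numpy(dtype=np.int8)
        rng = np.random.default_rng(self.random_state)
        dag, self.score_ = self._hill_climb(data, len(self.nodes_), rng)
        self.edges_ = sorted(
            (self.nodes_[u], self.nodes_[v])
            for v, ps in enumerate(dag) for u in ps)

        boot_counts: dict = {}
        n = data.shape[0]
        for _ in range(self.n_boot):
            idx = rng.integers(0, n, size=n)
            bdag, _ = self._hill_climb(data[idx], len(self.nodes_), rng)
            seen = set()
            for v, ps in enumerate(bdag):
                for u in ps:
                    seen.add(frozenset((self.nodes_[u], self.nodes_[v])))
            for e in seen:
                boot_counts[e] = boot_counts.get(e, 0) + 1
        self.confidence_ = {e: c / self.n_boot
                            for e, c in boot_counts.items()} if self.n_boot else {}
        return self

    def graph_(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(getattr(self, "nodes_", []))
        g.add_edges_from(getattr(self, "edges_", []))
        return g


def learn_network(matrix: MutationMatrix, min_patients: int = 7,
                  n_boot: int = 50, seed: int = 0) -> GeneNetworkLearner:
    """Fit a :class:`GeneNetworkLearner` on the presence matrix."""
    return GeneNetworkLearner(min_patients=min_patients, n_boot=n_boot,
                              random_state=seed).fit(matrix.presence)


# ---------------------------------------------------------------------------
# Hierarchical clustering of genes
# ---------------------------------------------------------------------------

class GeneClusterer(BaseEstimator):
    """Average-linkage clustering of gene categories by VAF profile.

    Distance between two categories is ``1 - |Spearman rho|`` of their VAF
    columns (zeros treated as absent). Constant or empty columns get distance
    1 to all others and are flagged. Column order is fixed lexicographically
    so ties resolve deterministically.
    """

    def __init__(self, n_clusters: int | None = None):
        self.n_clusters = n_clusters

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("clustering needs at least 2 categories")
        cols = sorted(X.columns, key=str)
        X = X[cols]
        self.categories_ = [str(c) for c in cols]
        m = len(cols)
        dist = np.ones((m, m))
        np.fill_diagonal(dist, 0.0)
        self.degenerate_ = []
        arr = X.to_numpy(dtype=float)
        const = [np.nanstd(arr[:, j]) == 0 or np.all(np.isnan(arr[:, j]))
                 for j in range(m)]
        self.degenerate_ = [self.categories_[j] for j in range(m) if const[j]]
        for i, j in itertools.combinations(range(m), 2):
            if const[i] or const[j]:
                continue
            rho = stats.spearmanr(arr[:, i], arr[:, j]).statistic
            if np.isnan(rho):
                continue
            dist[i, j] = dist[j, i] = 1.0 - abs(rho)
        self.distance_ = dist
        self.linkage_ = hierarchy.average(squareform(dist, checks=False))
        k = self.n_clusters
        if k is None:
            # cut mid-tree: halfway up the final merge height
            cut = self.linkage_[-1, 2] / 2.0 if m > 1 else 0.0
            self.labels_ = hierarchy.fcluster(self.linkage_, cut,
                                              criterion="distance")
        else:
            self.labels_ = hierarchy.fcluster(self.linkage_, k,
                                              criterion="maxclust")
        return self


def cluster_genes(matrix: MutationMatrix,
                  n_clusters: int | None = None) -> GeneClusterer:
    """Cluster gene categories on their per-patient maximum-VAF profiles."""
    return GeneClusterer(n_clusters=n_clusters).fit(matrix.max_vaf)
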