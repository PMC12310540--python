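"""Time-dependent prognostic performance metrics.

Harrell's concordance index (0.5 credit for risk ties), the Graf-style IPCW
Brier score, and the cumulative/dynamic IPCW AUC, plus a multi-model
comparison table over the endpoints {overall survival, hematologic
transformation} at the 6/10/14-year horizons. Censoring weights come from the
Kaplan-Meier estimate of the censoring distribution G(t) on the whole sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .multistate import SurvivalCurve, kaplan_meier

HORIZONS = (6.0, 10.0, 14.0)
ENDPOINTS = ("overall_survival", "transformation")


def censoring_km(times, status) -> SurvivalCurve:
    """Kaplan-Meier of the censoring distribution G(t).

    Censorings are the 'events' here; true events act as censorings of the
    censoring time. At tied times true events are processed first, so event
    subjects at t remain in G's risk set at t: G keeps the standard
    Graf convention where an event at t uses G(t-).
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    order = np.argsort(times, kind="stable")
    t, d = times[order], status[order]
    uniq = np.unique(t)
    n = t.size
    surv, jump_t = [], []
    g = 1.0
    for u in uniq:
        at_risk = np.sum(t >= u)
        n_cens = np.sum((t == u) & (d == 0))
        n_ev = np.sum((t == u) & (d == 1))
        # events first: censorings at u face the risk set minus events at u
        denom = at_risk - n_ev
        if n_cens > 0 and denom > 0:
            g *= 1.0 - n_cens / denom
        jump_t.append(u)
        surv.append(g)
    return SurvivalCurve(np.asarray(jump_t), np.asarray(surv), label="G")


def harrell_c(times, status, risk_scores) -> float:
    """Harrell's C over censoring-usable pairs.

    A pair (i, j) is usable when i has an event and t_i < t_j; it is
    concordant when r_i > r_j, and risk ties earn 0.5.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(status, dtype=int)
    r = np.asarray(risk_scores, dtype=float)
    if not (t.size == d.size == r.size):
        raise ValueError("length mismatch")
    earlier_event = (d[:, None] == 1) & (t[:, None] < t[None, :])
    n_pairs = earlier_event.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs under censoring")
    conc = (earlier_event & (r[:, None] > r[None, :])).sum()
    ties = (earlier_event & (r[:, None] == r[None, :])).sum()
    return float((conc + 0.5 * ties) / n_pairs)


def _weights_at_horizon(times, status, horizon, G: SurvivalCurve):
    """Graf IPCW weights: 1/G(t_i-) for events by t, 1/G(t) past t, else 0."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(status, dtype=int)
    case = (t <= horizon) & (d == 1)
    at_risk = (t > horizon) | ((t == horizon) & (d == 0))
    w = np.zeros(t.size)
    g_left = G.at_left(t[case])
    g_h = float(G.at(horizon)[0])
    if np.any(g_left <= 0) or (at_risk.any() and g_h <= 0):
        raise ValueError(
            "censoring survival G reaches 0 before the horizon; "
            "use a smaller horizon")
    w[case] = 1.0 / g_left
    w[at_risk] = 1.0 / g_h
    return w, case, at_risk


def ipcw_brier(times, status, predicted_event_prob, horizon: float) -> float:
    """IPCW Brier score at a horizon (Graf weights, censoring-KM G).

    Mean over all subjects of w_i * (1{event by t} - p_i)^2, where subjects
    censored before min(event, horizon) get weight 0.
    """
    p = np.asarray(predicted_event_prob, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t = np.asarray(times, dtype=float)
    d = np.asarray(status, dtype=int)
    G = censoring_km(t, d)
    w, case, at_risk = _weights_at_horizon(t, d, horizon, G)
    y = case.astype(float)
    return float(np.mean(w * (y - p) ** 2))


def ipcw_auc(times, status, risk_scores, horizon: float) -> float:
    """Cumulative/dynamic IPCW AUC at a horizon.

    Cases are subjects with an event by the horizon, controls are subjects
    still at risk past it; the statistic is the IPCW-weighted proportion of
    correctly ordered case-control pairs, risk ties counting 0.5.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(status, dtype=int)
    r = np.asarray(risk_scores, dtype=float)
    G = censoring_km(t, d)
    w, case, at_risk = _weights_at_horizon(t, d, horizon, G)
    if not case.any() or not at_risk.any():
        raise ValueError("need at least one case and one control at the horizon")
    wc, rc = w[case], r[case]
    wk, rk = w[at_risk], r[at_risk]
    ww = np.outer(wc, wk)
    greater = rc[:, None] > rk[None, :]
    equal = rc[:, None] == rk[None, :]
    num = (ww * (greater + 0.5 * equal)).sum()
    return float(num / ww.sum())


# ---------------------------------------------------------------------------
# Endpoint extraction and risk models
# ---------------------------------------------------------------------------

def endpoint_times(clinical: pd.DataFrame, endpoint: str):
    """(time, status) arrays for an endpoint.

    ``overall_survival``: time to death, censored at last follow-up.
    ``transformation``: time to hematologic transformation, with death before
    transformation treated as cause-specific censoring.
    """
    dead = clinical["event_death"].astype(bool).to_numpy()
    t_d = clinical["time_death"].to_numpy(dtype=float)
    t_c = clinical["time_censor"].to_numpy(dtype=float)
    follow = np.where(dead, np.fmin(t_d, t_c), t_c)
    if endpoint == "overall_survival":
        return follow, dead.astype(int)
    if endpoint == "transformation":
        tr = clinical["event_transformation"].astype(bool).to_numpy()
        t_tr = clinical["time_transformation"].to_numpy(dtype=float)
        time = np.where(tr, t_tr, follow)
        return time, tr.astype(int)
    raise ValueError(f"unknown endpoint {endpoint!r}")


class CategoricalRiskModel:
    """Risk model from an ordered categorical score (per-category KM).

    The risk score is the category code; predicted event probabilities at a
    horizon are 1 - S_g(t) from the Kaplan-Meier fit within each category.
    """

    def __init__(self, categories: pd.Series, order=None, name: str = "score"):
        self.name = name
        cats = pd.Series(categories)
        self.order = list(order) if order is not None else \
            sorted(cats.dropna().unique())
        self.codes = cats.map({c: i for i, c in enumerate(self.order)})

    def fit(self, clinical: pd.DataFrame, endpoint: str):
        time, status = endpoint_times(clinical, endpoint)
        self._curves = {}
        for i, cat in enumerate(self.order):
            sel = (self.codes == i).to_numpy()
            if sel.sum() == 0:
                self._curves[i] = None
                continue
            self._curves[i] = kaplan_meier(time[sel], status[sel],
                                           label=str(cat))
        self._marginal = kaplan_meier(time, status)
        return self

    def risk_score(self, clinical: pd.DataFrame) -> np.ndarray:
        return self.codes.to_numpy(dtype=float)

    def event_prob(self, clinical: pd.DataFrame, horizon: float) -> np.ndarray:
        probs = np.empty(len(self.codes))
        for i in range(len(self.order)):
            curve = self._curves.get(i) or self._marginal
            p = 1.0 - float(curve.at(horizon)[0])
            probs[self.codes.to_numpy() == i] = p
        return probs


class CoxRiskModel:
    """Risk model from a fitted Cox transition model on chosen covariates."""

    def __init__(self, covariates, name: str = "cox", ties: str = "breslow"):
        self.covariates = list(covariates)
        self.name = name
        self.ties = ties

    def fit(self, clinical: pd.DataFrame, endpoint: str):
        from .multistate import TransitionCox
        time, status = endpoint_times(clinical, endpoint)
        df = clinical[self.covariates].copy()
        df["entry"] = 0.0
        df["exit"] = time
        df["status"] = status
        self._model = TransitionCox(ties=self.ties).fit(df, self.covariates)
        self._clin_index = clinical.index
        return self

    def risk_score(self, clinical: pd.DataFrame) -> np.ndarray:
        return self._model.predict_partial_hazard(clinical).to_numpy()

    def event_prob(self, clinical: pd.DataFrame, horizon: float) -> np.ndarray:
        return self._model.predict_event_prob(clinical, horizon).to_numpy()


class RandomRiskModel:
    """Seeded uniform noise scores — the null comparator."""

    def __init__(self, seed: int = 0, name: str = "random"):
        self.seed = seed
        self.name = name

    def fit(self, clinical: pd.DataFrame, endpoint: str):
        rng = np.random.default_rng(self.seed)
        self._scores = rng.uniform(size=len(clinical))
        return self

    def risk_score(self, clinical: pd.DataFrame) -> np.ndarray:
        return self._scores

    def event_prob(self, clinical: pd.DataFrame, horizon: float) -> np.ndarray:
        return self._scores


def compare_models(clinical: pd.DataFrame, models: dict,
                   horizons=HORIZONS, endpoints=ENDPOINTS) -> pd.DataFrame:
    """Performance table: per model x endpoint x horizon C / AUC / Brier.

    ``models`` maps name -> model object exposing ``fit(clinical, endpoint)``,
    ``risk_score(clinical)`` and ``event_prob(clinical, horizon)``. The
    overall C-index (horizon-free) is reported once per endpoint. Cells whose
    metric raises are reported as NaN with the reason in ``note``. The best
    value per endpoint x horizon x metric is flagged (highest C/AUC, lowest
    Brier).
    """
    rows = []
    for endpoint in endpoints:
        time, status = endpoint_times(clinical, endpoint)
        for name, model in models.items():
            model.fit(clinical, endpoint)
            risk = model.risk_score(clinical)
            try:
                c_overall = harrell_c(time, status, risk)
                note = ""
            except ValueError as exc:
                c_overall, note = np.nan, str(exc)
            rows.append({"model": name, "endpoint": endpoint,
                         "horizon": np.nan, "metric": "c_index",
                         "value": c_overall, "note": note})
            for h in horizons:
                for metric in ("auc", "brier"):
                    try:
                        if metric == "auc":
                            val = ipcw_auc(time, status, risk, h)
                        else:
                            p = np.asarray(model.event_prob(clinical, h))
                            val = ipcw_brier(time, status, p, h)
                        note = ""
                    except ValueError as exc:
                        val, note = np.nan, str(exc)
                    rows.append({"model": name, "endpoint": endpoint,
                                 "horizon": h, "metric": metric,
                                 "value": val, "note": note})
    report = pd.DataFrame(rows)
    report["best"] = False
    for (endpoint, h, metric), grp in report.groupby(
            ["endpoint", "horizon", "metric"], dropna=False):
        vals = grp["value"]
        if vals.notna().sum() == 0:
            continue
        idx = vals.idxmin() if metric == "brier" else vals.idxmax()
        report.loc[idx, "best"] = True
    return report
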