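"""Illness-death multistate machinery.

Three states: 1 = chronic phase, 2 = hematologic transformation (secondary
myelofibrosis or MDS/AML), 3 = death; transitions 1->2, 1->3 and 2->3. The
clock is time since diagnosis for every transition (clock-forward Markov
model); the 2->3 transition enters its risk set at the transformation time
via left truncation.

Pieces: long-format dataset construction, Kaplan-Meier (lifelines),
transition-specific Cox proportional hazards with Breslow (default) or Efron
ties and left truncation, the Aalen-Johansen state-occupation estimator, and
stepwise downward covariate selection on Wald p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger("pvhmr")

TRANSITIONS = ("1->2", "1->3", "2->3")


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Long-format construction
# ---------------------------------------------------------------------------

def to_multistate(clinical: pd.DataFrame, covariates=()) -> pd.DataFrame:
    """Expand a clinical table into long-format transition records.

    Every patient contributes a 1->2 and a 1->3 row from time 0; patients who
    transform additionally contribute a 2->3 row entering at the
    transformation time. Competing events are censored cause-specifically
    (1->2 is censored at death without transformation and vice versa).
    Intervals are half-open (entry, exit].
    """
    covariates = list(covariates)
    transformed = clinical["event_transformation"].astype(bool).to_numpy()
    dead = clinical["event_death"].astype(bool).to_numpy()
    t_tr = clinical["time_transformation"].to_numpy(dtype=float)
    t_d = clinical["time_death"].to_numpy(dtype=float)
    t_c = clinical["time_censor"].to_numpy(dtype=float)
    if np.any(transformed & np.isnan(t_tr)):
        raise ValueError("transformed patient without transformation time")
    follow = np.where(dead, np.fmin(t_d, t_c), t_c)
    exit1 = np.where(transformed, t_tr, follow)
    if np.any(~(exit1 > 0)):
        pid = clinical["patient_id"].to_numpy()[~(exit1 > 0)][0]
        raise ValueError(
            f"patient {pid}: non-positive chronic-phase follow-up")

    base = clinical[["patient_id", *covariates]].reset_index(drop=True)

    def rows(transition, entry, exit_, status, mask=None):
        out = base.copy() if mask is None else base.loc[mask].copy()
        out.insert(1, "transition", transition)
        out.insert(2, "entry", entry if mask is None else entry[mask])
        out.insert(3, "exit", exit_ if mask is None else exit_[mask])
        out.insert(4, "status", (status if mask is None
                                 else status[mask]).astype(int))
        return out

    zeros = np.zeros(len(clinical))
    parts = [
        rows("1->2", zeros, exit1, transformed),
        rows("1->3", zeros, exit1, dead & ~transformed),
    ]
    if transformed.any():
        exit2 = np.where(dead, t_d, t_c)
        bad = transformed & dead & ~(t_d > t_tr)
        if bad.any():
            pid = clinical["patient_id"].to_numpy()[bad][0]
            raise ValueError(
                f"patient {pid}: death at or before transformation")
        bad = transformed & ~(exit2 > t_tr)
        if bad.any():
            pid = clinical["patient_id"].to_numpy()[bad][0]
            raise ValueError(
                f"patient {pid}: no follow-up after transformation")
        parts.append(rows("2->3", t_tr, exit2, dead, mask=transformed))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Step-function survival / occupation curve with risk-set bookkeeping."""

    times: np.ndarray          # jump times, increasing
    values: np.ndarray         # S(t) (or P_s(t)) just after each jump
    at_risk: np.ndarray | None = None
    events: np.ndarray | None = None
    label: str = ""

    def at(self, t) -> np.ndarray:
        """Right-continuous evaluation S(t); S(0-)=1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)

    def at_left(self, t) -> np.ndarray:
        """Left-limit evaluation S(t-)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="left") - 1
        return np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)


def kaplan_meier(times, status, label: str = "") -> SurvivalCurve:
    """Product-limit survival estimate (events precede censorings at ties)."""
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    if times.size == 0:
        raise ValueError("kaplan_meier: empty input")
    if np.any(times < 0):
        raise ValueError("kaplan_meier: negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, status, label=label or "KM")
    tbl = kmf.event_table
    jumps = tbl.index[tbl["observed"] > 0]
    surv = kmf.survival_function_.loc[jumps].to_numpy().ravel()
    return SurvivalCurve(times=np.asarray(jumps, dtype=float), values=surv,
                         at_risk=tbl.loc[jumps, "at_risk"].to_numpy(),
                         events=tbl.loc[jumps, "observed"].to_numpy(),
                         label=label)


# ---------------------------------------------------------------------------
# Cox proportional hazards with left truncation
# ---------------------------------------------------------------------------

class TransitionCox(BaseEstimator):
    """Cox proportional-hazards model for one transition's at-risk set.

    Maximizes the partial likelihood with Breslow ties (default; Efron behind
    ``ties='efron'``) by Newton-Raphson with step halving; left truncation is
    respected through entry times (a subject is at risk at t when
    entry < t <= exit). Convergence when the max absolute score component
    falls below ``tol`` (default 1e-8) within ``max_iter`` iterations.

    Attributes after ``fit``: ``coef_``, ``se_``, ``hazard_ratios_``,
    ``confidence_intervals_`` (95% Wald, HR scale), ``p_values_``,
    ``baseline_cumhaz_`` (Breslow estimator, a :class:`SurvivalCurve`-like
    step function stored as a Series), ``n_iter_``, ``converged_``,
    ``loglik_``.
    """

    def __init__(self, ties: str = "breslow", tol: float = 1e-8,
                 max_iter: int = 50, alpha: float = 0.05):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha

    # -- internals ----------------------------------------------------------
    def _prepare(self, entry, exit_, status):
        event_times = np.unique(exit_[status == 1])
        risk_sets = [np.flatnonzero((entry < t) & (exit_ >= t))
                     for t in event_times]
        death_sets = [np.flatnonzero((exit_ == t) & (status == 1))
                      for t in event_times]
        return event_times, risk_sets, death_sets

    def _loglik_grad_hess(self, beta, X, risk_sets, death_sets):
        eta = X @ beta
        # guard against overflow during divergent steps
        w = np.exp(np.clip(eta, -500, 500))
        p = X.shape[1]
        ll = 0.0
        U = np.zeros(p)
        H = np.zeros((p, p))
        efron = self.ties == "efron"
        for R, D in zip(risk_sets, death_sets):
            d = len(D)
            xs = X[D].sum(axis=0)
            ll += eta[D].sum()
            U += xs
            wR = w[R]
            XR = X[R]
            W = wR.sum()
            S1 = wR @ XR
            S2 = (wR[:, None] * XR).T @ XR
            if not efron or d == 1:
                ll -= d * np.log(W)
                xbar = S1 / W
                U -= d * xbar
                H -= d * (S2 / W - np.outer(xbar, xbar))
            else:
                wD = w[D]
                WD = wD.sum()
                S1D = wD @ X[D]
                S2D = (wD[:, None] * X[D]).T @ X[D]
                for l in range(d):
                    f = l / d
                    Wl = W - f * WD
                    S1l = S1 - f * S1D
                    S2l = S2 - f * S2D
                    ll -= np.log(Wl)
                    xbar = S1l / Wl
                    U -= xbar
                    H -= S2l / Wl - np.outer(xbar, xbar)
        return ll, U, H

    # -- fitting ------------------------------------------------------------
    def fit(self, df: pd.DataFrame, covariates, entry_col: str = "entry",
            exit_col: str = "exit", status_col: str = "status"):
        covariates = list(covariates)
        X = df[covariates].to_numpy(dtype=float)
        entry = df[entry_col].to_numpy(dtype=float)
        exit_ = df[exit_col].to_numpy(dtype=float)
        status = df[status_col].to_numpy(dtype=int)
        if status.sum() == 0:
            raise ValueError("no events on this transition")
        if np.any(entry >= exit_):
            raise ValueError("entry times must precede exit times")
        const = [c for c, col in zip(covariates, X.T) if np.ptp(col) == 0]
        if const:
            raise ValueError(
                f"constant covariate(s) within the transition rows: {const}")

        event_times, risk_sets, death_sets = self._prepare(entry, exit_, status)
        beta = np.zeros(len(covariates))
        ll, U, H = self._loglik_grad_hess(beta, X, risk_sets, death_sets)
        converged = len(covariates) == 0
        it = 0
        for it in range(1, self.max_iter + 1 if covariates else 1):
            try:
                step = np.linalg.solve(H, -U)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    f"singular information matrix: {exc}") from exc
            # step halving: insist the partial likelihood does not decrease
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new, U_new, H_new = self._loglik_grad_hess(
                    cand, X, risk_sets, death_sets)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            beta, ll, U, H = cand, ll_new, U_new, H_new
            # score criterion, plus parameter stationarity for large samples
            # where the summed score hits floating-point cancellation first
            if (np.max(np.abs(U)) < self.tol
                    or np.max(np.abs(scale * step)) < 1e-10):
                converged = True
                break
        self.n_iter_ = it
        self.converged_ = converged
        # |log HR| beyond ~15 only arises when the partial likelihood is
        # monotone in that coefficient (separation), never from real effects
        if np.any(np.abs(beta) > 15):
            j = int(np.argmax(np.abs(beta)))
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation) for "
                f"covariate {covariates[j]!r}")
        if not converged:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {self.max_iter} "
                f"iterations (max |score| = {np.max(np.abs(U)):.3g})")

        cov = np.linalg.inv(-H)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        zcrit = stats.norm.ppf(1 - self.alpha / 2)
        self.covariates_ = covariates
        self.coef_ = pd.Series(beta, index=covariates, name="coef")
        self.se_ = pd.Series(se, index=covariates, name="se")
        self.loglik_ = float(ll)
        self.hazard_ratios_ = np.exp(self.coef_).rename("HR")
        self.p_values_ = pd.Series(2 * stats.norm.sf(np.abs(z)),
                                   index=covariates, name="p")
        self.confidence_intervals_ = pd.DataFrame(
            {"lower": np.exp(beta - zcrit * se),
             "upper": np.exp(beta + zcrit * se)}, index=covariates)

        # Breslow baseline cumulative hazard at beta-hat
        w = np.exp(np.clip(X @ beta, -500, 500))
        increments = np.array([len(D) / w[R].sum()
                               for R, D in zip(risk_sets, death_sets)])
        self.baseline_cumhaz_ = pd.Series(np.cumsum(increments),
                                          index=event_times, name="cumhaz")
        return self

    # -- prediction ---------------------------------------------------------
    def predict_partial_hazard(self, X: pd.DataFrame) -> pd.Series:
        lp = X[self.covariates_].to_numpy(dtype=float) @ self.coef_.to_numpy()
        return pd.Series(lp, index=X.index, name="linear_predictor")

    def cumhaz_at(self, t: float) -> float:
        ch = self.baseline_cumhaz_
        idx = np.searchsorted(ch.index.to_numpy(), t, side="right") - 1
        return float(ch.iloc[idx]) if idx >= 0 else 0.0

    def predict_event_prob(self, X: pd.DataFrame, horizon: float) -> pd.Series:
        """P(event by horizon) = 1 - exp(-Lambda0(t) * exp(x beta))."""
        lp = self.predict_partial_hazard(X)
        return 1.0 - np.exp(-self.cumhaz_at(horizon) * np.exp(lp))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef_, "HR": self.hazard_ratios_, "se": self.se_,
            "p": self.p_values_,
            "HR_lower": self.confidence_intervals_["lower"],
            "HR_upper": self.confidence_intervals_["upper"],
        })


def fit_cox_transition(dataset: pd.DataFrame, transition: str, covariates,
                       ties: str = "breslow") -> TransitionCox:
    """Fit the Cox model to one transition of a long-format dataset."""
    if transition not in TRANSITIONS:
        raise ValueError(f"unknown transition {transition!r}")
    sub = dataset.loc[dataset["transition"] == transition]
    return TransitionCox(ties=ties).fit(sub, covariates)


# ---------------------------------------------------------------------------
# Aalen-Johansen state occupation
# ---------------------------------------------------------------------------

def aalen_johansen(dataset: pd.DataFrame) -> dict:
    """State-occupation probabilities for {chronic, transformed, dead}.

    Product-integral of the empirical transition-intensity matrix over event
    times, starting from everyone in the chronic state. Returns a dict of
    state name -> :class:`SurvivalCurve`.
    """
    subs = {tr: dataset.loc[dataset["transition"] == tr] for tr in TRANSITIONS}
    ev_times = np.unique(np.concatenate([
        subs[tr].loc[subs[tr]["status"] == 1, "exit"].to_numpy(dtype=float)
        for tr in TRANSITIONS]))
    if ev_times.size == 0:
        t = np.array([0.0])
        one = np.array([1.0])
        zero = np.array([0.0])
        return {"chronic": SurvivalCurve(t, one, label="chronic"),
                "transformed": SurvivalCurve(t, zero, label="transformed"),
                "dead": SurvivalCurve(t, zero, label="dead")}

    # risk-set sizes by vectorized searchsorted (entry < t <= exit)
    def at_risk(sub, times):
        entry = np.sort(sub["entry"].to_numpy(dtype=float))
        exit_ = np.sort(sub["exit"].to_numpy(dtype=float))
        return (np.searchsorted(entry, times, side="left")
                - np.searchsorted(exit_, times, side="left"))

    def events(sub, times):
        e = sub.loc[sub["status"] == 1, "exit"].to_numpy(dtype=float)
        e = np.sort(e)
        return (np.searchsorted(e, times, side="right")
                - np.searchsorted(e, times, side="left"))

    n1 = at_risk(subs["1->2"], ev_times)           # same patients as 1->3
    n2 = at_risk(subs["2->3"], ev_times) if len(subs["2->3"]) \
        else np.zeros_like(ev_times, dtype=int)
    d12 = events(subs["1->2"], ev_times)
    d13 = events(subs["1->3"], ev_times)
    d23 = events(subs["2->3"], ev_times) if len(subs["2->3"]) \
        else np.zeros_like(ev_times, dtype=int)

    occ = np.zeros((ev_times.size, 3))
    p = np.array([1.0, 0.0, 0.0])
    for k in range(ev_times.size):
        trans = np.eye(3)
        if n1[k] > 0:
            h12 = d12[k] / n1[k]
            h13 = d13[k] / n1[k]
            trans[0] = [1.0 - h12 - h13, h12, h13]
        if n2[k] > 0:
            h23 = d23[k] / n2[k]
            trans[1] = [0.0, 1.0 - h23, h23]
        p = p @ trans
        occ[k] = p
    return {
        "chronic": SurvivalCurve(ev_times, occ[:, 0], label="chronic"),
        "transformed": SurvivalCurve(ev_times, occ[:, 1], label="transformed"),
        "dead": SurvivalCurve(ev_times, occ[:, 2], label="dead"),
    }


# ---------------------------------------------------------------------------
# Stepwise downward selection
# ---------------------------------------------------------------------------

def stepwise_select(dataset: pd.DataFrame, transition: str, covariates,
                    alpha: float = 0.05, ties: str = "breslow"):
    """Backward elimination on Wald p-values for one transition.

    Iteratively drops the covariate with the largest p > ``alpha`` (ties
    broken by covariate name, lexicographically first dropped), refits, and
    stops when all remaining p <= ``alpha``. Returns
    ``(selected_covariates, fitted TransitionCox, drop_log)``.
    """
    remaining = list(covariates)
    log = []
    model = fit_cox_transition(dataset, transition, remaining, ties=ties)
    while len(remaining) > 1:
        p = model.p_values_
        worst_p = p.max()
        if worst_p <= alpha:
            break
        candidates = sorted(p.index[np.isclose(p, worst_p, atol=1e-12)])
        drop = candidates[0]
        log.append({"dropped": drop, "p": float(p[drop])})
        remaining = [c for c in remaining if c != drop]
        model = fit_cox_transition(dataset, transition, remaining, ties=ties)
    if len(remaining) == 1 and model.p_values_.iloc[0] > alpha:
        log.append({"dropped": remaining[0],
                    "p": float(model.p_values_.iloc[0])})
        remaining, model = [], None
    return remaining, model, log
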