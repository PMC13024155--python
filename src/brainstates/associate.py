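"""Mixed-effects association between state dynamics and the outcome score.

For each state and each dynamic measure (occupancy %, transition count), a
linear mixed model is fit by REML:

    stress ~ measure + group + measure:group + avg_drinks + (1 | participant)

with mindfulness as the reference group. Wald t statistics use a
residual-based degrees-of-freedom approximation (n_obs - n_fixed). Models
whose measure-by-group interaction survives FDR are refit within each group
(the stratified follow-up).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .inference import fdr_correct

logger = logging.getLogger(__name__)

__all__ = ["MixedModelResult", "fit_mixed", "interaction_screen_and_stratify"]

REFERENCE_GROUP = "mindfulness"
TERMS = ("intercept", "measure", "group", "avg_drinks", "measure_x_group")
STRAT_TERMS = ("intercept", "measure", "avg_drinks")


@dataclass
class MixedModelResult:
    state: int
    measure: str                       # 'occupancy' or 'transition_frequency'
    coefficients: pd.DataFrame         # index=term, cols=[estimate, std_error, t, p]
    n_obs: int
    n_participants: int
    random_intercept_var: float
    boundary: bool                     # random-intercept variance collapsed to ~0
    stratified: dict | None = None     # group -> coefficient table


def _wald_table(params, bse, names, df_resid) -> pd.DataFrame:
    t = params / bse
    p = 2.0 * stats.t.sf(np.abs(t), df=max(df_resid, 1))
    return pd.DataFrame(
        {"estimate": params, "std_error": bse, "t": t, "p": p}, index=list(names)
    )


def _fit_lmm(X: np.ndarray, names, y: np.ndarray, groups: np.ndarray):
    """REML random-intercept fit; falls back to OLS at the variance boundary."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        for method in ("lbfgs", "bfgs", "cg"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if res is None:
            # degenerate likelihood (e.g. zero residual variance): boundary case
            logger.warning("mixed-model likelihood degenerate; using the OLS boundary fit")
            ols = sm.OLS(y, X).fit()
            return _wald_table(ols.params, ols.bse, names, ols.df_resid), 0.0, True
    ri_var = float(np.asarray(res.cov_re)[0, 0]) if np.asarray(res.cov_re).size else 0.0
    boundary = ri_var < 1e-8
    if boundary:
        logger.warning("random-intercept variance ~0; boundary fit (equivalent to OLS)")
        ols = sm.OLS(y, X).fit()
        table = _wald_table(ols.params, ols.bse, names, ols.df_resid)
        return table, 0.0, True
    df_resid = len(y) - X.shape[1]
    table = _wald_table(np.asarray(res.fe_params), np.asarray(res.bse_fe), names, df_resid)
    return table, ri_var, False


def fit_mixed(data: pd.DataFrame, state: int = -1,
              measure_name: str = "occupancy") -> MixedModelResult:
    """Fit the per-state mixed model from a per-scan table.

    `data` needs columns: stress, measure, group, avg_drinks, participant_id.
    """
    df = data.dropna(subset=["stress", "measure", "group", "avg_drinks"]).copy()
    if df["measure"].nunique() <= 1:
        raise ValueError("measure has zero variance; model is unidentifiable")
    per_group = df.groupby("group")["participant_id"].nunique()
    if len(per_group) < 2 or (per_group < 2).any():
        raise ValueError("need at least two participants per group")
    ctrl = (df["group"] != REFERENCE_GROUP).astype(float).to_numpy()
    meas = df["measure"].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(df)), meas, ctrl, df["avg_drinks"].to_numpy(dtype=float),
        meas * ctrl,
    ])
    table, ri_var, boundary = _fit_lmm(
        X, TERMS, df["stress"].to_numpy(dtype=float), df["participant_id"].to_numpy()
    )
    return MixedModelResult(
        state=state, measure=measure_name, coefficients=table,
        n_obs=len(df), n_participants=df["participant_id"].nunique(),
        random_intercept_var=ri_var, boundary=boundary,
    )


def _fit_stratified(df: pd.DataFrame) -> dict:
    out = {}
    for group, sub in df.groupby("group"):
        meas = sub["measure"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), meas,
                             sub["avg_drinks"].to_numpy(dtype=float)])
        table, _, _ = _fit_lmm(X, STRAT_TERMS, sub["stress"].to_numpy(dtype=float),
                               sub["participant_id"].to_numpy())
        out[group] = table
    return out


def interaction_screen_and_stratify(results: list, data_by_key: dict,
                                    alpha: float = 0.05) -> pd.DataFrame:
    """FDR-screen the interaction terms; refit within groups where flagged.

    results: MixedModelResult per (state, measure); data_by_key maps
    (state, measure) to the per-scan table used for the fit. Returns a tidy
    long table of all coefficients, with stratified blocks appended for
    flagged models (stratified is None elsewhere).
    """
    pvals = [r.coefficients.loc["measure_x_group", "p"] for r in results]
    qs, rejected = fdr_correct(pvals, alpha=alpha) if results else (np.array([]), np.array([]))
    rows = []
    for r, q, flag in zip(results, qs, rejected):
        if flag:
            r.stratified = _fit_stratified(data_by_key[(r.state, r.measure)])
            logger.info("state %d %s: interaction q=%.4g < %.2f; stratified fits run",
                        r.state, r.measure, q, alpha)
        for term, c in r.coefficients.iterrows():
            rows.append({"state": r.state, "measure": r.measure, "stratum": "all",
                         "term": term, "estimate": c.estimate,
                         "std_error": c.std_error, "t": c.t, "p": c.p,
                         "interaction_q": float(q),
                         "stratified": bool(flag)})
        if r.stratified:
            for group, table in r.stratified.items():
                for term, c in table.iterrows():
                    rows.append({"state": r.state, "measure": r.measure,
                                 "stratum": group, "term": term,
                                 "estimate": c.estimate, "std_error": c.std_error,
                                 "t": c.t, "p": c.p, "interaction_q": float(q),
                                 "stratified": True})
    if not rows:
        return pd.DataFrame(columns=["state", "measure", "stratum", "term",
                                     "estimate", "std_error", "t", "p",
                                     "interaction_q", "stratified"])
    return pd.DataFrame(rows)
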