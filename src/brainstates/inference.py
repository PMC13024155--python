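"""Group-difference inference for state dynamics.

Permutation tests shuffle *participant* group labels (both of a
participant's scans move together), compare mindfulness-minus-control mean
differences (two-sided, on the absolute difference) or a symmetrized KL
divergence between pooled group dwell densities, and use the add-one
p-value (1 + #{null >= observed}) / (n_perm + 1). Benjamini-Hochberg FDR is
applied within each dynamic-property family (one family per summary:
occupancy, transitions, dwell-KL, each spanning the K states).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dynamics import dwell_density

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "permutation_test_mean_diff",
    "kl_divergence",
    "symmetrized_kl",
    "permutation_test_dwell_kl",
    "fdr_correct",
    "group_difference_tests",
]

GROUP_ORDER = ("mindfulness", "control")


@dataclass
class GroupTestResult:
    state: int
    statistic_name: str
    observed: float
    null_samples: np.ndarray
    p_value: float
    q_value: float = np.nan
    significant: bool = False


def _check_groups(groups) -> np.ndarray:
    g = np.asarray(groups)
    if g.size == 0:
        raise ValueError("no participants")
    uniq = set(g.tolist())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {sorted(uniq)}")
    return g


def permutation_test_mean_diff(values, groups, n_perm: int = 500, seed: int = 0,
                               state: int = -1,
                               statistic_name: str = "mean_occupancy_diff") -> GroupTestResult:
    """Two-sided permutation test on |mean(group1) - mean(group2)|.

    `values` holds one number per participant (the scan-mean of the summary);
    permutations shuffle the participant-level group labels.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    v = np.asarray(values, dtype=float)
    g = _check_groups(groups)
    g1, g2 = GROUP_ORDER if set(g.tolist()) == set(GROUP_ORDER) else tuple(sorted(set(g.tolist())))
    mask1 = g == g1
    n1 = int(mask1.sum())
    observed = v[mask1].mean() - v[~mask1].mean()

    rng = np.random.default_rng(seed)
    n = v.size
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        idx1 = perm[:n1]
        m1 = v[idx1].mean()
        null[b] = m1 - (v.sum() - v[idx1].sum()) / (n - n1)
    exceed = int((np.abs(null) >= abs(observed) - 1e-12).sum())
    p = (1 + exceed) / (n_perm + 1)
    return GroupTestResult(state=state, statistic_name=statistic_name,
                           observed=float(observed), null_samples=null, p_value=p)


def kl_divergence(p, q) -> float:
    """KL(p || q) = sum p log(p/q), natural log; densities on a shared grid."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {q.shape}")
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError("densities must be strictly positive (epsilon-floored)")
    for name, x in (("p", p), ("q", q)):
        if abs(x.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} does not sum to 1")
    return float((p * np.log(p / q)).sum())


def symmetrized_kl(p, q) -> float:
    return 0.5 * (kl_divergence(p, q) + kl_divergence(q, p))


def permutation_test_dwell_kl(dwells_by_participant, groups, n_perm: int = 500,
                              seed: int = 0, max_dwell: int = 50, state: int = -1,
                              symmetrize: bool = True) -> GroupTestResult:
    """Permutation test on the (symmetrized) KL divergence between pooled
    group dwell densities for one state.

    dwells_by_participant: one list of dwell lengths per participant (their
    scans pooled). Permutations that leave a group with no dwells are
    redrawn (counted and logged).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dw = [np.asarray(d, dtype=float) for d in dwells_by_participant]
    g = _check_groups(groups)
    g1 = GROUP_ORDER[0] if GROUP_ORDER[0] in set(g.tolist()) else sorted(set(g.tolist()))[0]
    mask1 = g == g1
    n1 = int(mask1.sum())
    n = len(dw)

    def stat(idx1_mask: np.ndarray) -> float:
        a = np.concatenate([dw[i] for i in range(n) if idx1_mask[i]]) if any(idx1_mask) else np.array([])
        b = np.concatenate([dw[i] for i in range(n) if not idx1_mask[i]]) if not all(idx1_mask) else np.array([])
        if a.size == 0 or b.size == 0:
            raise ValueError("a group has no dwells")
        pa = dwell_density(a, max_dwell)
        pb = dwell_density(b, max_dwell)
        return symmetrized_kl(pa, pb) if symmetrize else kl_divergence(pa, pb)

    observed = stat(mask1)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_redrawn = 0
    for b in range(n_perm):
        for _attempt in range(1000):
            perm = rng.permutation(n)
            m = np.zeros(n, dtype=bool)
            m[perm[:n1]] = True
            try:
                null[b] = stat(m)
                break
            except ValueError:
                n_redrawn += 1
        else:
            raise RuntimeError("could not draw a permutation with dwells in both groups")
    if n_redrawn:
        logger.info("redrew %d permutations that emptied a group", n_redrawn)
    exceed = int((null >= observed - 1e-12).sum())
    p = (1 + exceed) / (n_perm + 1)
    return GroupTestResult(state=state, statistic_name="dwell_kl",
                           observed=float(observed), null_samples=null, p_value=p)


def fdr_correct(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up; returns (q_values, rejected)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, rejected


def group_difference_tests(summary: pd.DataFrame, K: int, n_perm: int = 500,
                           alpha: float = 0.05, seed: int = 0,
                           max_dwell: int = 50) -> pd.DataFrame:
    """Run all three property families of tests from a long-format summary table.

    Participant-level values are scan means (occupancy, transitions) or
    scan-pooled dwell lists; FDR is applied within each property across the
    K states. Returns a tidy table (state, property, observed, p, q,
    significant).
    """
    parts = summary.groupby("participant_id", sort=True)
    pids = sorted(summary["participant_id"].unique())
    groups = np.array([summary.loc[summary.participant_id == p, "group"].iloc[0]
                       for p in pids])
    ss = np.random.SeedSequence(seed).generate_state(3 * K)
    results = []
    for prop, col in (("occupancy", "occupancy_pct"), ("transitions", "transitions_in")):
        for k in range(K):
            sub = summary[summary.state == k].groupby("participant_id")[col].mean()
            vals = sub.loc[pids].to_numpy()
            name = "mean_occupancy_diff" if prop == "occupancy" else "mean_transition_diff"
            res = permutation_test_mean_diff(
                vals, groups, n_perm=n_perm,
                seed=int(ss[(0 if prop == "occupancy" else 1) * K + k]),
                state=k, statistic_name=name)
            results.append((prop, res))
    for k in range(K):
        dwlists = []
        for p in pids:
            rows = summary[(summary.participant_id == p) & (summary.state == k)]
            pooled = []
            for cell in rows["dwells"]:
                if isinstance(cell, str) and cell:
                    pooled.extend(int(x) for x in cell.split(";"))
                elif isinstance(cell, (list, tuple)):
                    pooled.extend(int(x) for x in cell)
            dwlists.append(pooled)
        res = permutation_test_dwell_kl(dwlists, groups, n_perm=n_perm,
                                        seed=int(ss[2 * K + k]),
                                        max_dwell=max_dwell, state=k)
        results.append(("dwell_kl", res))

    rows = []
    for prop in ("occupancy", "transitions", "dwell_kl"):
        fam = [(p, r) for p, r in results if p == prop]
        qs, rej = fdr_correct([r.p_value for _, r in fam], alpha=alpha)
        for (prop_, r), q, dec in zip(fam, qs, rej):
            r.q_value = float(q)
            r.significant = bool(dec)
            rows.append({"state": r.state, "property": prop_,
                         "observed": r.observed, "p_value": r.p_value,
                         "q_value": r.q_value, "significant": r.significant})
    return pd.DataFrame(rows)
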