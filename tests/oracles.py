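"""Independent reference implementations used only to check the package.

These deliberately avoid the package's recursions: the HSMM oracle
enumerates every label path; the modularity oracle enumerates every set
partition. Both are exponential and only run on tiny inputs.
"""

import itertools

import numpy as np
from scipy.stats import multivariate_normal

from brainstates.characterize import modularity


def brute_force_hsmm(params, Y):
    """Exhaustive marginal loglik and MAP path over all K^T label paths.

    Path probability: init * dwell-pmf per completed run * transition per
    change-point * survival for the final (right-censored) run * emissions.
    Returns (log marginal, best log joint, best path).
    """
    K, T, D = params.n_states, Y.shape[0], params.max_dwell
    logpmf = np.stack([d.log_pmf(D) for d in params.dwell], axis=1)
    pmf = np.exp(logpmf)
    sf = np.cumsum(pmf[::-1], axis=0)[::-1]
    em = np.stack(
        [multivariate_normal.logpdf(Y, params.means[k], params.covs[k]) for k in range(K)],
        axis=1,
    )
    em = np.atleast_2d(em)
    total = -np.inf
    best = (-np.inf, None)
    for path in itertools.product(range(K), repeat=T):
        path = np.asarray(path)
        runs = []
        cur, ln = path[0], 1
        for s in path[1:]:
            if s == cur:
                ln += 1
            else:
                runs.append((cur, ln))
                cur, ln = s, 1
        runs.append((cur, ln))
        lp = np.log(params.init[runs[0][0]])
        ok = True
        for i, (s, d) in enumerate(runs):
            if d > D:
                ok = False
                break
            lp += np.log(sf[d - 1, s]) if i == len(runs) - 1 else logpmf[d - 1, s]
            if i > 0:
                tp = params.trans[runs[i - 1][0], s]
                if tp <= 0:
                    ok = False
                    break
                lp += np.log(tp)
        if not ok:
            continue
        lp += em[np.arange(T), path].sum()
        total = np.logaddexp(total, lp)
        if lp > best[0]:
            best = (lp, path)
    return total, best[0], best[1]


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1:]
        yield [[first]] + p


def exhaustive_max_modularity(adj, gamma=1.0):
    """Max Q over every set partition of the nodes (n <= 8 only)."""
    n = adj.shape[0]
    best = -np.inf
    for p in set_partitions(list(range(n))):
        lab = np.empty(n, dtype=int)
        for c, block in enumerate(p):
            lab[block] = c
        best = max(best, modularity(adj, lab, gamma))
    return best


def random_hsmm_params(K=2, R=2, D=6, seed=0, lam_range=(0.5, 3.0)):
    """Random valid parameter set for oracle comparisons."""
    from brainstates.durations import ShiftedPoissonDwell
    from brainstates.hsmm import HSMMParams

    r = np.random.default_rng(seed)
    means = r.normal(size=(K, R)) * 2.0
    covs = []
    for _ in range(K):
        A = r.normal(size=(R, R))
        covs.append(A @ A.T + 0.5 * np.eye(R))
    if K == 1:
        trans = np.zeros((1, 1))
    else:
        rows = r.dirichlet(np.ones(K - 1), size=K)
        trans = np.zeros((K, K))
        for k in range(K):
            trans[k, np.arange(K) != k] = rows[k]
    dwell = tuple(ShiftedPoissonDwell(r.uniform(*lam_range)) for _ in range(K))
    init = r.dirichlet(np.ones(K))
    return HSMMParams(means=means, covs=np.stack(covs), trans=trans,
                      dwell=dwell, init=init, max_dwell=D)
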