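"""Explicit-duration hidden semi-Markov model with multivariate Gaussian emissions.

The observation vector at each timepoint is drawn from a state-specific
multivariate normal N(mu_s, Sigma_s). The latent process is semi-Markov: on
entering state s the chain draws a dwell length d from that state's dwell
distribution, stays d timepoints, then jumps to a different state according
to a zero-diagonal transition matrix. Dwell pmfs are truncated to
1..max_dwell and renormalised, so the forward/backward/Viterbi recursions
cost O(T * K * max_dwell) per scan.

Boundary convention: the first dwell starts at t=0 (no left censoring); the
final dwell is right-censored at the end of the scan, so it contributes the
survival probability P(D >= observed run length). This matches the
generative sampler, which truncates the last drawn dwell at T.

All recursions run in log space. Scans pooled into one fit are treated as
independent sequences sharing parameters; they are never concatenated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg
from sklearn.cluster import KMeans

from .durations import ShiftedPoissonDwell, dwell_from_dict
from .io import ScanSeries

logger = logging.getLogger(__name__)

__all__ = [
    "HSMMParams",
    "StateSequence",
    "FitResult",
    "EMConfig",
    "init_params",
    "loglikelihood",
    "viterbi_decode",
    "em_fit",
    "posterior_marginals",
]

_NEG_INF = -np.inf


@dataclass(frozen=True)
class HSMMParams:
    """Complete parameter set: emissions, transitions, dwells, initial probs."""

    means: np.ndarray          # (K, R) state mean activity
    covs: np.ndarray           # (K, R, R) state covariances, SPD
    trans: np.ndarray          # (K, K) stochastic, zero diagonal (next *distinct* state)
    dwell: tuple               # K dwell distributions on d >= 1
    init: np.ndarray           # (K,) initial state probabilities
    max_dwell: int = 50

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        covs = np.asarray(self.covs, dtype=float)
        trans = np.atleast_2d(np.asarray(self.trans, dtype=float))
        init = np.atleast_1d(np.asarray(self.init, dtype=float))
        K, R = means.shape
        if covs.shape != (K, R, R):
            raise ValueError(f"covs must have shape {(K, R, R)}, got {covs.shape}")
        if trans.shape != (K, K):
            raise ValueError(f"trans must be {K}x{K}, got {trans.shape}")
        if len(self.dwell) != K or init.shape != (K,):
            raise ValueError("dwell and init must have one entry per state")
        if self.max_dwell < 1:
            raise ValueError("max_dwell must be positive")
        if np.abs(np.diag(trans)).max(initial=0.0) > 1e-12:
            raise ValueError("transition matrix must have a zero diagonal")
        if K >= 2 and np.abs(trans.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("transition rows must sum to 1")
        if np.abs(init.sum() - 1.0) > 1e-8 or (init < -1e-12).any():
            raise ValueError("init must be a probability vector")
        for k in range(K):
            sym = covs[k] - covs[k].T
            if np.abs(sym).max() > 1e-8:
                raise ValueError(f"covariance of state {k} is not symmetric")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covs", covs)
        object.__setattr__(self, "trans", trans)
        object.__setattr__(self, "init", init)
        object.__setattr__(self, "dwell", tuple(self.dwell))

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_regions(self) -> int:
        return self.means.shape[1]

    def permuted(self, perm) -> "HSMMParams":
        """Return the same model with state indices relabelled by perm."""
        perm = np.asarray(perm)
        return replace(
            self,
            means=self.means[perm],
            covs=self.covs[perm],
            trans=self.trans[np.ix_(perm, perm)],
            dwell=tuple(self.dwell[k] for k in perm),
            init=self.init[perm],
        )

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "covs": self.covs.tolist(),
            "trans": self.trans.tolist(),
            "dwell": [d.to_dict() for d in self.dwell],
            "init": self.init.tolist(),
            "max_dwell": self.max_dwell,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HSMMParams":
        return cls(
            means=np.asarray(d["means"], dtype=float),
            covs=np.asarray(d["covs"], dtype=float),
            trans=np.asarray(d["trans"], dtype=float),
            dwell=tuple(dwell_from_dict(x) for x in d["dwell"]),
            init=np.asarray(d["init"], dtype=float),
            max_dwell=int(d["max_dwell"]),
        )


@dataclass(frozen=True)
class StateSequence:
    """A decoded per-scan label path and the log joint probability of (path, data)."""

    labels: np.ndarray
    log_joint: float = np.nan

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class FitResult:
    params: HSMMParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class EMConfig:
    max_iter: int = 100
    tol: float = 1e-5
    n_starts: int = 5
    max_dwell: int = 50
    ridge: float = 1e-6
    seed: int = 0


# ---------------------------------------------------------------------------
# emission log-densities

def _emission_loglik(Y: np.ndarray, params: HSMMParams) -> np.ndarray:
    """(T, K) matrix of log N(y_t | mu_k, Sigma_k)."""
    T, R = Y.shape
    K = params.n_states
    B = np.empty((T, K))
    for k in range(K):
        try:
            chol = linalg.cholesky(params.covs[k], lower=True)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance of state {k} is singular or not positive definite"
            ) from exc
        dev = Y - params.means[k]
        sol = linalg.solve_triangular(chol, dev.T, lower=True)
        maha = (sol ** 2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        B[:, k] = -0.5 * (R * np.log(2.0 * np.pi) + logdet + maha)
    return B


def _dwell_tables(params: HSMMParams, T: int):
    """Truncated log pmf and log survival tables, shape (D, K), D = min(max_dwell, T)."""
    D = min(params.max_dwell, T)
    logpmf = np.stack([d.log_pmf(params.max_dwell)[:D] for d in params.dwell], axis=1)
    # log survival: log P(D >= d) on the *full* truncated support 1..max_dwell
    full = np.stack([d.log_pmf(params.max_dwell) for d in params.dwell], axis=1)
    pmf = np.exp(full)
    sf = np.cumsum(pmf[::-1], axis=0)[::-1]
    with np.errstate(divide="ignore"):
        logsf = np.log(np.clip(sf, 0.0, None))[:D]
    return D, logpmf, logsf


def _lse0(a: np.ndarray) -> np.ndarray:
    """logsumexp along axis 0, tolerant of all -inf columns."""
    m = a.max(axis=0)
    safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = safe + np.log(np.exp(a - safe).sum(axis=0))
    return np.where(np.isfinite(m), out, _NEG_INF)


# ---------------------------------------------------------------------------
# forward / backward

def _forward(B: np.ndarray, params: HSMMParams):
    """Explicit-duration forward pass.

    Returns (A, E, A_cens, loglik) where
      A[t, k]  = log P(y_0..t, a segment of state k ends exactly at t)
      E[tau,k] = log "entry weight" of a segment of state k starting at tau
      A_cens[k] = final-column variant with the last dwell right-censored.
    """
    T, K = B.shape
    D, logpmf, logsf = _dwell_tables(params, T)
    with np.errstate(divide="ignore"):
        logtrans = np.log(params.trans + 0.0)
        loginit = np.log(params.init + 0.0)
    CS = np.vstack([np.zeros(K), np.cumsum(B, axis=0)])
    A = np.full((T, K), _NEG_INF)
    E = np.full((T, K), _NEG_INF)
    E[0] = loginit
    A_cens = np.full(K, _NEG_INF)
    for t in range(T):
        dmax = min(D, t + 1)
        starts = t - np.arange(1, dmax + 1) + 1          # tau for d = 1..dmax
        seg = CS[t + 1][None, :] - CS[starts]            # (dmax, K)
        core = E[starts] + seg
        A[t] = _lse0(core + logpmf[:dmax])
        if t == T - 1:
            A_cens = _lse0(core + logsf[:dmax])
        elif t + 1 < T:
            E[t + 1] = _lse0(A[t][:, None] + logtrans)
    loglik = float(_lse0(A_cens[:, None])[0])
    return A, E, A_cens, loglik


def _backward(B: np.ndarray, params: HSMMParams):
    """Explicit-duration backward pass.

    Returns (beta, W, W_init) where
      beta[t, k] = log P(y_{t+1..T-1} | a segment of state k ended at t)
      W[t, k']   = log P(y_{t+1..T-1}, next segment is state k' | segment ended at t)
                   marginalised over the next segment's duration
      W_init[k]  = the same quantity for t = -1 (start of scan).
    """
    T, K = B.shape
    D, logpmf, logsf = _dwell_tables(params, T)
    with np.errstate(divide="ignore"):
        logtrans = np.log(params.trans + 0.0)
    CS = np.vstack([np.zeros(K), np.cumsum(B, axis=0)])
    beta = np.full((T, K), _NEG_INF)
    beta[T - 1] = 0.0
    W = np.full((T, K), _NEG_INF)
    W_init = np.full(K, _NEG_INF)
    for t in range(T - 2, -2, -1):
        dmax = min(D, T - 1 - t)
        ds = np.arange(1, dmax + 1)
        ends = t + ds
        seg = CS[ends + 1] - CS[t + 1]
        dterm = logpmf[:dmax].copy()
        if ends[-1] == T - 1:                            # censored final segment
            dterm[-1] = logsf[dmax - 1]
        vals = seg + dterm + beta[ends]
        Wt = _lse0(vals)
        if t >= 0:
            W[t] = Wt
            beta[t] = _lse0((logtrans + Wt[None, :]).T)
        else:
            W_init = Wt
    return beta, W, W_init


def loglikelihood(params: HSMMParams, scan: ScanSeries | np.ndarray) -> float:
    """Marginal log p(Y) over all duration-respecting state paths."""
    Y = scan.matrix if isinstance(scan, ScanSeries) else np.asarray(scan, dtype=float)
    if Y.shape[1] != params.n_regions:
        raise ValueError(
            f"scan has {Y.shape[1]} regions but model expects {params.n_regions}"
        )
    B = _emission_loglik(Y, params)
    if params.n_states == 1:
        return float(B.sum())
    return _forward(B, params)[3]


def posterior_marginals(params: HSMMParams, scan: ScanSeries | np.ndarray) -> np.ndarray:
    """(T, K) posterior state-occupation probabilities (rows sum to 1)."""
    Y = scan.matrix if isinstance(scan, ScanSeries) else np.asarray(scan, dtype=float)
    B = _emission_loglik(Y, params)
    if params.n_states == 1:
        return np.ones((Y.shape[0], 1))
    stats = _estep_single(B, params)
    return stats["gamma"]


# ---------------------------------------------------------------------------
# E-step sufficient statistics for one scan

def _estep_single(B: np.ndarray, params: HSMMParams) -> dict:
    T, K = B.shape
    D, logpmf, logsf = _dwell_tables(params, T)
    with np.errstate(divide="ignore"):
        logtrans = np.log(params.trans + 0.0)
    A, E, A_cens, L = _forward(B, params)
    beta, W, W_init = _backward(B, params)
    if not np.isfinite(L):
        raise FloatingPointError("non-finite log-likelihood in E-step")
    CS = np.vstack([np.zeros(K), np.cumsum(B, axis=0)])

    gamma_diff = np.zeros((T + 1, K))
    dur_hist = np.zeros((D, K))
    pmf_full = np.exp(logpmf)                # truncated pmf on 1..D
    sf_full = np.exp(logsf)
    for tau in range(T):
        dmax = min(D, T - tau)
        ds = np.arange(1, dmax + 1)
        ends = tau + ds - 1
        seg = CS[ends + 1] - CS[tau]
        dterm = logpmf[:dmax].copy()
        censored = ends[-1] == T - 1
        if censored:
            dterm[-1] = logsf[dmax - 1]
        logxi = E[tau] + seg + dterm + beta[ends] - L
        xi = np.exp(logxi)                   # (dmax, K) segment posteriors
        gamma_diff[tau] += xi.sum(axis=0)
        np.subtract.at(gamma_diff, ends + 1, xi)
        if censored:
            dur_hist[: dmax - 1] += xi[:-1]
            # censored segment: spread weight over true durations d' >= d_obs
            d_obs = dmax
            w = xi[-1]                       # (K,)
            tail = pmf_full[d_obs - 1:]      # (D-d_obs+1, K)
            denom = np.clip(sf_full[d_obs - 1], 1e-300, None)
            dur_hist[d_obs - 1:] += w[None, :] * tail / denom[None, :]
        else:
            dur_hist[:dmax] += xi

    gamma = np.cumsum(gamma_diff[:T], axis=0)
    gamma = np.clip(gamma, 0.0, None)

    # expected transition counts j -> k
    logtc = A[: T - 1, :, None] + logtrans[None, :, :] + W[: T - 1, None, :] - L
    trans_counts = np.exp(logtc).sum(axis=0)
    init_counts = np.exp(np.log(np.clip(params.init, 1e-300, None)) + W_init - L)

    return {
        "gamma": gamma,
        "dur_hist": dur_hist,
        "trans_counts": trans_counts,
        "init_counts": init_counts,
        "loglik": L,
    }


# ---------------------------------------------------------------------------
# Viterbi

def viterbi_decode(params: HSMMParams, scan: ScanSeries | np.ndarray) -> StateSequence:
    """Jointly most probable duration-respecting path.

    Ties break toward the lower state index, then the shorter current dwell
    (argmax scan order makes both deterministic).
    """
    Y = scan.matrix if isinstance(scan, ScanSeries) else np.asarray(scan, dtype=float)
    if Y.shape[1] != params.n_regions:
        raise ValueError(
            f"scan has {Y.shape[1]} regions but model expects {params.n_regions}"
        )
    T = Y.shape[0]
    K = params.n_states
    if K == 1:
        B = _emission_loglik(Y, params)
        return StateSequence(labels=np.zeros(T, dtype=int), log_joint=float(B.sum()))
    B = _emission_loglik(Y, params)
    D, logpmf, logsf = _dwell_tables(params, T)
    with np.errstate(divide="ignore"):
        logtrans = np.log(params.trans + 0.0)
        loginit = np.log(params.init + 0.0)
    CS = np.vstack([np.zeros(K), np.cumsum(B, axis=0)])

    Av = np.full((T, K), _NEG_INF)
    Ev = np.full((T, K), _NEG_INF)
    Ev[0] = loginit
    bp_state = np.zeros((T, K), dtype=int)   # best previous state for entry at tau
    bp_dur = np.zeros((T, K), dtype=int)     # best duration for segment ending at t
    for t in range(T):
        dmax = min(D, t + 1)
        starts = t - np.arange(1, dmax + 1) + 1
        seg = CS[t + 1][None, :] - CS[starts]
        core = Ev[starts] + seg
        cand = core + logpmf[:dmax]
        best_d = cand.argmax(axis=0)
        Av[t] = cand[best_d, np.arange(K)]
        bp_dur[t] = best_d + 1
        if t == T - 1:
            cand_c = core + logsf[:dmax]
            best_dc = cand_c.argmax(axis=0)
            Av_cens = cand_c[best_dc, np.arange(K)]
            bp_dur_cens = best_dc + 1
        elif t + 1 < T:
            step = Av[t][:, None] + logtrans
            bp_state[t + 1] = step.argmax(axis=0)
            Ev[t + 1] = step[bp_state[t + 1], np.arange(K)]

    labels = np.empty(T, dtype=int)
    k = int(Av_cens.argmax())
    log_joint = float(Av_cens[k])
    d = int(bp_dur_cens[k])
    t = T - 1
    while True:
        tau = t - d + 1
        labels[tau: t + 1] = k
        if tau == 0:
            break
        k = int(bp_state[tau, k])
        t = tau - 1
        d = int(bp_dur[t, k])
    return StateSequence(labels=labels, log_joint=log_joint)


# ---------------------------------------------------------------------------
# initialisation and EM

def init_params(scans, K: int, seed: int = 0, max_dwell: int = 50,
                ridge: float = 1e-6) -> HSMMParams:
    """K-means initialisation of emission parameters on pooled timepoints."""
    Y = np.vstack([s.matrix if isinstance(s, ScanSeries) else np.asarray(s) for s in scans])
    T_pool, R = Y.shape
    if K > T_pool:
        raise ValueError(f"K={K} exceeds pooled timepoints {T_pool}")
    pooled_cov = np.cov(Y.T) + ridge * np.eye(R)
    if K == 1:
        return HSMMParams(
            means=Y.mean(axis=0)[None, :], covs=pooled_cov[None],
            trans=np.zeros((1, 1)), dwell=(ShiftedPoissonDwell(4.0),),
            init=np.ones(1), max_dwell=max_dwell,
        )
    km = KMeans(n_clusters=K, n_init=3, random_state=seed).fit(Y)
    means = km.cluster_centers_.copy()
    covs = np.empty((K, R, R))
    for k in range(K):
        members = Y[km.labels_ == k]
        if members.shape[0] > R + 1:
            covs[k] = np.cov(members.T) + ridge * np.eye(R)
        else:
            covs[k] = pooled_cov
    trans = np.full((K, K), 1.0 / (K - 1))
    np.fill_diagonal(trans, 0.0)
    return HSMMParams(
        means=means, covs=covs, trans=trans,
        dwell=tuple(ShiftedPoissonDwell(4.0) for _ in range(K)),
        init=np.full(K, 1.0 / K), max_dwell=max_dwell,
    )


def _mstep(stats_list, scans_Y, params: HSMMParams, ridge: float,
           dwell_family=ShiftedPoissonDwell) -> HSMMParams:
    K, R = params.n_states, params.n_regions
    D = stats_list[0]["dur_hist"].shape[0]
    S0 = np.zeros(K)
    S1 = np.zeros((K, R))
    S2 = np.zeros((K, R, R))
    dur_hist = np.zeros((D, K))
    trans_counts = np.zeros((K, K))
    init_counts = np.zeros(K)
    for st, Y in zip(stats_list, scans_Y):
        g = st["gamma"]
        S0 += g.sum(axis=0)
        S1 += g.T @ Y
        for k in range(K):
            S2[k] += (Y * g[:, k:k + 1]).T @ Y
        dh = st["dur_hist"]
        dur_hist[: dh.shape[0]] += dh
        trans_counts += st["trans_counts"]
        init_counts += st["init_counts"]

    means = params.means.copy()
    covs = params.covs.copy()
    pooled = np.vstack(scans_Y)
    for k in range(K):
        if S0[k] < 1e-8:
            # empty state: re-seed from the worst-fit timepoints
            logger.warning("state %d lost all responsibility; re-seeding", k)
            B = _emission_loglik(pooled, params)
            worst = np.argsort(B.max(axis=1))[: max(R + 2, 10)]
            means[k] = pooled[worst].mean(axis=0)
            covs[k] = np.cov(pooled.T) + ridge * np.eye(R)
            continue
        mu = S1[k] / S0[k]
        sig = S2[k] / S0[k] - np.outer(mu, mu)
        sig = 0.5 * (sig + sig.T)
        sig += ridge * max(np.trace(sig) / R, 1e-12) * np.eye(R)
        means[k] = mu
        covs[k] = sig

    trans = trans_counts.copy()
    np.fill_diagonal(trans, 0.0)
    rowsum = trans.sum(axis=1, keepdims=True)
    uniform = np.full((K, K), 1.0 / (K - 1))
    np.fill_diagonal(uniform, 0.0)
    trans = np.where(rowsum > 1e-12, trans / np.clip(rowsum, 1e-300, None), uniform)

    init = init_counts + 1e-12
    init = init / init.sum()

    ds = np.arange(1, D + 1)
    new_dwell = []
    for k in range(K):
        w = dur_hist[:, k]
        if w.sum() <= 1e-12:
            new_dwell.append(params.dwell[k])
        else:
            new_dwell.append(dwell_family.fit(ds, w))
    return replace(params, means=means, covs=covs, trans=trans,
                   dwell=tuple(new_dwell), init=init)


def _em_single_start(scans_Y, K: int, config: EMConfig, start_seed: int) -> FitResult:
    params = init_params(scans_Y, K, seed=start_seed,
                         max_dwell=config.max_dwell, ridge=config.ridge)
    if K == 1:
        ll = sum(float(_emission_loglik(Y, params).sum()) for Y in scans_Y)
        return FitResult(params=params, loglik_trace=np.array([ll]),
                         n_iter=1, converged=True)
    trace = []
    converged = False
    for it in range(config.max_iter):
        stats_list = []
        total_ll = 0.0
        for Y in scans_Y:
            B = _emission_loglik(Y, params)
            st = _estep_single(B, params)
            stats_list.append(st)
            total_ll += st["loglik"]
        if not np.isfinite(total_ll):
            raise FloatingPointError(f"non-finite log-likelihood at EM iteration {it}")
        trace.append(total_ll)
        logger.debug("EM iter %d: loglik %.6f", it, total_ll)
        if it >= 1:
            prev = trace[-2]
            rel = (total_ll - prev) / (abs(prev) + 1e-300)
            if abs(rel) < config.tol:
                converged = True
                break
        params = _mstep(stats_list, scans_Y, params, config.ridge)
    return FitResult(params=params, loglik_trace=np.asarray(trace),
                     n_iter=len(trace), converged=converged)


def em_fit(scans, K: int, config: EMConfig | None = None) -> FitResult:
    """Fit the pooled model by multi-start EM; scans are independent sequences."""
    config = config or EMConfig()
    scans_Y = [s.matrix if isinstance(s, ScanSeries) else np.asarray(s, dtype=float)
               for s in scans]
    if not scans_Y:
        raise ValueError("no scans provided")
    R = scans_Y[0].shape[1]
    if any(Y.shape[1] != R for Y in scans_Y):
        raise ValueError("all scans must share the same number of regions")
    seeds = np.random.SeedSequence(config.seed).generate_state(max(config.n_starts, 1))
    best = None
    for s in seeds[: max(config.n_starts, 1)]:
        fit = _em_single_start(scans_Y, K, config, int(s % (2 ** 31)))
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit
    return best


def match_states(fitted_means: np.ndarray, true_means: np.ndarray) -> np.ndarray:
    """Map fitted state index -> true state index by Hungarian assignment on mean distance."""
    from scipy.optimize import linear_sum_assignment

    cost = np.linalg.norm(fitted_means[:, None, :] - true_means[None, :, :], axis=2)
    row, col = linear_sum_assignment(cost)
    out = np.empty(fitted_means.shape[0], dtype=int)
    out[row] = col
    return out
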