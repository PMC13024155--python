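"""State characterization: weighted networks, spectral modularity, activity maps.

Each fitted state's covariance is converted to a correlation matrix (the
weighted network for that state); negative edges are dropped to form the
positive network; communities come from Newman's leading-eigenvector
spectral bisection with Kernighan-Lin-style fine-tuning under a
resolution-scaled null model (gamma = 1 reproduces the classic modularity).
Activity maps z-score each region's mean across states, showing which
regions are more or less active in a state relative to the other states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsmm import HSMMParams

__all__ = [
    "StateNetwork",
    "ActivityMap",
    "cov_to_corr",
    "positive_network",
    "modularity",
    "newman_partition",
    "activity_map",
    "characterize_states",
]


@dataclass
class StateNetwork:
    state: int
    corr: np.ndarray
    positive_adj: np.ndarray
    modules: np.ndarray          # community label per region
    Q: float
    gamma: float


@dataclass
class ActivityMap:
    zmap: np.ndarray             # (K, R) z-scores across states per region


def cov_to_corr(sigma: np.ndarray) -> np.ndarray:
    """corr[i, j] = sigma[i, j] / sqrt(sigma[i, i] * sigma[j, j])."""
    s = np.asarray(sigma, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("covariance must be square")
    if np.abs(s - s.T).max() > 1e-8:
        raise ValueError("covariance must be symmetric")
    d = np.diag(s)
    if (d <= 0).any():
        raise ValueError("covariance diagonal must be strictly positive")
    corr = s / np.sqrt(np.outer(d, d))
    np.fill_diagonal(corr, 1.0)
    return corr


def positive_network(corr: np.ndarray) -> np.ndarray:
    """Keep positive off-diagonal weights; zero the diagonal."""
    adj = np.maximum(np.asarray(corr, dtype=float), 0.0)
    np.fill_diagonal(adj, 0.0)
    return adj


def modularity(adj: np.ndarray, labels, gamma: float = 1.0) -> float:
    """Weighted Q = (1/2m) sum_ij (A_ij - gamma k_i k_j / 2m) delta(c_i, c_j)."""
    A = np.asarray(adj, dtype=float)
    labels = np.asarray(labels)
    m2 = A.sum()
    if m2 <= 0:
        raise ValueError("empty network")
    k = A.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    B = A - gamma * np.outer(k, k) / m2
    return float((B * same).sum() / m2)


def _fine_tune(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Greedy single-vertex flips maximising s^T Bg s (deterministic)."""
    s = s.copy()
    while True:
        Bs = Bg @ s
        gains = -4.0 * s * Bs + 4.0 * np.diag(Bg)
        i = int(np.argmax(gains))
        if gains[i] <= 1e-12:
            return s
        s[i] = -s[i]


def newman_partition(adj: np.ndarray, gamma: float = 1.0):
    """Recursive leading-eigenvector bisection of the gamma-scaled modularity
    matrix; each split is fine-tuned and kept only if it increases Q.

    Returns (labels, Q) with community labels 0..C-1 in order of discovery.
    """
    A = np.asarray(adj, dtype=float)
    n = A.shape[0]
    if A.ndim != 2 or A.shape[1] != n:
        raise ValueError("adjacency must be square")
    if np.abs(A - A.T).max() > 1e-8 or (A < 0).any():
        raise ValueError("adjacency must be symmetric and nonnegative")
    if np.abs(np.diag(A)).max(initial=0.0) > 0:
        raise ValueError("adjacency diagonal must be zero")
    m2 = A.sum()
    if m2 <= 0:
        raise ValueError("empty network")
    k = A.sum(axis=1)
    B = A - gamma * np.outer(k, k) / m2

    labels = np.zeros(n, dtype=int)
    final = []
    stack = [np.arange(n)]
    while stack:
        idx = stack.pop()
        if idx.size == 1:
            final.append(idx)
            continue
        Bg = B[np.ix_(idx, idx)].copy()
        Bg[np.diag_indices(idx.size)] -= Bg.sum(axis=1)
        vals, vecs = np.linalg.eigh(Bg)
        lead = vecs[:, -1]
        if vals[-1] <= 1e-12:
            final.append(idx)
            continue
        s = np.where(lead >= 0, 1.0, -1.0)
        s = _fine_tune(Bg, s)
        dQ = float(s @ Bg @ s) / (2.0 * m2)
        if dQ <= 1e-12 or np.all(s == s[0]):
            final.append(idx)
            continue
        stack.append(idx[s > 0])
        stack.append(idx[s < 0])

    for c, idx in enumerate(sorted(final, key=lambda ix: ix.min())):
        labels[idx] = c
    return labels, modularity(A, labels, gamma)


def activity_map(params: HSMMParams, sd_floor: float = 1e-12) -> ActivityMap:
    """Z-score each region's K state means across states (mean 0, SD 1)."""
    means = params.means
    if params.n_states < 2:
        raise ValueError("activity map needs at least two states")
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    z = (means - mu) / np.maximum(sd, sd_floor)
    z[:, sd <= sd_floor] = 0.0
    return ActivityMap(zmap=z)


def characterize_states(params: HSMMParams, gamma: float = 1.0):
    """Per-state network + community structure, plus the cross-state activity map."""
    nets = []
    for k in range(params.n_states):
        corr = cov_to_corr(params.covs[k])
        adj = positive_network(corr)
        modules, Q = newman_partition(adj, gamma=gamma)
        nets.append(StateNetwork(state=k, corr=corr, positive_adj=adj,
                                 modules=modules, Q=Q, gamma=gamma))
    amap = activity_map(params) if params.n_states >= 2 else None
    return nets, amap
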