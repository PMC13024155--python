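"""State-count selection by the maximin pairwise-distance rule.

Candidate models over a range of K are each fit by EM; the chosen K
maximises the minimum Euclidean distance between any pair of fitted state
means (more separated states = more distinct network configurations). Ties
break toward smaller K. Distances are computed on raw mean vectors by
default; pass standardize=True to z-score regions first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .hsmm import EMConfig, HSMMParams, em_fit

logger = logging.getLogger(__name__)

__all__ = ["SelectionReport", "min_state_distance", "select_k"]


@dataclass
class SelectionReport:
    candidates: list
    min_pairwise_distance: dict      # K -> distance (NaN for failed fits)
    chosen_k: int
    fits: dict                       # K -> FitResult


def min_state_distance(params: HSMMParams, standardize: bool = False) -> float:
    """Minimum Euclidean distance between any pair of state mean vectors."""
    if params.n_states < 2:
        raise ValueError("min_state_distance needs at least two states")
    means = params.means
    if standardize:
        sd = means.std(axis=0, ddof=0)
        means = (means - means.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return float(pdist(means).min())


def select_k(scans, k_range, config: EMConfig | None = None,
             standardize: bool = False) -> SelectionReport:
    """Fit every candidate K and pick the argmax of the maximin distance."""
    lo, hi = (k_range if isinstance(k_range, tuple) else (min(k_range), max(k_range)))
    if lo < 2:
        raise ValueError("candidate state counts must be >= 2")
    candidates = list(range(lo, hi + 1))
    fits = {}
    dists = {}
    for K in candidates:
        try:
            fit = em_fit(scans, K, config)
            fits[K] = fit
            dists[K] = min_state_distance(fit.params, standardize=standardize)
            logger.info("K=%d: min pairwise state distance %.4f", K, dists[K])
        except Exception as exc:  # candidate excluded, not fatal
            logger.warning("fit failed for K=%d: %s", K, exc)
            dists[K] = float("nan")
    ok = [K for K in candidates if np.isfinite(dists[K])]
    if not ok:
        raise RuntimeError("every candidate state count failed to fit")
    best = max(dists[K] for K in ok)
    chosen = min(K for K in ok if dists[K] == best)   # ties -> smaller K
    return SelectionReport(candidates=candidates, min_pairwise_distance=dists,
                           chosen_k=chosen, fits=fits)
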