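"""Dwell (sojourn) time distributions for explicit-duration semi-Markov models.

A dwell distribution lives on the positive integers d = 1, 2, ... and is
always evaluated truncated to 1..max_dwell with renormalisation, so the
recursions that consume it see a proper pmf on a finite grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = ["ShiftedPoissonDwell", "TabularDwell", "dwell_from_dict"]


@dataclass(frozen=True)
class ShiftedPoissonDwell:
    """d - 1 ~ Poisson(lam), so support is d >= 1 and E[d] = 1 + lam."""

    lam: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be nonnegative, got {self.lam}")

    @property
    def mean(self) -> float:
        return 1.0 + self.lam

    def log_pmf(self, max_dwell: int) -> np.ndarray:
        """Log pmf on d = 1..max_dwell, renormalised over the truncated support."""
        d = np.arange(1, max_dwell + 1)
        lp = stats.poisson.logpmf(d - 1, max(self.lam, 1e-12))
        return lp - logsumexp(lp)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return 1 + rng.poisson(self.lam, size=size)

    @classmethod
    def fit(cls, durations: np.ndarray, weights: np.ndarray) -> "ShiftedPoissonDwell":
        """Weighted ML fit: lam = weighted mean duration - 1 (floored at ~0)."""
        w = np.asarray(weights, dtype=float)
        d = np.asarray(durations, dtype=float)
        tot = w.sum()
        if tot <= 0:
            raise ValueError("cannot fit dwell distribution to zero total weight")
        return cls(lam=max(float((w * d).sum() / tot) - 1.0, 1e-3))

    def to_dict(self) -> dict:
        return {"family": "shifted_poisson", "lam": self.lam}


@dataclass(frozen=True)
class TabularDwell:
    """Nonparametric pmf over d = 1..len(pmf); renormalised on evaluation."""

    pmf: tuple

    @classmethod
    def from_array(cls, pmf: np.ndarray) -> "TabularDwell":
        p = np.asarray(pmf, dtype=float)
        if p.ndim != 1 or p.size == 0 or (p < 0).any() or p.sum() <= 0:
            raise ValueError("pmf must be a nonnegative 1-d array with positive mass")
        return cls(pmf=tuple(p / p.sum()))

    @property
    def mean(self) -> float:
        p = np.asarray(self.pmf)
        return float((np.arange(1, p.size + 1) * p).sum())

    def log_pmf(self, max_dwell: int) -> np.ndarray:
        p = np.zeros(max_dwell)
        src = np.asarray(self.pmf)[:max_dwell]
        p[: src.size] = src
        if p.sum() <= 0:
            raise ValueError("dwell pmf has no mass on 1..max_dwell")
        with np.errstate(divide="ignore"):
            return np.log(p / p.sum())

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        p = np.asarray(self.pmf)
        return rng.choice(np.arange(1, p.size + 1), size=size, p=p)

    @classmethod
    def fit(cls, durations: np.ndarray, weights: np.ndarray) -> "TabularDwell":
        d = np.asarray(durations, dtype=int)
        w = np.asarray(weights, dtype=float)
        pmf = np.zeros(int(d.max()))
        np.add.at(pmf, d - 1, w)
        return cls.from_array(pmf)

    def to_dict(self) -> dict:
        return {"family": "tabular", "pmf": list(self.pmf)}


def dwell_from_dict(d: dict):
    family = d.get("family")
    if family == "shifted_poisson":
        return ShiftedPoissonDwell(lam=float(d["lam"]))
    if family == "tabular":
        return TabularDwell.from_array(np.asarray(d["pmf"], dtype=float))
    raise ValueError(f"unknown dwell family {family!r}")
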