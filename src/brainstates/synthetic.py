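"""Synthetic two-group cohorts with known semi-Markov brain-state structure.

The generator emulates the study design this pipeline targets: 32
participants (15 mindfulness, 17 control), two recovery scans each, 281
usable volumes per scan at TR = 2 s, and 36 ROIs spanning two subnetworks.
Emission parameters (state means and covariances) are shared across groups —
states are population-level — while the groups differ only in transition
rows and dwell parameters. A per-scan outcome ("stress") score is linearly
coupled to state occupancy with a per-participant random intercept, giving
the association stage a recoverable ground truth.

One master seed drives a hierarchical stream (parameters -> paths ->
observations -> scores), so each layer is individually reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .durations import ShiftedPoissonDwell
from .hsmm import HSMMParams, StateSequence
from .io import CohortManifest, ScanSeries

__all__ = [
    "StressModel",
    "GroundTruth",
    "CohortDesign",
    "generate_params",
    "sample_path",
    "sample_observations",
    "generate_cohort",
    "generate_stress",
    "stationary_occupancy",
]


@dataclass(frozen=True)
class StressModel:
    """score = intercept + slopes . occupancy_pct + participant intercept + noise,
    clipped to the instrument's 1-10 scale."""

    intercept: float = 4.5
    slope_per_state: tuple = ()
    noise_sd: float = 1.0
    random_intercept_sd: float = 0.5


@dataclass
class GroundTruth:
    """Everything the generator knows and downstream stages try to recover."""

    params_by_group: dict                 # group -> HSMMParams (shared emissions)
    true_paths: dict                      # (participant_id, scan_id) -> StateSequence
    stress_model: StressModel

    def __post_init__(self):
        ms = [p.means for p in self.params_by_group.values()]
        for m in ms[1:]:
            if not np.allclose(m, ms[0]):
                raise ValueError("emission parameters must be identical across groups")


@dataclass
class CohortDesign:
    """Study-scale defaults with a designated-state group contrast.

    Group 1 (mindfulness) dwells longer in `designated_state` and transitions
    into it more often; group 2 (control) follows the base dynamics. Stress
    is negatively coupled to designated-state occupancy, echoing the
    association the pipeline is meant to detect.
    """

    n_group1: int = 15
    n_group2: int = 17
    scans_per_participant: int = 2
    T: int = 281
    R: int = 36
    K: int = 6
    separation: float = 4.0
    tr_seconds: float = 2.0
    max_dwell: int = 50
    base_dwell_mean: float = 5.0          # timepoints; >= 3 per generator contract
    designated_state: int = 0
    group1_designated_dwell_mean: float = 9.0
    group1_p_to_designated: float = 0.45  # off-diagonal mass toward the designated state
    # symmetric baseline dynamics keep the group contrast concentrated in the
    # designated state; with a random baseline the contrast is confounded by
    # whatever asymmetry the draw happens to contain
    uniform_base_trans: bool = True
    stress_intercept: float = 4.5
    stress_slope_designated: float = -0.06    # per occupancy percentage point
    stress_noise_sd: float = 1.0
    stress_random_intercept_sd: float = 0.5


def _random_spd(rng: np.random.Generator, R: int) -> np.ndarray:
    """Unit-scale SPD covariance with modest random correlations."""
    A = rng.normal(size=(R, R + 5)) / np.sqrt(R + 5)
    S = A @ A.T + 0.5 * np.eye(R)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def generate_params(R: int, K: int, separation: float = 4.0, seed: int = 0,
                    dwell_mean: float = 5.0, max_dwell: int = 50,
                    geometry: str = "random") -> HSMMParams:
    """Ground-truth parameters with minimum pairwise mean separation.

    Means are placed so every pair is at least `separation` apart (Euclidean,
    in units of the within-state signal scale, which is ~1 per region).
    geometry="random" draws them freely (with bounded retries); "simplex"
    places them at the vertices of a randomly-oriented regular simplex with
    edge exactly `separation`, i.e. all states equally distinct.
    """
    if K < 1 or R < 2:
        raise ValueError("need K >= 1 and R >= 2")
    if dwell_mean < 3:
        raise ValueError("mean dwell must be >= 3 timepoints")
    rng = np.random.default_rng(seed)
    if geometry == "simplex":
        if K - 1 > R:
            raise ValueError("simplex geometry needs K - 1 <= R")
        V = np.eye(K, R)                       # K unit vectors, edge sqrt(2)
        V = (V - V.mean(axis=0)) * (separation / np.sqrt(2.0))
        Q, _ = np.linalg.qr(rng.normal(size=(R, R)))
        means = V @ Q
    elif geometry == "random":
        for _ in range(200):
            # typical pairwise distance ~1.5x separation, so retries stay rare
            means = rng.normal(scale=1.5 * separation / np.sqrt(2 * R), size=(K, R))
            if K == 1:
                break
            dists = np.linalg.norm(means[:, None] - means[None, :], axis=2)
            np.fill_diagonal(dists, np.inf)
            if dists.min() >= separation:
                break
        else:
            raise RuntimeError(
                f"could not place {K} means with separation {separation} "
                f"after bounded retries"
            )
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    covs = np.stack([_random_spd(rng, R) for _ in range(K)])
    if K == 1:
        trans = np.zeros((1, 1))
    else:
        trans = rng.dirichlet(np.ones(K - 1), size=K)
        full = np.zeros((K, K))
        for k in range(K):
            full[k, np.arange(K) != k] = trans[k]
        trans = full
    dwell = tuple(ShiftedPoissonDwell(dwell_mean - 1.0) for _ in range(K))
    init = np.full(K, 1.0 / K)
    return HSMMParams(means=means, covs=covs, trans=trans, dwell=dwell,
                      init=init, max_dwell=max_dwell)


def sample_path(params: HSMMParams, T: int, seed_or_rng) -> StateSequence:
    """Semi-Markov sampling; the final dwell is truncated at T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    K = params.n_states
    labels = np.empty(T, dtype=int)
    if K == 1:
        labels[:] = 0
        return StateSequence(labels=labels)
    t = 0
    state = int(rng.choice(K, p=params.init))
    while t < T:
        d = int(params.dwell[state].sample(rng))
        end = min(t + d, T)
        labels[t:end] = state
        t = end
        if t < T:
            if K == 1:
                raise RuntimeError("single-state model cannot transition")
            state = int(rng.choice(K, p=params.trans[state]))
    return StateSequence(labels=labels)


def sample_observations(params: HSMMParams, path: StateSequence, seed_or_rng) -> np.ndarray:
    """Draw row t from the multivariate normal of state path[t], independently."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    labels = path.labels
    if labels.max(initial=0) >= params.n_states:
        raise ValueError("path contains labels outside the model's states")
    T = labels.size
    R = params.n_regions
    Y = np.empty((T, R))
    Z = rng.standard_normal(size=(T, R))
    for k in range(params.n_states):
        idx = np.flatnonzero(labels == k)
        if idx.size == 0:
            continue
        chol = np.linalg.cholesky(params.covs[k])
        Y[idx] = params.means[k] + Z[idx] @ chol.T
    return Y


def _group_params(base: HSMMParams, design: CohortDesign, group1: bool) -> HSMMParams:
    if not group1 or base.n_states == 1:
        return base
    k0 = design.designated_state
    dwell = list(base.dwell)
    dwell[k0] = ShiftedPoissonDwell(design.group1_designated_dwell_mean - 1.0)
    K = base.n_states
    trans = base.trans.copy()
    p0 = design.group1_p_to_designated
    for j in range(K):
        if j == k0:
            continue
        others = [c for c in range(K) if c not in (j, k0)]
        if not others:           # K=2: the designated state is the only target
            trans[j, k0] = 1.0
            continue
        rest = trans[j, others]
        rest = rest / rest.sum() if rest.sum() > 0 else np.full(len(others), 1.0 / len(others))
        trans[j, k0] = p0
        trans[j, others] = (1.0 - p0) * rest
    return dataclasses.replace(base, dwell=tuple(dwell), trans=trans)


def generate_cohort(design: CohortDesign | None = None, seed: int = 0):
    """Generate (manifest, scans, ground_truth) for a two-group cohort.

    Group-1 scans are sampled under the group-1 dwell/transition parameters
    and likewise for group 2; emissions are shared. Fully reproducible from
    the seed.
    """
    design = design or CohortDesign()
    if min(design.n_group1, design.n_group2, design.scans_per_participant, design.T) < 1:
        raise ValueError("all cohort counts must be positive")
    ss = np.random.SeedSequence(seed)
    s_params, s_paths, s_obs, s_scores = ss.spawn(4)

    base = generate_params(
        design.R, design.K, separation=design.separation,
        seed=int(s_params.generate_state(1)[0] % (2 ** 31)),
        dwell_mean=design.base_dwell_mean, max_dwell=design.max_dwell,
    )
    if design.uniform_base_trans and design.K > 1:
        uni = np.full((design.K, design.K), 1.0 / (design.K - 1))
        np.fill_diagonal(uni, 0.0)
        base = dataclasses.replace(base, trans=uni)
    params_by_group = {
        "mindfulness": _group_params(base, design, group1=True),
        "control": _group_params(base, design, group1=False),
    }
    slopes = np.zeros(design.K)
    slopes[design.designated_state] = design.stress_slope_designated
    stress_model = StressModel(
        intercept=design.stress_intercept, slope_per_state=tuple(slopes),
        noise_sd=design.stress_noise_sd,
        random_intercept_sd=design.stress_random_intercept_sd,
    )

    rng_paths = np.random.default_rng(s_paths)
    rng_obs = np.random.default_rng(s_obs)
    region_names = tuple(f"roi{j}" for j in range(design.R))
    rows = []
    scans = []
    true_paths = {}
    groups = (["mindfulness"] * design.n_group1) + (["control"] * design.n_group2)
    for i, group in enumerate(groups):
        pid = f"sub{i:03d}"
        for s in range(design.scans_per_participant):
            sid = f"scan{s}"
            path = sample_path(params_by_group[group], design.T, rng_paths)
            Y = sample_observations(params_by_group[group], path, rng_obs)
            scans.append(ScanSeries(
                participant_id=pid, scan_id=sid, group=group, matrix=Y,
                tr_seconds=design.tr_seconds, region_names=region_names,
            ))
            true_paths[(pid, sid)] = path
            rows.append({"participant_id": pid, "scan_id": sid, "group": group,
                         "stress_score": np.nan, "avg_drinks": np.nan,
                         "path": f"{pid}_{sid}.csv"})

    truth = GroundTruth(params_by_group=params_by_group, true_paths=true_paths,
                        stress_model=stress_model)

    # occupancy of each true path -> stress scores and a drinks covariate
    occ = np.stack([
        100.0 * np.bincount(true_paths[(r["participant_id"], r["scan_id"])].labels,
                            minlength=design.K) / design.T
        for r in rows
    ])
    pids = [r["participant_id"] for r in rows]
    scores = generate_stress(truth, occ, pids, np.random.default_rng(s_scores))
    rng_scores = np.random.default_rng(s_scores.spawn(1)[0])
    drinks_by_pid = {p: float(np.clip(rng_scores.normal(2.2, 0.8), 0.0, None))
                     for p in dict.fromkeys(pids)}
    for r, sc in zip(rows, scores):
        r["stress_score"] = float(sc)
        r["avg_drinks"] = drinks_by_pid[r["participant_id"]]

    manifest = CohortManifest(rows=pd.DataFrame(rows))
    return manifest, scans, truth


def generate_stress(truth: GroundTruth, occupancy_pct: np.ndarray,
                    participant_ids, seed_or_rng) -> np.ndarray:
    """Outcome scores from the linear occupancy model, clipped to [1, 10]."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    occ = np.atleast_2d(np.asarray(occupancy_pct, dtype=float))
    sm = truth.stress_model
    slopes = np.asarray(sm.slope_per_state, dtype=float)
    if occ.shape[0] != len(participant_ids):
        raise ValueError("need one occupancy vector per scan")
    if slopes.size != occ.shape[1]:
        raise ValueError("slope_per_state length must match the number of states")
    intercepts = {}
    for p in dict.fromkeys(participant_ids):
        intercepts[p] = rng.normal(0.0, sm.random_intercept_sd) if sm.random_intercept_sd > 0 else 0.0
    raw = (sm.intercept + occ @ slopes
           + np.array([intercepts[p] for p in participant_ids])
           + (rng.normal(0.0, sm.noise_sd, size=occ.shape[0]) if sm.noise_sd > 0 else 0.0))
    clipped = np.clip(raw, 1.0, 10.0)
    n_clip = int((clipped != raw).sum())
    if n_clip:
        import logging
        logging.getLogger(__name__).info("clipped %d stress scores to [1, 10]", n_clip)
    return clipped


def stationary_occupancy(params: HSMMParams) -> np.ndarray:
    """Long-run occupancy fractions: occ_k ∝ pi_k * E[dwell_k], with pi the
    stationary distribution of the embedded (jump) chain."""
    K = params.n_states
    if K == 1:
        return np.ones(1)
    P = params.trans
    vals, vecs = np.linalg.eig(P.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = pi / pi.sum()
    m = np.array([d.mean for d in params.dwell])
    occ = pi * m
    return occ / occ.sum()
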