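"""Per-scan state-dynamics summaries from decoded label sequences.

Three summaries per the analysis design: occupancy time (percent of
timepoints per state), transition frequency (number of entries into each
state; the initial state is not an entry), and dwell times (run lengths,
with the first and last runs of a scan excluded by default, since the time
spent in a state immediately before/after the scan window is unknown).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .hsmm import StateSequence

__all__ = [
    "DynamicsSummary",
    "occupancy_time",
    "transition_frequency",
    "dwell_times",
    "dwell_density",
    "run_lengths",
    "summarize_scan",
    "summarize_cohort",
]


@dataclass(frozen=True)
class DynamicsSummary:
    occupancy_pct: np.ndarray      # (K,) percentages, sums to 100
    transitions_in: np.ndarray     # (K,) nonnegative entry counts
    dwells: dict                   # state -> list of run lengths (edge-excluded)


def _labels_of(seq) -> np.ndarray:
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq, dtype=int)
    if labels.size == 0:
        raise ValueError("empty state sequence")
    return labels


def occupancy_time(seq, K: int) -> np.ndarray:
    """100 * (timepoints in state k) / T for each state."""
    labels = _labels_of(seq)
    if labels.max() >= K or labels.min() < 0:
        raise ValueError(f"labels outside 0..{K - 1}")
    return 100.0 * np.bincount(labels, minlength=K) / labels.size


def transition_frequency(seq, K: int, count_initial: bool = False) -> np.ndarray:
    """Number of change-points entering each state.

    The state occupied at t=0 is not counted as an entry unless
    count_initial is set (the inclusive convention).
    """
    labels = _labels_of(seq)
    if labels.max() >= K or labels.min() < 0:
        raise ValueError(f"labels outside 0..{K - 1}")
    change = labels[1:][labels[1:] != labels[:-1]]
    counts = np.bincount(change, minlength=K)
    if count_initial:
        counts[labels[0]] += 1
    return counts


def run_lengths(labels: np.ndarray):
    """Run-length encoding: list of (state, length) covering the sequence."""
    labels = np.asarray(labels)
    breaks = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [labels.size]])
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def dwell_times(seq, K: int, exclude_edges: bool = True) -> dict:
    """Map state -> list of dwell lengths; first/last runs dropped if excluding edges."""
    labels = _labels_of(seq)
    if labels.max() >= K or labels.min() < 0:
        raise ValueError(f"labels outside 0..{K - 1}")
    runs = run_lengths(labels)
    if exclude_edges:
        runs = runs[1:-1] if len(runs) > 2 else []
    out = {k: [] for k in range(K)}
    for state, length in runs:
        out[state].append(length)
    return out


def dwell_density(dwells, max_dwell: int, bandwidth: float | None = None,
                  floor: float = 1e-10) -> np.ndarray:
    """Discrete density on 1..max_dwell by Gaussian-kernel smoothing.

    Bandwidth defaults to Silverman's rule on the integer data (floored so a
    degenerate sample still yields a near-point mass). The result is floored
    at `floor` and renormalised, so downstream KL divergences are finite.
    """
    d = np.asarray(list(dwells), dtype=float)
    if d.size == 0:
        raise ValueError("no dwells for state")
    if bandwidth is None:
        sd = d.std(ddof=1) if d.size > 1 else 0.0
        iqr = np.subtract(*np.percentile(d, [75, 25])) if d.size > 1 else 0.0
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * spread * d.size ** (-0.2) if spread > 0 else 0.25
    bandwidth = max(bandwidth, 1e-3)
    grid = np.arange(1, max_dwell + 1)
    dens = norm.pdf(grid[:, None], loc=d[None, :], scale=bandwidth).mean(axis=1)
    dens = np.maximum(dens, floor)
    return dens / dens.sum()


def summarize_scan(seq, K: int) -> DynamicsSummary:
    return DynamicsSummary(
        occupancy_pct=occupancy_time(seq, K),
        transitions_in=transition_frequency(seq, K),
        dwells=dwell_times(seq, K, exclude_edges=True),
    )


def summarize_cohort(decoded: dict, manifest, K: int) -> pd.DataFrame:
    """Long-format table: one row per (scan, state).

    decoded maps (participant_id, scan_id) -> StateSequence or label array.
    Dwell lists are serialized as ';'-joined integers to keep the table flat.
    """
    records = []
    for row in manifest.rows.itertuples(index=False):
        key = (str(row.participant_id), str(row.scan_id))
        summ = summarize_scan(decoded[key], K)
        for k in range(K):
            records.append({
                "participant_id": key[0], "scan_id": key[1], "group": row.group,
                "state": k,
                "occupancy_pct": summ.occupancy_pct[k],
                "transitions_in": int(summ.transitions_in[k]),
                "dwells": ";".join(str(x) for x in summ.dwells[k]),
            })
    return pd.DataFrame(records)
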