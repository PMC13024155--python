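"""Reading, writing and shared domain types for the state-dynamics pipeline.

Inputs are already-parcellated ROI time series: one delimited text matrix per
scan (timepoints x regions, header row of region names) plus a cohort
manifest tying scans to participants, groups, outcome scores and covariates.
All upstream image processing (registration, filtering, nuisance regression)
is assumed done before this stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

GROUPS = ("mindfulness", "control")

MANIFEST_COLUMNS = ["participant_id", "scan_id", "group", "stress_score", "avg_drinks", "path"]

__all__ = [
    "GROUPS",
    "ScanSeries",
    "CohortManifest",
    "RunConfig",
    "read_manifest",
    "write_manifest",
    "read_scan",
    "write_scan",
    "trim_series",
    "write_json",
    "read_json",
]


class ValidationError(ValueError):
    """Raised for malformed manifests or scan matrices."""


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


@dataclass(frozen=True)
class ScanSeries:
    """One scan's ROI time series with identity and group metadata.

    matrix has shape (T, R): T timepoints by R regions, arbitrary signal
    units. Region order is fixed by region_names and must agree across scans
    entering a pooled fit.
    """

    participant_id: str
    scan_id: str
    group: str
    matrix: np.ndarray
    tr_seconds: float = 2.0
    region_names: tuple = ()

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
            raise ValidationError(
                f"scan {self.participant_id}/{self.scan_id}: matrix must be T x R with "
                f"T >= 2 and R >= 2, got shape {m.shape}"
            )
        if not np.isfinite(m).all():
            raise ValidationError(
                f"scan {self.participant_id}/{self.scan_id}: matrix contains non-finite values"
            )
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if not self.region_names:
            object.__setattr__(
                self, "region_names", tuple(f"roi{j}" for j in range(m.shape[1]))
            )
        names = tuple(self.region_names)
        object.__setattr__(self, "region_names", names)
        if len(names) != m.shape[1] or len(set(names)) != len(names):
            raise ValidationError("region_names must be unique and match the matrix width")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class CohortManifest:
    """Table of scans: participant, scan, group, stress score, drinks, file path."""

    rows: pd.DataFrame

    def __post_init__(self):
        df = self.rows
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("no scans in manifest")
        df = df.copy()
        df["group"] = df["group"].astype(str).str.strip().str.lower()
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown group labels {bad}; expected {GROUPS}")
        dup = df.duplicated(subset=["participant_id", "scan_id"])
        if dup.any():
            pairs = df.loc[dup, ["participant_id", "scan_id"]].values.tolist()
            raise ValidationError(f"duplicate (participant_id, scan_id) rows: {pairs}")
        n_groups = df.groupby("participant_id")["group"].nunique()
        split = n_groups[n_groups > 1]
        if len(split):
            raise ValidationError(
                f"participants assigned to more than one group: {list(split.index)}"
            )
        object.__setattr__(self, "rows", df.reset_index(drop=True))

    @property
    def participants(self) -> list:
        return list(dict.fromkeys(self.rows["participant_id"]))

    def group_of(self, participant_id: str) -> str:
        sel = self.rows.loc[self.rows["participant_id"] == participant_id, "group"]
        return sel.iloc[0]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the study's analysis choices."""

    n_states_range: tuple = (3, 7)
    n_permutations: int = 500
    fdr_alpha: float = 0.05
    modularity_gamma: float = 1.0
    seed: int = 0
    trim_leading: int = 10
    trim_edges: int = 3
    max_dwell: int = 50

    def __post_init__(self):
        lo, hi = self.n_states_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"bad n_states_range {self.n_states_range}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must lie in (0, 1)")
        if self.modularity_gamma <= 0:
            raise ValidationError("modularity_gamma must be positive")
        if self.trim_leading < 0 or self.trim_edges < 0:
            raise ValidationError("trim counts must be nonnegative")
        if self.max_dwell < 1:
            raise ValidationError("max_dwell must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "n_states_range" in raw:
            raw["n_states_range"] = tuple(raw["n_states_range"])
        return cls(**raw)


def read_manifest(path) -> CohortManifest:
    """Read a delimited-text cohort manifest (CSV or TSV by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if len(df) == 0:
        raise ValidationError(f"no scans in manifest {path}")
    return CohortManifest(rows=df)


def write_manifest(manifest: CohortManifest, path) -> None:
    path = Path(path)
    manifest.rows.to_csv(path, sep=_sep_for(path), index=False)


def read_scan(path, *, participant_id: str, scan_id: str, group: str,
              tr_seconds: float = 2.0, region_names=None) -> ScanSeries:
    """Read one scan matrix (T x R delimited text with a region-name header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    header = tuple(str(c) for c in df.columns)
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{path}: non-numeric cell {df.iat[i, j]!r} at row {i}, "
                        f"column {j} ({header[j]})"
                    ) from None
        arr = df.astype(float).to_numpy()
    if np.isnan(arr).any():
        i, j = map(int, np.argwhere(np.isnan(arr))[0])
        raise ValidationError(f"{path}: missing value at row {i}, column {j} ({header[j]})")
    if region_names is not None and tuple(region_names) != header:
        raise ValidationError(
            f"{path}: region order {header} does not match expected {tuple(region_names)}"
        )
    return ScanSeries(
        participant_id=participant_id, scan_id=scan_id, group=group,
        matrix=arr, tr_seconds=tr_seconds, region_names=header,
    )


def write_scan(scan: ScanSeries, path) -> None:
    path = Path(path)
    pd.DataFrame(scan.matrix, columns=list(scan.region_names)).to_csv(
        path, sep=_sep_for(path), index=False
    )


def load_cohort(manifest: CohortManifest, base_dir=None, tr_seconds: float = 2.0) -> list:
    """Read every scan in the manifest; region order checked against the first scan."""
    scans = []
    region_names = None
    for row in manifest.rows.itertuples(index=False):
        p = Path(row.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        scan = read_scan(
            p, participant_id=str(row.participant_id), scan_id=str(row.scan_id),
            group=row.group, tr_seconds=tr_seconds, region_names=region_names,
        )
        if region_names is None:
            region_names = scan.region_names
        scans.append(scan)
    return scans


def trim_series(scan: ScanSeries, trim_leading: int, trim_edges: int) -> ScanSeries:
    """Drop the leading settle-in block, then a symmetric edge block.

    The leading volumes are removed first (signal steady-state), then
    trim_edges timepoints from each end (band-pass edge effects), matching
    the acquisition convention: 297 volumes - 10 - 3 - 3 = 281 usable.
    """
    if trim_leading < 0 or trim_edges < 0:
        raise ValueError("trim counts must be nonnegative")
    T = scan.n_timepoints
    remaining = T - trim_leading - 2 * trim_edges
    if remaining < 2:
        raise ValidationError(
            f"scan {self_id(scan)}: trimming {trim_leading}+2*{trim_edges} from T={T} "
            f"leaves {remaining} < 2 timepoints"
        )
    m = scan.matrix[trim_leading:]
    if trim_edges:
        m = m[trim_edges:-trim_edges]
    return dataclasses.replace(scan, matrix=m)


def self_id(scan: ScanSeries) -> str:
    return f"{scan.participant_id}/{scan.scan_id}"


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    """Write a results object (dataclass / dict / arrays) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_NumpyEncoder, indent=1)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
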