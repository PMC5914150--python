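"""Functional connectivity construction from ROI time series.

Subjects are scanned in two task conditions; each scan yields one T x d
matrix of regional signal time courses (d regions of a parcellation atlas).
Pairwise Pearson correlation followed by Fisher's z transform gives a
symmetric d x d connectivity matrix per subject and condition.  Graph
analysis keeps only positive connections: edges are placed where the
Fisher-z value exceeds a non-negative threshold, producing an unweighted,
undirected adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegionAtlas",
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "Adjacency",
    "pearson_fisher_connectivity",
    "positive_adjacency",
    "group_average_connectivity",
    "load_atlas",
    "load_timeseries",
    "load_connectivity_matrix",
    "save_connectivity_matrix",
]

DEFAULT_CLIP = 1.0 - 1e-7


class ConnectomeError(ValueError):
    """Invalid connectome input (dimensions, variance, labels)."""


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered parcellation: region names define node indices (0-based)."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        if len(names) < 3:
            raise ConnectomeError(f"atlas needs >= 3 regions, got {len(names)}")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConnectomeError(f"duplicate region names in atlas: {dupes}")

    @property
    def d(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class RoiTimeSeries:
    """One scan: T timepoints x d regional signal courses."""

    subject_id: str
    condition: str
    values: np.ndarray
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConnectomeError("time series must be a 2-D (T x d) array")
        T, d = self.values.shape
        if d != self.atlas.d:
            raise ConnectomeError(
                f"time series has {d} columns but atlas has {self.atlas.d} regions"
            )
        if T < 3:
            raise ConnectomeError(f"need >= 3 timepoints, got {T}")
        if not np.all(np.isfinite(self.values)):
            raise ConnectomeError("time series contains non-finite values")
        sd = self.values.std(axis=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            names = [self.atlas.names[i] for i in flat]
            raise ConnectomeError(
                f"zero-variance (constant) time course for region(s): {names}"
            )

    @property
    def T(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric d x d Fisher-z connectivity, zero diagonal."""

    subject_id: str
    condition: str
    z: np.ndarray
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        d = self.atlas.d
        if self.z.shape != (d, d):
            raise ConnectomeError(
                f"connectivity is {self.z.shape}, atlas expects ({d}, {d})"
            )
        if not np.all(np.isfinite(self.z)):
            raise ConnectomeError("connectivity contains non-finite entries")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ConnectomeError("connectivity matrix is not symmetric")
        # Enforce exact conventions rather than trusting float round-trips.
        self.z = (self.z + self.z.T) / 2.0
        np.fill_diagonal(self.z, 0.0)

    @property
    def d(self) -> int:
        return self.atlas.d


@dataclass
class Adjacency:
    """Binary undirected graph obtained by thresholding positive z values."""

    a: np.ndarray
    threshold: float
    atlas: RegionAtlas | None = field(default=None)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        if self.a.ndim != 2 or self.a.shape[0] != self.a.shape[1]:
            raise ConnectomeError("adjacency must be square")
        if not np.array_equal(self.a, self.a.T):
            raise ConnectomeError("adjacency must be symmetric")
        vals = np.unique(self.a)
        if not np.all(np.isin(vals, (0, 1))):
            raise ConnectomeError("adjacency entries must be 0/1")
        self.a = self.a.astype(np.int8)
        np.fill_diagonal(self.a, 0)

    @property
    def d(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2


def pearson_fisher_connectivity(
    ts: RoiTimeSeries, clip: float = DEFAULT_CLIP
) -> ConnectivityMatrix:
    """Pearson correlation between all region pairs, Fisher-z transformed.

    Correlations are clamped to [-clip, clip] before atanh so that duplicated
    (perfectly correlated) regions yield a large finite z instead of inf.
    """
    if not 0.0 < clip < 1.0:
        raise ConnectomeError(f"clip must lie in (0, 1), got {clip}")
    r = np.corrcoef(ts.values, rowvar=False)
    z = np.arctanh(np.clip(r, -clip, clip))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(ts.subject_id, ts.condition, z, ts.atlas)


def positive_adjacency(c: ConnectivityMatrix, threshold: float = 0.0) -> Adjacency:
    """Binarize: edge wherever z > threshold (strict), threshold >= 0.

    Negative connections are always dropped, never absolute-valued; a negative
    threshold would re-admit them and is rejected.
    """
    if threshold < 0:
        raise ConnectomeError(
            f"threshold must be >= 0 (positive-connections convention), got {threshold}"
        )
    a = (c.z > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return Adjacency(a=a, threshold=float(threshold), atlas=c.atlas)


def group_average_connectivity(cs: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of Fisher-z matrices across subjects, one condition."""
    if not cs:
        raise ConnectomeError("cannot average an empty list of matrices")
    atlas = cs[0].atlas
    condition = cs[0].condition
    for c in cs[1:]:
        if c.atlas.names != atlas.names:
            raise ConnectomeError("matrices have mismatched atlases")
        if c.condition != condition:
            raise ConnectomeError(
                f"mixed conditions in group average: {c.condition!r} vs {condition!r}"
            )
    z = np.mean([c.z for c in cs], axis=0)
    return ConnectivityMatrix("group", condition, z, atlas)


# ---------------------------------------------------------------------------
# Delimited-text I/O


def load_atlas(path: str | Path) -> RegionAtlas:
    """Atlas file: one region name per line; order defines node index."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    names = [ln for ln in lines if ln and not ln.startswith("#")]
    if not names:
        raise ConnectomeError(f"atlas file {path} contains no region names")
    return RegionAtlas(tuple(names))


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def load_timeseries(
    path: str | Path, atlas: RegionAtlas, subject_id: str, condition: str
) -> RoiTimeSeries:
    """Read a T x d delimited table whose header names must match the atlas."""
    path = Path(path)
    df = _read_delimited(path)
    cols = [str(c) for c in df.columns]
    if cols != list(atlas.names):
        missing = [n for n in atlas.names if n not in cols]
        extra = [c for c in cols if c not in atlas.names]
        raise ConnectomeError(
            f"{path}: column names do not match atlas "
            f"(missing {missing[:5]}, unexpected {extra[:5]})"
        )
    return RoiTimeSeries(subject_id, condition, df.to_numpy(dtype=float), atlas)


def load_connectivity_matrix(
    path: str | Path, atlas: RegionAtlas, subject_id: str, condition: str
) -> ConnectivityMatrix:
    """Read a d x d delimited Fisher-z matrix (optional header row)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, header=None)
    if raw.shape[0] == atlas.d + 1:  # header row present
        raw = pd.read_csv(path, sep=sep)
    z = raw.to_numpy(dtype=float)
    if z.shape != (atlas.d, atlas.d):
        raise ConnectomeError(
            f"{path}: matrix shape {z.shape} does not match atlas d={atlas.d}"
        )
    return ConnectivityMatrix(subject_id, condition, z, atlas)


def save_connectivity_matrix(c: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    pd.DataFrame(c.z, columns=list(c.atlas.names)).to_csv(path, sep=sep, index=False)
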