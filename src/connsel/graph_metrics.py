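"""Nodal graph metrics and Newman modularity on binary positive-edge graphs.

Three nodal metrics form the classifier feature space, one value per region:

* degree — number of links attached to the node;
* clustering coefficient — fraction of the node's neighbour pairs that are
  themselves connected (triangles around the node);
* betweenness centrality — for every other node pair, the fraction of their
  shortest paths passing through the node, summed over unordered pairs.

Modularity Q of a partition is the within-community edge fraction minus its
degree-based expectation, Q = sum_c (e_c / m - (d_c / 2m)^2).  Communities
are found with Newman's leading-eigenvector spectral bisection, iteratively
subdividing and fine-tuning each split with Kernighan-Lin style single-node
moves.  Spectral bisection is a heuristic: Q is guaranteed consistent with
the returned assignment, not globally optimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Adjacency, ConnectivityMatrix, positive_adjacency

__all__ = [
    "NodalMetricVector",
    "FeatureTable",
    "ModularityPartition",
    "METRICS",
    "nodal_degree",
    "nodal_clustering",
    "nodal_betweenness",
    "nodal_metric",
    "modularity_value",
    "newman_modularity",
    "compute_feature_table",
]

METRICS = ("degree", "clustering", "betweenness")


@dataclass
class NodalMetricVector:
    metric_name: str
    values: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric_name not in METRICS:
            raise ValueError(f"unknown metric {self.metric_name!r}")


@dataclass
class ModularityPartition:
    """Community assignment (contiguous indices from 0) and its Q value."""

    assignment: np.ndarray
    Q: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        labels = np.unique(self.assignment)
        if not np.array_equal(labels, np.arange(labels.size)):
            raise ValueError("community indices must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1


def nodal_degree(a: Adjacency) -> NodalMetricVector:
    return NodalMetricVector("degree", a.a.sum(axis=1).astype(float))


def nodal_clustering(a: Adjacency) -> NodalMetricVector:
    """2 t_i / (k_i (k_i - 1)); zero where the degree is below 2."""
    A = a.a.astype(float)
    k = A.sum(axis=1)
    triangles = np.diag(A @ A @ A) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return NodalMetricVector("clustering", c)


def nodal_betweenness(a: Adjacency, normalized: bool = False) -> NodalMetricVector:
    """Brandes betweenness over unordered pairs; unreachable pairs count 0."""
    g = nx.from_numpy_array(a.a)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return NodalMetricVector("betweenness", np.array([bc[i] for i in range(a.d)]))


def nodal_metric(a: Adjacency, metric_name: str) -> NodalMetricVector:
    if metric_name == "degree":
        return nodal_degree(a)
    if metric_name == "clustering":
        return nodal_clustering(a)
    if metric_name == "betweenness":
        return nodal_betweenness(a)
    raise ValueError(f"unknown metric {metric_name!r}; choose from {METRICS}")


# ---------------------------------------------------------------------------
# Newman modularity


def modularity_value(A: np.ndarray, assignment: np.ndarray) -> float:
    """Q = sum_c (e_c/m - (d_c/2m)^2) for a binary symmetric adjacency."""
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    q = 0.0
    for c in np.unique(assignment):
        idx = assignment == c
        e_c = A[np.ix_(idx, idx)].sum() / 2.0
        d_c = k[idx].sum()
        q += e_c / (two_m / 2.0) - (d_c / two_m) ** 2
    return q


def _kl_refine(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style fine-tuning of a bisection vector s in {-1,+1}.

    Repeated sweeps: move each vertex once, in order of best gain, keeping
    the best configuration seen during the sweep; stop when a full sweep
    yields no improvement.
    """
    s = s.copy()
    best_val = s @ Bg @ s
    improved = True
    while improved:
        improved = False
        moved = np.zeros(len(s), dtype=bool)
        s_work = s.copy()
        val = best_val
        trail = []
        for _ in range(len(s)):
            # Gain of flipping vertex i: delta = -4 s_i (Bg s)_i + 4 Bg_ii
            bs = Bg @ s_work
            gains = -4.0 * s_work * bs + 4.0 * np.diag(Bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            s_work[i] = -s_work[i]
            moved[i] = True
            val = val + gains[i]
            trail.append((val, s_work.copy()))
        sweep_best_val, sweep_best_s = max(trail, key=lambda t: t[0])
        if sweep_best_val > best_val + 1e-12:
            best_val, s = sweep_best_val, sweep_best_s
            improved = True
    return s


def newman_modularity(
    c: ConnectivityMatrix | Adjacency,
    threshold: float = 0.0,
    refine: bool = True,
) -> ModularityPartition:
    """Leading-eigenvector community detection with iterative subdivision.

    A connectivity matrix is first reduced to its positive-edge binary graph
    at ``threshold``.  Each community is split along the sign of the leading
    eigenvector of its generalized modularity matrix; a split is kept only if
    it increases Q (after optional Kernighan-Lin refinement), otherwise the
    community is declared indivisible.
    """
    if isinstance(c, ConnectivityMatrix):
        a = positive_adjacency(c, threshold)
    else:
        a = c
    A = a.a.astype(float)
    n = A.shape[0]
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined: graph has no positive edges")
    B = A - np.outer(k, k) / two_m

    assignment = np.zeros(n, dtype=int)
    queue = [np.arange(n)]
    next_label = 1
    while queue:
        idx = queue.pop()
        if idx.size < 2:
            continue
        Bsub = B[np.ix_(idx, idx)]
        # Generalized modularity matrix: remove row sums on the diagonal.
        Bg = Bsub - np.diag(Bsub.sum(axis=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            evals, evecs = np.linalg.eigh(Bg)
        if evals[-1] <= 1e-12:
            continue  # indivisible
        u = evecs[:, -1]
        s = np.where(u >= 0, 1, -1)
        if refine:
            s = _kl_refine(Bg, s)
        dq = (s @ Bg @ s) / (2.0 * two_m)
        if dq <= 1e-12 or len(set(s)) < 2:
            continue
        sub_idx = idx[s < 0]
        assignment[sub_idx] = next_label
        next_label += 1
        queue.append(idx[s > 0])
        queue.append(sub_idx)

    # Relabel contiguously in order of first appearance.
    _, contiguous = np.unique(assignment, return_inverse=True)
    first_seen: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(contiguous):
        if lab not in first_seen:
            first_seen[lab] = len(first_seen)
        out[i] = first_seen[lab]
    return ModularityPartition(out, modularity_value(A, out))


# ---------------------------------------------------------------------------
# Feature tables


@dataclass
class FeatureTable:
    """Design matrix for the state classifier: one row per subject-condition.

    Every subject contributes exactly one sample per condition, so the two
    classes are exactly balanced and subjects can be held out whole.
    """

    metric_name: str
    X: np.ndarray
    labels: np.ndarray  # condition per row
    groups: np.ndarray  # subject id per row
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        n, d = self.X.shape
        if len(self.labels) != n or len(self.groups) != n:
            raise ValueError("labels/groups length must match number of rows")
        if len(self.region_names) != d:
            raise ValueError("region_names length must match number of columns")
        conds = np.unique(self.labels)
        if conds.size != 2:
            raise ValueError(f"need exactly two conditions, found {list(conds)}")
        for s in np.unique(self.groups):
            got = sorted(self.labels[self.groups == s])
            if got != sorted(conds):
                raise ValueError(
                    f"subject {s!r} must have exactly one sample per condition, "
                    f"found {got}"
                )

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_subjects(self) -> int:
        return np.unique(self.groups).size

    @property
    def conditions(self) -> tuple[str, str]:
        a, b = sorted(np.unique(self.labels).tolist())
        return (a, b)

    def paired_difference(self) -> np.ndarray:
        """(n_subjects x d) per-subject difference, condition B minus A."""
        cond_a, cond_b = self.conditions
        subjects = np.unique(self.groups)
        diff = np.empty((subjects.size, self.d))
        for i, s in enumerate(subjects):
            xa = self.X[(self.groups == s) & (self.labels == cond_a)][0]
            xb = self.X[(self.groups == s) & (self.labels == cond_b)][0]
            diff[i] = xb - xa
        return diff

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.region_names))
        df.insert(0, "condition", self.labels)
        df.insert(0, "subject", self.groups)
        df.insert(0, "metric", self.metric_name)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        meta = {"metric", "subject", "condition"}
        regions = [c for c in df.columns if c not in meta]
        metric = str(df["metric"].iloc[0]) if "metric" in df else "degree"
        return cls(
            metric_name=metric,
            X=df[regions].to_numpy(dtype=float),
            labels=df["condition"].to_numpy(),
            groups=df["subject"].to_numpy(),
            region_names=tuple(regions),
        )


def compute_feature_table(
    cs: list[ConnectivityMatrix], metric_name: str, threshold: float = 0.0
) -> FeatureTable:
    """Nodal metric of every subject-condition positive graph, stacked."""
    if not cs:
        raise ValueError("no connectivity matrices supplied")
    atlas = cs[0].atlas
    rows, labels, groups = [], [], []
    for c in cs:
        v = nodal_metric(positive_adjacency(c, threshold), metric_name)
        rows.append(v.values)
        labels.append(c.condition)
        groups.append(c.subject_id)
    return FeatureTable(
        metric_name=metric_name,
        X=np.vstack(rows),
        labels=np.array(labels),
        groups=np.array(groups),
        region_names=atlas.names,
    )
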