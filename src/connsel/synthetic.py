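"""Synthetic two-condition, within-subject cohorts with planted structure.

Emulates a working-memory style study: each of ``n_subjects`` is observed in
two conditions ("2back" / "3back"); a planted subset S of regions carries the
condition difference, the ground truth against which feature selection is
scored.  Two generation modes:

* ``network`` — a base correlation matrix comes from a low-rank factor model
  (latent communities give realistic modular structure); in the high-load
  condition only, ``edge_effect`` is added to all correlations incident to S;
  matrices are repaired to the nearest valid correlation matrix (eigenvalue
  clipping) and each subject contributes T multivariate-normal timepoints
  per condition, with subject-level loading jitter for between-subject
  variability.

* ``feature`` — graph-metric tables are emitted directly as
  region mean + subject intercept + delta * 1[region in S, high condition]
  + unit-variance noise, so ``feature_effect`` is the planted shift in
  within-subject standard-deviation units.

The generator makes no attempt at hemodynamics or autocorrelated noise;
see the methods note for what that implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectome import RegionAtlas, RoiTimeSeries
from .graph_metrics import METRICS, FeatureTable
from .selection import SelectionMask

__all__ = ["SynthConfig", "generate_cohort", "recovery_score", "default_atlas"]

CONDITIONS = ("2back", "3back")


def default_atlas(d: int) -> RegionAtlas:
    return RegionAtlas(tuple(f"Region_{i:03d}" for i in range(d)))


@dataclass
class SynthConfig:
    d: int = 40
    n_subjects: int = 28
    T: int = 150
    planted_set: tuple[int, ...] | None = None  # default: n_planted drawn at random
    n_planted: int = 10
    edge_effect: float = 0.3  # correlation-scale shift, network mode
    feature_effect: float = 1.5  # shift in noise-sd units, feature mode
    subject_sd: float = 0.1
    base_density: float = 0.6  # target positive-edge fraction of the base matrix
    n_factors: int = 5
    rng_seed: int | None = None
    mode: str = "network"

    def __post_init__(self) -> None:
        if self.mode not in ("network", "feature"):
            raise ValueError(f"mode must be 'network' or 'feature', got {self.mode!r}")
        if self.edge_effect < 0 or self.feature_effect < 0:
            raise ValueError("effect sizes must be non-negative")
        if not 0.0 < self.base_density < 1.0:
            raise ValueError("base_density must lie in (0, 1)")
        if self.planted_set is not None:
            s = tuple(sorted(int(i) for i in self.planted_set))
            if s and (s[0] < 0 or s[-1] >= self.d):
                raise ValueError("planted_set indices must lie in [0, d)")
            if len(set(s)) != len(s):
                raise ValueError("planted_set has duplicates")
            self.planted_set = s


def _cov2corr(c: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(c))
    r = c / np.outer(sd, sd)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def _nearest_correlation(r: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped PSD repair, renormalized to unit diagonal."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    w = np.clip(w, floor, None)
    return _cov2corr((v * w) @ v.T)


def _factor_correlation(loadings: np.ndarray, noise_var: float) -> np.ndarray:
    return _cov2corr(loadings @ loadings.T + noise_var * np.eye(loadings.shape[0]))


def _base_loadings(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Community-structured loadings: strong on the own factor, weak elsewhere."""
    comm = rng.permutation(np.arange(cfg.d) % cfg.n_factors)
    L = rng.normal(0.0, 0.15, size=(cfg.d, cfg.n_factors))
    L[np.arange(cfg.d), comm] += rng.normal(0.8, 0.2, size=cfg.d)
    return L


def _density_shift(r: np.ndarray, target: float) -> float:
    """Off-diagonal additive shift matching the positive-entry fraction."""
    off = r[~np.eye(r.shape[0], dtype=bool)]

    def density(s: float) -> float:
        return float(np.mean(off + s > 0))

    lo, hi = -1.0, 1.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if density(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _subject_correlation(
    L: np.ndarray,
    shift: float,
    cfg: SynthConfig,
    rng: np.random.Generator,
    planted: np.ndarray,
    high_load: bool,
) -> np.ndarray:
    Ls = L + cfg.subject_sd * rng.normal(size=L.shape)
    r = _factor_correlation(Ls, noise_var=0.5)
    r = r + shift * (1.0 - np.eye(cfg.d))
    if high_load and cfg.edge_effect > 0:
        bump = np.zeros_like(r)
        bump[planted, :] += cfg.edge_effect
        bump[:, planted] += cfg.edge_effect
        bump[np.ix_(planted, planted)] /= 2.0  # planted-planted edges bumped once
        np.fill_diagonal(bump, 0.0)
        bumped = bump > 0
        r = r + bump
        if (r[bumped] > 0.995).mean() > 0.5:
            raise ValueError(
                "edge_effect saturates most planted correlations at 1; "
                "reduce edge_effect or base_density"
            )
    off = ~np.eye(cfg.d, dtype=bool)
    r[off] = np.clip(r[off], -0.99, 0.99)
    return _nearest_correlation(r)


def _planted_indices(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.planted_set is not None:
        return np.asarray(cfg.planted_set, dtype=int)
    return np.sort(rng.choice(cfg.d, size=cfg.n_planted, replace=False))


def generate_cohort(cfg: SynthConfig):
    """Build a cohort and its ground truth.

    Returns ``(data, planted)`` where ``planted`` is the sorted array of
    planted region indices and ``data`` is a list of RoiTimeSeries
    (network mode) or a dict of FeatureTable keyed by metric name
    (feature mode).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    planted = _planted_indices(cfg, rng)
    if cfg.mode == "feature":
        return _feature_cohort(cfg, rng, planted), planted
    return _network_cohort(cfg, rng, planted), planted


def _network_cohort(cfg, rng, planted) -> list[RoiTimeSeries]:
    atlas = default_atlas(cfg.d)
    L = _base_loadings(cfg, rng)
    shift = _density_shift(_factor_correlation(L, 0.5), cfg.base_density)
    out = []
    for s in range(cfg.n_subjects):
        sid = f"sub{s + 1:03d}"
        for cond, high in zip(CONDITIONS, (False, True)):
            r = _subject_correlation(L, shift, cfg, rng, planted, high)
            chol = np.linalg.cholesky(r + 1e-10 * np.eye(cfg.d))
            x = rng.normal(size=(cfg.T, cfg.d)) @ chol.T
            out.append(RoiTimeSeries(sid, cond, x, atlas))
    return out


def _feature_cohort(cfg, rng, planted) -> dict[str, FeatureTable]:
    atlas = default_atlas(cfg.d)
    subjects = [f"sub{s + 1:03d}" for s in range(cfg.n_subjects)]
    groups = np.repeat(subjects, 2)
    labels = np.tile(CONDITIONS, cfg.n_subjects)
    tables = {}
    for metric in METRICS:
        mu = rng.normal(0.0, 1.0, size=cfg.d)
        b = rng.normal(0.0, cfg.subject_sd, size=cfg.n_subjects)
        X = np.empty((2 * cfg.n_subjects, cfg.d))
        for i, (g, lab) in enumerate(zip(groups, labels)):
            s = subjects.index(g)
            row = mu + b[s] + rng.normal(0.0, 1.0, size=cfg.d)
            if lab == CONDITIONS[1]:
                row[planted] += cfg.feature_effect
            X[i] = row
        tables[metric] = FeatureTable(
            metric_name=metric,
            X=X,
            labels=labels.copy(),
            groups=groups.copy(),
            region_names=atlas.names,
        )
    return tables


def recovery_score(mask: SelectionMask, planted, d: int | None = None) -> dict:
    """How well a selected mask recovers the planted region set.

    Returns Jaccard index, sensitivity, specificity, and the hypergeometric
    enrichment p-value (probability of at least the observed overlap when
    drawing ``n_selected`` regions at random).
    """
    planted = np.asarray(planted, dtype=int)
    d = len(mask) if d is None else d
    sel = set(mask.indices().tolist())
    tru = set(planted.tolist())
    inter = len(sel & tru)
    union = len(sel | tru)
    jaccard = inter / union if union else 1.0
    sensitivity = inter / len(tru) if tru else 1.0
    neg = d - len(tru)
    specificity = (neg - len(sel - tru)) / neg if neg else 1.0
    p = float(stats.hypergeom.sf(inter - 1, d, len(tru), len(sel))) if sel else 1.0
    return {
        "jaccard": jaccard,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "enrichment_p": p,
        "n_overlap": inter,
    }
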