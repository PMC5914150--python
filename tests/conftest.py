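import numpy as np
import pytest

from connsel import (
    Adjacency,
    FeatureTable,
    RegionAtlas,
    default_atlas,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def atlas6() -> RegionAtlas:
    return default_atlas(6)


def random_adjacency(rng: np.random.Generator, d: int, p: float = 0.4) -> Adjacency:
    upper = np.triu(np.ones((d, d), dtype=bool), 1)
    a = (upper & (rng.random((d, d)) < p)).astype(int)
    a = a + a.T
    return Adjacency(a=a, threshold=0.0)


def make_feature_table(
    rng: np.random.Generator,
    n_subjects: int = 10,
    d: int = 8,
    delta: float = 0.0,
    planted=(),
    metric: str = "degree",
) -> FeatureTable:
    """Paired two-condition table with an optional planted shift."""
    subjects = [f"s{i}" for i in range(n_subjects)]
    groups = np.repeat(subjects, 2)
    labels = np.tile(["2back", "3back"], n_subjects)
    X = rng.normal(size=(2 * n_subjects, d))
    for i, lab in enumerate(labels):
        if lab == "3back" and len(planted):
            X[i, list(planted)] += delta
    return FeatureTable(
        metric_name=metric,
        X=X,
        labels=labels,
        groups=groups,
        region_names=tuple(f"R{i}" for i in range(d)),
    )


def separable_table(n_subjects: int = 8, d: int = 4) -> FeatureTable:
    """First feature separates the conditions with a huge gap."""
    rng = np.random.default_rng(7)
    ft = make_feature_table(rng, n_subjects, d)
    gap = np.where(ft.labels == "3back", 50.0, -50.0)
    X = ft.X.copy()
    X[:, 0] = gap + rng.normal(scale=0.1, size=len(gap))
    return FeatureTable(ft.metric_name, X, ft.labels, ft.groups, ft.region_names)
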