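import numpy as np
import pytest

from connsel import (
    ConnectivityMatrix,
    RegionAtlas,
    RoiTimeSeries,
    group_average_connectivity,
    load_atlas,
    load_connectivity_matrix,
    load_timeseries,
    pearson_fisher_connectivity,
    positive_adjacency,
)
from connsel.connectome import DEFAULT_CLIP, ConnectomeError, save_connectivity_matrix


def _ts(values, atlas, subject="s1", cond="2back"):
    return RoiTimeSeries(subject, cond, np.asarray(values, float), atlas)


class TestAtlas:
    def test_rejects_duplicates_and_tiny(self):
        with pytest.raises(ConnectomeError, match="duplicate"):
            RegionAtlas(("A", "B", "A"))
        with pytest.raises(ConnectomeError, match=">= 3"):
            RegionAtlas(("A", "B"))


class TestPearsonFisher:
    def test_orthogonal_signals_give_zero(self):
        atlas = RegionAtlas(("a", "b", "c"))
        t = [[1, 1, 1], [-1, 1, -1], [1, -1, 1], [-1, -1, -1]]
        c = pearson_fisher_connectivity(_ts(t, atlas))
        assert c.z[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_region_is_clamped_finite(self, rng):
        atlas = RegionAtlas(("a", "b", "c"))
        x = rng.normal(size=20)
        t = np.column_stack([x, x, rng.normal(size=20)])
        c = pearson_fisher_connectivity(_ts(t, atlas))
        assert np.isfinite(c.z[0, 1])
        assert c.z[0, 1] == pytest.approx(np.arctanh(DEFAULT_CLIP))

    def test_known_half_correlation(self):
        # col2 = 0.5*t + sqrt(0.75)*u with t ⟂ u, both zero-mean unit-norm,
        # gives r = 0.5 exactly; z = atanh(0.5).
        atlas = RegionAtlas(("a", "b", "c"))
        t = np.array([1.0, 1.0, -1.0, -1.0])
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, -1.0, -1.0, 1.0])
        data = np.column_stack([t, 0.5 * t + np.sqrt(0.75) * u, v])
        c = pearson_fisher_connectivity(_ts(data, atlas))
        assert c.z[0, 1] == pytest.approx(0.5493061443, abs=1e-6)

    def test_symmetric_zero_diagonal_on_random_inputs(self, rng, atlas6):
        for _ in range(20):
            c = pearson_fisher_connectivity(
                _ts(rng.normal(size=(30, 6)), atlas6)
            )
            assert np.max(np.abs(c.z - c.z.T)) == 0.0
            assert np.all(np.diag(c.z) == 0.0)

    def test_affine_invariance(self, rng, atlas6):
        x = rng.normal(size=(40, 6))
        scale = rng.uniform(0.5, 5.0, size=6)
        shift = rng.normal(size=6)
        c1 = pearson_fisher_connectivity(_ts(x, atlas6))
        c2 = pearson_fisher_connectivity(_ts(x * scale + shift, atlas6))
        np.testing.assert_allclose(c1.z, c2.z, atol=1e-10)

    def test_constant_column_rejected_by_name(self, atlas6):
        x = np.random.default_rng(0).normal(size=(10, 6))
        x[:, 3] = 2.5
        with pytest.raises(ConnectomeError, match="Region_003"):
            _ts(x, atlas6)

    def test_too_few_timepoints(self, atlas6):
        with pytest.raises(ConnectomeError, match="timepoints"):
            _ts(np.random.default_rng(0).normal(size=(2, 6)), atlas6)

    def test_bad_clip_rejected(self, rng, atlas6):
        ts = _ts(rng.normal(size=(10, 6)), atlas6)
        with pytest.raises(ConnectomeError):
            pearson_fisher_connectivity(ts, clip=1.0)


class TestPositiveAdjacency:
    def _cm(self, z, atlas):
        return ConnectivityMatrix("s", "2back", z, atlas)

    def test_only_positive_entries_become_edges(self):
        atlas = RegionAtlas(("a", "b", "c"))
        z = np.array([[0, 0.3, -0.2], [0.3, 0, 0.0], [-0.2, 0.0, 0]])
        a = positive_adjacency(self._cm(z, atlas), 0.0)
        assert a.a[0, 1] == 1 and a.a[0, 2] == 0 and a.a[1, 2] == 0

    def test_all_negative_gives_empty_graph(self):
        atlas = RegionAtlas(("a", "b", "c"))
        z = -0.4 * (1 - np.eye(3))
        a = positive_adjacency(self._cm(z, atlas))
        assert a.n_edges == 0

    def test_strict_threshold_boundary(self):
        atlas = RegionAtlas(("a", "b", "c"))
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 0.6
        z[1, 2] = z[2, 1] = 0.5
        a = positive_adjacency(self._cm(z, atlas), 0.5)
        assert a.n_edges == 1 and a.a[0, 1] == 1

    def test_negative_threshold_rejected(self, rng, atlas6):
        c = pearson_fisher_connectivity(_ts(rng.normal(size=(20, 6)), atlas6))
        with pytest.raises(ConnectomeError, match="positive"):
            positive_adjacency(c, -0.1)

    def test_monotone_in_threshold(self, rng, atlas6):
        c = pearson_fisher_connectivity(_ts(rng.normal(size=(20, 6)), atlas6))
        prev = positive_adjacency(c, 0.0).a
        for tau in (0.1, 0.3, 0.6):
            cur = positive_adjacency(c, tau).a
            assert np.all(cur <= prev)
            prev = cur


class TestGroupAverage:
    def test_mean_and_idempotence(self, rng, atlas6):
        c = pearson_fisher_connectivity(_ts(rng.normal(size=(20, 6)), atlas6))
        avg = group_average_connectivity([c, c, c])
        np.testing.assert_allclose(avg.z, c.z)
        c2 = pearson_fisher_connectivity(
            _ts(rng.normal(size=(20, 6)), atlas6, subject="s2")
        )
        avg = group_average_connectivity([c, c2])
        np.testing.assert_allclose(avg.z, (c.z + c2.z) / 2)
        assert np.max(np.abs(avg.z - avg.z.T)) == 0.0

    def test_mixed_conditions_rejected(self, rng, atlas6):
        c1 = pearson_fisher_connectivity(_ts(rng.normal(size=(20, 6)), atlas6))
        c2 = pearson_fisher_connectivity(
            _ts(rng.normal(size=(20, 6)), atlas6, cond="3back")
        )
        with pytest.raises(ConnectomeError, match="condition"):
            group_average_connectivity([c1, c2])
        with pytest.raises(ConnectomeError, match="empty"):
            group_average_connectivity([])


class TestIO:
    def test_atlas_and_timeseries_roundtrip(self, tmp_path, rng, atlas6):
        apath = tmp_path / "atlas.txt"
        apath.write_text("".join(f"{n}\n" for n in atlas6.names))
        atlas = load_atlas(apath)
        assert atlas.names == atlas6.names

        import pandas as pd

        x = rng.normal(size=(15, 6))
        tpath = tmp_path / "ts.tsv"
        pd.DataFrame(x, columns=list(atlas.names)).to_csv(tpath, sep="\t", index=False)
        ts = load_timeseries(tpath, atlas, "s1", "2back")
        np.testing.assert_allclose(ts.values, x)

        bad = tmp_path / "bad.tsv"
        pd.DataFrame(x[:, :5], columns=list(atlas.names[:5])).to_csv(
            bad, sep="\t", index=False
        )
        with pytest.raises(ConnectomeError, match="atlas"):
            load_timeseries(bad, atlas, "s1", "2back")

    def test_matrix_roundtrip(self, tmp_path, rng, atlas6):
        c = pearson_fisher_connectivity(_ts(rng.normal(size=(20, 6)), atlas6))
        mpath = tmp_path / "conn.tsv"
        save_connectivity_matrix(c, mpath)
        c2 = load_connectivity_matrix(mpath, atlas6, "s1", "2back")
        np.testing.assert_allclose(c2.z, c.z, atol=1e-12)
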