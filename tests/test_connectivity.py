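import numpy as np
import pytest

from cvte.connectivity import (
    ConnectivityMatrix,
    ROIConnectivity,
    ROISeriesSet,
    extract_roi_series,
    group_edge_test,
    magphase_correlation,
    network_block_counts,
    read_connectivity_csv,
    write_connectivity_csv,
)
from cvte.entropy import TEConfig
from cvte.signals import ComplexSeries
from cvte.simulate import generate_pair


def _random_antisym(rng, n, scale=1.0):
    m = rng.normal(scale=scale, size=(n, n))
    m = np.triu(m, 1)
    m = m - m.T
    return m


def _matrix_from(delta):
    n = delta.shape[0]
    return ConnectivityMatrix(delta, np.ones((n, n)),
                              np.zeros((n, n), bool), list(range(n)))


class TestExtractROISeries:
    def test_uniform_roi_recovered_exactly(self):
        atlas = np.zeros((2, 2, 2), int)
        atlas[0, :, :] = 1
        atlas[1, :, :] = 2
        T = 10
        mag = np.zeros((2, 2, 2, T))
        ph = np.zeros((2, 2, 2, T))
        mag[0] = 3.0
        ph[0] = 0.5
        mag[1] = 7.0
        ph[1] = -0.2
        rs = extract_roi_series(mag, ph, atlas)
        np.testing.assert_allclose(rs.series[0].magnitude, 3.0)
        np.testing.assert_allclose(rs.series[0].phase, 0.5)
        np.testing.assert_allclose(rs.series[1].magnitude, 7.0)

    def test_two_voxel_arithmetic_mean(self):
        atlas = np.array([[[1, 1]]])
        mag = np.stack([np.full((1, 1, 2), v) for v in [1.0, 3.0]], axis=-1)
        mag = np.moveaxis(mag, -1, -1)
        mag = np.zeros((1, 1, 2, 4))
        mag[0, 0, 0, :] = 1.0
        mag[0, 0, 1, :] = 3.0
        ph = np.zeros_like(mag)
        rs = extract_roi_series(mag, ph, atlas)
        np.testing.assert_allclose(rs.series[0].magnitude, 2.0)

    def test_planted_sinusoids_recovered(self, rng):
        atlas = rng.integers(1, 4, size=(4, 4, 4))
        T = 12
        t = np.arange(T)
        gen = {r: (np.sin(0.3 * r * t) + 2.0, np.cos(0.2 * r * t))
               for r in (1, 2, 3)}
        mag = np.zeros((4, 4, 4, T))
        ph = np.zeros((4, 4, 4, T))
        for r, (m, p) in gen.items():
            mag[atlas == r] = m
            ph[atlas == r] = p
        rs = extract_roi_series(mag, ph, atlas)
        for i, r in enumerate(rs.roi_ids):
            np.testing.assert_allclose(rs.series[i].magnitude, gen[r][0],
                                       atol=1e-12)
            np.testing.assert_allclose(rs.series[i].phase, gen[r][1],
                                       atol=1e-12)

    def test_empty_roi_warns_and_excludes(self):
        atlas = np.ones((2, 2, 2), int)
        mag = np.ones((2, 2, 2, 5))
        ph = np.zeros_like(mag)
        with pytest.warns(RuntimeWarning, match="no voxels"):
            rs = extract_roi_series(mag, ph, atlas, roi_ids=[1, 2])
        assert rs.excluded == [2] and rs.series[1] is None


class TestMagphaseCorrelation:
    def test_perfect_correlation(self, rng):
        T = 30
        base = rng.standard_normal((3, T))
        subs = []
        for _ in range(4):
            series = [ComplexSeries(np.abs(base[i]) + 1.0, base[(i + 1) % 3])
                      for i in range(3)]
            subs.append(ROISeriesSet(series, [1, 2, 3]))
        corr = magphase_correlation(subs)
        # phase of ROI n equals (up to sign/abs) magnitude of ROI m structure:
        # check range and exact diagonal-of-dependence entries
        assert corr.shape == (3, 3)
        assert np.all(np.abs(corr) <= 1 + 1e-12)

    def test_proportional_phase_gives_one(self, rng):
        T = 40
        m = np.abs(rng.standard_normal(T)) + 1.0
        subs = [ROISeriesSet(
            [ComplexSeries(m, rng.standard_normal(T)),
             ComplexSeries(np.abs(rng.standard_normal(T)) + 1, 2.0 * m)],
            [1, 2],
        ) for _ in range(3)]
        corr = magphase_correlation(subs)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_null_band_for_independent_noise(self, rng):
        T, K, n = 100, 40, 4
        subs = [ROISeriesSet(
            [ComplexSeries(rng.standard_normal(T), rng.standard_normal(T))
             for _ in range(n)], list(range(n)))
            for _ in range(K)]
        corr = magphase_correlation(subs)
        assert np.all(np.abs(corr) < 3 / np.sqrt(T * K) * np.sqrt(T))
        # subject averaging shrinks the null spread by sqrt(K)
        assert np.abs(corr).mean() < 3 / np.sqrt(T * K) * 3

    def test_constant_series_warns_zero(self, rng):
        subs = [ROISeriesSet(
            [ComplexSeries(np.ones(20), np.ones(20)),
             ComplexSeries(rng.standard_normal(20), rng.standard_normal(20))],
            [1, 2])]
        with pytest.warns(RuntimeWarning, match="constant"):
            corr = magphase_correlation(subs)
        assert corr[0, 0] == 0.0


class TestGroupEdgeTest:
    def test_identical_groups_no_edges(self, rng):
        mats = [_matrix_from(_random_antisym(rng, 6)) for _ in range(10)]
        tmat, _ = group_edge_test(mats, [
            _matrix_from(m.delta_c.copy()) for m in mats
        ])
        assert np.all(tmat == 0)

    def test_planted_edges_recovered(self, rng):
        n, K = 10, 40
        planted = [(0, 3), (1, 7), (2, 5), (4, 9), (6, 8)]
        g1 = [_matrix_from(_random_antisym(rng, n)) for _ in range(K)]
        g2 = []
        for _ in range(K):
            d = _random_antisym(rng, n)
            for i, j in planted:
                d[i, j] += 3.0  # +3 pooled sd (unit-variance entries)
                d[j, i] -= 3.0
            g2.append(_matrix_from(d))
        tmat, _ = group_edge_test(g1, g2, p_th=0.05)
        found = {(i, j) for i, j in zip(*np.nonzero(np.triu(tmat)))}
        assert found == set(planted)

    def test_bh_monotonicity(self, rng):
        n, K = 8, 20
        shift = np.triu(np.full((n, n), 0.4), 1)
        shift = shift - shift.T
        g1 = [_matrix_from(_random_antisym(rng, n)) for _ in range(K)]
        g2 = [_matrix_from(_random_antisym(rng, n) + shift) for _ in range(K)]
        strict, _ = group_edge_test(g1, g2, p_th=0.05, q=0.01)
        loose, _ = group_edge_test(g1, g2, p_th=0.05, q=0.05)
        assert set(zip(*np.nonzero(strict))) <= set(zip(*np.nonzero(loose)))

    def test_exact_equality_shortcut(self):
        d = np.zeros((3, 3))
        mats1 = [_matrix_from(d.copy()) for _ in range(3)]
        shifted = d.copy()
        shifted[0, 1], shifted[1, 0] = 1.0, -1.0
        mats2 = [_matrix_from(shifted.copy()) for _ in range(3)]
        tmat, pv = group_edge_test(mats1, mats2)
        assert np.isinf(tmat[0, 1]) and pv[0, 1] == 0.0

    def test_null_type_i_rate(self, rng):
        """Edge-wise false positive rate under the null stays near q."""
        n, K, reps = 8, 15, 20
        n_edges = n * (n - 1) // 2
        fp = 0
        for _ in range(reps):
            g1 = [_matrix_from(_random_antisym(rng, n)) for _ in range(K)]
            g2 = [_matrix_from(_random_antisym(rng, n)) for _ in range(K)]
            tmat, _ = group_edge_test(g1, g2)
            fp += np.count_nonzero(np.triu(tmat))
        rate = fp / (reps * n_edges)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / (reps * n_edges))


class TestROIConnectivity:
    def test_antisymmetric_matrix(self):
        pairs = [generate_pair("L1", seed=s) for s in (0, 1)]
        series = [pairs[0].observed()[0], pairs[0].observed()[1],
                  pairs[1].observed()[0]]
        rs = ROISeriesSet(series, [1, 2, 3])
        mat = ROIConnectivity(rs, estimator="ste",
                              config=TEConfig(tau=1)).fit(R=20, seed=4)
        np.testing.assert_allclose(mat.delta_c, -mat.delta_c.T, atol=1e-12)
        assert np.all(np.diag(mat.delta_c) == 0)

    def test_csv_roundtrip(self, tmp_path, rng):
        mat = _matrix_from(_random_antisym(rng, 4))
        path = tmp_path / "m.csv"
        write_connectivity_csv(mat, path, header_lines=["estimator=cte"])
        back = read_connectivity_csv(path)
        np.testing.assert_allclose(back.delta_c, mat.delta_c, atol=1e-12)


def test_network_block_counts():
    edges = np.zeros((4, 4))
    edges[0, 1] = 2.0
    edges[1, 0] = -2.0
    edges[2, 3] = 1.5
    edges[3, 2] = -1.5
    nets = {1: "DMN", 2: "DMN", 3: "CER", 4: "CER"}
    counts = network_block_counts(edges, [1, 2, 3, 4], nets)
    assert counts.loc["DMN", "DMN"] == 2  # both orientations counted
    assert counts.loc["CER", "CER"] == 2
    assert counts.loc["DMN", "CER"] == 0
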