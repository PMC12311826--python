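"""Spatial statistics: Moran's I, isolation index, Kulldorff scan."""

import numpy as np
import pytest

from vaxhes import (SpatialField, ZipGraph, isolation_index, kulldorff_scan,
                    morans_i)
from vaxhes.stats import _poisson_llr

from conftest import random_graph


def field_on(W, h, p=None):
    n = len(h)
    g = ZipGraph([f"z{i}" for i in range(n)], W)
    return SpatialField(np.asarray(h, float),
                        np.asarray(p if p is not None else np.ones(n), float),
                        g)


def morans_oracle(W, h):
    """Brute-force quadruple-loop version of the autocorrelation statistic."""
    n = len(h)
    hbar = sum(h) / n
    num = 0.0
    wsum = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (h[i] - hbar) * (h[j] - hbar)
            wsum += W[i, j]
    den = sum((x - hbar) ** 2 for x in h)
    return n * num / (wsum * den)


class TestMoransI:
    def test_two_node_antithetic_is_minus_one(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert morans_i(field_on(W, [1.0, 0.0])) == pytest.approx(-1.0)

    def test_constant_field_errors(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            morans_i(field_on(W, [0.3, 0.3]))

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError):
            morans_i(field_on(np.zeros((3, 3)), [0.1, 0.2, 0.3]))

    def test_matches_quadruple_loop_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 21))
            g = random_graph(rng, n)
            if not g.W.any():
                continue
            h = rng.random(n)
            f = SpatialField(h, np.ones(n), g)
            assert morans_i(f) == pytest.approx(morans_oracle(g.W, h),
                                                abs=1e-10)

    def test_affine_invariance(self, rng):
        g = random_graph(rng, 12)
        h = rng.random(12)
        f1 = SpatialField(h, np.ones(12), g)
        f2 = SpatialField(3.7 * h - 1.2, np.ones(12), g)
        assert morans_i(f1) == pytest.approx(morans_i(f2), abs=1e-10)


class TestIsolationIndex:
    def test_constant_field_returns_constant(self, rng):
        g = random_graph(rng, 8)
        p = rng.random(8) * 100 + 1
        f = SpatialField(np.full(8, 0.27), p, g)
        assert isolation_index(f) == pytest.approx(0.27)

    def test_single_contributing_node(self, rng):
        g = random_graph(rng, 2)
        f = SpatialField(np.array([0.2, 0.0]), np.array([10.0, 90.0]), g)
        assert isolation_index(f) == pytest.approx(0.2)

    def test_matches_two_pass_oracle(self, rng):
        g = random_graph(rng, 15)
        h = rng.random(15)
        p = rng.random(15) * 500
        f = SpatialField(h, p, g)
        total = sum(hi * pi for hi, pi in zip(h, p))
        oracle = sum((hi * pi / total) * hi for hi, pi in zip(h, p))
        assert isolation_index(f) == pytest.approx(oracle, abs=1e-12)

    def test_population_scaling_invariance(self, rng):
        g = random_graph(rng, 10)
        h = rng.random(10)
        p = rng.random(10) * 100 + 1
        f1 = SpatialField(h, p, g)
        f2 = SpatialField(h, 13.5 * p, g)
        assert isolation_index(f1) == pytest.approx(isolation_index(f2),
                                                    abs=1e-12)

    def test_no_hesitant_population_errors(self, rng):
        g = random_graph(rng, 4)
        with pytest.raises(ValueError):
            isolation_index(SpatialField(np.zeros(4), np.ones(4), g))

    def test_bounded_by_field_range(self, rng):
        g = random_graph(rng, 20)
        h = rng.random(20) * 0.5
        p = rng.random(20) * 300 + 10
        val = isolation_index(SpatialField(h, p, g))
        assert h.min() <= val <= h.max()


class TestPoissonLLR:
    def test_hand_value(self):
        expected = 10 * np.log(2) + 90 * np.log(90 / 95)
        assert _poisson_llr(10, 5, 100) == pytest.approx(expected, abs=1e-12)

    def test_zero_when_not_elevated(self):
        assert _poisson_llr(5, 5, 100) == 0.0
        assert _poisson_llr(3, 5, 100) == 0.0

    def test_monotone_in_cases(self):
        vals = [_poisson_llr(c, 5, 100) for c in range(6, 40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestKulldorffScan:
    def ring_graph(self, n):
        W = np.zeros((n, n))
        for i in range(n):
            W[i, (i + 1) % n] = W[(i + 1) % n, i] = 1.0
        return ZipGraph([f"z{i}" for i in range(n)], W)

    def test_uniform_rates_give_zero_llr(self):
        g = self.ring_graph(12)
        p = np.full(12, 100.0)
        h = np.full(12, 0.10)           # cases exactly proportional
        f = SpatialField(h, p, g)
        results = kulldorff_scan(f, n_mc=19, seed=0)
        assert results == []

    def test_planted_cluster_recovered(self):
        rng = np.random.default_rng(0)
        n = 60
        from scipy.spatial import Delaunay
        pts = rng.random((n, 2))
        tri = Delaunay(pts)
        W = np.zeros((n, n))
        for s in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    W[s[a], s[b]] = W[s[b], s[a]] = 1.0
        g = ZipGraph([f"z{i}" for i in range(n)], W)
        seedn = 5
        planted = {seedn}
        frontier = [seedn]
        while len(planted) < 5:
            nxt = int(np.nonzero(W[frontier[0]])[0][0])
            candidates = [j for j in np.nonzero(W[list(planted)].sum(0))[0]
                          if j not in planted]
            planted.add(int(candidates[0]))
        p = np.full(n, 200.0)
        base = 0.05
        h = rng.binomial(200, base, n) / 200.0
        for i in planted:
            h[i] = rng.binomial(200, 3 * base) / 200.0
        f = SpatialField(h, p, g)
        results = kulldorff_scan(f, n_mc=199, seed=0)
        assert results, "no cluster found"
        top = results[0].cluster
        jacc = len(top & planted) / len(top | planted)
        assert jacc >= 0.6
        assert results[0].p_value <= 0.05

    def test_mc_too_small_errors(self, rng):
        g = self.ring_graph(6)
        f = SpatialField(rng.random(6), np.full(6, 50.0), g)
        with pytest.raises(ValueError):
            kulldorff_scan(f, n_mc=5)

    def test_no_cases_errors(self):
        g = self.ring_graph(6)
        f = SpatialField(np.zeros(6), np.full(6, 50.0), g)
        with pytest.raises(ValueError):
            kulldorff_scan(f, n_mc=19)

    def test_clusters_connected_and_non_overlapping(self, small_study):
        panel = small_study["panel"]
        from vaxhes import build_adjacency_graph
        geom = small_study["geom"]
        g = build_adjacency_graph(geom, sorted(geom.centroids))
        f = SpatialField(panel.h[:, -1], panel.p[:, -1].astype(float), g)
        results = kulldorff_scan(f, n_mc=99, seed=1)
        used: set = set()
        for r in results:
            assert not (r.cluster & used)
            used |= r.cluster
            if len(r.cluster) > 1:
                sub = g.W[np.ix_(sorted(r.cluster), sorted(r.cluster))]
                # connectivity via reachability on the induced subgraph
                import scipy.sparse.csgraph as csg
                ncomp, _ = csg.connected_components(sub > 0)
                assert ncomp == 1
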