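"""Wiring: distances, Gaussian edge sampling, gap junctions, census."""
import numpy as np
import pytest

from thetagamma import params as P
from thetagamma.network import (
    NetworkGraph, build_cross_edges, build_gap_junctions, build_network,
    build_ring_edges, build_torus_edges, mean_census, ring_distance,
    torus_distance,
)

TABLE1_MODEL = {
    "FS->FS": 4.24, "P->FS": 4.47, "P->P": 28.09,
    "FS->P": 6.30, "ext->FS": 7.09, "ext->P": 49.80,
}


class TestDistances:
    def test_ring_wraparound(self):
        assert ring_distance(0, 9, 10) == 1
        assert ring_distance(3, 3, 10) == 0

    def test_ring_maximum(self):
        n = 11
        idx = np.arange(n)
        d = ring_distance(idx[:, None], idx[None, :], n)
        assert d.max() == n // 2

    def test_ring_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ring_distance(0, 10, 10)

    def test_torus_folds(self):
        assert torus_distance((0, 0), (0, 9), (10, 10)) == 1.0
        assert torus_distance((0, 0), (9, 9), (10, 10)) == pytest.approx(
            np.sqrt(2))

    def test_torus_matches_image_enumeration(self, rng):
        # oracle: minimum over the 9 periodic images
        rows, cols = 7, 11
        for _ in range(200):
            a = rng.integers(0, [rows, cols])
            b = rng.integers(0, [rows, cols])
            best = min(
                np.hypot(a[0] - (b[0] + dr * rows), a[1] - (b[1] + dc * cols))
                for dr in (-1, 0, 1) for dc in (-1, 0, 1))
            assert torus_distance(a, b, (rows, cols)) == pytest.approx(best)

    def test_torus_rejects_bad_dims(self):
        with pytest.raises(ValueError):
            torus_distance((0, 0), (1, 1), (0, 5))


class TestIntraEdges:
    def test_no_edge_beyond_dmax_or_self(self, rng):
        e = build_ring_edges(40, 10.0, sigma=5.0, d_max=8, rng=rng)
        d = ring_distance(e[0], e[1], 40)
        assert d.max() <= 8
        assert d.min() >= 1

    def test_mean_in_degree_matches_target(self):
        # Monte-Carlo: realized mean in-degree within 5% of target
        n, target = 60, 20.0
        counts = []
        for seed in range(20):
            e = build_ring_edges(n, target, sigma=12.0, d_max=25,
                                 rng=np.random.default_rng(seed))
            counts.append(e.shape[1] / n)
        assert np.mean(counts) == pytest.approx(target, rel=0.05)

    def test_flat_gaussian_gives_uniform_probability(self, rng):
        # sigma >> d_max: edge probability independent of distance
        n, target = 50, 12.0
        tallies = np.zeros(n // 2 + 1)
        trials = np.zeros(n // 2 + 1)
        for seed in range(40):
            e = build_ring_edges(n, target, sigma=1e6, d_max=n // 2,
                                 rng=np.random.default_rng(seed))
            d = ring_distance(e[0], e[1], n)
            for dist in range(1, n // 2 + 1):
                tallies[dist] += np.sum(d == dist)
        # cells per distance: 2 for d < n/2, 1 at exactly n/2 (n even)
        per_d = np.array([0] + [2] * (n // 2 - 1) + [1]) * n * 40
        p_hat = tallies[1:] / per_d[1:]
        assert p_hat.std() / p_hat.mean() < 0.1

    def test_unattainable_target_raises(self, rng):
        with pytest.raises(ValueError):
            build_ring_edges(30, 25.0, sigma=1.0, d_max=3, rng=rng)

    def test_torus_edges_respect_dmax(self, rng):
        e = build_torus_edges(8, 8, 12.0, sigma=2.5, d_max=3.5, rng=rng)
        coords = np.stack(np.unravel_index(np.arange(64), (8, 8)), axis=-1)
        d = torus_distance(coords[e[0]], coords[e[1]], (8, 8))
        assert d.max() <= 3.5 and d.min() >= 1.0


class TestGapJunctions:
    def test_probability_zero_empty(self, rng):
        assert build_gap_junctions(20, 2, 0.0, rng).shape[1] == 0

    def test_probability_one_complete(self, rng):
        e = build_gap_junctions(20, 2, 1.0, rng)
        assert e.shape[1] == 20 * 2  # n * range unordered pairs

    def test_mean_count_matches_expectation(self):
        n, rng_range, p = 50, 2, 0.75
        counts = [build_gap_junctions(n, rng_range, p,
                                      np.random.default_rng(s)).shape[1]
                  for s in range(40)]
        expected = n * rng_range * p
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)

    def test_no_duplicates_and_ordered(self, rng):
        e = build_gap_junctions(30, 3, 0.8, rng)
        pairs = set(map(tuple, e.T))
        assert len(pairs) == e.shape[1]
        assert np.all(e[0] < e[1])


class TestCrossEdges:
    def test_zero_mean_empty(self, rng):
        assert build_cross_edges(10, 5, 0.0, rng).shape[1] == 0

    def test_full_mean_complete_bipartite(self, rng):
        e = build_cross_edges(10, 5, 10.0, rng)
        assert e.shape[1] == 50

    def test_monte_carlo_mean(self):
        counts = [build_cross_edges(100, 40, 12.0,
                                    np.random.default_rng(s)).shape[1] / 40
                  for s in range(30)]
        assert np.mean(counts) == pytest.approx(12.0, rel=0.05)

    def test_excess_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            build_cross_edges(10, 5, 11.0, rng)


class TestCensus:
    def test_fractions_sum_to_100(self):
        g = build_network(P.DESK_NET, seed=3)
        assert g.census().sum() == pytest.approx(100.0, abs=1e-9)

    def test_hand_counted_toy_graph(self):
        # 2 + 3 + 5 hand-placed edges -> hand-computed fractions
        e = lambda *pairs: np.asarray(pairs, dtype=np.int64).T.reshape(2, -1)
        g = NetworkGraph(
            params=P.NetworkParams(n_fs=4, p_rows=2, p_cols=2),
            seed=0,
            fs_fs=e((0, 1), (1, 2)),                      # 2
            p_fs=e((0, 0), (1, 1), (2, 2)),               # 3
            p_p=e((0, 1), (1, 2), (2, 3), (3, 0), (0, 2)),  # 5
            fs_p=np.empty((2, 0), dtype=np.int64),
            gap=np.empty((2, 0), dtype=np.int64),
            const_fs=np.empty((2, 0), dtype=np.int64),
            theta_fs=np.empty((2, 0), dtype=np.int64),
            const_p=np.empty((2, 0), dtype=np.int64),
            theta_p=np.empty((2, 0), dtype=np.int64),
        )
        c = g.census()
        assert c["FS->FS"] == pytest.approx(100 * 2 / 10)
        assert c["P->FS"] == pytest.approx(100 * 3 / 10)
        assert c["P->P"] == pytest.approx(100 * 5 / 10)
        assert c["FS->P"] == 0.0

    def test_wiring_deterministic_under_seed(self):
        g1 = build_network(P.DESK_NET, seed=11)
        g2 = build_network(P.DESK_NET, seed=11)
        for name in ("fs_fs", "p_fs", "p_p", "fs_p", "gap",
                     "const_fs", "theta_fs", "const_p", "theta_p"):
            np.testing.assert_array_equal(getattr(g1, name),
                                          getattr(g2, name))

    def test_full_model_census_matches_anatomy(self):
        # averaged over 10 wiring seeds, each synapse-type fraction lies
        # within 0.5 percentage points of the anatomical census
        c = mean_census(P.PAPER_NET, n_seeds=10, seed=0)
        for key, want in TABLE1_MODEL.items():
            assert c[key] == pytest.approx(want, abs=0.5), key

    def test_roundtrip_export(self, tmp_path):
        g = build_network(P.DESK_NET, seed=5)
        g.save(tmp_path / "net")
        g2 = NetworkGraph.load(tmp_path / "net")
        assert g2.params == g.params and g2.seed == g.seed
        for name in ("fs_fs", "p_fs", "p_p", "fs_p", "gap",
                     "const_fs", "theta_fs", "const_p", "theta_p"):
            np.testing.assert_array_equal(getattr(g, name),
                                          getattr(g2, name))
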