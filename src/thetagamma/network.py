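"""Wiring of the FS ring, the P torus, cross-projections and afferent fibres.

The FS interneurons sit on a one-dimensional ring, the P cells on a
two-dimensional sheet folded into a torus; both choices remove edge effects
from the distance-dependent connection probability.  Within each subnetwork
a synapse from a neighbour exists with a Gaussian probability of the cell
distance, cut off at a maximum distance and scaled so that the expected
in-degree matches a target; the probability governs only synapse existence,
never strength.  Cross-subnetwork projections and afferent fibre fan-ins are
uniform random.

Cell indices are 0-based; torus coordinates are (row, col) flattened
row-major.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import NetworkParams

CENSUS_ROWS = ("FS->FS", "P->FS", "P->P", "FS->P", "ext->FS", "ext->P")


def ring_distance(i, j, n: int):
    """Shortest distance on a ring of n cells."""
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 0) or np.any(i >= n) or np.any(j < 0) or np.any(j >= n):
        raise ValueError("cell index out of range")
    d = np.abs(i - j)
    return np.minimum(d, n - d)


def torus_distance(a, b, dims):
    """Euclidean distance on a (rows, cols) torus between coords a and b."""
    rows, cols = dims
    if rows <= 0 or cols <= 0:
        raise ValueError("invalid torus dimensions")
    a = np.asarray(a)
    b = np.asarray(b)
    dr = np.abs(a[..., 0] - b[..., 0])
    dc = np.abs(a[..., 1] - b[..., 1])
    dr = np.minimum(dr, rows - dr)
    dc = np.minimum(dc, cols - dc)
    return np.sqrt(dr ** 2 + dc ** 2)


@dataclass
class NetworkGraph:
    """Typed directed synapse edges plus gap junctions and fibre fan-ins.

    Chemical and fibre edges are stored as (pre, post) index arrays per
    projection; gap junctions as an undirected (i, j) pair array with i < j.
    """

    params: NetworkParams
    seed: int
    fs_fs: np.ndarray       # (2, E) within-ring GABA
    p_fs: np.ndarray        # (2, E) P -> FS glutamate
    p_p: np.ndarray         # (2, E) within-torus glutamate
    fs_p: np.ndarray        # (2, E) FS -> P GABA
    gap: np.ndarray         # (2, E) undirected FS pairs
    const_fs: np.ndarray    # (2, E) constant-rate fibre -> FS
    theta_fs: np.ndarray    # (2, E) theta fibre -> FS
    const_p: np.ndarray     # (2, E)
    theta_p: np.ndarray     # (2, E)

    def census(self) -> pd.Series:
        """Synapse counts by type as percentages of the total (sums to 100)."""
        counts = np.array([
            self.fs_fs.shape[1],
            self.p_fs.shape[1],
            self.p_p.shape[1],
            self.fs_p.shape[1],
            self.const_fs.shape[1] + self.theta_fs.shape[1],
            self.const_p.shape[1] + self.theta_p.shape[1],
        ], dtype=float)
        total = counts.sum()
        if total == 0:
            raise ValueError("empty graph")
        return pd.Series(100.0 * counts / total, index=CENSUS_ROWS)

    def to_frame(self) -> pd.DataFrame:
        """All edges as a tidy (projection, pre, post) table."""
        parts = []
        for name in ("fs_fs", "p_fs", "p_p", "fs_p", "gap",
                     "const_fs", "theta_fs", "const_p", "theta_p"):
            e = getattr(self, name)
            parts.append(pd.DataFrame(
                {"projection": name, "pre": e[0], "post": e[1]}))
        return pd.concat(parts, ignore_index=True)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "edges.csv", index=False)
        from dataclasses import asdict
        header = {"seed": self.seed, "params": asdict(self.params)}
        (directory / "network.json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "NetworkGraph":
        """Rebuild a graph from its columnar export."""
        directory = Path(directory)
        header = json.loads((directory / "network.json").read_text())
        edges = pd.read_csv(directory / "edges.csv")
        parts = {}
        for name in ("fs_fs", "p_fs", "p_p", "fs_p", "gap",
                     "const_fs", "theta_fs", "const_p", "theta_p"):
            sub = edges[edges.projection == name]
            parts[name] = np.vstack([sub.pre.to_numpy(),
                                     sub.post.to_numpy()]).astype(np.int64) \
                if len(sub) else _empty_edges()
        return cls(params=NetworkParams(**header["params"]),
                   seed=header["seed"], **parts)


def _empty_edges() -> np.ndarray:
    return np.empty((2, 0), dtype=np.int64)


def _edges_from_mask(mask: np.ndarray) -> np.ndarray:
    pre, post = np.nonzero(mask)
    return np.vstack([pre, post]).astype(np.int64)


def gaussian_edge_probability(dist, sigma: float, d_max: float,
                              target_in_degree: float, kernel_sum: float):
    """Bernoulli probability for one candidate edge at distance ``dist``.

    The Gaussian is scaled so that the expected in-degree equals the target;
    the peak probability is capped at 1.
    """
    p0 = target_in_degree / kernel_sum
    if p0 > 1.0 + 1e-9:
        raise ValueError(
            f"target in-degree {target_in_degree} unattainable: needs peak "
            f"probability {p0:.3f} > 1 within d_max={d_max}")
    p = p0 * np.exp(-np.asarray(dist, dtype=float) ** 2 / (2.0 * sigma ** 2))
    return np.where(np.asarray(dist) <= d_max, np.minimum(p, 1.0), 0.0)


def build_ring_edges(n: int, target_in_degree: float, sigma: float,
                     d_max: int, rng: np.random.Generator) -> np.ndarray:
    """Within-ring synapses with Gaussian distance-dependent probability."""
    if sigma <= 0 or d_max < 1:
        raise ValueError("need sigma > 0 and d_max >= 1")
    idx = np.arange(n)
    dist = ring_distance(idx[:, None] * np.ones(n, dtype=int),
                         np.broadcast_to(idx, (n, n)), n)
    valid = (dist > 0) & (dist <= d_max)
    # kernel sum per postsynaptic cell (ring: identical for all cells)
    kernel = np.exp(-dist[0, valid[0]] ** 2 / (2.0 * sigma ** 2)).sum()
    p = gaussian_edge_probability(dist, sigma, d_max, target_in_degree, kernel)
    p = np.where(valid, p, 0.0)
    return _edges_from_mask(rng.random((n, n)) < p)


def build_torus_edges(rows: int, cols: int, target_in_degree: float,
                      sigma: float, d_max: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Within-torus synapses with 2-D Gaussian distance-dependent probability."""
    if sigma <= 0 or d_max <= 0:
        raise ValueError("need sigma > 0 and d_max > 0")
    n = rows * cols
    coords = np.stack(np.unravel_index(np.arange(n), (rows, cols)), axis=-1)
    dist = torus_distance(coords[:, None, :], coords[None, :, :], (rows, cols))
    valid = (dist > 0) & (dist <= d_max)
    kernel = np.exp(-dist[0, valid[0]] ** 2 / (2.0 * sigma ** 2)).sum()
    p = gaussian_edge_probability(dist, sigma, d_max, target_in_degree, kernel)
    p = np.where(valid, p, 0.0)
    return _edges_from_mask(rng.random((n, n)) < p)


def build_gap_junctions(n: int, neighbour_range: int, probability: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Gap junctions between near neighbours on the FS ring.

    Each unordered pair within ``neighbour_range`` ring distance carries a
    junction with the given probability (so each cell is coupled to its
    2*neighbour_range nearest neighbours at most).
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    pairs = []
    for i in range(n):
        for off in range(1, neighbour_range + 1):
            j = (i + off) % n
            if j == i:
                continue
            a, b = min(i, j), max(i, j)
            pairs.append((a, b))
    pairs = sorted(set(pairs))
    if not pairs:
        return _empty_edges()
    keep = rng.random(len(pairs)) < probability
    kept = np.asarray(pairs, dtype=np.int64)[keep]
    return kept.T.reshape(2, -1)


def build_cross_edges(n_pre: int, n_post: int, mean_in_degree: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniform random bipartite fan-in: each (pre, post) pair independently
    connected with probability mean_in_degree / n_pre."""
    if mean_in_degree > n_pre:
        raise ValueError("mean in-degree exceeds presynaptic pool size")
    if mean_in_degree <= 0:
        return _empty_edges()
    p = mean_in_degree / n_pre
    return _edges_from_mask(rng.random((n_pre, n_post)) < p)


def build_network(params: NetworkParams | None = None,
                  seed: int = 0) -> NetworkGraph:
    """Construct the full two-subnetwork graph from one wiring seed."""
    params = params or NetworkParams()
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(7)]
    n_fs, n_p = params.n_fs, params.n_p
    return NetworkGraph(
        params=params,
        seed=seed,
        fs_fs=build_ring_edges(n_fs, params.m_fs_fs, params.sigma_fs,
                               params.d_max_fs, streams[0]),
        p_p=build_torus_edges(params.p_rows, params.p_cols, params.m_p_p,
                              params.sigma_p, params.d_max_p, streams[1]),
        gap=build_gap_junctions(n_fs, params.gap_neighbour_range,
                                params.gap_probability, streams[2]),
        p_fs=build_cross_edges(n_p, n_fs, params.m_p_fs, streams[3]),
        fs_p=build_cross_edges(n_fs, n_p, params.m_fs_p, streams[4]),
        const_fs=build_cross_edges(params.n_fibres_const, n_fs,
                                   params.fibres_const_fs, streams[5]),
        theta_fs=build_cross_edges(params.n_fibres_theta, n_fs,
                                   params.fibres_theta_fs, streams[5]),
        const_p=build_cross_edges(params.n_fibres_const, n_p,
                                  params.fibres_const_p, streams[6]),
        theta_p=build_cross_edges(params.n_fibres_theta, n_p,
                                  params.fibres_theta_p, streams[6]),
    )


def connectivity_census(graph: NetworkGraph) -> pd.Series:
    """Per-type synapse fractions (%) of the fully built network."""
    return graph.census()


def mean_census(params: NetworkParams | None = None, n_seeds: int = 10,
                seed: int = 0) -> pd.Series:
    """Census averaged over ``n_seeds`` independent wiring seeds."""
    rows = [build_network(params, seed=seed + k).census()
            for k in range(n_seeds)]
    return pd.concat(rows, axis=1).mean(axis=1)
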