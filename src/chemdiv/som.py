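"""Self-organizing maps over descriptor vectors and the dataset affinity score.

A rectangular Kohonen map is trained online on one dataset's descriptor
vectors; a second dataset is then projected onto the frozen map and the
affinity of the projection is scored as

    S_a = sum_i p_B_i * exp(-(|p_A_i - p_B_i| + |dbar_A_i - dbar_B_i| / (dmax_A_i - dmin_A_i)))

where p_X_i is the proportion of set X assigned to node i and dbar/dmax/dmin
summarize molecule-to-codebook distances within the node.  S_a lies in
[0, 1]; projecting a dataset onto its own map gives exactly 1.  Nodes whose
reference spread is degenerate (fewer than two reference molecules) carry no
distance information: they contribute only when the projected mean distance
coincides with the reference one, and are counted in a diagnostic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class SOMSchedule:
    """Online training schedule: epochs, learning-rate and radius decay."""

    n_epochs: int = 100
    lr_start: float = 0.05
    lr_end: float = 0.01
    #: neighborhood radius decays linearly from sigma_start (default: a third
    #: of the grid diagonal) to sigma_end over the epochs
    sigma_start: float | None = None
    sigma_end: float = 1.0


@dataclass
class SOMGrid:
    rows: int
    cols: int
    codebook: np.ndarray  # (rows*cols, n_features)
    seed: int
    schedule: SOMSchedule
    qe_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def fingerprint(self) -> tuple:
        return (self.rows, self.cols, self.codebook.shape[1], float(self.codebook.sum()))


def train_som(
    X: np.ndarray,
    rows: int,
    cols: int,
    schedule: SOMSchedule | None = None,
    seed: int = 0,
) -> SOMGrid:
    """Classical online Kohonen training on a rectangular grid.

    Deterministic given the seed: the codebook is initialized from a seeded
    random sample of the data and samples are presented in a seeded shuffled
    order each epoch.  The per-epoch mean quantization error is recorded.
    """
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("cannot train a SOM on an empty feature set")
    schedule = schedule or SOMSchedule()
    n_nodes = rows * cols
    if n_nodes > len(X):
        warnings.warn(
            f"grid has {n_nodes} nodes for {len(X)} samples; empty nodes expected",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    init_idx = rng.integers(0, len(X), size=n_nodes)
    codebook = X[init_idx].astype(float).copy()
    gy, gx = np.divmod(np.arange(n_nodes), cols)
    grid_pos = np.column_stack([gy, gx]).astype(float)
    sigma0 = schedule.sigma_start
    if sigma0 is None:
        sigma0 = max(np.hypot(rows - 1, cols - 1) / 3.0, schedule.sigma_end)
    qe_trace = np.empty(schedule.n_epochs)
    denom = max(schedule.n_epochs - 1, 1)
    for epoch in range(schedule.n_epochs):
        frac = epoch / denom
        lr = schedule.lr_start + (schedule.lr_end - schedule.lr_start) * frac
        sigma = sigma0 + (schedule.sigma_end - sigma0) * frac
        order = rng.permutation(len(X))
        qe = 0.0
        for i in order:
            x = X[i]
            d2 = ((codebook - x) ** 2).sum(axis=1)
            bmu = int(d2.argmin())
            qe += np.sqrt(d2[bmu])
            gdist2 = ((grid_pos - grid_pos[bmu]) ** 2).sum(axis=1)
            h = np.exp(-gdist2 / (2.0 * sigma**2))
            codebook += (lr * h)[:, None] * (x - codebook)
        qe_trace[epoch] = qe / len(X)
    return SOMGrid(rows, cols, codebook, seed, schedule, qe_trace)


def project(som: SOMGrid, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-matching unit and distance for each row (ties -> lowest node index)."""
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        return np.array([], dtype=int), np.array([])
    if X.shape[1] != som.codebook.shape[1]:
        raise ValueError(
            f"feature length {X.shape[1]} does not match codebook {som.codebook.shape[1]}"
        )
    D = cdist(X, som.codebook)
    bmu = D.argmin(axis=1)
    return bmu.astype(int), D[np.arange(len(X)), bmu]


@dataclass
class NodeStats:
    """Per-node occupancy proportions and distance statistics for one dataset."""

    p: np.ndarray      # occupancy proportion per node; sums to 1
    d_mean: np.ndarray  # NaN where the node is empty
    d_max: np.ndarray
    d_min: np.ndarray
    som_fingerprint: tuple


def node_stats(som: SOMGrid, assignments: np.ndarray, distances: np.ndarray) -> NodeStats:
    n_nodes = som.n_nodes
    p = np.zeros(n_nodes)
    d_mean = np.full(n_nodes, np.nan)
    d_max = np.full(n_nodes, np.nan)
    d_min = np.full(n_nodes, np.nan)
    if len(assignments):
        counts = np.bincount(assignments, minlength=n_nodes)
        p = counts / len(assignments)
        for i in np.flatnonzero(counts):
            d = distances[assignments == i]
            d_mean[i] = d.mean()
            d_max[i] = d.max()
            d_min[i] = d.min()
    return NodeStats(p, d_mean, d_max, d_min, som.fingerprint())


@dataclass
class AffinityReport:
    score: float
    density_term: float
    distance_term: float
    n_degenerate_nodes: int


def affinity(stats_A: NodeStats, stats_B: NodeStats) -> AffinityReport:
    """Affinity of projected dataset B to the map built on dataset A.

    Nodes with p_B = 0 contribute nothing.  Where A's within-node distance
    range is degenerate (empty node or a single molecule), the distance
    ratio is taken as 0 when the projected mean distance coincides with the
    reference mean and the node's contribution is dropped otherwise; such
    nodes are counted in the degeneracy diagnostic.
    """
    if stats_A.som_fingerprint != stats_B.som_fingerprint:
        raise ValueError("node statistics come from different SOMs")
    score = density = distance = 0.0
    n_degenerate = 0
    for i in range(len(stats_A.p)):
        pB = stats_B.p[i]
        if pB == 0.0:
            continue
        dp = abs(stats_A.p[i] - pB)
        rng = stats_A.d_max[i] - stats_A.d_min[i]
        dd = abs(stats_A.d_mean[i] - stats_B.d_mean[i])
        if np.isnan(rng) or rng == 0.0:
            if np.isnan(dd) or dd != 0.0:
                n_degenerate += 1
                density += pB * np.exp(-dp)
                continue
            ratio = 0.0
        else:
            ratio = dd / rng
        score += pB * np.exp(-(dp + ratio))
        density += pB * np.exp(-dp)
        distance += pB * np.exp(-ratio)
    return AffinityReport(
        score=float(score),
        density_term=float(density),
        distance_term=float(distance),
        n_degenerate_nodes=n_degenerate,
    )
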