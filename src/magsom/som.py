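"""A small batch-trained self-organizing map on a toroidal grid.

The map plays the role the emergent SOM plays in compositional binning:
scaffolds' tetranucleotide profiles are projected onto a 2-D grid of
weight vectors whose U-matrix valleys correspond to genomes. Batch
training (all samples update the codebook per epoch) is used instead of
online updates because it is independent of input order — a property the
binning contract relies on — and deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class SOMGrid:
    rows: int
    cols: int
    weights: np.ndarray  # (rows * cols, dim)
    toroidal: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_coords(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([r, c])

    def bmu(self, profiles: np.ndarray) -> np.ndarray:
        """Best-matching unit per profile (ties -> lowest node index)."""
        return np.argmin(cdist(profiles, self.weights), axis=1)


def default_grid_shape(n_profiles: int, aspect: float = 1.618) -> tuple[int, int]:
    """Emergent-scale grid: about one node per three profiles.

    Cluster structure only emerges on the U-matrix when the map has far
    more nodes than clusters; small maps (a few dozen nodes) compress
    distinct clusters onto adjacent nodes and their boundaries vanish.
    """
    total = max(64, int(np.ceil(n_profiles / 3.0)))
    rows = max(2, int(round(np.sqrt(total / aspect))))
    cols = max(2, int(np.ceil(total / rows)))
    return rows, cols


def _grid_sq_distances(rows: int, cols: int, toroidal: bool) -> np.ndarray:
    r, c = np.divmod(np.arange(rows * cols), cols)
    dr = np.abs(r[:, None] - r[None, :])
    dc = np.abs(c[:, None] - c[None, :])
    if toroidal:
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    return (dr**2 + dc**2).astype(float)


def train_som(
    profiles: np.ndarray,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 20,
    seed: int = 0,
    toroidal: bool = True,
    sigma_start: float | None = None,
    sigma_end: float = 2.0,
) -> SOMGrid:
    """Batch-train a SOM on row-vector profiles.

    Gaussian neighborhood with linearly decaying radius; weights are
    initialized around the data mean from the seeded generator. The
    radius anneals to ``sigma_end`` rather than to a point: keeping the
    final map smooth suppresses spurious within-cluster U-matrix ridges
    that would otherwise strand profiles on boundary nodes. Records a
    quantization-error checkpoint per epoch in ``metadata['qe_history']``.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or len(profiles) == 0:
        raise ValueError("profiles must be a non-empty 2-D array")
    n, dim = profiles.shape
    if rows is None or cols is None:
        rows, cols = default_grid_shape(n)
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mean = profiles.mean(axis=0)
    std = profiles.std(axis=0)
    weights = mean + rng.normal(0.0, 1.0, size=(rows * cols, dim)) * 0.1 * (std + 1e-12)

    grid_d2 = _grid_sq_distances(rows, cols, toroidal)
    if sigma_start is None:
        sigma_start = max(rows, cols) / 2.0
    qe_history: list[float] = []
    for t in range(epochs):
        frac = t / max(epochs - 1, 1)
        sigma = sigma_start + (sigma_end - sigma_start) * frac
        d = cdist(profiles, weights)
        bmu = np.argmin(d, axis=1)
        qe_history.append(float(d[np.arange(n), bmu].mean()))
        h = np.exp(-grid_d2 / (2.0 * sigma**2))  # (nodes, nodes)
        a = h[bmu]  # (n, nodes): influence of each sample on each node
        denom = a.sum(axis=0)
        weights = (a.T @ profiles) / denom[:, None]
    d = cdist(profiles, weights)
    qe_history.append(float(d.min(axis=1).mean()))
    return SOMGrid(
        rows,
        cols,
        weights,
        toroidal,
        metadata={
            "epochs": epochs,
            "seed": seed,
            "sigma_start": sigma_start,
            "sigma_end": sigma_end,
            "qe_history": qe_history,
        },
    )


def quantization_error(grid: SOMGrid, profiles: np.ndarray) -> float:
    d = cdist(np.asarray(profiles, float), grid.weights)
    return float(d.min(axis=1).mean())


def umatrix(grid: SOMGrid) -> np.ndarray:
    """Mean distance of each node's weight to its 8 grid neighbors.

    Ridges (high values) mark cluster boundaries; valleys mark clusters.
    """
    w = grid.weights.reshape(grid.rows, grid.cols, -1)
    out = np.zeros((grid.rows, grid.cols))
    shifts = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for r in range(grid.rows):
        for c in range(grid.cols):
            dists = []
            for dr, dc in shifts:
                rr, cc = r + dr, c + dc
                if grid.toroidal:
                    rr %= grid.rows
                    cc %= grid.cols
                elif not (0 <= rr < grid.rows and 0 <= cc < grid.cols):
                    continue
                dists.append(np.linalg.norm(w[r, c] - w[rr, cc]))
            out[r, c] = np.mean(dists)
    return out
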