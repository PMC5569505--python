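"""Compositional binning of scaffolds into MAG bins.

Profiles every scaffold >= 5 kb in tetranucleotide space (windowed for
long scaffolds), trains a SOM, delineates bins as connected
below-threshold regions of the U-matrix, and assigns each scaffold by a
majority vote over its windows. Automated delineation stands in for the
manual sorting step of classical ESOM binning; all its parameters are
recorded so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import som as som_mod
from . import tnf as tnf_mod
from .utils import gc_fraction

UNBINNED = -1


@dataclass
class MAGBin:
    bin_id: int
    scaffold_ids: list[str]
    total_length: int
    mean_gc: float


@dataclass
class BinningResult:
    assignments: pd.DataFrame  # scaffold_id, bin_id, n_windows, vote_fraction
    bins: dict[int, MAGBin]
    excluded: list[str]  # scaffolds below the length gate (or all-ambiguous)
    grid: som_mod.SOMGrid
    node_labels: np.ndarray  # per-node bin id (UNBINNED for boundary nodes)
    params: dict = field(default_factory=dict)

    def bin_of(self) -> dict[str, int]:
        return dict(zip(self.assignments.scaffold_id, self.assignments.bin_id))


def delineate_bins(
    grid: som_mod.SOMGrid,
    profiles: np.ndarray,
    threshold_percentile: float = 60.0,
    min_contrast: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each profile to a U-matrix valley component, or UNBINNED.

    Nodes whose U-matrix value is at or below the given percentile are
    cluster (valley) nodes; connected components of valley nodes
    (8-connectivity, wrapping on a toroidal grid) become bins, numbered by
    their smallest node index. Profiles whose best-matching unit is a
    boundary node are unbinned. A map whose U-matrix maximum is below
    ``min_contrast`` times its median carries no ridge structure
    (homogeneous input); the whole map is then a single valley.

    Returns (per-profile bin labels, per-node bin labels).
    """
    u = som_mod.umatrix(grid)
    thr = np.percentile(u, threshold_percentile)
    if u.max() <= min_contrast * max(np.median(u), 1e-12):
        valley = np.ones_like(u, dtype=bool)
    else:
        valley = u <= thr
    labels = np.full((grid.rows, grid.cols), UNBINNED, dtype=int)
    comps: list[int] = []
    next_label = 0
    for r in range(grid.rows):
        for c in range(grid.cols):
            if not valley[r, c] or labels[r, c] != UNBINNED:
                continue
            stack = [(r, c)]
            labels[r, c] = next_label
            while stack:
                rr, cc = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        r2, c2 = rr + dr, cc + dc
                        if grid.toroidal:
                            r2 %= grid.rows
                            c2 %= grid.cols
                        elif not (0 <= r2 < grid.rows and 0 <= c2 < grid.cols):
                            continue
                        if valley[r2, c2] and labels[r2, c2] == UNBINNED:
                            labels[r2, c2] = next_label
                            stack.append((r2, c2))
            comps.append(next_label)
            next_label += 1
    node_labels = labels.ravel()
    bmu = grid.bmu(profiles)
    return node_labels[bmu], node_labels


def scaffold_bin_vote(window_labels: dict[str, list[int]]) -> pd.DataFrame:
    """Majority vote over a scaffold's window assignments.

    Ties between real bins go to the lowest bin id; a real bin beats
    UNBINNED on a tie; a scaffold whose windows are majority-unbinned
    stays unbinned. Columns: scaffold_id, bin_id, n_windows, vote_fraction.
    """
    rows = []
    for sid in sorted(window_labels):
        votes = window_labels[sid]
        counts: dict[int, int] = {}
        for v in votes:
            counts[v] = counts.get(v, 0) + 1
        best = max(counts.values())
        candidates = sorted(b for b, k in counts.items() if k == best)
        real = [b for b in candidates if b != UNBINNED]
        winner = real[0] if real else UNBINNED
        rows.append(
            {
                "scaffold_id": sid,
                "bin_id": winner,
                "n_windows": len(votes),
                "vote_fraction": counts[winner] / len(votes),
            }
        )
    return pd.DataFrame(rows, columns=["scaffold_id", "bin_id", "n_windows", "vote_fraction"])


def bin_scaffolds(
    scaffolds: dict[str, str],
    min_scaffold_len: int = 5000,
    window_len: int = 10_000,
    canonical: bool = True,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int = 20,
    threshold_percentile: float = 60.0,
    seed: int = 0,
    coverage: dict[str, float] | None = None,
    reference_profiles: np.ndarray | None = None,
) -> BinningResult:
    """Full compositional binning of a scaffold set.

    ``coverage`` optionally appends a standardized per-scaffold coverage
    column as an extra feature; ``reference_profiles`` optionally mixes
    known genome signatures into SOM training (they influence the map but
    receive no assignment).
    """
    profiles, excluded = tnf_mod.profile_scaffolds(
        scaffolds, window_len, min_scaffold_len, canonical
    )
    if not profiles:
        raise ValueError("no scaffold passed the binning length gate")
    x = np.vstack([p.values for p in profiles])
    if coverage is not None:
        cov = np.array([coverage[p.scaffold_id] for p in profiles], float)
        cov = (cov - cov.mean()) / (cov.std() + 1e-12)
        # scale to the magnitude of one TNF feature so it informs, not dominates
        x = np.column_stack([x, cov * x.std()])
    train_x = x
    if reference_profiles is not None:
        train_x = np.vstack([x, np.asarray(reference_profiles, float)])
    grid = som_mod.train_som(train_x, rows=rows, cols=cols, epochs=epochs, seed=seed)
    labels, node_labels = delineate_bins(grid, x, threshold_percentile)

    window_labels: dict[str, list[int]] = {}
    for p, lab in zip(profiles, labels):
        window_labels.setdefault(p.scaffold_id, []).append(int(lab))
    assignments = scaffold_bin_vote(window_labels)

    bins: dict[int, MAGBin] = {}
    for bin_id, grp in assignments[assignments.bin_id != UNBINNED].groupby("bin_id"):
        sids = sorted(grp.scaffold_id)
        total = sum(len(scaffolds[s]) for s in sids)
        gc = float(np.mean([gc_fraction(scaffolds[s]) for s in sids]))
        bins[int(bin_id)] = MAGBin(int(bin_id), sids, total, gc)

    return BinningResult(
        assignments=assignments,
        bins=bins,
        excluded=excluded,
        grid=grid,
        node_labels=node_labels,
        params={
            "min_scaffold_len": min_scaffold_len,
            "window_len": window_len,
            "canonical": canonical,
            "epochs": epochs,
            "threshold_percentile": threshold_percentile,
            "seed": seed,
            "grid_rows": grid.rows,
            "grid_cols": grid.cols,
        },
    )
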