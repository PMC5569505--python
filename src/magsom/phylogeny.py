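"""Concatenated marker-gene phylogenetics for MAGs.

Builds a supermatrix from per-gene aligned ribosomal-protein blocks
(missing genes gap-filled, taxa admitted only with at least 8 of the 15
markers), computes pairwise p-distances with pairwise gap deletion, and
infers a neighbor-joining tree with column-resampling bootstrap support.
NJ is exact on additive distance matrices, which the tests exploit;
maximum-likelihood inference is reachable by exporting the supermatrix
(FASTA + partition file) to an external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the 15 syntenic ribosomal proteins used for the primary MAG phylogeny
RIBOSOMAL_15 = (
    "rpL2", "rpL3", "rpL4", "rpL5", "rpL6",
    "rpL14", "rpL15", "rpL18", "rpL22", "rpL24",
    "rpS3", "rpS8", "rpS10", "rpS17", "rpS19",
)

#: extended single-copy marker set for more robust placements
EXTENDED_MARKERS = (
    "rpS2", "rpS3", "rpS5", "rpS7", "rpS8", "rpS9", "rpS10", "rpS11",
    "rpS12", "rpS13", "rpS15P", "rpS17", "rpS19",
    "rpL1", "rpL2", "rpL3", "rpL4", "rpL5", "rpL6", "rpL11", "rpL13",
    "rpL14b", "rpL15", "rpL16", "rpL18P", "rpL22", "rpL24", "rpL25", "rpL29",
    "IF-2", "pheS", "pheT", "truB", "hemC", "rnhB",
)

GAP = "-"


@dataclass(frozen=True)
class MarkerCatalog:
    name: str
    markers: tuple[str, ...]


SET15 = MarkerCatalog("set15", RIBOSOMAL_15)
SET37 = MarkerCatalog("set37", EXTENDED_MARKERS)


# ---------------------------------------------------------------------------
# marker extraction and supermatrix
# ---------------------------------------------------------------------------


def extract_markers(
    annotations, catalog: MarkerCatalog = SET15
) -> tuple[dict[str, dict[str, str]], list[str]]:
    """Collect at most one sequence per (taxon, marker) from an annotation
    table with columns taxon, marker, sequence.

    On duplicates the longest sequence is kept; each resolution is logged.
    Returns ({marker: {taxon: sequence}}, log lines).
    """
    wanted = set(catalog.markers)
    out: dict[str, dict[str, str]] = {}
    log: list[str] = []
    for _, row in annotations.iterrows():
        marker, taxon, seq = row["marker"], row["taxon"], row["sequence"]
        if marker not in wanted:
            continue
        slot = out.setdefault(marker, {})
        if taxon in slot:
            if len(seq) > len(slot[taxon]):
                log.append(
                    f"{taxon}/{marker}: kept duplicate of length {len(seq)} over {len(slot[taxon])}"
                )
                slot[taxon] = seq
            else:
                log.append(
                    f"{taxon}/{marker}: kept existing length {len(slot[taxon])} over {len(seq)}"
                )
        else:
            slot[taxon] = seq
    return out, log


@dataclass
class Supermatrix:
    taxa: list[str]
    sequences: dict[str, str]  # taxon -> concatenated aligned row
    blocks: list[tuple[str, int, int]]  # (marker, start, end) 0-based half-open
    presence: dict[str, set[str]]  # taxon -> markers present
    excluded: list[str] = field(default_factory=list)  # taxa below min_markers

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.blocks)

    def partition_lines(self) -> list[str]:
        """Block coordinates, 1-based inclusive as in common partition formats."""
        return [f"{m} = {s + 1}-{e}" for m, s, e in self.blocks]


def concatenate(
    gene_alignments: dict[str, dict[str, str]],
    catalog: MarkerCatalog = SET15,
    min_markers: int = 8,
) -> Supermatrix:
    """Concatenate per-gene aligned blocks into a supermatrix.

    Gene order follows the catalog; a taxon missing a gene receives gaps
    over the full block; taxa carrying fewer than ``min_markers`` catalog
    markers are excluded (the >= 8 ribosomal-protein inclusion rule).
    """
    markers = [m for m in catalog.markers if m in gene_alignments]
    block_len: dict[str, int] = {}
    all_taxa: set[str] = set()
    for m in markers:
        rows = gene_alignments[m]
        lengths = {len(s) for s in rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"gene block {m} has unequal row lengths: {sorted(lengths)}")
        block_len[m] = lengths.pop() if lengths else 0
        all_taxa.update(rows)

    presence = {
        t: {m for m in markers if t in gene_alignments[m]} for t in sorted(all_taxa)
    }
    taxa = [t for t in sorted(all_taxa) if len(presence[t]) >= min_markers]
    excluded = [t for t in sorted(all_taxa) if len(presence[t]) < min_markers]

    blocks: list[tuple[str, int, int]] = []
    pos = 0
    for m in markers:
        blocks.append((m, pos, pos + block_len[m]))
        pos += block_len[m]
    sequences = {
        t: "".join(
            gene_alignments[m].get(t, GAP * block_len[m]) for m in markers
        )
        for t in taxa
    }
    return Supermatrix(taxa, sequences, blocks, {t: presence[t] for t in taxa}, excluded)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def pairwise_distances(
    sm: Supermatrix,
    correction: str | None = None,
    min_shared: int = 50,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """P-distances with pairwise gap deletion.

    For each taxon pair, only columns where both rows are non-gap count;
    pairs sharing fewer than ``min_shared`` columns are flagged
    unreliable; a pair sharing none is an error. ``correction='poisson'``
    applies -ln(1 - p).
    """
    if len(sm.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    arrs = {
        t: np.frombuffer(sm.sequences[t].encode("ascii"), dtype=np.uint8) for t in sm.taxa
    }
    gap = ord(GAP)
    n = len(sm.taxa)
    d = np.zeros((n, n))
    unreliable: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[sm.taxa[i]], arrs[sm.taxa[j]]
            shared = (a != gap) & (b != gap)
            ns = int(shared.sum())
            if ns == 0:
                raise ValueError(
                    f"taxa {sm.taxa[i]} and {sm.taxa[j]} share no aligned columns"
                )
            p = float((a[shared] != b[shared]).sum()) / ns
            if ns < min_shared:
                unreliable.append((sm.taxa[i], sm.taxa[j]))
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("poisson correction undefined at p >= 1")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return d, unreliable


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(f"{c._newick()}:{bl:.6f}" for c, bl in self.children)
        label = "" if self.support is None else f"{self.support:.3f}"
        return f"({inner}){label}"


@dataclass
class DistanceTree:
    root: TreeNode  # trifurcating root of the unrooted tree
    taxa: list[str]

    def to_newick(self) -> str:
        return self.root.to_newick()

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each encoded as the side not
        containing the alphabetically first taxon."""
        anchor = min(self.taxa)
        full = set(self.taxa)
        out: set[frozenset[str]] = set()

        def _walk(node: TreeNode) -> set[str]:
            if node.is_leaf():
                return {node.name}
            below: set[str] = set()
            for c, _ in node.children:
                below |= _walk(c)
            if node is not self.root and 1 < len(below) < len(full) - 1:
                side = below if anchor not in below else full - below
                out.add(frozenset(side))
            return below

        _walk(self.root)
        return out

    def path_lengths(self) -> np.ndarray:
        """Leaf-to-leaf path-length matrix, taxa in ``self.taxa`` order."""
        idx = {t: i for i, t in enumerate(self.taxa)}
        n = len(self.taxa)
        d = np.zeros((n, n))

        def _walk(node: TreeNode) -> dict[int, float]:
            if node.is_leaf():
                return {idx[node.name]: 0.0}
            sides: list[dict[int, float]] = []
            for c, bl in node.children:
                sub = _walk(c)
                sides.append({k: v + bl for k, v in sub.items()})
            for a in range(len(sides)):
                for b in range(a + 1, len(sides)):
                    for i, di in sides[a].items():
                        for j, dj in sides[b].items():
                            d[i, j] = d[j, i] = di + dj
            merged: dict[int, float] = {}
            for s in sides:
                merged.update(s)
            return merged

        _walk(self.root)
        return d

    def annotate_support(self, support: dict[frozenset[str], float]) -> None:
        anchor = min(self.taxa)
        full = set(self.taxa)

        def _walk(node: TreeNode) -> set[str]:
            if node.is_leaf():
                return {node.name}
            below: set[str] = set()
            for c, _ in node.children:
                below |= _walk(c)
            if node is not self.root and 1 < len(below) < len(full) - 1:
                side = below if anchor not in below else full - below
                node.support = support.get(frozenset(side), 0.0)
            return below

        _walk(self.root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sibling so
    the pair's total path length is conserved."""
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def nj_tree(dist: np.ndarray, labels: list[str]) -> DistanceTree:
    """Neighbor joining with deterministic tie-breaking.

    Pair choice minimizes the Q criterion; exact Q ties resolve to the
    lexicographically smallest pair of node names (a node's name is the
    smallest leaf label beneath it). Exact on additive matrices.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in labels}
    names = list(labels)
    d = {a: {b: float(dist[i, j]) for j, b in enumerate(labels)} for i, a in enumerate(labels)}

    while len(names) > 3:
        m = len(names)
        r = {a: sum(d[a][b] for b in names if b != a) for a in names}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = names[ii], names[jj]
                q = (m - 2) * d[a][b] - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        li = d[a][b] / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = d[a][b] - li
        li, lj = _clamp_pair(li, lj)
        new_name = min(a, b)
        u = TreeNode(children=[(nodes[a], li), (nodes[b], lj)])
        du = {}
        for k in names:
            if k in (a, b):
                continue
            du[k] = max((d[a][k] + d[b][k] - d[a][b]) / 2.0, 0.0)
        for k in list(d):
            d[k].pop(a, None)
            d[k].pop(b, None)
        d.pop(a)
        d.pop(b)
        for k, v in du.items():
            d[k][new_name] = v
        d[new_name] = du
        d[new_name][new_name] = 0.0
        names = [x for x in names if x not in (a, b)]
        names.append(new_name)
        nodes.pop(a)
        nodes.pop(b)
        nodes[new_name] = u

    a, b, c = sorted(names)
    la = (d[a][b] + d[a][c] - d[b][c]) / 2.0
    lb = (d[a][b] + d[b][c] - d[a][c]) / 2.0
    lc = (d[a][c] + d[b][c] - d[a][b]) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return DistanceTree(root=root, taxa=sorted(labels))


def bootstrap_support(
    sm: Supermatrix,
    n_replicates: int = 100,
    seed: int = 0,
    correction: str | None = None,
) -> tuple[DistanceTree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap over the supermatrix.

    Each replicate resamples alignment columns with replacement, rebuilds
    the NJ tree, and contributes its splits; support is the fraction of
    replicates containing each split of the original tree. Deterministic
    for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    d, _ = pairwise_distances(sm, correction=correction, min_shared=1)
    tree = nj_tree(d, sm.taxa)
    target = tree.splits()
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cols = np.array([np.frombuffer(sm.sequences[t].encode(), np.uint8) for t in sm.taxa])
    length = cols.shape[1]
    gap = ord(GAP)
    for _ in range(n_replicates):
        pick = rng.integers(0, length, size=length)
        rep = cols[:, pick]
        n = len(sm.taxa)
        dd = np.zeros((n, n))
        ok = rep != gap
        for i in range(n):
            for j in range(i + 1, n):
                shared = ok[i] & ok[j]
                ns = int(shared.sum())
                if ns == 0:
                    dd[i, j] = dd[j, i] = 1.0
                    continue
                p = float((rep[i, shared] != rep[j, shared]).sum()) / ns
                if correction == "poisson" and p < 1.0:
                    p = -np.log(1.0 - p)
                dd[i, j] = dd[j, i] = p
        rep_tree = nj_tree(dd, sm.taxa)
        for s in rep_tree.splits():
            if s in counts:
                counts[s] += 1
    support = {s: c / n_replicates for s, c in counts.items()}
    tree.annotate_support(support)
    return tree, support
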