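"""Ground-truthed synthetic metagenome communities.

Every downstream stage of the pipeline (compositional binning, bin QC,
read recruitment, functional calling, marker phylogenetics) is exercised
on communities produced here. The generator controls exactly the features
those stages assume:

* genomes with distinct oligonucleotide composition (order-k Markov
  chains with per-genome transition tables) and controlled GC content;
* scaffolds drawn from a truncated log-normal length distribution with a
  deliberate sub-5-kb tail, tiling each genome without gaps or overlaps;
* cross-bin contaminant scaffolds with a controlled GC offset;
* paired 125-bp reads at controlled per-genome depth with substitution
  errors;
* single-copy marker genes placed at controlled completeness and
  duplication;
* multi-database annotation records with controlled per-database
  detection probability and false-positive rate.

All randomness flows from one top-level seed through named substreams
(:func:`magsom.utils.substream`), so each stage can be regenerated
independently and outputs are byte-identical across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .utils import (
    decode_sequence,
    encode_sequence,
    gc_fraction,
    reverse_complement,
    substream,
)

GC_BAND = (0.2, 0.8)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic source genome.

    ``relative_depth`` is the expected sequencing-coverage weight used by
    :func:`simulate_reads`; the realized read share is proportional to
    ``relative_depth * length``.
    """

    genome_id: str
    length: int
    gc_target: float
    markov_order: int = 3
    relative_depth: float = 1.0
    seed: int = 0


@njit(cache=True)
def _sample_chain(cum: np.ndarray, first: np.ndarray, n: int, u: np.ndarray, k: int) -> np.ndarray:
    out = np.empty(n, dtype=np.uint8)
    for i in range(k):
        out[i] = first[i]
    ctx = 0
    for i in range(k):
        ctx = ctx * 4 + first[i]
    mod = 4 ** (k - 1)
    for i in range(k, n):
        row = cum[ctx]
        x = u[i - k]
        b = 0
        while row[b] < x:
            b += 1
        out[i] = b
        ctx = (ctx % mod) * 4 + b
    return out


def _transition_table(rng: np.random.Generator, order: int, gc_target: float) -> np.ndarray:
    """Per-context base probabilities with stationary GC pinned to target.

    Rows are Dirichlet(1,1,1,1) draws, then rescaled so that in every
    context P(G)+P(C) equals ``gc_target`` exactly; composition between
    contexts still differs, which is what separates genomes in
    tetranucleotide space.
    """
    n_ctx = 4**order
    table = rng.dirichlet(np.ones(4), size=n_ctx)
    at = table[:, 0] + table[:, 3]
    gc = table[:, 1] + table[:, 2]
    # guard against degenerate rows
    at = np.maximum(at, 1e-9)
    gc = np.maximum(gc, 1e-9)
    table[:, 0] *= (1.0 - gc_target) / at
    table[:, 3] *= (1.0 - gc_target) / at
    table[:, 1] *= gc_target / gc
    table[:, 2] *= gc_target / gc
    return table / table.sum(axis=1, keepdims=True)


def generate_genome(spec: GenomeSpec, gc_band: tuple[float, float] = GC_BAND) -> str:
    """Sample an order-k Markov genome of exactly ``spec.length`` bases.

    Raises ``ValueError`` for a gc_target outside the configured band or a
    non-positive length. Deterministic for a fixed spec.
    """
    if not (gc_band[0] < spec.gc_target < gc_band[1]):
        raise ValueError(
            f"gc_target {spec.gc_target} outside allowed band ({gc_band[0]}, {gc_band[1]})"
        )
    if spec.length < spec.markov_order + 1:
        raise ValueError(f"genome length must exceed markov order, got {spec.length}")
    if spec.markov_order < 0:
        raise ValueError("markov_order must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    k = max(spec.markov_order, 1)
    table = _transition_table(rng, k, spec.gc_target)
    cum = np.cumsum(table, axis=1)
    cum[:, -1] = 1.0  # absorb rounding
    base0 = np.array(
        [(1 - spec.gc_target) / 2, spec.gc_target / 2, spec.gc_target / 2, (1 - spec.gc_target) / 2]
    )
    first = rng.choice(4, size=k, p=base0).astype(np.uint8)
    u = rng.random(spec.length - k)
    codes = _sample_chain(cum, first, spec.length, u, k)
    return decode_sequence(codes)


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------


@dataclass
class Scaffold:
    scaffold_id: str
    sequence: str
    genome_id: str
    start: int  # 0-based, half-open on the source genome
    end: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass
class ScaffoldTruth:
    genome_id: str
    start: int
    end: int
    contaminant_in: str | None = None


@dataclass
class TruthTable:
    """Ground truth for every emitted record.

    ``bin_of`` maps each scaffold to its truth bin: the source genome,
    unless :func:`inject_contaminants` relabeled it into a foreign bin
    (the scaffold entry then keeps the original genome and the recipient
    bin id).
    """

    scaffolds: dict[str, ScaffoldTruth] = field(default_factory=dict)
    bin_of: dict[str, str] = field(default_factory=dict)
    reads: dict[str, str] = field(default_factory=dict)
    markers: pd.DataFrame | None = None
    pathways: dict[str, set[str]] = field(default_factory=dict)

    def bins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, b in self.bin_of.items():
            out.setdefault(b, []).append(sid)
        return out


def draw_scaffold_lengths(
    n_large: int,
    n_small: int,
    rng: np.random.Generator,
    min_len: int = 200,
    max_len: int = 177_401,
    boundary: int = 5000,
    log_median: float = 8000.0,
    log_sigma: float = 1.0,
) -> np.ndarray:
    """Truncated log-normal scaffold lengths: ``n_large`` at or above the
    binning boundary plus ``n_small`` below it, shuffled."""
    mu = np.log(log_median)

    def _draw(n: int, lo: int, hi: int) -> list[int]:
        out: list[int] = []
        while len(out) < n:
            x = rng.lognormal(mu, log_sigma, size=4 * n)
            x = x[(x >= lo) & (x <= hi)]
            out.extend(int(v) for v in x[: n - len(out)])
        return out

    lens = _draw(n_large, boundary, max_len) + _draw(n_small, min_len, boundary - 1)
    lens = np.array(lens, dtype=np.int64)
    rng.shuffle(lens)
    return lens


def fragment_genome(
    sequence: str,
    min_len: int = 200,
    max_len: int = 177_401,
    seed: int = 0,
    genome_id: str = "genome",
    lengths: np.ndarray | list[int] | None = None,
    log_median: float = 8000.0,
    log_sigma: float = 1.0,
) -> list[Scaffold]:
    """Cut a genome into scaffolds that tile it without gap or overlap.

    Lengths are either supplied (they must sum to the genome length) or
    drawn from the truncated log-normal until the genome is exhausted; a
    final remainder shorter than ``min_len`` is merged into the previous
    scaffold, so fragment lengths always sum to the genome length.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    if min_len < 200:
        raise ValueError("min_len must be at least 200")
    n = len(sequence)
    if lengths is not None:
        lengths = [int(x) for x in lengths]
        if sum(lengths) != n:
            raise ValueError("explicit lengths must sum to the genome length")
        cuts = lengths
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        mu = np.log(log_median)
        cuts = []
        remaining = n
        while remaining > 0:
            x = int(np.clip(rng.lognormal(mu, log_sigma), min_len, max_len))
            if x >= remaining:
                if remaining < min_len and cuts:
                    cuts[-1] += remaining
                else:
                    cuts.append(remaining)
                remaining = 0
            else:
                cuts.append(x)
                remaining -= x
    scaffolds = []
    pos = 0
    for i, ln in enumerate(cuts):
        sid = f"{genome_id}_s{i:04d}"
        scaffolds.append(Scaffold(sid, sequence[pos : pos + ln], genome_id, pos, pos + ln))
        pos += ln
    return scaffolds


# ---------------------------------------------------------------------------
# contaminants
# ---------------------------------------------------------------------------


def inject_contaminants(
    truth: TruthTable,
    scaffold_seqs: dict[str, str],
    rate: float,
    donor_policy: str = "gc_extreme",
    seed: int = 0,
    min_scaffold_len: int = 5000,
    min_gc_offset: float = 0.30,
) -> list[str]:
    """Relabel a fraction of each bin's scaffolds as cross-bin contaminants.

    For each recipient bin, ``round(rate * bin size)`` scaffolds from a
    donor genome are moved into the bin (their ``bin_of`` entry changes;
    the scaffold truth keeps the original genome and records the recipient
    in ``contaminant_in``). Policy ``gc_extreme`` picks the donor with the
    largest genome-level GC offset and only injects into recipients for
    which that offset reaches ``min_gc_offset`` (mid-GC bins without an
    extreme donor receive no contaminants); policy ``random`` picks any
    other genome. Returns the injected scaffold ids.
    """
    if not (0 <= rate < 0.5):
        raise ValueError(f"contamination rate must be in [0, 0.5), got {rate}")
    genome_ids = sorted({t.genome_id for t in truth.scaffolds.values()})
    if len(genome_ids) < 2:
        raise ValueError("contaminant injection needs at least 2 genomes")
    if rate == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genome_gc = {
        g: float(
            np.mean(
                [
                    gc_fraction(scaffold_seqs[sid])
                    for sid, t in truth.scaffolds.items()
                    if t.genome_id == g
                ]
            )
        )
        for g in genome_ids
    }
    bins = truth.bins()
    # snapshot of pre-injection bin sizes: the injected count per bin is
    # rate * original membership, independent of processing order
    initial_size = {
        b: sum(1 for s in members if truth.scaffolds[s].contaminant_in is None)
        for b, members in bins.items()
    }
    injected: list[str] = []
    moved: set[str] = set()
    for recipient in sorted(bins):
        n_inject = int(round(rate * initial_size[recipient]))
        if n_inject == 0:
            continue
        others = [g for g in genome_ids if g != recipient]
        if donor_policy == "gc_extreme":
            donor = max(others, key=lambda g: abs(genome_gc[g] - genome_gc[recipient]))
            if abs(genome_gc[donor] - genome_gc[recipient]) < min_gc_offset:
                continue  # no sufficiently extreme donor for this bin
        elif donor_policy == "random":
            donor = others[int(rng.integers(len(others)))]
        else:
            raise ValueError(f"unknown donor policy: {donor_policy}")
        pool = [
            s
            for s in bins[donor]
            if s not in moved
            and truth.scaffolds[s].contaminant_in is None
            and len(scaffold_seqs[s]) >= min_scaffold_len
        ]
        take = rng.choice(len(pool), size=min(n_inject, len(pool)), replace=False)
        for idx in sorted(take):
            sid = pool[idx]
            truth.bin_of[sid] = recipient
            truth.scaffolds[sid].contaminant_in = recipient
            moved.add(sid)
            injected.append(sid)
    return injected


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    codes = encode_sequence(seq).copy()
    hits = np.nonzero(rng.random(len(codes)) < rate)[0]
    if len(hits):
        codes[hits] = (codes[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return decode_sequence(codes)


def simulate_reads(
    scaffolds: dict[str, str],
    scaffold_genome: dict[str, str],
    depth_weights: dict[str, float],
    n_pairs: int,
    read_len: int = 125,
    error_rate: float = 0.0,
    insert_range: tuple[int, int] = (360, 420),
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Paired-end reads sampled uniformly within scaffolds.

    Fragment positions are uniform; the mate pair covers an insert drawn
    uniformly from ``insert_range`` (clipped to the scaffold), read 1 on
    the forward strand and read 2 the reverse complement of the insert
    end. A genome's share of pairs is proportional to
    ``depth_weight * genome length``. Returns the reads in emission order
    plus a read-id -> source-genome truth map.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    sids = sorted(scaffolds)
    shortest = min(len(scaffolds[s]) for s in sids)
    if read_len > shortest:
        raise ValueError(f"read_len {read_len} exceeds shortest scaffold ({shortest} bp)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w = np.array([len(scaffolds[s]) * depth_weights[scaffold_genome[s]] for s in sids], float)
    probs = w / w.sum()
    counts = rng.multinomial(n_pairs, probs)
    reads: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    pair_no = 0
    for sid, k in zip(sids, counts):
        seq = scaffolds[sid]
        gid = scaffold_genome[sid]
        for _ in range(int(k)):
            insert = int(rng.integers(insert_range[0], insert_range[1] + 1))
            insert = min(insert, len(seq))
            start = int(rng.integers(0, len(seq) - insert + 1))
            frag = seq[start : start + insert]
            r1 = frag[:read_len]
            r2 = reverse_complement(frag[-read_len:])
            if error_rate > 0:
                r1 = _mutate(r1, rng, error_rate)
                r2 = _mutate(r2, rng, error_rate)
            for mate, r in ((1, r1), (2, r2)):
                rid = f"p{pair_no:07d}/{mate}"
                reads.append((rid, r))
                truth[rid] = gid
            pair_no += 1
    return reads, truth


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def place_markers(
    genome_id: str,
    scaffold_ids: list[str],
    marker_list: list[str],
    completeness: float,
    duplication: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Place single-copy markers on a genome's scaffolds at controlled
    completeness and duplication.

    Exactly ``round(completeness * M)`` distinct markers are present and
    ``round(duplication * M)`` of those appear twice. Columns:
    genome_id, marker, scaffold_id, gene_id, copy.
    """
    if not marker_list:
        raise ValueError("marker_list must be non-empty")
    if not (0 <= completeness <= 1) or not (0 <= duplication <= 1):
        raise ValueError("completeness and duplication must be in [0, 1]")
    if duplication > completeness:
        raise ValueError("duplication cannot exceed completeness")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = len(marker_list)
    n_present = int(round(completeness * m))
    n_dup = int(round(duplication * m))
    present = sorted(rng.choice(m, size=n_present, replace=False))
    dup = set(rng.choice(present, size=n_dup, replace=False)) if n_dup else set()
    rows = []
    gene_no = 0
    for idx in present:
        copies = 2 if idx in dup else 1
        for c in range(copies):
            sid = scaffold_ids[int(rng.integers(len(scaffold_ids)))]
            rows.append(
                {
                    "genome_id": genome_id,
                    "marker": marker_list[idx],
                    "scaffold_id": sid,
                    "gene_id": f"{genome_id}_m{gene_no:03d}",
                    "copy": c,
                }
            )
            gene_no += 1
    return pd.DataFrame(rows, columns=["genome_id", "marker", "scaffold_id", "gene_id", "copy"])


def simulate_marker_proteins(
    genome_ids: list[str],
    markers: list[str],
    divergence: dict[str, float],
    seed: int = 0,
    length_range: tuple[int, int] = (100, 200),
) -> dict[str, dict[str, str]]:
    """Per-marker protein sequences: one random reference per marker,
    mutated per genome at its ``divergence`` rate. All copies of a marker
    share a length, so blocks arrive pre-aligned."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    out: dict[str, dict[str, str]] = {}
    for marker in markers:
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        ref = rng.integers(0, len(aa), size=ln)
        out[marker] = {}
        for gid in genome_ids:
            seq = ref.copy()
            hits = np.nonzero(rng.random(ln) < divergence[gid])[0]
            if len(hits):
                seq[hits] = (seq[hits] + rng.integers(1, len(aa), size=len(hits))) % len(aa)
            out[marker][gid] = aa[seq].tobytes().decode()
    return out


def evolve_alignment(
    tree: tuple,
    seq_len: int,
    seed: int = 0,
    alphabet: str = AMINO_ACIDS,
) -> dict[str, str]:
    """Simulate one aligned block down a known tree.

    ``tree`` is ``(label, [(child, branch_length), ...])``; a leaf has an
    empty child list. Each site substitutes along a branch with
    probability equal to the branch length (to a uniformly chosen other
    state), so expected p-distances track path lengths for short branches.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    root = rng.integers(0, len(sigma), size=seq_len)
    leaves: dict[str, str] = {}

    def _walk(node: tuple, state: np.ndarray) -> None:
        label, children = node
        if not children:
            leaves[label] = sigma[state].tobytes().decode()
            return
        for child, bl in children:
            s = state.copy()
            hits = np.nonzero(rng.random(seq_len) < bl)[0]
            if len(hits):
                s[hits] = (s[hits] + rng.integers(1, len(sigma), size=len(hits))) % len(sigma)
            _walk(child, s)

    _walk(tree, root)
    return leaves


# ---------------------------------------------------------------------------
# annotations & gene families
# ---------------------------------------------------------------------------


def simulate_annotations(
    genome_enzymes: dict[str, set[str]],
    databases: list[str],
    detection_prob: float,
    false_positive_rate: float,
    seed: int = 0,
    enzyme_universe: list[str] | None = None,
    subthreshold_rate: float = 0.02,
) -> pd.DataFrame:
    """Multi-database annotation records for truly-present enzyme sets.

    Each truly present enzyme yields one record per database with
    probability ``detection_prob`` (e-value well past the 1e-20 gate by
    construction); absent enzymes appear per database at
    ``false_positive_rate``; a further ``subthreshold_rate`` of absent
    enzymes yield records whose e-value fails the gate, to exercise
    filtering. Columns: gene_id, mag_id, database, enzyme_id, score,
    score_type.
    """
    if len(databases) < 2:
        raise ValueError("need >= 2 databases to exercise consensus calling")
    for p, name in ((detection_prob, "detection_prob"), (false_positive_rate, "false_positive_rate")):
        if not (0 <= p <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if enzyme_universe is None:
        enzyme_universe = sorted(set().union(*genome_enzymes.values())) if genome_enzymes else []
    rows = []
    gene_no = 0
    for gid in sorted(genome_enzymes):
        present = genome_enzymes[gid]
        for db in databases:
            for enz in enzyme_universe:
                if enz in present:
                    if rng.random() < detection_prob:
                        ev = 10.0 ** (-rng.uniform(25, 60))
                    else:
                        continue
                elif rng.random() < false_positive_rate:
                    ev = 10.0 ** (-rng.uniform(21, 30))
                elif rng.random() < subthreshold_rate:
                    ev = 10.0 ** (-rng.uniform(5, 19))
                else:
                    continue
                rows.append(
                    {
                        "gene_id": f"{gid}_g{gene_no:05d}",
                        "mag_id": gid,
                        "database": db,
                        "enzyme_id": enz,
                        "score": ev,
                        "score_type": "evalue",
                    }
                )
                gene_no += 1
    return pd.DataFrame(
        rows, columns=["gene_id", "mag_id", "database", "enzyme_id", "score", "score_type"]
    )


def simulate_gene_families(
    n_archaea: int,
    n_bacteria: int,
    family_means: dict[str, tuple[float, float]],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Poisson gene-family counts per MAG with domain-specific means.

    Returns a (MAG x family) count matrix and a MAG -> domain map. With
    equal means per family this is the null configuration used to check
    the family-wise error rate of the domain comparison test.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mags = [f"arch_{i:02d}" for i in range(n_archaea)] + [
        f"bact_{i:02d}" for i in range(n_bacteria)
    ]
    domains = {m: ("archaea" if m.startswith("arch") else "bacteria") for m in mags}
    data = {}
    for fam, (lam_a, lam_b) in family_means.items():
        lam = np.array([lam_a] * n_archaea + [lam_b] * n_bacteria)
        data[fam] = rng.poisson(lam)
    return pd.DataFrame(data, index=mags), domains


def simulate_scaffold_evidence(
    truth: TruthTable,
    scaffold_seqs: dict[str, str],
    genome_phylum: dict[str, str],
    genes_per_scaffold: int = 8,
    confidence_mean: float = 85.0,
    confidence_sd: float = 3.0,
    contaminant_confidence_mean: float = 50.0,
    contaminant_confidence_sd: float = 5.0,
    tax_error: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene taxonomy/confidence evidence used by bin decontamination.

    Native scaffolds carry their genome's phylum at high confidence;
    contaminant scaffolds carry the donor's phylum at depressed
    confidence, so all three removal rules (taxonomy, GC, confidence) have
    true positives to find. Columns: scaffold_id, gene_id, taxonomy,
    confidence, gc.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    phyla = sorted(set(genome_phylum.values()))
    rows = []
    for sid in sorted(truth.scaffolds):
        t = truth.scaffolds[sid]
        own = genome_phylum[t.genome_id]
        is_contam = t.contaminant_in is not None
        mu = contaminant_confidence_mean if is_contam else confidence_mean
        sd = contaminant_confidence_sd if is_contam else confidence_sd
        gc = gc_fraction(scaffold_seqs[sid])
        for g in range(genes_per_scaffold):
            tax = own
            if tax_error > 0 and rng.random() < tax_error:
                tax = phyla[int(rng.integers(len(phyla)))]
            conf = float(np.clip(rng.normal(mu, sd), 0, 100))
            rows.append(
                {
                    "scaffold_id": sid,
                    "gene_id": f"{sid}_g{g}",
                    "taxonomy": tax,
                    "confidence": conf,
                    "gc": gc,
                }
            )
    return pd.DataFrame(rows, columns=["scaffold_id", "gene_id", "taxonomy", "confidence", "gc"])


# ---------------------------------------------------------------------------
# whole community
# ---------------------------------------------------------------------------


@dataclass
class CommunityConfig:
    """Defaults are the study conditions every downstream test assumes:
    five compositionally distinct genomes, 200 binnable (>=5 kb) scaffolds
    each plus a sub-5-kb tail, 10% cross-bin contamination at extreme GC
    offset, equal sequencing depth, and four annotation sources."""

    genome_ids: tuple[str, ...] = ("g1", "g2", "g3", "g4", "g5")
    gc_targets: tuple[float, ...] = (0.30, 0.40, 0.50, 0.60, 0.70)
    relative_depths: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    domains: tuple[str, ...] = ("archaea", "archaea", "bacteria", "bacteria", "bacteria")
    phyla: tuple[str, ...] = (
        "Bathyarchaeota",
        "Methanomicrobia",
        "Chloroflexi",
        "Deltaproteobacteria",
        "Bacteroidetes",
    )
    markov_order: int = 3
    n_scaffolds_large: int = 200
    n_scaffolds_small: int = 50
    min_scaffold_len: int = 200
    max_scaffold_len: int = 177_401
    large_boundary: int = 5000
    scaffold_log_median: float = 8000.0
    scaffold_log_sigma: float = 1.0
    contamination_rate: float = 0.10
    donor_policy: str = "gc_extreme"
    n_read_pairs: int = 20_000
    read_len: int = 125
    error_rate: float = 0.002
    insert_range: tuple[int, int] = (360, 420)
    marker_completeness: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.55)
    marker_duplication: tuple[float, ...] = (0.0, 0.05, 0.10, 0.0, 0.05)
    databases: tuple[str, ...] = ("hmmer", "blastp", "kaas", "img")
    detection_prob: float = 0.9
    false_positive_rate: float = 0.01
    pathway_sets: tuple[frozenset[str], ...] = (
        frozenset({"reverse_methanogenesis", "beta_oxidation"}),
        frozenset({"sulfate_reduction"}),
        frozenset({"beta_oxidation", "denitrification"}),
        frozenset({"fumarate_addition"}),
        frozenset(),
    )
    min_tnf_separation: float = 0.02


@dataclass
class Community:
    config: CommunityConfig
    specs: dict[str, GenomeSpec]
    genomes: dict[str, str]
    scaffolds: dict[str, str]
    truth: TruthTable
    reads: list[tuple[str, str]]
    annotations: pd.DataFrame
    marker_table: pd.DataFrame
    domains: dict[str, str]
    phyla: dict[str, str]

    def scaffolds_of(self, genome_id: str) -> list[str]:
        return sorted(
            s for s, t in self.truth.scaffolds.items() if t.genome_id == genome_id
        )


def simulate_community(
    config: CommunityConfig | None = None,
    seed: int = 0,
    marker_list: list[str] | None = None,
    with_reads: bool = True,
) -> Community:
    """Generate a full ground-truthed community from one top-level seed."""
    from . import phylogeny, profiling, tnf  # local import avoids a cycle

    cfg = config or CommunityConfig()
    if marker_list is None:
        marker_list = list(phylogeny.RIBOSOMAL_15)
    n = len(cfg.genome_ids)
    frag_rng = substream(seed, "fragment")
    genome_rng = substream(seed, "genome")

    specs: dict[str, GenomeSpec] = {}
    genomes: dict[str, str] = {}
    scaffolds: dict[str, str] = {}
    truth = TruthTable()
    per_genome_lengths = {}
    for i, gid in enumerate(cfg.genome_ids):
        lens = draw_scaffold_lengths(
            cfg.n_scaffolds_large,
            cfg.n_scaffolds_small,
            frag_rng,
            cfg.min_scaffold_len,
            cfg.max_scaffold_len,
            cfg.large_boundary,
            cfg.scaffold_log_median,
            cfg.scaffold_log_sigma,
        )
        per_genome_lengths[gid] = lens
        spec = GenomeSpec(
            genome_id=gid,
            length=int(lens.sum()),
            gc_target=cfg.gc_targets[i],
            markov_order=cfg.markov_order,
            relative_depth=cfg.relative_depths[i],
            seed=int(genome_rng.integers(2**31)),
        )
        specs[gid] = spec
        genomes[gid] = generate_genome(spec)
        for sc in fragment_genome(genomes[gid], genome_id=gid, lengths=per_genome_lengths[gid]):
            scaffolds[sc.scaffold_id] = sc.sequence
            truth.scaffolds[sc.scaffold_id] = ScaffoldTruth(gid, sc.start, sc.end)
            truth.bin_of[sc.scaffold_id] = gid

    # enforced composition separation so binning tests are well-posed
    profiles = np.vstack([tnf.tetranucleotide_frequencies(genomes[g]) for g in cfg.genome_ids])
    from scipy.spatial.distance import pdist

    if n >= 2 and pdist(profiles).min() < cfg.min_tnf_separation:
        raise RuntimeError(
            "generated genomes violate the minimum tetranucleotide separation; "
            "use more distinct seeds or GC targets"
        )

    inject_contaminants(
        truth,
        scaffolds,
        cfg.contamination_rate,
        cfg.donor_policy,
        seed=int(substream(seed, "contaminant").integers(2**31)),
        min_scaffold_len=cfg.large_boundary,
    )

    marker_rng = substream(seed, "marker")
    tables = []
    for i, gid in enumerate(cfg.genome_ids):
        eligible = [s for s in truth.scaffolds if truth.scaffolds[s].genome_id == gid
                    and len(scaffolds[s]) >= 1000]
        tables.append(
            place_markers(
                gid,
                sorted(eligible),
                marker_list,
                cfg.marker_completeness[i],
                cfg.marker_duplication[i],
                seed=int(marker_rng.integers(2**31)),
            )
        )
    truth.markers = pd.concat(tables, ignore_index=True)

    truth.pathways = {gid: set(cfg.pathway_sets[i]) for i, gid in enumerate(cfg.genome_ids)}
    catalog = profiling.starter_pathways()
    genome_enzymes = {
        gid: set().union(*(catalog[p].components for p in pw)) if pw else set()
        for gid, pw in truth.pathways.items()
    }
    universe = sorted(set().union(*(d.components for d in catalog.values())))
    annotations = simulate_annotations(
        genome_enzymes,
        list(cfg.databases),
        cfg.detection_prob,
        cfg.false_positive_rate,
        seed=int(substream(seed, "annotation").integers(2**31)),
        enzyme_universe=universe,
    )

    reads: list[tuple[str, str]] = []
    if with_reads:
        depth = {g: specs[g].relative_depth for g in cfg.genome_ids}
        scaffold_genome = {s: t.genome_id for s, t in truth.scaffolds.items()}
        reads, read_truth = simulate_reads(
            scaffolds,
            scaffold_genome,
            depth,
            cfg.n_read_pairs,
            cfg.read_len,
            cfg.error_rate,
            cfg.insert_range,
            seed=int(substream(seed, "read").integers(2**31)),
        )
        truth.reads = read_truth

    return Community(
        config=cfg,
        specs=specs,
        genomes=genomes,
        scaffolds=scaffolds,
        truth=truth,
        reads=reads,
        annotations=annotations,
        marker_table=truth.markers,
        domains=dict(zip(cfg.genome_ids, cfg.domains)),
        phyla=dict(zip(cfg.genome_ids, cfg.phyla)),
    )
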