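"""Bin quality control: marker-based completeness/duplication, quality
gates, and contaminant-scaffold removal.

Completeness is the fraction of an expected single-copy marker set seen
at least once in a bin; duplication the fraction seen at least twice —
a deliberately simple estimator over a configurable marker list (default:
the 15 ribosomal proteins), not a lineage-aware one.

Decontamination applies three deviation rules against bin-level means
that are computed once on the initial membership and then frozen: a
scaffold is removed if its GC deviates by more than 0.25 (absolute, on
the GC fraction scale), its majority gene taxonomy at the configured rank
disagrees with the bin's majority, or its mean gene-assignment confidence
deviates by more than 25 percentage points. One pass only: removing a
scaffold never changes another scaffold's verdict within the pass.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class QCReport:
    bin_id: str
    completeness: float  # percent
    duplication: float  # percent
    n_markers_present: int
    n_markers_duplicated: int
    mean_gc: float | None = None
    mean_confidence: float | None = None


@dataclass
class Removal:
    scaffold_id: str
    bin_id: str
    reasons: list[str]
    values: dict = field(default_factory=dict)


@dataclass
class ScaffoldEvidence:
    scaffold_id: str
    gc: float
    gene_taxa: list[str]
    gene_confidences: list[float]

    def majority_taxa(self) -> set[str]:
        """All modal taxonomy labels of this scaffold's genes (ties kept)."""
        if not self.gene_taxa:
            return set()
        counts = Counter(self.gene_taxa)
        best = max(counts.values())
        return {t for t, k in counts.items() if k == best}

    def mean_confidence(self) -> float:
        return sum(self.gene_confidences) / len(self.gene_confidences)


def estimate_completeness(
    marker_counts: dict[str, int],
    marker_list: list[str],
    bin_id: str = "bin",
) -> QCReport:
    """Completeness/duplication of one bin from marker occurrence counts.

    completeness = 100 * |markers present| / |marker list|;
    duplication = 100 * |markers present >= 2 times| / |marker list|.
    A marker in the table but not in the list is an error.
    """
    if not marker_list:
        raise ValueError("marker_list must be non-empty")
    unknown = set(marker_counts) - set(marker_list)
    if unknown:
        raise ValueError(f"unknown markers in table: {sorted(unknown)}")
    present = [m for m, c in marker_counts.items() if c >= 1]
    duplicated = [m for m, c in marker_counts.items() if c >= 2]
    m = len(marker_list)
    return QCReport(
        bin_id=bin_id,
        completeness=100.0 * len(present) / m,
        duplication=100.0 * len(duplicated) / m,
        n_markers_present=len(present),
        n_markers_duplicated=len(duplicated),
    )


def marker_counts_per_bin(
    marker_hits: pd.DataFrame, bin_of: dict[str, str]
) -> dict[str, dict[str, int]]:
    """Aggregate a marker-hit table (scaffold_id, marker) into per-bin counts."""
    out: dict[str, dict[str, int]] = {}
    for _, row in marker_hits.iterrows():
        b = bin_of.get(row["scaffold_id"])
        if b is None:
            continue
        out.setdefault(b, {})
        out[b][row["marker"]] = out[b].get(row["marker"], 0) + 1
    return out


def gate_bins(
    reports: list[QCReport],
    min_completeness: float = 50.0,
    max_duplication: float = 10.0,
) -> tuple[list[QCReport], list[QCReport]]:
    """Apply the MAG quality gates: completeness strictly above the
    minimum, duplication at or below the maximum. Returns (kept, rejected)."""
    kept, rejected = [], []
    for r in reports:
        if r.completeness > min_completeness and r.duplication <= max_duplication:
            kept.append(r)
        else:
            rejected.append(r)
    return kept, rejected


def decontaminate(
    bin_id: str,
    scaffold_ids: list[str],
    evidence: dict[str, ScaffoldEvidence],
    gc_delta: float = 0.25,
    conf_delta: float = 25.0,
    min_bin_size: int = 3,
) -> tuple[list[str], list[Removal], list[str]]:
    """One-pass removal of deviant scaffolds from a bin.

    Bin means (GC, confidence, majority taxonomy over all member genes)
    are computed on the initial membership and frozen for the pass.
    Scaffolds without evidence are retained and flagged unevaluated.
    Returns (kept, removals, unevaluated).
    """
    evaluated = [s for s in scaffold_ids if s in evidence]
    unevaluated = [s for s in scaffold_ids if s not in evidence]
    if len(scaffold_ids) < min_bin_size:
        warnings.warn(
            f"bin {bin_id} has fewer than {min_bin_size} scaffolds; "
            "deviation-from-mean filtering is ill-posed, passing through unfiltered"
        )
        return list(scaffold_ids), [], unevaluated
    if not evaluated:
        return list(scaffold_ids), [], unevaluated

    mean_gc = sum(evidence[s].gc for s in evaluated) / len(evaluated)
    mean_conf = sum(evidence[s].mean_confidence() for s in evaluated) / len(evaluated)
    gene_taxa = Counter(t for s in evaluated for t in evidence[s].gene_taxa)
    if gene_taxa:
        best = max(gene_taxa.values())
        bin_taxa = {t for t, k in gene_taxa.items() if k == best}
    else:
        bin_taxa = set()

    kept: list[str] = list(unevaluated)
    removals: list[Removal] = []
    for s in evaluated:
        ev = evidence[s]
        reasons = []
        values: dict = {}
        if abs(ev.gc - mean_gc) > gc_delta:
            reasons.append("gc")
            values["gc"] = ev.gc
            values["bin_mean_gc"] = mean_gc
        # tie -> no removal: any overlap between modal label sets keeps it
        if bin_taxa and ev.gene_taxa and not (ev.majority_taxa() & bin_taxa):
            reasons.append("taxonomy")
            values["taxonomy"] = sorted(ev.majority_taxa())
            values["bin_taxonomy"] = sorted(bin_taxa)
        if ev.gene_confidences and abs(ev.mean_confidence() - mean_conf) > conf_delta:
            reasons.append("confidence")
            values["confidence"] = ev.mean_confidence()
            values["bin_mean_confidence"] = mean_conf
        if reasons:
            removals.append(Removal(s, bin_id, reasons, values))
        else:
            kept.append(s)
    return kept, removals, unevaluated


def evidence_from_table(table: pd.DataFrame) -> dict[str, ScaffoldEvidence]:
    """Build per-scaffold evidence from a long gene table with columns
    scaffold_id, taxonomy, confidence, gc."""
    out: dict[str, ScaffoldEvidence] = {}
    for sid, grp in table.groupby("scaffold_id"):
        out[str(sid)] = ScaffoldEvidence(
            scaffold_id=str(sid),
            gc=float(grp["gc"].iloc[0]),
            gene_taxa=list(grp["taxonomy"]),
            gene_confidences=list(grp["confidence"]),
        )
    return out
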