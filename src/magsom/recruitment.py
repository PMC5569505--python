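"""Exact full-length read recruitment and genome-size-normalized abundance.

A read is recruited to a MAG iff its complete sequence occurs as an exact
substring of any member scaffold, on either strand — no mismatches, no
partial alignment. Relative abundance divides recruited reads by genome
size, normalizes by the sample's total read count, and scales by 1e6:

    abundance(m, s) = count(m, s) / genome_size(m) / total_reads(s) * 1e6
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .utils import reverse_complement


@dataclass
class RecruitmentCounts:
    counts: dict[tuple[str, str], int] = field(default_factory=dict)  # (mag, sample) -> reads
    sample_totals: dict[str, int] = field(default_factory=dict)
    genome_sizes: dict[str, int] = field(default_factory=dict)
    ambiguous: dict[str, list[str]] = field(default_factory=dict)  # read -> mags (if > 1)
    unmatchable: dict[str, int] = field(default_factory=dict)  # sample -> non-ACGT reads
    wrong_length: dict[str, int] = field(default_factory=dict)  # sample -> rejected reads

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mag_id": m,
                "sample_id": s,
                "reads": c,
                "genome_size": self.genome_sizes[m],
                "sample_total": self.sample_totals[s],
            }
            for (m, s), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["mag_id", "sample_id", "reads", "genome_size", "sample_total"]
        )


def recruit_reads(
    reads: list[tuple[str, str]],
    mags: dict[str, dict[str, str]],
    sample_id: str = "sample1",
    read_len: int = 125,
    counts: RecruitmentCounts | None = None,
) -> RecruitmentCounts:
    """Recruit fixed-length reads to MAGs by exact full-length matching.

    ``mags`` maps mag_id -> {scaffold_id: sequence}. Each mate counts
    independently; a read matching several scaffolds of one MAG counts
    once; a read matching several MAGs counts once per MAG and is listed
    in the ambiguity report. Reads of the wrong length or containing
    non-ACGT symbols are tallied and never match. Call once per sample,
    passing the running ``counts`` to accumulate a multi-sample table.
    """
    res = counts or RecruitmentCounts()
    if sample_id in res.sample_totals:
        raise ValueError(f"sample {sample_id} already recruited")
    res.sample_totals[sample_id] = len(reads)
    res.unmatchable.setdefault(sample_id, 0)
    res.wrong_length.setdefault(sample_id, 0)
    for m, scaffolds in mags.items():
        size = sum(len(s) for s in scaffolds.values())
        if m in res.genome_sizes and res.genome_sizes[m] != size:
            raise ValueError(f"genome size of {m} changed between samples")
        res.genome_sizes[m] = size

    # index: read sequence (and its reverse complement) -> read ids
    lookup: dict[str, list[str]] = {}
    for rid, seq in reads:
        if len(seq) != read_len:
            res.wrong_length[sample_id] += 1
            continue
        if any(b not in "ACGT" for b in seq):
            res.unmatchable[sample_id] += 1
            continue
        lookup.setdefault(seq, []).append(rid)
        lookup.setdefault(reverse_complement(seq), []).append(rid)

    hits: dict[str, set[str]] = {}  # read id -> mags
    for mag_id in sorted(mags):
        recruited: set[str] = set()
        for seq in mags[mag_id].values():
            for i in range(len(seq) - read_len + 1):
                ids = lookup.get(seq[i : i + read_len])
                if ids:
                    recruited.update(ids)
        res.counts[(mag_id, sample_id)] = len(recruited)
        for rid in recruited:
            hits.setdefault(rid, set()).add(mag_id)
    for rid, mags_hit in hits.items():
        if len(mags_hit) > 1:
            res.ambiguous[rid] = sorted(mags_hit)
    return res


def relative_abundance(counts: RecruitmentCounts, scale: float = 1e6) -> pd.DataFrame:
    """Genome-size- and depth-normalized relative abundance per MAG/sample."""
    rows = []
    for (m, s), c in sorted(counts.counts.items()):
        size = counts.genome_sizes[m]
        total = counts.sample_totals[s]
        if size <= 0:
            raise ValueError(f"MAG {m} has non-positive genome size")
        if total <= 0:
            raise ValueError(f"sample {s} has non-positive read total")
        rows.append(
            {
                "mag_id": m,
                "sample_id": s,
                "reads": c,
                "abundance": c / size / total * scale,
            }
        )
    return pd.DataFrame(rows, columns=["mag_id", "sample_id", "reads", "abundance"])
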