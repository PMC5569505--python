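"""End-to-end pipeline on a synthetic community.

Simulate -> bin -> QC/decontaminate -> recruit/abundance -> pathway calls
-> marker phylogeny, writing every stage's output as plain text. All
randomness derives from one seed, so two runs with the same seed produce
byte-identical output trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import binning, phylogeny, profiling, quality, recruitment, synthetic
from .io import write_fasta, write_fastq, write_tsv
from .utils import substream


@dataclass
class PipelineResult:
    community: synthetic.Community
    binning: binning.BinningResult
    qc_reports: list[quality.QCReport]
    kept_bins: list[str]
    removals: list[quality.Removal]
    abundance: pd.DataFrame
    pathway_calls: pd.DataFrame
    tree: phylogeny.DistanceTree | None
    supermatrix: phylogeny.Supermatrix | None


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    config: synthetic.CommunityConfig | None = None,
    bootstrap_replicates: int = 100,
) -> PipelineResult:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or synthetic.CommunityConfig()

    comm = synthetic.simulate_community(cfg, seed=seed)
    write_fasta(dict(sorted(comm.scaffolds.items())), out / "scaffolds.fasta")
    write_fastq([r for r in comm.reads if r[0].endswith("/1")], out / "reads_R1.fastq")
    write_fastq([r for r in comm.reads if r[0].endswith("/2")], out / "reads_R2.fastq")
    truth_rows = [
        {
            "scaffold_id": sid,
            "genome_id": t.genome_id,
            "start": t.start,
            "end": t.end,
            "truth_bin": comm.truth.bin_of[sid],
            "is_contaminant": t.contaminant_in is not None,
        }
        for sid, t in sorted(comm.truth.scaffolds.items())
    ]
    write_tsv(pd.DataFrame(truth_rows), out / "truth_scaffolds.tsv")
    write_tsv(comm.annotations, out / "annotations.tsv")
    (out / "pathways.txt").write_text(profiling.format_pathways(profiling.starter_pathways()))

    # --- compositional binning -------------------------------------------
    bin_seed = int(substream(seed, "binning").integers(2**31))
    result = binning.bin_scaffolds(comm.scaffolds, seed=bin_seed)
    write_tsv(result.assignments, out / "bin_assignments.tsv")

    # --- QC and decontamination ------------------------------------------
    marker_list = list(phylogeny.RIBOSOMAL_15)
    bin_of = {s: f"bin_{b:03d}" for s, b in result.bin_of().items() if b != binning.UNBINNED}
    counts = quality.marker_counts_per_bin(comm.marker_table, bin_of)
    reports = [
        quality.estimate_completeness(counts.get(b, {}), marker_list, bin_id=b)
        for b in sorted(set(bin_of.values()))
    ]
    kept_reports, rejected = quality.gate_bins(reports)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "bin_id": r.bin_id,
                    "completeness": r.completeness,
                    "duplication": r.duplication,
                    "n_markers_present": r.n_markers_present,
                    "n_markers_duplicated": r.n_markers_duplicated,
                    "passed": r in kept_reports,
                }
                for r in reports
            ]
        ),
        out / "qc_reports.tsv",
    )

    ev_seed = int(substream(seed, "evidence").integers(2**31))
    ev_table = synthetic.simulate_scaffold_evidence(
        comm.truth, comm.scaffolds, comm.phyla, seed=ev_seed
    )
    evidence = quality.evidence_from_table(ev_table)
    removals: list[quality.Removal] = []
    filtered_bins: dict[str, list[str]] = {}
    members: dict[str, list[str]] = {}
    for s, b in bin_of.items():
        members.setdefault(b, []).append(s)
    for b in sorted(members):
        kept, rem, _ = quality.decontaminate(b, sorted(members[b]), evidence)
        filtered_bins[b] = kept
        removals.extend(rem)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "scaffold_id": r.scaffold_id,
                    "bin_id": r.bin_id,
                    "reasons": ",".join(r.reasons),
                }
                for r in removals
            ],
            columns=["scaffold_id", "bin_id", "reasons"],
        ),
        out / "removal_log.tsv",
    )

    # --- read recruitment and abundance ----------------------------------
    mags = {
        b: {s: comm.scaffolds[s] for s in sids}
        for b, sids in sorted(filtered_bins.items())
        if sids
    }
    rec = recruitment.recruit_reads(comm.reads, mags, sample_id="sample1",
                                    read_len=cfg.read_len)
    abundance = recruitment.relative_abundance(rec)
    write_tsv(rec.to_frame(), out / "recruitment_counts.tsv")
    write_tsv(abundance, out / "abundance.tsv")

    # --- functional profiling --------------------------------------------
    calls = profiling.call_pathways(comm.annotations, profiling.starter_pathways())
    write_tsv(calls, out / "pathway_calls.tsv")

    # --- marker phylogeny -------------------------------------------------
    div = {g: 0.05 + 0.05 * i for i, g in enumerate(sorted(comm.genomes))}
    prot_seed = int(substream(seed, "proteins").integers(2**31))
    blocks = synthetic.simulate_marker_proteins(
        sorted(comm.genomes), marker_list, div, seed=prot_seed
    )
    sm = phylogeny.concatenate(blocks, phylogeny.SET15, min_markers=8)
    tree = None
    if len(sm.taxa) >= 3:
        tree, support = phylogeny.bootstrap_support(
            sm, n_replicates=bootstrap_replicates, seed=int(substream(seed, "bootstrap").integers(2**31))
        )
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        write_fasta(sm.sequences, out / "supermatrix.fasta")
        (out / "partitions.txt").write_text("\n".join(sm.partition_lines()) + "\n")

    (out / "run_metadata.json").write_text(
        json.dumps({"seed": seed, "binning": result.params}, indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(
        community=comm,
        binning=result,
        qc_reports=reports,
        kept_bins=[r.bin_id for r in kept_reports],
        removals=removals,
        abundance=abundance,
        pathway_calls=calls,
        tree=tree,
        supermatrix=sm,
    )
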