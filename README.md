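# magsom

Genome-resolved metagenomics of deep-sea sediment communities, as a
tested, reusable pipeline: compositional binning of assembled scaffolds
into metagenome-assembled genomes (MAGs), marker-based quality control
and decontamination, exact-match read-recruitment abundance profiling,
consensus metabolic-pathway calling, domain-level gene-family statistics,
and concatenated ribosomal-protein phylogenetics. A ground-truthed
synthetic-community simulator makes every stage quantitatively testable.

## Who this is for

Microbial ecologists and bioinformaticians who reconstruct draft genomes
from sediment/hydrothermal metagenomes (ANME archaea, Bathyarchaeota,
*Chloroflexi*, *Deltaproteobacteria*, ...) and want the classic
ESOM-style binning workflow as an automated, reproducible library rather
than a chain of manual steps — plus anyone who needs a simulator that
emits scaffolds, reads, markers and multi-database annotations with
known truth.

## The methods at its core

- **Tetranucleotide binning.** Every scaffold ≥ 5 kb is profiled by its
  canonical tetranucleotide frequencies (256 4-mers folded with reverse
  complements into 136 classes, so the signature is strand-independent).
  Profiles are projected onto a toroidal self-organizing map; valleys of
  the map's U-matrix (connected node regions below the 60th percentile)
  become bins, and each scaffold takes the majority bin of its 10-kb
  windows.
- **Bin QC.** Completeness = % of an expected single-copy marker set
  (default: 15 syntenic ribosomal proteins) present; duplication = %
  present ≥ 2×. Bins pass with completeness > 50% (strict) and
  duplication ≤ 10% (inclusive). Decontamination removes scaffolds
  deviating from the frozen bin means: |ΔGC| > 0.25, discordant majority
  gene taxonomy, or |Δconfidence| > 25 points — one pass, means computed
  on the initial membership.
- **Abundance.** A 125-bp read is recruited to a MAG iff its complete
  sequence matches a member scaffold exactly (either strand). Relative
  abundance = count / genome_size / sample_total × 10⁶, so equal
  coverage ⇒ equal abundance.
- **Pathway calls.** A metabolic process is present in a MAG iff every
  key enzyme (e.g. *mcrA* for reverse methanogenesis, *dsrAB* for
  sulfate reduction) is confirmed by ≥ 2 annotation sources after the
  e-value ≤ 1e-20 gate, and strictly > 50% of pathway components are
  detected.
- **Gene-family statistics.** Per-family archaea-vs-bacteria comparison
  by two-sided Mann–Whitney U (exact by enumeration for small groups),
  Bonferroni corrected; means normalized per MAG.
- **Phylogeny.** Per-marker aligned blocks are concatenated into a
  supermatrix (taxa need ≥ 8 of 15 ribosomal proteins), p-distances use
  pairwise gap deletion, trees come from neighbor joining (exact on
  additive matrices) with column-resampling bootstrap. A 35-gene
  extended catalog runs through the same code path, and the supermatrix
  exports as FASTA + partition file for external ML tools.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from magsom import binning, synthetic as syn

comm = syn.simulate_community(seed=1, with_reads=False)   # 5 genomes, truth known
result = binning.bin_scaffolds(comm.scaffolds, seed=7)
for bin_id, mag in sorted(result.bins.items()):
    print(bin_id, len(mag.scaffold_ids), f"{mag.total_length/1e6:.2f} Mb", f"GC {mag.mean_gc:.2f}")
```

prints

```
0 200 3.50 Mb GC 0.30
1 200 3.46 Mb GC 0.40
2 200 3.43 Mb GC 0.50
3 200 3.41 Mb GC 0.60
4 200 3.34 Mb GC 0.70
```

five bins of 200 scaffolds each, one per source genome, ordered by GC —
and the adjusted Rand index against the generator's truth is 1.000, i.e.
composition alone separates these genomes perfectly. The
`examples/` directory has one short script per capability
(simulation, binning, QC, recruitment, functional profiling, phylogeny);
each prints its numbers with a line on what they mean. A thin CLI mirrors
the stages (`magsom simulate|bin|qc|abundance|functions|phylogeny|pipeline`).

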