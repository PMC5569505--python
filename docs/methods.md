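# Methods

This note records the models, parameter choices and numerical decisions
behind `magsom`, and what the synthetic benchmarks do and do not show
about real sediment metagenomes.

## Synthetic communities

The generator emulates the statistical structure the pipeline assumes,
with full ground truth.

**Genomes.** Each genome is an order-3 Markov chain over {A,C,G,T}. Rows
of the transition table are independent Dirichlet(1,1,1,1) draws, then
rescaled so that P(G)+P(C) equals the genome's GC target in every
context. Pinning GC per context makes realized GC binomially tight
(±0.2 points at 3 Mb) while the A/T and G/C balance still differs freely
between contexts and genomes — which is exactly what separates genomes
in tetranucleotide space. GC targets are validated against a (0.2, 0.8)
band; the defaults span 0.30–0.70 in five steps, comparable to the
spread between, say, ANME archaea and *Chloroflexi*. Generation of the
~17 Mb default community uses a numba-compiled inner loop.

**Scaffolds.** Lengths follow a log-normal (median 8 kb, σ = 1 on the
log scale) truncated to [200, 177,401] bp — the range printed assemblies
of this kind of sample actually span. The default community draws, per
genome, 200 lengths from the ≥ 5 kb part of the distribution plus 50
from the sub-5-kb part, and the genome length is their sum (~3.4 Mb).
Drawing lengths first makes "200 binnable scaffolds per genome" exact by
construction. Scaffolds tile the genome without gaps or overlap, so
fragment lengths always sum to the genome length.

**Contaminants.** With rate *r*, each bin receives `round(r × bin size)`
scaffolds moved in from a donor genome; the truth table keeps the
original genome. The default `gc_extreme` policy picks the donor with
the largest genome-level GC offset and only injects where that offset is
≥ 0.30, creating exactly the cases the GC-deviation removal rule must
catch; mid-GC bins receive none. Donor scaffolds carry the donor's
taxonomy and a depressed annotation confidence (mean 50 vs 85), so all
three removal rules have true positives.

**Reads.** Paired 2 × 125 bp, insert uniform in [360, 420] bp, mates on
opposite strands, positions uniform within scaffolds (not raw genomes,
so every error-free read is an exact substring of some scaffold). A
genome's expected share of pairs is proportional to depth weight ×
genome length. Substitution errors at a constant per-base rate (default
0.002); no indels, no chimeras, no quality-score realism — quality lines
are constant Q40. Default 20,000 pairs: enough for ±1–2% abundance
precision without dominating test runtime.

**Markers, annotations, gene families.** `place_markers` puts exactly
`round(completeness × M)` of the M markers on a genome's scaffolds,
`round(duplication × M)` of them twice, so QC estimates can be checked
for exact round-trip. Annotation records are emitted per database with a
controlled detection probability (default 0.9 over four sources —
an hmmer-, blast-, KAAS- and IMG-like source), false positives at 0.01,
and a small stream of sub-threshold records (e-values > 1e-20) to
exercise the filter. Gene-family counts are Poisson per MAG with
domain-specific means.

All randomness derives from one top-level seed through named substreams
(CRC32 of the stage name spawns a child `SeedSequence`), so a stage can
be regenerated alone and whole runs are byte-reproducible.

## Binning

Canonical 136-class tetranucleotide profiles are the default (assembly
strand is arbitrary); raw 256-mer profiles sit behind a flag. Windows of
10 kb (non-overlapping; a final partial window < 5 kb merges into its
neighbor) stabilize long-scaffold placement; most default scaffolds are
single-window.

The SOM is batch-trained: every epoch assigns all profiles to their
best-matching unit, then replaces each node weight by the
neighborhood-weighted mean of the data. Batch training was chosen over
online updates because it is invariant to input order (a contract the
tests assert) and deterministic for a fixed seed. Toroidal grid,
Gaussian neighborhood, radius annealed linearly from max(rows, cols)/2
to 2.0 over 20 epochs; weights initialize around the data mean. Two
choices matter and were made after measuring recovery on the default
community:

- **Grid size ~ n/3 nodes** (default ≈ 19×32 for ~1,800 profiles).
  Cluster boundaries only *emerge* on the U-matrix when the map is much
  larger than the cluster count; with a few dozen nodes the five genomes
  collapse onto adjacent nodes and the watershed merges them (measured
  ARI 0.2–0.6 versus ≥ 0.999 at emergent scale).
- **Final radius 2.0, not a point.** Annealing to σ ≈ 0.5 lets nodes
  specialize to within-genome noise, which raises spurious U-matrix
  ridges inside genome territories and strands ~10% of profiles on
  "boundary" nodes. A smoother final map keeps within-cluster U flat
  while inter-genome ridges stay 3–5× the median.

Bins are connected components (8-neighborhood, wrapping) of nodes at or
below the 60th U-matrix percentile; profiles mapping to boundary nodes
are unbinned, and a scaffold takes the majority bin of its windows (ties
to the lowest bin id; a real bin beats "unbinned" on a tie). If the
U-matrix maximum is under 2× its median the map has no ridge structure
(homogeneous input) and the whole map is one valley — without this guard
a single-genome community fragments on noise. Optional features: a
standardized per-scaffold coverage column as a 137th dimension, and
reference-genome profiles mixed into training (both off by default;
composition alone is the primary signal).

## Quality control

The completeness estimator is deliberately simple: presence/duplication
counting over a configurable single-copy marker list (default the 15
ribosomal proteins; any larger set plugs in). It does not attempt
lineage-specific marker selection, so absolute completeness values are
not comparable to lineage-aware tools — but against the generator the
round-trip is exact. Gates: completeness strictly > 50, duplication
≤ 10 (both in percent, both configurable).

Decontamination interprets "> 25% difference" in GC as absolute points
on the GC-fraction scale (0.25): a relative reading would remove
scaffolds at |ΔGC| ≈ 0.12 for a 0.5-GC bin, which would shred real
genomes. Confidence is the mean per-gene taxonomic-assignment score
(0–100), compared in points. Taxonomy is evaluated at one rank (default
phylum): scaffold label = majority over its genes, bin label = majority
over all member genes, with ties resolved toward keeping the scaffold.
The pass is one-shot with means frozen at the initial membership —
removal never re-indicts other scaffolds within the pass; iterating is
an explicit second call. Bins with < 3 scaffolds pass through unfiltered
with a warning (deviation from a mean of two is ill-posed), and
scaffolds without evidence are kept but flagged.

## Read recruitment and abundance

The matching contract is "exact full-length substring, either strand";
the implementation indexes read sequences (and reverse complements) in a
hash map and slides one window over each scaffold, which is
oracle-tested bit-identical to the naive scan. Mates count
independently; a read matching several scaffolds of one MAG counts
once; matches to several MAGs count once per MAG and are reported as
ambiguous. Reads of the wrong length or containing non-ACGT are tallied
and never match. Abundance = count / genome_size / sample_total × 10⁶.
The normalization order is one consistent reading of
"per genome size, per sampling depth, × 10⁶"; absolute values are only
comparable within this convention, rankings are invariant to it.

## Functional profiling

E-value records pass at ≤ 1e-20 inclusive; bit-score databases use
per-family custom minimums. "Multiple databases" means ≥ 2 distinct
sources (configurable). The component fraction counts any detected
component — confirmed or single-source — while key enzymes must be
confirmed; this asymmetry mirrors how key-enzyme evidence and general
pathway-component evidence are treated differently in practice. The
starter pathway catalog (reverse methanogenesis / *mcrA*, dissimilatory
sulfate reduction / *dsrAB*, beta-oxidation's four core steps,
denitrification / *napA*, fumarate-addition hydrocarbon activation /
*bssA*+*assA*) is an editable INI-style text format, not a database.

The Mann–Whitney test enumerates the exact permutation null (all
assignments of the pooled observations) whenever min(n₁,n₂) ≤ 8 and the
combination count stays under 2×10⁵; the two-sided p is the null
probability of a U at least as far from n₁n₂/2 as observed, which
handles ties exactly. Larger groups use the normal approximation with
tie and continuity correction (via scipy). Constant pooled data gives
p = 1 by convention. Bonferroni multiplies by the number of families and
caps at 1.

## Phylogeny

Per-gene alignment is delegated: callers supply aligned blocks (the
generator emits equal-length marker proteins; real data would come from
an external aligner). Missing genes are gap-filled over the whole block;
taxa enter the supermatrix with ≥ 8 catalog markers (applied to both the
15-gene and the extended catalog — the extended list as printed carries
35 named genes). Distances are p-distances with pairwise gap deletion
(complete deletion wastes too many columns with partial MAGs); pairs
sharing < 50 columns are flagged, zero shared columns is an error; an
optional Poisson correction −ln(1−p) sits behind a flag. NJ uses the
standard Q criterion with deterministic tie-breaks (smallest Q, then
lexicographic pair of node names); a negative branch length is clamped
to zero with the deficit moved to its sibling so the pair's path length
is conserved. Bootstrap resamples supermatrix columns with replacement
and reports, per internal edge of the point tree, the fraction of
replicates containing that split. Maximum-likelihood inference is out of
scope; the supermatrix + partition file export feeds external tools.

## What the benchmarks show — and don't

Synthetic genomes are stationary Markov chains: no repeats, no mobile
elements, no rRNA operons, no strain microheterogeneity, no
between-window composition shifts. Binning recovery on them (ARI ≈ 1.0)
demonstrates the machinery is correct, not that real Guaymas-like
communities separate this cleanly — real TNF clouds overlap and real
curation is iterative. Likewise the decontamination benchmark plants
contaminants at ≥ 30-point GC offset; contaminants with near-native GC
are only catchable by the taxonomy/confidence rules, and contaminants
resembling the recipient in all three signals are invisible by
construction. Read recruitment is exact-match by design, so its
benchmark is a correctness check, not a sensitivity study; with
substitution rate *e* the recruited fraction is (1−e)¹²⁵ and indel-rich
platforms would need a different matching rule. Problem sizes (5 × 3.4
Mb genomes, 20,000 read pairs, 1,000-replicate null simulations, 20-seed
tree-recovery runs) were chosen to make the full suite and the
acceptance script run comfortably on a laptop-class single core.
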