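# Methods

This package re-implements, as testable library code, the bespoke
computational stages of a wild-soybean reference-genome project: calling
insertions and large structural variants from whole-genome synteny blocks,
classifying transposable-element (TE) insertions and the genes they affect,
assembly quality metrics, optical-genome-map (OM) processing, merging of two
independent scaffold orderings, and recombinant-inbred-line (RIL) binmap
construction with QTL scanning. Because the original analyses require
hundreds of gigabases of sequencing data and external assemblers, every
stage here is exercised on synthetic data with planted ground truth; the
generators are first-class, tested code.

## Synthetic data

`synthdata.generate_reference` draws i.i.d. bases at a specified GC content
(soybean-like default 0.35), builds a TE library of 500 bp–10 Kb random
elements, overwrites the background with verbatim TE copies (the TE
annotation), and places non-overlapping gene intervals.

`derive_variant_genome` applies a plan of events in a fixed order —
reciprocal/intra-chromosomal translocations, then inversions, then
insertions, then background SNPs — on a segment list that tracks ancestor
provenance, so every planted breakpoint has an exact image in query
coordinates (the emitted liftover). Insertions are a TE-library fragment
plus random filler in a controlled ratio, which makes the >80% TE-occupancy
rule exactly steerable. Background SNPs are kept ≥200 bp from all piece
boundaries so anchors abut event junctions; conservation holds exactly
(query length = reference + Σ insertion lengths).

`simulate_ril_population` models a selfed RIL: crossovers per line per
chromosome are Poisson with mean 2 × (genetic length in Morgans) — the
classical two-fold map expansion of selfed RILs relative to one meiosis —
with uniform positions on a uniform 200 Kb/cM physical map. Two qualitative
features of plant meiosis are included: crossover interference (no two
crossovers of a line within 5 cM) and suppression of exchanges immediately
at the termini (2.5 cM exclusion). Both are defaults, not fitted values;
they matter because a 15-SNP window caller cannot, even in principle,
resolve two crossovers inside one window span. Genotypes are homozygous
A/B with a ≤1% residual-heterozygosity option, plus configurable genotype
error and missingness. Phenotypes are Σ additive QTL effects (A = +a,
B = −a) plus Gaussian noise scaled so the narrow-sense heritability equals
the requested h².

`simulate_optical_molecules` samples molecules as uniform subintervals of a
source map, perturbs true labels with Gaussian sizing error, drops them
independently (false negatives), adds a Poisson process of false labels,
and attaches a backbone-intensity scalar. It emulates label-level noise of
nanochannel data; it does not model chimeric molecules, stretch-factor
drift, or site-specific nicking efficiency — results on real molecules
depend on those too.

## Synteny blocks

The built-in aligner stands in for a unique-match, no-extension
whole-genome aligner. It finds k-mers (default k = 21) occurring exactly
once in the reference and once across both strands of the query, collapses
diagonal runs, and chains runs per (reference chromosome, query chromosome,
strand) by iterative maximum-weight co-linear chaining (a Fenwick-tree
weighted LIS, re-run on the leftovers), so displaced runs — translocated
segments — survive as their own blocks instead of being discarded as
outliers. Consecutive chain segments merge into one block while their
reference and query gaps agree within 20 bp (substitution clusters and
anchor deserts over shared repeats) and are below 20 Kb, so balanced-gap
events such as inversions are never merged through. Micro-homology at
event junctions lets exact matching extend both flanks over shared bases;
resulting ≤2k-bp overlaps between consecutive blocks are trimmed to the
left block, keeping gap signs meaningful. Block coordinates are 1-based
inclusive; PAF input/output converts at the boundary. Breakpoints are
accurate to anchor resolution (±k bp), which is the tolerance used
throughout the tests.

Known limitation: inside repeated sequence there are no unique anchors, so
events planted within a repeat copy cannot be localised — the oracle-
equivalence tests therefore use repeat-free pairs, and the benchmark scene
(`scenes.sv_benchmark_scene`) shifts planted breakpoints ≥2.5 Kb away from
annotated TE copies so the planted truth is well-posed at anchor
resolution. Repeat-containing genomes are still aligned end to end; only
the breakpoints sit in unique sequence.

## Event calling

The literal calling rules, all strict inequalities:

* insertion in the query — adjacent blocks (same chromosomes and strand,
  query order consistent with strand) with query gap > 1000 bp and
  0 ≤ reference gap < 100 bp; overlapping blocks are not gaps;
* TE insertion — union-covered TE fraction of the query interval > 0.8;
  the reference-side gap is the TE insertion site;
* TE-affected gene — gene body extended by 500 bp (closed intervals,
  boundary inclusive) intersects the insertion site of a TE insertion;
* large SV — per reference chromosome, the dominant query partner and
  dominant strand are those receiving the most aligned bases; maximal runs
  of blocks mapping to another chromosome (inter-chromosomal
  translocation), on the opposite strand (inversion), or displaced off the
  co-linear backbone (intra-chromosomal translocation) are reported when
  the reference span exceeds 100 Kb, with breakpoints at the inner edges
  of the flanking collinear blocks. Run-level grouping and the
  deterministic breakpoint rule replace manual curation.

## Assembly metrics

Nxx is the classic cumulative statistic (smallest member length whose
≥-length pieces cover x% of the total). Occupancy tracks use a 1 Mb window
with 500 Kb step (repeats/genes) and non-overlapping 200 Kb windows for GC
(non-N denominator; all-N windows are NaN); final partial windows are
normalised by actual span and flagged. Telomeres are tandem arrays of the
plant motif CCCTAAA (TTTAGGG on the other strand), ≥10 consecutive copies
with ≤1 mismatch per copy, within 10 Kb of an end — the window and copy
thresholds are package defaults, configurable. Centromeric arrays are found
by direct identity scan of a user-supplied monomer (both strands, ≥0.8
identity), merging hits within one monomer length. In silico PCR finds
primer sites with ≤2 mismatches and an exact 3′-terminal trinucleotide,
requires opposite strands with facing 3′ ends and product < 1000 bp, and
retains only pairs with exactly one product genome-wide.

## Optical maps

Digestion labels the forward-strand start of each nicking-motif occurrence
on either strand (constant within-motif nick offsets cancel in
comparisons). Labels closer than 1 Kb merge greedily left-to-right into
rounded cluster midpoints, iterated to a fixed point so merging is
idempotent. Molecule QC removes molecules with length < 150 Kb, intensity
> 0.6, or < 9 labels, recording every reason. Maps whose inter-label
spacing is ≥90% concentrated within ±10% of the modal spacing are flagged
repetitive (a tandem-array signature standing in for unpublished
"low-density" heuristics). The aligner is a dynamic program over label
pairs: matched pairs must have interval sums agreeing within the sizing
tolerance × intervals spanned, skipped labels are penalised, both
orientations are scored, and ties prefer fewer skips then forward
orientation. Region comparisons require ≥30 molecules whose aligned span
covers the region.

## Scaffold merging and gap closing

Both scaffold sources are reduced to orientation-canonical adjacencies of
contig ends ((A+,B+) ≡ (B−,A−)). Adjacencies present in both sources get
evidence "both"; source-exclusive adjacencies are kept ("hic"/"map")
unless the other source puts a different neighbour on the same contig end,
in which case neither join is made and the pair is reported as a conflict —
conservative and auditable. Emitted superscaffolds are simple paths; every
input adjacency is either emitted with its class or listed as a conflict.

Gap closing compares the suffix of the left flank with the prefix of the
right flank (head-to-tail) at every overlap length, reporting the longest
overlap ≥ min length at ≥ min identity (defaults 1 Kb, 0.98). The decision
to trim one copy needs strictly more one-copy than two-copy spanning
evidence and at least 5 one-copy observations (count abstraction over
mate-pair inserts / OM spans); ties keep the gap. Closure conserves
sequence: joined length = left + right − overlap.

## Binmap and QTL

SNP filters: quality > 30 (strict), any 10 bp window holding ≥3 loci drops
all of them, heterozygous calls become missing, loci informative in <20
lines are dropped. Per line and chromosome, 15-SNP windows (step 1) are
called A/B when ≥11 of the non-missing calls agree, H otherwise, missing
below 5 informative calls; the majority threshold scales proportionally
for a short terminal chromosome. A breakpoint is a transition between
opposite homozygous window states; its uncertainty interval spans the
transition (including interior H/missing windows) and its point estimate
is the midpoint.

Bins live on a fixed 50 Kb grid anchored at position 1. A boundary is
retained when any line's breakpoint interval overlaps it — and the
boundary nearest each breakpoint midpoint is always retained, so a
crossover whose uncertainty fits inside one cell still cuts the map. Each
line's bin genotype is its piecewise state switching at the retained
boundary nearest each midpoint; bins are therefore internally consistent
and every detected crossover contributes exactly one adjacent-bin
discordance. Distances use the observed discordance R corrected to a
meiotic fraction r = R/(2−2R) (the standard selfed-RIL treatment, so a
simulated 100 cM chromosome maps back to ≈100 cM) and the Kosambi function
25·ln((1+2r)/(1−2r)) by default (Haldane selectable).

The scan is single-QTL interval mapping on a 0.5 cM grid: the phenotype is
regressed on the expected ±1 genotype score given flanking bins (two-state
Markov conditioning through the mapping function's inverse), and
LOD = (n/2)·log10(RSS0/RSS1) = (n/2)·log10(1/(1−R²)). The genome-wide
threshold is the empirical (1−α) quantile of max LOD over phenotype
permutations (default 1000, α = 0.05, seeded). Composite interval mapping
is not implemented; the 10 cM window parameter is accepted for interface
compatibility. QTL regions are maximal super-threshold runs, merged when
closer than 10 cM (noise dips otherwise fragment one linked QTL), each
reported with its peak and 1.5-LOD support interval.

## Numerical and scale choices

Sequences are handled as uint8 code arrays; k-mers are 2-bit packed into
uint64 (k ≤ 31). All generators take integer seeds and are bit-reproducible
(string labels are hashed with crc32, not Python's salted hash). The
acceptance and test workloads use desk-scale problem sizes chosen to
exercise every rule: a 10 Mb three-chromosome genome pair for SV recovery,
100 Kb pairs for oracle equivalence, 96 lines × 1000 SNPs × 100 cM for
binmap recovery, and 200-replicate null calibration at 200 permutations
with power measured over 100 replicates at h² = 0.3. The acceptance script
runs the same pipelines at moderately reduced replicate counts.

## Limitations

Synthetic genomes have i.i.d. background composition, verbatim TE copies
and no nested/decayed repeats; aligner behaviour on real paralogy and
segmental duplication is not tested here. The OM model omits chimeras and
stretch drift. The QTL stage implements plain interval mapping only, and
map distances assume selfed-RIL expansion; other cross designs need a
different correction.
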