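# Methods

## The detection model

A micro-inversion (MI) replaces a reference segment with its reverse
complement. In a short read, the single-inversion model is the exact
decomposition

    read = ref[a, s) + revcomp(ref[s, e)) + ref[e, b)

with `e − s` in [10, 99] and both flanks at least 10 bp. The implementation
requires the flanks to match the reference exactly by default
(`max_flank_mismatches = 0`, configurable up to 2): exact flanks make every
call reproducible bit-for-bit and keep the recovery tests deterministic.
Among all valid decompositions the detector reports the one with the
smallest inversion start, then the shortest inverted segment; this
tie-break is arbitrary but fixed, so outputs are stable across runs and
platforms. Palindromic inverted segments (`revcomp(x) == x`) are never
reported: the inverted allele would be byte-identical to the reference
allele, making the variant undetectable in principle.

Candidate placements come from mapper-style anchoring: all reference
positions where the read's first or last k-mer occurs exactly. The anchor
length is k = 10, equal to the minimum flank. It must not exceed it: with
100 bp reads the two flanks of a 79 bp inversion are only 10–11 bp, so any
longer anchor (e.g. 12) systematically misses the longest admissible
alleles — an effect we confirmed empirically before settling on k = 10.
Within a window the decomposition search is bounded by the longest common
prefix/suffix of read and reference window, so background reads cost one
string comparison and inversion-bearing reads a few hundred. An exhaustive
enumeration over all `(placement, s, e)` triples is kept in the test suite
as the independent oracle; the anchored detector must agree with it
everywhere.

Per individual, identical intervals found in several reads are collapsed
into one call whose `support` is the read count; the same interval in
different individuals remains distinct calls (that distinction is what MIR
hit counts measure).

### Breakpoint ambiguity

A random inverted segment admits a strictly larger, equally exact
decomposition whenever its flanking bases are complementary
(`ref[s−1] == complement(ref[e])` lets the segment extend symmetrically by
one on both sides). This happens with probability ≈ 1/4 per locus on
i.i.d. sequence, so "the detector returns exactly the planted interval"
cannot hold for arbitrary planted inversions. The synthetic generator
therefore validates each planted locus by running the detector on the
allele's own read layout and resamples the locus until the planted interval
is the unique (tie-break-winning) decomposition. Recovery guarantees in the
tests apply to generator output; on arbitrary input the detector still
agrees with the exhaustive oracle, it just may report the extended
interval.

## Cross-species alignment scan

For species call sets the input is gap-free pairwise alignment blocks in
reference coordinates. The scanner reports maximal runs where the query
equals the reverse complement of the reference segment, flanked by ≥ 5
exactly matching bases, with run length 10–125 bp (the wider upper bound
used for cross-species comparisons; human MI calls are subsequently
filtered to 10–99 bp). A maximal run longer than 125 bp yields no call
rather than a truncated one. Candidate runs are enumerated around mismatch
runs, since a non-palindromic inverted segment necessarily contains a
mismatch; the probe bound extends 25 bp beyond the reporting cap so
over-long runs are seen and rejected. Species-specific detection-rate
parameters quoted for external alignment tools are accepted in
configuration for provenance only; the simplified scanner does not use
them.

## MIR construction

MIRs are built greedily left-to-right over calls sorted by (chromosome,
start, end, individual): a call joins the open MIR iff it overlaps the
current union by ≥ 1 bp and the new union is at most 4 bp longer than the
shortest member including the candidate; otherwise a new MIR opens. Under
this length constraint members pairwise overlap by construction, and
segment feasibility is inherited by sub-segments, which makes the greedy
partition provably minimal in MIR count with the longest-first tie-break;
the test suite checks it against exhaustive enumeration of all
order-respecting partitions on instances of up to 12 calls. Adjacent MIRs
may overlap each other when the constraint forces a split; MIR disjointness
is deliberately not asserted. Whether a globally optimal rather than greedy
partition is intended is genuinely open; greedy was chosen for determinism
and order stability and is documented as such.

## Genomic-context classification

Each MIR receives exactly one class with precedence
`CDS > UTR > other_exonic > intronic > intergenic_promoter > intergenic`.
An MIR is genic if it overlaps any gene body by ≥ 1 bp ("overlap" is not
given a stricter quantitative meaning). Candidate promoters are the 2000 bp
flank upstream of the gene body in gene orientation — left of plus-strand
genes, right of minus-strand genes — and apply only to non-genic MIRs,
mirroring the convention of reporting promoter MIRs as a fraction of
intergenic ones. Non-coding exonic feature types (miRNA, rRNA and similar)
drive the `other_exonic` class. MIRs on chromosomes absent from the
annotation are classified intergenic with a logged warning rather than
rejected.

## Population statistics

The average inverted-allele count per individual is
`C̄_p = (Σᵢ Cᵢ) / N_p` over the individuals of population (or
super-population) p. A flag excludes zero-count individuals from numerator
and denominator (the carriers-only variant); an empty denominator is
reported as undefined (None/NaN), never as 0. In summary tables, MIR and
multi-supported-MIR counts are recomputed from each row's own calls —
pooled MIRs are used only in the Total row — because per-population MIR
counts can legitimately sum to more than the pooled total when the same
locus appears in several populations. Ratios are printed to 2 decimals,
the unmapped-read fraction to 1 decimal.

## Population structure

The count matrix has MIRs as rows and populations (or super-populations) as
columns; a cell is the number of member inverted alleles of that MIR
carried by the group's individuals. Distances are Euclidean between raw
column vectors by default. Dividing each column by its sample size first is
available behind a flag (off by default): the two conventions answer
slightly different questions (total vs per-individual burden) and the raw
variant is the operational default. A gene-region-only variant restricts
rows to genic MIRs.

Neighbor joining is the standard Saitou–Nei agglomeration implemented
in-package so the tie-break can be fixed: among equal Q criteria the
lexicographically lowest label pair joins. Negative branch-length estimates
(possible on non-additive inputs) are clamped to zero with a log note. On
additive matrices the algorithm is exact; tests verify tree-to-distance
round trips to 1e-9 on random 4–8-taxon trees and cross-check topology
against an independent library implementation.

PCA treats populations as observations and MIRs as features (the matrix is
transposed), centers features, and applies no scaling — raw allele counts
share a scale, and scaling would inflate rare loci. Component signs are
fixed by making the largest-magnitude loading positive. Coordinates and
explained-variance fractions are validated against a direct
eigendecomposition of the feature covariance.

## Sharing and cross-species counts

A MIR belongs to a group iff at least one member allele comes from that
group; the 2^k − 1 non-empty membership regions partition the MIRs (no
frequency threshold). Singletons are MIRs with exactly one hit. A human
inverted allele is shared with a species iff some species call overlaps it
with both boundary differences ≤ 4 bp — the MIR tolerance reused for
consistency, since the matching rule is otherwise unspecified; an
exact-coordinate mode is available behind a flag. Shared counts are
per-locus (the group's calls are merged into MIRs first), so a locus
carried by many individuals counts once.

## Synthetic data: what it emulates and what it does not

The generator emulates the features the pipeline depends on: a reference
genome (homopolymer runs capped at 8 bp to limit boundary ambiguity), a
GENCODE-style annotation (multi-exon genes, CDS with flanking UTRs, ~20%
non-coding genes, mixed strands, 2000 bp promoter clearance), ancestral
alleles segregating in all populations versus derived alleles confined to
one super-population clade, haploid presence/absence genotypes drawn as
independent Bernoulli trials at the population frequency, and 100 bp reads
with exact flanks plus 50 background reads per individual. Planted alleles
are 10–99 bp (capped at read_length − 21 so both flanks stay > 10 bp),
non-palindromic, separated by at least one read length on a chromosome so
each read carries at most one inversion, and validated for unique
recoverability as described above. `plant_population_alleles` takes the
read length directly because both the separation invariant and the
recoverability check depend on it.

It does **not** model sequencing error, quality-score variation, paired
ends, diploid genotypes (zygosity is not modelled anywhere in the analysis,
so presence/absence suffices), coverage fluctuation, repetitive sequence,
or linkage between loci. Passing tests therefore demonstrate correctness of
the algorithms under the stated single-inversion, exact-flank model — not
detector performance on real, noisy unmapped reads, where flank mismatches
and mapping ambiguity would reduce recall.

## Problem sizes and numerical choices

The end-to-end recovery study uses 6 populations of 50 individuals in two
clades, 110 planted alleles on an 80 kb two-chromosome genome, 100 bp
reads, 50 background reads per individual, and 20 seeded replicates —
large enough that between-clade divergence (derived-allele frequency
≥ 0.3) dominates sampling noise, and small enough to run in tens of seconds
on one CPU. Success is defined as (a) some tree edge inducing exactly the
planted clade bipartition and (b) the PC1 ranges of the two clades being
disjoint. All randomness flows through numpy Generators seeded explicitly;
identical seeds give byte-identical FASTA/FASTQ/BED/TSV outputs.
Floating-point tolerances: NJ round trips at 1e-9 (additive inputs are
exact up to accumulation), PCA agreement at 1e-8, Q-criterion ties at
1e-12 before the lexicographic tie-break.

## Known limitations

* The detector's candidate windows rely on one exact 10-mer anchor; reads
  whose both anchor k-mers are mutated or absent from the reference are
  undetectable by `scan_reads` (the core `detect_inversion_in_read` accepts
  arbitrary windows).
* The alignment scanner is quadratic around mismatch runs and intended for
  desk-scale blocks, not whole-genome alignments.
* Greedy MIR construction is order-stable but not claimed unique among all
  valid partitions of equal size beyond its stated tie-break.
* Cross-species sharing assumes both call sets use identical chromosome
  names; a disjoint name set is rejected rather than lifted over.
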