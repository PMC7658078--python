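# microinv

Micro-inversion (MI) landscape analysis for population genetics.

A micro-inversion is a short chromosomal segment — here 10–99 bp — whose
sequence is replaced by its reverse complement relative to a reference
genome. MIs are too short for conventional structural-variant callers and
hide inside *unmapped* short reads: a 100 bp read spanning a 30 bp inversion
fails exact alignment even though both its flanks match the reference
perfectly. Because MIs are rare and have low homoplasy, they are attractive
phylogenetic markers for comparing human populations.

`microinv` implements the full analysis chain:

1. **Detection** — decompose a read as
   `read = ref[a,s) + revcomp(ref[s,e)) + ref[e,b)` with ≥ 10 bp exact
   flanks and an inverted segment of 10–99 bp (`detect_inversion_in_read`,
   `scan_reads`), plus a scanner for inverted runs (10–125 bp, ≥ 5 bp exact
   flanks) in gap-free pairwise genome alignments for cross-species call
   sets (`scan_pairwise_alignment`).
2. **MI regions (MIRs)** — merge overlapping MIs from different individuals
   into MIRs under the constraint that an MIR is at most 4 bp longer than
   any member MI; each MI belongs to exactly one MIR and an *MIR hit* is the
   number of MI alleles it contains (`merge_mis_to_mirs`).
3. **Genomic context** — classify each MIR as CDS, UTR, other-exonic,
   intronic, candidate promoter (the 2000 bp strand-aware upstream flank of
   a gene body) or intergenic against a GENCODE-style annotation
   (`classify_mir`, `annotate_all`).
4. **Population statistics** — the average inverted-allele count per
   individual, `C̄_p = (Σᵢ Cᵢ) / N_p`, per-population summary tables
   (samples, MIs, MIRs, multi-supported MIRs and their ratios), unmapped-read
   fractions, and Pearson correlation of per-chromosome counts against
   chromosome length (`population_summary`, `average_inverted_alleles`).
5. **Population structure** — an MIR × population count matrix whose cells
   are inverted-allele sums, Euclidean distances between population column
   vectors, Saitou–Nei neighbor joining with deterministic tie-breaks, and
   PCA with populations as observations and MIRs as features
   (`build_count_matrix`, `neighbor_joining`, `pca_populations`).
6. **Sharing** — MIR membership regions across super-populations (Venn
   counts), singleton/non-singleton hit classification, and counts of
   inverted alleles shared between humans and other species on the same
   reference coordinates (`venn_sharing`, `classify_hits`,
   `cross_species_share`).

A first-class synthetic-data module (`generate_reference`,
`generate_annotation`, `plant_population_alleles`, `emit_reads`) produces
all inputs at desk scale with known ground truth: ancestral alleles
segregating in every population, derived alleles confined to one
super-population clade, haploid presence/absence genotypes, and reads whose
planted inversions are guaranteed uniquely recoverable.

## Worked example

```python
import microinv as mi

ref   = mi.generate_reference(2, [30000, 20000], seed=7)
ann   = mi.generate_annotation(ref, n_genes=8, seed=3)
specs = [mi.PopulationSpec(f"P{i}", "CLADE_A" if i < 3 else "CLADE_B", 20)
         for i in range(6)]
truth = mi.plant_population_alleles(ref, specs, 60, mi.FrequencyModel(), seed=5)
reads = mi.emit_reads(ref, truth, seed=9)

calls = mi.filter_mi(mi.scan_reads(reads, ref, truth.population_map))
mirs  = mi.merge_mis_to_mirs(calls)
print(f"{len(reads)} reads -> {len(calls)} MI calls -> {len(mirs)} MIRs")

table = mi.population_summary(calls, mirs, truth.population_map)
print(table[table.level != "population"].to_string(index=False))

groups = mi.groups_from_population_map(truth.population_map, "population")
matrix = mi.build_count_matrix(calls, mirs, groups)
tree   = mi.neighbor_joining(mi.euclidean_distances(matrix))
print(mi.tree_to_newick(tree))
```

prints

```
7667 reads -> 1667 MI calls -> 60 MIRs
           level    name  n_samples  n_mir  n_mi  mul_sup  mi_per_sample  mul_sup_pct
super_population CLADE_A         60     43   945       43          15.75        100.0
super_population CLADE_B         60     33   722       33          12.03        100.0
           total   Total        120     60  1667       60          13.89        100.0
((((P1:8.88,P2:10.87):1.84,P0:10.62):41.38,P3:8.05):0.88,P4:6.61,P5:7.53);
```

Every one of the 60 planted loci is recovered (1667 calls across 120
individuals collapse to exactly the 60 planted MIRs), `mi_per_sample` is
C̄_p for each super-population, and the long internal branch (41.4) in the
Newick tree separates the two planted clades P0–P2 vs P3–P5. (Branch
lengths above are shortened for display; the code prints full precision.)

The same steps are available from the shell:

```sh
microinv simulate --chromosomes 2 --lengths 30000,20000 \
    --populations P0:CLADE_A:20,P1:CLADE_A:20,P2:CLADE_A:20,P3:CLADE_B:20,P4:CLADE_B:20,P5:CLADE_B:20 \
    --n-alleles 60 --seed 7 --outdir sim/
microinv detect --reads sim/reads.fastq --reference sim/reference.fasta \
    --population-map sim/population_map.tsv --out calls.tsv
microinv mir --calls calls.tsv --out mirs.tsv
microinv stats --calls calls.tsv --population-map sim/population_map.tsv --out table.tsv
microinv structure --calls calls.tsv --population-map sim/population_map.tsv \
    --out-tree tree.nwk --out-pca pca.tsv
```

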