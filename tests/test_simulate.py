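"""Synthetic-data generator: determinism, structure, and truth consistency."""

import math

import pytest

import microinv as mi
from microinv import io as mio
from helpers_oracles import revcomp


class TestGenerateReference:
    def test_determinism_and_length_contract(self):
        a = mi.generate_reference(2, [500, 300], seed=1)
        b = mi.generate_reference(2, [500, 300], seed=1)
        assert a.sequences == b.sequences
        assert a.lengths == {"chr1": 500, "chr2": 300}

    def test_different_seeds_differ(self):
        a = mi.generate_reference(1, [1000], seed=7)
        b = mi.generate_reference(1, [1000], seed=8)
        assert a.sequences["chr1"] != b.sequences["chr1"]
        same = mi.generate_reference(1, [1000], seed=7)
        assert a.sequences == same.sequences

    def test_alphabet_and_homopolymer_cap(self):
        ref = mi.generate_reference(1, [5000], seed=3, max_homopolymer=8)
        seq = ref.sequences["chr1"]
        assert set(seq) <= set("ACGT")
        for base in "ACGT":
            assert base * 9 not in seq

    def test_nonpositive_length_rejected_naming_chromosome(self):
        with pytest.raises(ValueError, match="chr2"):
            mi.generate_reference(2, [500, 0], seed=1)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="200"):
            mi.ReferenceGenome({"chr1": "ACGT" * 10})


@pytest.fixture(scope="module")
def ann(small_ref):
    return mi.generate_annotation(small_ref, n_genes=10, seed=11)


class TestGenerateAnnotation:
    def test_structural_identities(self, ann, small_ref):
        assert len(ann.genes) == 10
        for g in ann.genes:
            assert 0 <= g.start < g.end <= small_ref.lengths[g.chromosome]
            assert len(g.exons) >= 2
            exon_union = sorted(g.exons)
            for s, e in g.cds + g.utrs:
                assert any(es <= s and e <= ee for es, ee in exon_union)
            # introns = gene body minus exons, and at least one exists
            introns = g.introns
            assert introns
            covered = sum(e - s for s, e in exon_union) + sum(e - s for s, e in introns)
            assert covered == g.end - g.start
            ps, pe = g.promoter()
            assert pe <= g.start or ps >= g.end  # promoter outside own gene body

    def test_strands_mixed_and_some_noncoding(self, ann):
        strands = {g.strand for g in ann.genes}
        assert strands == {"+", "-"}
        assert any(not g.cds for g in ann.genes)
        assert any(g.cds for g in ann.genes)

    def test_determinism(self, small_ref):
        a = mi.generate_annotation(small_ref, n_genes=6, seed=2)
        b = mi.generate_annotation(small_ref, n_genes=6, seed=2)
        assert a.genes == b.genes

    def test_too_short_chromosome_rejected(self):
        tiny = mi.ReferenceGenome({"chr1": "ACGT" * 100})  # 400 bp
        with pytest.raises(ValueError):
            mi.generate_annotation(tiny, n_genes=5, seed=0)


class TestPlantPopulationAlleles:
    def test_degenerate_frequency_one_population(self, small_ref):
        specs = [mi.PopulationSpec("A", "S1", 10), mi.PopulationSpec("B", "S2", 10)]
        truth = mi.plant_population_alleles(
            small_ref, specs, 5, {"A": 1.0, "B": 0.0}, seed=3
        )
        all_ids = {a.allele_id for a in truth.alleles}
        for ind, (pop, _) in truth.population_map.items():
            if pop == "A":
                assert truth.genotypes[ind] == all_ids
            else:
                assert truth.genotypes[ind] == frozenset()

    def test_zero_frequency_everywhere(self, small_ref):
        specs = [mi.PopulationSpec("A", "S1", 8)]
        truth = mi.plant_population_alleles(small_ref, specs, 4, {"A": 0.0}, seed=3)
        assert all(g == frozenset() for g in truth.genotypes.values())

    def test_binomial_carrier_counts(self, small_ref):
        # frequency recovery at n=1000, tolerance 3*sqrt(p(1-p)/n)
        n, p = 1000, 0.5
        specs = [mi.PopulationSpec("A", "S1", n)]
        truth = mi.plant_population_alleles(small_ref, specs, 3, {"A": p}, seed=17)
        for a in truth.alleles:
            carriers = sum(a.allele_id in g for g in truth.genotypes.values())
            assert abs(carriers / n - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_placement_invariants(self, small_ref, small_sim):
        truth, _ = small_sim
        read_length = 100
        by_chrom = {}
        for a in truth.alleles:
            assert 10 <= a.length <= 99
            seg = small_ref.fetch(a.interval.chromosome, a.interval.start, a.interval.end)
            assert revcomp(seg) != seg  # never palindromic
            by_chrom.setdefault(a.interval.chromosome, []).append(a.interval)
        for ivs in by_chrom.values():
            ivs.sort()
            for prev, nxt in zip(ivs, ivs[1:]):
                assert nxt.start - prev.end >= read_length

    def test_ancestral_everywhere_derived_in_clade(self, small_sim):
        truth, _ = small_sim
        sup_of = {p: s for (p, s) in truth.population_map.values()}
        for a in truth.alleles:
            freqs = truth.frequencies[a.allele_id]
            if a.allele_class == "ancestral":
                assert all(v > 0 for v in freqs.values())
            else:
                sups = {sup_of[p] for p, v in freqs.items() if v > 0}
                assert len(sups) == 1

    def test_capacity_exceeded_rejected(self):
        tiny = mi.generate_reference(1, [400], seed=0)
        with pytest.raises(ValueError, match="capacity"):
            mi.plant_population_alleles(
                tiny, [mi.PopulationSpec("A", "S", 2)], 50, {"A": 0.5}, seed=0
            )


class TestEmitReads:
    def test_inversion_read_construction_identity(self, small_ref, small_sim):
        truth, reads = small_sim
        by_id = {a.allele_id: a for a in truth.alleles}
        inv_reads = [r for r in reads if r.allele_id is not None]
        assert inv_reads
        for r in inv_reads[:50]:
            iv = by_id[r.allele_id].interval
            chrom_seq = small_ref.sequences[iv.chromosome]
            # read = ref[a,s) + revcomp(ref[s,e)) + ref[e,b) for some window
            a = chrom_seq.find(r.sequence[:10])
            found = False
            while a != -1:
                b = a + len(r.sequence)
                expect = (
                    chrom_seq[a : iv.start]
                    + revcomp(chrom_seq[iv.start : iv.end])
                    + chrom_seq[iv.end : b]
                )
                if expect == r.sequence:
                    found = True
                    break
                a = chrom_seq.find(r.sequence[:10], a + 1)
            assert found
            assert r.sequence not in chrom_seq  # truth consistency

    def test_background_reads_are_exact_substrings(self, small_ref, small_sim):
        _, reads = small_sim
        bg = [r for r in reads if r.allele_id is None]
        assert bg
        for r in bg[:100]:
            assert any(r.sequence in seq for seq in small_ref.sequences.values())

    def test_zero_allele_individual_gets_only_background(self, small_ref):
        specs = [mi.PopulationSpec("A", "S1", 3)]
        truth = mi.plant_population_alleles(small_ref, specs, 4, {"A": 0.0}, seed=2)
        reads = mi.emit_reads(small_ref, truth, seed=4, n_background=7)
        assert len(reads) == 3 * 7
        assert all(r.allele_id is None for r in reads)

    def test_read_names_encode_individual(self, small_sim):
        _, reads = small_sim
        for r in reads[:50]:
            assert r.name.split(":")[0] == r.individual

    def test_read_length_too_small_rejected_naming_allele(self, small_ref):
        specs = [mi.PopulationSpec("A", "S1", 2)]
        truth = mi.plant_population_alleles(small_ref, specs, 6, {"A": 1.0}, seed=5)
        longest = max(truth.alleles, key=lambda a: a.length)
        with pytest.raises(ValueError, match=longest.allele_id):
            mi.emit_reads(small_ref, truth, read_length=longest.length + 15, seed=0)


def test_file_outputs_byte_identical_across_runs(tmp_path, small_ref):
    specs = [mi.PopulationSpec("A", "S1", 4), mi.PopulationSpec("B", "S2", 4)]

    def produce(sub):
        d = tmp_path / sub
        d.mkdir()
        truth = mi.plant_population_alleles(small_ref, specs, 8, seed=13)
        reads = mi.emit_reads(small_ref, truth, seed=14, n_background=5)
        mio.write_reference_fasta(small_ref, d / "ref.fasta")
        mio.write_reads_fastq(reads, d / "reads.fastq")
        mio.write_truth_bed(truth, d / "truth.bed")
        mio.write_genotypes_tsv(truth, d / "genotypes.tsv")
        mio.write_population_map_tsv(truth.population_map, d / "pops.tsv")
        return {p.name: p.read_bytes() for p in sorted(d.iterdir())}

    assert produce("run1") == produce("run2")
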