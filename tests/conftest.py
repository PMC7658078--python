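import pytest

import microinv as mi


@pytest.fixture(scope="session")
def small_ref():
    return mi.generate_reference(2, [30000, 20000], seed=7)


@pytest.fixture(scope="session")
def small_sim(small_ref):
    """A two-clade simulation reused across read-level tests."""
    specs = [
        mi.PopulationSpec(f"P{i}", "SPA" if i < 3 else "SPB", 20) for i in range(6)
    ]
    truth = mi.plant_population_alleles(
        small_ref, specs, 60, mi.FrequencyModel(), seed=5
    )
    reads = mi.emit_reads(small_ref, truth, seed=9, n_background=20)
    return truth, reads


@pytest.fixture(scope="session")
def small_calls(small_ref, small_sim):
    truth, reads = small_sim
    return mi.scan_reads(reads, small_ref, truth.population_map)


@pytest.fixture(scope="session")
def fixture_gene_annotation():
    """One plus-strand gene [1000, 2000) with exon [1000, 1200), CDS
    [1050, 1150), UTRs flanking the CDS, and a second exon near the end."""
    gene = mi.Gene(
        gene_id="geneA",
        chromosome="chr1",
        start=1000,
        end=2000,
        strand="+",
        exons=((1000, 1200), (1900, 2000)),
        cds=((1050, 1150),),
        utrs=((1000, 1050), (1150, 1200), (1900, 2000)),
    )
    return mi.AnnotationIndex([gene])


def make_call(chrom, start, end, individual, population="POP", ref=None):
    """Construct a MICall with a synthesized non-palindromic allele sequence."""
    n = end - start
    seq = ("ACGTA" * ((n // 5) + 2))[:n]
    if ref is not None:
        seq = ref.fetch(chrom, start, end)
    from helpers_oracles import revcomp

    if revcomp(seq) == seq:
        seq = "A" + seq[1:]
    return mi.MICall(
        interval=mi.GenomicInterval(chrom, start, end),
        individual=individual,
        population=population,
        reference_allele_sequence=seq,
        inverted_allele_sequence=revcomp(seq),
    )
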