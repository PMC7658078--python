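"""Inversion detection: worked examples, oracle equivalence, round trips."""

import numpy as np
import pytest

import microinv as mi
from microinv.detect import AlignmentBlock
from helpers_oracles import brute_force_detect, revcomp


SPEC_REF = {"chrM": "ATGCATGCAT" + "AACCGGTTAACC" + "GTACGTACGT"}  # 32 bp
SPEC_WINDOW = [mi.GenomicInterval("chrM", 0, 32)]


class TestDetectInversionInRead:
    def test_worked_example(self):
        read = "ATGCATGCAT" + "GGTTAACCGGTT" + "GTACGTACGT"
        # independent confirmation that [10, 22) is the unique decomposition
        oracle = brute_force_detect(read, SPEC_REF, SPEC_WINDOW)
        assert oracle == ("chrM", 10, 22)
        res = mi.detect_inversion_in_read(read, SPEC_REF, SPEC_WINDOW)
        assert (res.inversion.start, res.inversion.end) == (10, 22)
        assert res.flank_mismatches == 0

    def test_exact_reference_substring_is_none(self):
        res = mi.detect_inversion_in_read(SPEC_REF["chrM"], SPEC_REF, SPEC_WINDOW)
        assert res is None

    def test_inverted_segment_below_minimum_is_none(self):
        # plant an 8 bp inversion: below the 10 bp MI minimum
        ref = mi.generate_reference(1, [300], seed=21)
        seq = ref.sequences["chr1"]
        s, e = 140, 148
        seg = seq[s:e]
        assert revcomp(seg) != seg
        read = seq[s - 15 : s] + revcomp(seg) + seq[e : e + 15]
        win = [mi.GenomicInterval("chr1", s - 15, e + 15)]
        assert mi.detect_inversion_in_read(read, ref, win) is None

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            mi.detect_inversion_in_read("ACGTN" * 10, SPEC_REF, SPEC_WINDOW)

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mi.detect_inversion_in_read("ACGT" * 10, SPEC_REF, [])

    def test_reconstruction_identity(self, small_ref, small_sim):
        # substituting the reverse complement at the reported interval
        # reproduces the read exactly (flank mismatch cap 0)
        truth, reads = small_sim
        checked = 0
        for r in reads:
            if r.allele_id is None:
                continue
            wins = mi.candidate_windows_for_read(r.sequence, small_ref)
            res = mi.detect_inversion_in_read(r.sequence, small_ref, wins)
            assert res is not None
            iv, w = res.inversion, res.read_window
            chrom = small_ref.sequences[iv.chromosome]
            rebuilt = (
                chrom[w.start : iv.start]
                + revcomp(chrom[iv.start : iv.end])
                + chrom[iv.end : w.end]
            )
            assert rebuilt == r.sequence
            checked += 1
            if checked >= 40:
                break
        assert checked == 40


def _random_case(rng):
    """One random detection case: (read, ref dict, window, planted or None)."""
    n = 300
    seq = "".join(rng.choice(list("ACGT"), size=n))
    ref = {"chr1": seq}
    win = [mi.GenomicInterval("chr1", 0, n)]
    kind = rng.integers(0, 3)
    a = int(rng.integers(0, n - 100))
    window = seq[a : a + 100]
    if kind == 0:  # planted inversion with >= 10 bp exact flanks
        alen = int(rng.integers(10, 80))
        s = a + int(rng.integers(10, 100 - alen - 10 + 1))
        seg = seq[s : s + alen]
        if revcomp(seg) == seg:
            return None
        read = seq[a:s] + revcomp(seg) + seq[s + alen : a + 100]
        return read, ref, win, (s, s + alen)
    if kind == 1:  # background: exact substring
        return window, ref, win, None
    # mutated substring: a few random SNPs, usually no valid decomposition
    read = list(window)
    for _ in range(int(rng.integers(1, 4))):
        i = int(rng.integers(0, 100))
        read[i] = rng.choice([b for b in "ACGT" if b != read[i]])
    return "".join(read), ref, win, None


def test_detector_equals_brute_force_oracle_on_random_reads():
    """Exhaustive (a, s, e) enumeration and the detector agree everywhere."""
    rng = np.random.default_rng(2024)
    n_cases = 0
    n_planted_recovered = 0
    while n_cases < 150:
        case = _random_case(rng)
        if case is None:
            continue
        read, ref, win, planted = case
        n_cases += 1
        oracle = brute_force_detect(read, ref, win)
        res = mi.detect_inversion_in_read(read, ref, win)
        if oracle is None:
            assert res is None
        else:
            assert res is not None
            assert (res.inversion.chromosome, res.inversion.start, res.inversion.end) == oracle
        if planted is not None and oracle == ("chr1", *planted):
            n_planted_recovered += 1
    assert n_planted_recovered > 20


def test_round_trip_recovers_every_planted_allele(small_ref):
    """Full round trip: generator -> reads -> detector == truth intervals."""
    specs = [mi.PopulationSpec("A", "S1", 1)]
    truth = mi.plant_population_alleles(small_ref, specs, 80, {"A": 1.0}, seed=31)
    reads = mi.emit_reads(small_ref, truth, seed=32, n_background=20)
    calls = mi.scan_reads(reads, small_ref, truth.population_map)
    assert {c.interval for c in calls} == {a.interval for a in truth.alleles}
    assert all(c.support == 1 for c in calls)


@pytest.fixture(scope="module")
def locus(small_ref):
    seq = small_ref.sequences["chr1"]
    s, e = 1000, 1024
    seg = seq[s:e]
    assert revcomp(seg) != seg
    read = seq[s - 38 : s] + revcomp(seg) + seq[e : e + 38]
    return (s, e), read


class TestScanReads:
    def test_same_individual_merged_with_support(self, small_ref, locus):
        (s, e), read = locus
        reads = [("I1:x:1", read), ("I1:x:2", read)]
        calls = mi.scan_reads(reads, small_ref, {"I1": ("A", "SA")})
        assert len(calls) == 1
        assert calls[0].support == 2
        assert (calls[0].interval.start, calls[0].interval.end) == (s, e)

    def test_two_individuals_two_calls(self, small_ref, locus):
        _, read = locus
        reads = [("I1:x:1", read), ("I2:x:1", read)]
        calls = mi.scan_reads(reads, small_ref, {"I1": ("A", "SA"), "I2": ("B", "SB")})
        assert len(calls) == 2
        assert {c.individual for c in calls} == {"I1", "I2"}
        assert calls[0].interval == calls[1].interval

    def test_no_inversion_reads_empty(self, small_ref):
        reads = [("I1:bg:1", small_ref.sequences["chr1"][500:600])]
        assert mi.scan_reads(reads, small_ref, {"I1": ("A", "SA")}) == []

    def test_unknown_individual_skipped_with_warning(self, small_ref, locus, caplog):
        _, read = locus
        with caplog.at_level("WARNING"):
            calls = mi.scan_reads([("ZZ:x:1", read)], small_ref, {"I1": ("A", "SA")})
        assert calls == []
        assert "unknown individual" in caplog.text

    def test_dedup_invariant(self, small_calls):
        keys = [(c.individual, c.interval) for c in small_calls]
        assert len(keys) == len(set(keys))


@pytest.fixture(scope="module")
def base():
    rng = np.random.default_rng(5)
    return "".join(rng.choice(list("ACGT"), size=80))


class TestScanPairwiseAlignment:
    def test_inverted_segment_with_exact_flanks(self, base):
        i, j = 30, 42
        seg = base[i:j]
        assert revcomp(seg) != seg
        query = base[:i] + revcomp(seg) + base[j:]
        calls = mi.scan_pairwise_alignment(
            [AlignmentBlock("chr1", 200, base, query)], "panTroX"
        )
        assert [(c.interval.start, c.interval.end) for c in calls] == [(230, 242)]
        assert calls[0].individual == "panTroX"

    def test_identical_sequences_empty(self, base):
        assert mi.scan_pairwise_alignment([AlignmentBlock("chr1", 0, base, base)], "sp") == []

    def test_run_longer_than_max_len_not_called(self):
        rng = np.random.default_rng(8)
        ref = "".join(rng.choice(list("ACGT"), size=250))
        i, j = 50, 180  # 130 bp inverted run > 125 cap
        query = ref[:i] + revcomp(ref[i:j]) + ref[j:]
        calls = mi.scan_pairwise_alignment([AlignmentBlock("chr1", 0, ref, query)], "sp")
        assert calls == []

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mi.scan_pairwise_alignment([AlignmentBlock("chr1", 0, "ACGTAC", "ACGT")], "sp")

    def test_short_flank_not_called(self, base):
        # inverted run starting at position 2: < 5 matching bases on the left
        i, j = 2, 14
        seg = base[i:j]
        if revcomp(seg) == seg:
            pytest.skip("palindromic fixture")
        query = base[:i] + revcomp(seg) + base[j:]
        calls = mi.scan_pairwise_alignment([AlignmentBlock("chr1", 0, base, query)], "sp")
        assert (2, 14) not in [(c.interval.start, c.interval.end) for c in calls]


class TestFilterMI:
    def test_length_bounds(self, small_ref):
        from conftest import make_call

        lengths = [8, 13, 45, 120]
        calls = [
            make_call("chr1", 100 * k, 100 * k + n, f"I{k}") for k, n in enumerate(lengths)
        ]
        kept = mi.filter_mi(calls)
        assert [c.length for c in kept] == [13, 45]

    def test_empty_and_passthrough(self, small_calls):
        assert mi.filter_mi([]) == []
        assert mi.filter_mi(small_calls) == list(small_calls)  # all in bounds

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            mi.filter_mi([], min_len=50, max_len=10)
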