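import numpy as np
import pytest

from mtauth.readio import (
    AlignedRead,
    Pileup,
    SamFormatError,
    build_pileup,
    deduplicate,
    read_alignments,
)
from mtauth.refhap import CircularReference
from mtauth.simulate import SimParams, simulate_reads, write_sam


def _read(rid, start, bases, strand="+", quals=None, cigar=None, mapq=60):
    quals = quals if quals is not None else (30,) * len(bases)
    cigar = cigar or (("M", len(bases)),)
    return AlignedRead(rid, start, strand, bases, quals, cigar, mapq=mapq)


class TestReadAlignments:
    def test_header_only_sam(self, tmp_path, toy_ref):
        path = tmp_path / "h.sam"
        write_sam([], toy_ref, path)
        assert read_alignments(path) == []

    def test_mapq_filter(self, tmp_path, toy_ref):
        reads = [
            _read("a", 1, toy_ref.fetch(1, 30)),
            _read("b", 5, toy_ref.fetch(5, 30), mapq=10),
            _read("c", 9, toy_ref.fetch(9, 30)),
        ]
        path = tmp_path / "m.sam"
        write_sam(reads, toy_ref, path)
        kept = read_alignments(path, min_mapq=30)
        assert sorted(r.id for r in kept) == ["a", "c"]

    def test_low_quality_bases_masked(self, tmp_path, toy_ref):
        quals = (30, 5, 30, 30, 5)
        reads = [_read("q", 3, toy_ref.fetch(3, 5), quals=quals)]
        path = tmp_path / "q.sam"
        write_sam(reads, toy_ref, path)
        got = read_alignments(path, min_baseq=20)[0]
        assert got.bases[1] == "N" and got.bases[4] == "N"
        assert got.bases[0] == toy_ref.base_at(3)

    def test_missing_sq_header(self, tmp_path):
        path = tmp_path / "nosq.sam"
        path.write_text("@HD\tVN:1.6\n")
        with pytest.raises(SamFormatError, match="@SQ"):
            read_alignments(path)

    def test_malformed_sam(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("@SQ\tSN:x\tLN:100\nnot a sam line\n")
        with pytest.raises((SamFormatError, ValueError)):
            read_alignments(path)

    def test_unmapped_and_secondary_excluded(self, tmp_path):
        path = tmp_path / "flags.sam"
        path.write_text(
            "@SQ\tSN:x\tLN:100\n"
            "u\t4\tx\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
            "s\t256\tx\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
            "p\t2048\tx\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
            "k\t0\tx\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        )
        kept = read_alignments(path, min_mapq=0, min_baseq=0)
        assert [r.id for r in kept] == ["k"]

    def test_simulator_round_trip_coordinates(self, tmp_path, ref, sample_hap,
                                              empty_hap):
        params = SimParams(n_fragments=200, contamination=0.1, seed=13)
        reads, _ = simulate_reads(ref, sample_hap, empty_hap, params)
        path = tmp_path / "rt.sam"
        write_sam(reads, ref, path)
        back = {r.id: r for r in read_alignments(path, min_mapq=0, min_baseq=0)}
        for orig in reads:
            assert (back[orig.id].start, back[orig.id].end) == (orig.start, orig.end)


class TestDeduplicate:
    def test_all_distinct_unchanged(self):
        reads = [_read(f"r{i}", 10 * i + 1, "ACGTA") for i in range(5)]
        kept, frac = deduplicate(reads)
        assert kept == reads and frac == 0.0

    def test_ten_copies_keep_one(self):
        reads = [_read(f"r{i}", 7, "ACGTA") for i in range(10)]
        kept, frac = deduplicate(reads)
        assert len(kept) == 1
        assert frac == pytest.approx(0.9)

    def test_representative_by_quality_then_id(self):
        lowq = _read("a", 1, "ACGTA", quals=(10,) * 5)
        highq = _read("z", 1, "ACGTA", quals=(40,) * 5)
        kept, _ = deduplicate([lowq, highq])
        assert kept[0].id == "z"
        tie1 = _read("m", 1, "ACGTA")
        tie2 = _read("b", 1, "ACGTA")
        kept, _ = deduplicate([tie1, tie2])
        assert kept[0].id == "b"

    def test_strand_distinguishes(self):
        fwd = _read("f", 1, "ACGTA", strand="+")
        rev = _read("r", 1, "ACGTA", strand="-")
        kept, frac = deduplicate([fwd, rev])
        assert len(kept) == 2 and frac == 0.0

    def test_empty_input(self):
        assert deduplicate([]) == ([], 0.0)

    def test_idempotent(self, ref, sample_hap, empty_hap):
        params = SimParams(n_fragments=2000, duplication_rate=2.0, seed=19)
        reads, _ = simulate_reads(ref, sample_hap, empty_hap, params)
        once, frac1 = deduplicate(reads)
        twice, frac2 = deduplicate(once)
        assert [r.id for r in twice] == [r.id for r in once]
        assert frac2 == 0.0 and frac1 > 0.5

    def test_poisson_duplication_expectation(self, ref, empty_hap):
        """fraction ~= lam/(1+lam) within 3 SE (plus a small allowance for
        coordinate collisions between distinct fragments)."""
        n, lam = 10000, 4.0
        params = SimParams(n_fragments=n, duplication_rate=lam, seed=29)
        reads, _ = simulate_reads(ref, empty_hap, empty_hap, params)
        _, frac = deduplicate(reads)
        expected = lam / (1 + lam)
        se = np.sqrt(lam / (n * (1 + lam) ** 4))
        assert abs(frac - expected) < 3 * se + 0.002


class TestPileup:
    def test_single_read_counts(self, toy_ref):
        pileup = build_pileup([_read("r", 5, "ACG")], toy_ref)
        assert pileup.base_count(5, "A") == 1
        assert pileup.base_count(6, "C") == 1
        assert pileup.base_count(7, "G") == 1
        assert pileup.depth(4) == 0

    def test_empty_reads_zero(self, toy_ref):
        pileup = build_pileup([], toy_ref)
        assert pileup.counts.sum() == 0 and not pileup.insertions

    def test_insertion_and_deletion_counting(self, toy_ref):
        read = _read("r", 10, "ACGTT", cigar=(("M", 2), ("I", 2), ("M", 1), ("D", 3)))
        pileup = build_pileup([read], toy_ref)
        assert pileup.insertion_counts(11, 1)[2] == 1  # G inserted after 11
        assert pileup.insertion_counts(11, 2)[3] == 1  # then T
        assert pileup.base_count(12, "T") == 1
        assert all(pileup.deletion_count(p) == 1 for p in (13, 14, 15))
        assert pileup.depth(13) == 1

    def test_wrapping_read_counts_modulo(self, toy_ref):
        L = toy_ref.length
        read = _read("w", L - 1, toy_ref.fetch(L - 1, 6))
        pileup = build_pileup([read], toy_ref)
        for pos in (L - 1, L, 1, 2, 3, 4):
            assert pileup.depth(pos) == 1

    def test_depth_equals_interval_stabbing_oracle(self, ref, sample_hap, empty_hap):
        params = SimParams(n_fragments=1000, seed=37)
        reads, _ = simulate_reads(ref, sample_hap, empty_hap, params)
        pileup = build_pileup(reads, ref)
        L = ref.length
        oracle = np.zeros(L + 1, dtype=int)
        for read in reads:
            for p in range(read.start, read.start + read.ref_span):
                oracle[(p - 1) % L + 1] += 1
        got = pileup.counts.sum(axis=1)
        assert np.array_equal(got, oracle)

    def test_conservation_of_bases(self, ref, sample_hap, empty_hap):
        params = SimParams(n_fragments=500, seq_error=0.01, seed=41)
        reads, _ = simulate_reads(ref, sample_hap, empty_hap, params)
        pileup = build_pileup(reads, ref)
        total_aligned = sum(r.query_length for r in reads)
        assert pileup.total_bases() == total_aligned

    def test_order_independence(self, ref, sample_hap, empty_hap):
        params = SimParams(n_fragments=300, seed=43)
        reads, _ = simulate_reads(ref, sample_hap, empty_hap, params)
        p1 = build_pileup(reads, ref)
        p2 = build_pileup(list(reversed(reads)), ref)
        assert np.array_equal(p1.counts, p2.counts)
        assert set(p1.insertions) == set(p2.insertions)
        for k in p1.insertions:
            assert np.array_equal(p1.insertions[k], p2.insertions[k])

    def test_tsv_round_trip(self, tmp_path, toy_ref):
        reads = [_read("r", 10, "ACGTT", cigar=(("M", 2), ("I", 2), ("M", 1), ("D", 3)))]
        pileup = build_pileup(reads, toy_ref)
        path = tmp_path / "p.tsv"
        pileup.to_tsv(path)
        back = Pileup.from_tsv(path, toy_ref)
        assert np.array_equal(back.counts, pileup.counts)
        assert set(back.insertions) == set(pileup.insertions)
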