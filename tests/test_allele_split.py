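import numpy as np
import pytest

from hybrid_ase import (
    AlignmentRecord,
    Category,
    SnpIndex,
    SnpRecord,
    assign_fragment,
    assign_read,
    dedupe_alignments,
    pair_fragments,
    read_sam,
    split_alignments,
    write_sam,
)


def rec(read_id="r1", chrom="chr1", pos=1, cigar=None, seq=None, strand="+",
        mate_pos=None, first=True):
    if cigar is None:
        cigar = [("M", len(seq))] if seq else [("M", 10)]
    if seq is None:
        seq = "A" * sum(n for op, n in cigar if op in "MSI")
    return AlignmentRecord(read_id, chrom, pos, cigar, seq, strand, mate_pos, first)


class TestDedupe:
    def test_identical_keys_collapse(self):
        records = [rec("a", pos=5), rec("b", pos=5)]
        assert len(list(dedupe_alignments(records))) == 1

    def test_opposite_strands_both_kept(self):
        records = [rec("a", pos=5, strand="+"), rec("b", pos=5, strand="-")]
        assert len(list(dedupe_alignments(records))) == 2

    def test_matches_hashset_oracle(self, rng):
        records = []
        for i in range(83):
            records.append(
                rec(
                    f"u{i}",
                    pos=int(rng.integers(1, 500)),
                    strand="+-"[rng.integers(2)],
                    mate_pos=int(rng.integers(1, 500)),
                )
            )
        # plant 17 exact-key duplicates of random existing records
        for i, j in enumerate(rng.choice(len(records), size=17, replace=False)):
            src = records[j]
            records.append(rec(f"d{i}", pos=src.pos, strand=src.strand, mate_pos=src.mate_pos))
        records.sort(key=lambda r: (r.chrom, r.pos))
        oracle = {(r.chrom, r.pos, r.strand, r.mate_pos) for r in records}
        out = list(dedupe_alignments(records))
        assert len(out) == len(oracle)

    def test_unsorted_input_raises(self):
        records = [rec("a", pos=100), rec("b", pos=5)]
        with pytest.raises(ValueError, match="sort"):
            list(dedupe_alignments(records))


class TestAssignRead:
    @pytest.fixture
    def index(self):
        return SnpIndex(
            [SnpRecord("chr1", 5, "A", "G"), SnpRecord("chr1", 15, "C", "T")]
        )

    def test_alt_base_is_genome2(self, index):
        read = rec(pos=1, seq="AAAAGAAAAA")  # SNP at pos 5 reads G = alt
        a = assign_read(read, index)
        assert a.category is Category.GENOME2
        assert (a.n_snps_seen, a.n_g1_bases, a.n_g2_bases) == (1, 0, 1)

    def test_ref_base_is_genome1(self, index):
        read = rec(pos=1, seq="AAAAAAAAAA")
        assert assign_read(read, index).category is Category.GENOME1

    def test_no_snp_overlap_unassigned(self, index):
        read = rec(pos=100, seq="AAAAAAAAAA")
        a = assign_read(read, index)
        assert a.category is Category.UNASSIGNED
        assert a.n_snps_seen == 0

    def test_third_base_is_uninformative(self, index):
        read = rec(pos=1, seq="AAAATAAAAA")  # T matches neither A nor G
        a = assign_read(read, index)
        assert a.category is Category.UNASSIGNED
        assert a.n_snps_seen == 1

    def test_two_snps_opposite_votes_conflict(self, index):
        # pos5 -> G (alt), pos15 -> C (ref)
        read = rec(pos=1, cigar=[("M", 20)], seq="AAAAGAAAAAAAAACAAAAA")
        assert assign_read(read, index).category is Category.CONFLICTING

    def test_snp_under_splice_gap_not_counted(self):
        index = SnpIndex([SnpRecord("chr1", 50, "A", "G")])
        read = rec(pos=1, cigar=[("M", 10), ("N", 100), ("M", 10)], seq="A" * 20)
        assert assign_read(read, index).n_snps_seen == 0

    def test_snp_under_deletion_not_counted(self):
        index = SnpIndex([SnpRecord("chr1", 12, "A", "G")])
        read = rec(pos=1, cigar=[("M", 10), ("D", 5), ("M", 10)], seq="A" * 20)
        assert assign_read(read, index).n_snps_seen == 0

    def test_soft_clip_shifts_read_coordinates(self):
        index = SnpIndex([SnpRecord("chr1", 10, "C", "T")])
        # 5S: first 5 bases unaligned; ref pos 10 is read offset 5+ (10-10)=5
        read = rec(pos=10, cigar=[("S", 5), ("M", 10)], seq="GGGGGTAAAAAAAAA")
        assert assign_read(read, index).category is Category.GENOME2

    def test_cigar_seq_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            AlignmentRecord("x", "chr1", 1, [("M", 5)], "AAAA")

    def test_matches_bruteforce_cigar_expansion(self, rng, small_sim):
        _, reference, snps, _ = small_sim
        index = SnpIndex(snps)
        lookup = {(s.chrom, s.pos): s for s in snps}
        seqs = {g.name: g.seq for g in reference}
        for _ in range(300):
            read = _random_read(rng, seqs)
            brute = _bruteforce_assign(read, lookup)
            ours = assign_read(read, index)
            assert (ours.n_snps_seen, ours.n_g1_bases, ours.n_g2_bases, ours.category) == brute


def _random_read(rng, chrom_seqs):
    chrom = list(chrom_seqs)[rng.integers(len(chrom_seqs))]
    shape = rng.integers(4)
    if shape == 0:
        cigar = [("M", 60)]
    elif shape == 1:
        cigar = [("S", 6), ("M", 50), ("S", 4)]
    elif shape == 2:
        cigar = [("M", 20), ("N", int(rng.integers(30, 200))), ("M", 30)]
    else:
        cigar = [("M", 15), ("I", 3), ("M", 10), ("D", 4), ("M", 25)]
    ref_len = sum(n for op, n in cigar if op in "MND")
    read_len = sum(n for op, n in cigar if op in "MSI")
    pos = int(rng.integers(1, len(chrom_seqs[chrom]) - ref_len))
    seq = "".join(rng.choice(list("ACGT"), size=read_len))
    return AlignmentRecord(f"rnd", chrom, pos, cigar, seq)


def _bruteforce_assign(read, snp_lookup):
    pairs = []  # explicit (ref_pos, read_base) expansion of the CIGAR
    ref, idx = read.pos, 0
    for op, n in read.cigar:
        for _ in range(n):
            if op == "M":
                pairs.append((ref, read.seq[idx]))
                ref += 1
                idx += 1
            elif op in "ND":
                ref += 1
            else:
                idx += 1
    seen = g1 = g2 = 0
    for ref_pos, base in pairs:
        snp = snp_lookup.get((read.chrom, ref_pos))
        if snp is None:
            continue
        seen += 1
        g1 += base == snp.ref_base
        g2 += base == snp.alt_base
    if g1 and g2:
        cat = Category.CONFLICTING
    elif g1:
        cat = Category.GENOME1
    elif g2:
        cat = Category.GENOME2
    else:
        cat = Category.UNASSIGNED
    return seen, g1, g2, cat


class TestAssignFragment:
    index = SnpIndex([SnpRecord("chr1", 5, "A", "G"), SnpRecord("chr1", 105, "C", "T")])

    def test_one_informative_mate_decides(self):
        r1 = rec("f", pos=1, seq="AAAAAAAAAA", mate_pos=200)
        r2 = rec("f", pos=200, seq="AAAAAAAAAA", mate_pos=1, first=False)
        assert assign_fragment(r1, r2, self.index).category is Category.GENOME1

    def test_opposing_mates_conflict(self):
        r1 = rec("f", pos=1, seq="AAAAAAAAAA", mate_pos=101)  # ref A at 5
        r2 = rec("f", pos=101, seq="AAAATAAAAA", mate_pos=1, first=False)  # alt T at 105
        assert assign_fragment(r1, r2, self.index).category is Category.CONFLICTING

    def test_mismatched_ids_rejected(self):
        r1 = rec("f1", pos=1, seq="A" * 10)
        r2 = rec("f2", pos=1, seq="A" * 10, first=False)
        with pytest.raises(ValueError, match="read ids"):
            assign_fragment(r1, r2, self.index)


class TestSplitAlignments:
    def test_empty_input(self):
        g1, g2, summary = split_alignments([], SnpIndex([]))
        assert (g1, g2) == ([], [])
        assert summary.total == 0

    def test_partition_conservation(self, rng, small_sim):
        _, reference, snps, _ = small_sim
        seqs = {g.name: g.seq for g in reference}
        records = [_random_read(rng, seqs) for _ in range(200)]
        for i, r in enumerate(records):
            r.read_id = f"r{i}"
        _, _, summary = split_alignments(records, SnpIndex(snps))
        assert summary.total == 200


def test_sam_round_trip(tmp_path):
    records = [
        rec("p1", pos=10, seq="ACGTACGTAC", mate_pos=100, first=True),
        rec("p1", pos=100, seq="ACGTACGTAC", strand="-", mate_pos=10, first=False),
        rec("s1", pos=55, cigar=[("M", 4), ("N", 20), ("M", 6)], seq="ACGTACGTAC"),
    ]
    path = tmp_path / "reads.sam"
    write_sam(records, path, {"chr1": 1000}, genome_tags={"p1": "G2"})
    back, contigs = read_sam(path)
    assert contigs == {"chr1": 1000}
    assert len(back) == 3
    by_key = {(r.read_id, r.is_first_mate): r for r in back}
    r = by_key[("p1", True)]
    assert (r.pos, r.seq, r.strand, r.mate_pos) == (10, "ACGTACGTAC", "+", 100)
    assert by_key[("s1", True)].cigar == [("M", 4), ("N", 20), ("M", 6)]
    assert "ga:Z:G2" in path.read_text()


def test_pair_fragments_groups_mates():
    r1 = rec("f", pos=1, seq="A" * 10, mate_pos=50)
    r2 = rec("f", pos=50, seq="A" * 10, mate_pos=1, first=False)
    solo = rec("s", pos=9, seq="A" * 10)
    frags = pair_fragments([r1, solo, r2])
    assert sorted((a.read_id, b.read_id if b else None) for a, b in frags) == [
        ("f", "f"), ("s", None)
    ]
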