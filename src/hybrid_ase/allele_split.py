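"""PCR-duplicate removal and SNP-based allele assignment of aligned reads.

After alignment to the N-masked reference, each uniquely mapped read is
inspected at the SNP positions it covers: a base matching the genome-1
(reference strain) allele votes for GENOME1, a base matching the genome-2
allele votes for GENOME2. A read with at least one vote for each genome is
CONFLICTING; a read covering no SNP, or whose bases at SNPs match neither
allele (e.g. a sequencing error), is UNASSIGNED. Paired mates are combined
by summing their votes, so one informative mate decides the fragment and
opposing mates conflict.

Base qualities are ignored: assignment is a deterministic function of the
aligned bases. CIGAR handling follows SAM semantics — M consumes reference
and read, N and D consume reference only (a SNP under a splice gap or
deletion is uninformative), S and I consume read only.
"""

from __future__ import annotations

import enum
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

from .genomes import SnpRecord

_REF_OPS = frozenset("MND")
_READ_OPS = frozenset("MSI")
_CIGAR_CODE = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S"}


@dataclass
class AlignmentRecord:
    """A uniquely mapped read reduced to what assignment and counting need."""

    read_id: str
    chrom: str
    pos: int  # 1-based leftmost mapped position
    cigar: list[tuple[str, int]]
    seq: str
    strand: str = "+"
    mate_pos: int | None = None
    is_first_mate: bool = True

    def __post_init__(self) -> None:
        read_len = sum(n for op, n in self.cigar if op in _READ_OPS)
        if read_len != len(self.seq):
            raise ValueError(
                f"{self.read_id}: CIGAR read length {read_len} != sequence "
                f"length {len(self.seq)}"
            )
        for op, n in self.cigar:
            if op not in "MNSID":
                raise ValueError(f"{self.read_id}: unsupported CIGAR op {op!r}")
            if n <= 0:
                raise ValueError(f"{self.read_id}: non-positive CIGAR length")

    @property
    def reference_end(self) -> int:
        """1-based inclusive end of the aligned span."""
        return self.pos + sum(n for op, n in self.cigar if op in _REF_OPS) - 1

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """0-based half-open reference intervals covered by M segments."""
        blocks: list[tuple[int, int]] = []
        ref = self.pos - 1
        for op, n in self.cigar:
            if op == "M":
                blocks.append((ref, ref + n))
            if op in _REF_OPS:
                ref += n
        return blocks


class Category(enum.Enum):
    GENOME1 = "genome1"
    GENOME2 = "genome2"
    UNASSIGNED = "unassigned"
    CONFLICTING = "conflicting"


@dataclass(frozen=True)
class AlleleAssignment:
    category: Category
    n_snps_seen: int = 0
    n_g1_bases: int = 0
    n_g2_bases: int = 0

    @staticmethod
    def from_tallies(n_snps_seen: int, n_g1: int, n_g2: int) -> "AlleleAssignment":
        if n_g1 > 0 and n_g2 > 0:
            cat = Category.CONFLICTING
        elif n_g1 > 0:
            cat = Category.GENOME1
        elif n_g2 > 0:
            cat = Category.GENOME2
        else:
            cat = Category.UNASSIGNED
        return AlleleAssignment(cat, n_snps_seen, n_g1, n_g2)


class SnpIndex:
    """Per-chromosome sorted-position index for range lookup of SNPs."""

    def __init__(self, snps: Iterable[SnpRecord]):
        by_chrom: dict[str, list[SnpRecord]] = {}
        for s in snps:
            by_chrom.setdefault(s.chrom, []).append(s)
        self._positions: dict[str, list[int]] = {}
        self._records: dict[str, list[SnpRecord]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.pos)
            self._positions[chrom] = [r.pos for r in recs]
            self._records[chrom] = recs

    def in_range(self, chrom: str, start_pos: int, end_pos: int) -> list[SnpRecord]:
        """SNPs with 1-based position in [start_pos, end_pos]."""
        pos = self._positions.get(chrom)
        if not pos:
            return []
        lo = bisect_left(pos, start_pos)
        hi = bisect_right(pos, end_pos)
        return self._records[chrom][lo:hi]

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())


@dataclass
class SummaryCounts:
    """Per-fragment partition of a split run; categories are exclusive."""

    g1: int = 0
    g2: int = 0
    unassigned: int = 0
    conflicting: int = 0

    @property
    def total(self) -> int:
        return self.g1 + self.g2 + self.unassigned + self.conflicting

    def add(self, category: Category) -> None:
        if category is Category.GENOME1:
            self.g1 += 1
        elif category is Category.GENOME2:
            self.g2 += 1
        elif category is Category.UNASSIGNED:
            self.unassigned += 1
        else:
            self.conflicting += 1


def dedupe_alignments(
    records: Iterable[AlignmentRecord],
) -> Iterator[AlignmentRecord]:
    """Drop PCR duplicates from a coordinate-sorted stream.

    Records sharing (chrom, 5' position, strand, mate position) are reduced
    to the first one encountered — the conventional rmdup key for uniquely
    mapped paired data. Requires input sorted by (chrom, pos); raises
    otherwise.
    """
    current: tuple[str, int] | None = None
    seen: set[tuple[str, int | None]] = set()
    seen_chroms: set[str] = set()
    for rec in records:
        key_pos = (rec.chrom, rec.pos)
        if key_pos != current:
            if current is not None:
                if rec.chrom == current[0] and rec.pos < current[1]:
                    raise ValueError(
                        f"input not coordinate-sorted at {rec.chrom}:{rec.pos}; "
                        "sort by (chrom, pos) first"
                    )
                if rec.chrom != current[0] and rec.chrom in seen_chroms:
                    raise ValueError(
                        f"input not coordinate-sorted: chromosome {rec.chrom} "
                        "appears in more than one block"
                    )
            seen_chroms.add(rec.chrom)
            current = key_pos
            seen = set()
        subkey = (rec.strand, rec.mate_pos)
        if subkey in seen:
            continue
        seen.add(subkey)
        yield rec


def assign_read(read: AlignmentRecord, snps: SnpIndex) -> AlleleAssignment:
    """Assign one read by comparing its bases at covered SNP positions.

    Walks the CIGAR; only SNPs falling under M segments are informative.
    """
    n_seen = n_g1 = n_g2 = 0
    ref = read.pos  # 1-based
    read_i = 0
    for op, n in read.cigar:
        if op == "M":
            for snp in snps.in_range(read.chrom, ref, ref + n - 1):
                n_seen += 1
                base = read.seq[read_i + (snp.pos - ref)]
                if base == snp.ref_base:
                    n_g1 += 1
                elif base == snp.alt_base:
                    n_g2 += 1
            ref += n
            read_i += n
        elif op in "ND":
            ref += n
        else:  # S, I
            read_i += n
    return AlleleAssignment.from_tallies(n_seen, n_g1, n_g2)


def assign_fragment(
    r1: AlignmentRecord, r2: AlignmentRecord | None, snps: SnpIndex
) -> AlleleAssignment:
    """Combine per-mate SNP tallies into one fragment-level assignment."""
    a1 = assign_read(r1, snps)
    if r2 is None:
        return a1
    if r2.read_id != r1.read_id:
        raise ValueError(f"mates have different read ids: {r1.read_id!r} vs {r2.read_id!r}")
    a2 = assign_read(r2, snps)
    return AlleleAssignment.from_tallies(
        a1.n_snps_seen + a2.n_snps_seen,
        a1.n_g1_bases + a2.n_g1_bases,
        a1.n_g2_bases + a2.n_g2_bases,
    )


def pair_fragments(
    records: Iterable[AlignmentRecord],
) -> list[tuple[AlignmentRecord, AlignmentRecord | None]]:
    """Group a record stream into (mate1, mate2-or-None) fragments by read id."""
    pending: dict[str, AlignmentRecord] = {}
    fragments: list[tuple[AlignmentRecord, AlignmentRecord | None]] = []
    for rec in records:
        if rec.read_id in pending:
            first = pending.pop(rec.read_id)
            r1, r2 = (first, rec) if first.is_first_mate else (rec, first)
            fragments.append((r1, r2))
        else:
            pending[rec.read_id] = rec
    for rec in pending.values():
        fragments.append((rec, None))
    return fragments


def split_alignments(
    records: Iterable[AlignmentRecord], snps: SnpIndex
) -> tuple[list[AlignmentRecord], list[AlignmentRecord], SummaryCounts]:
    """Partition deduped fragments between the two parental genomes.

    Returns the genome-1 records, genome-2 records, and a per-fragment
    summary; unassigned and conflicting fragments appear only in the
    summary. The four summary categories always sum to the number of input
    fragments.
    """
    g1: list[AlignmentRecord] = []
    g2: list[AlignmentRecord] = []
    summary = SummaryCounts()
    for r1, r2 in pair_fragments(records):
        assignment = assign_fragment(r1, r2, snps)
        summary.add(assignment.category)
        target = None
        if assignment.category is Category.GENOME1:
            target = g1
        elif assignment.category is Category.GENOME2:
            target = g2
        if target is not None:
            target.append(r1)
            if r2 is not None:
                target.append(r2)
    return g1, g2, summary


# --- SAM text I/O -----------------------------------------------------------

def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = []
    for code, n in seg.cigartuples or []:
        if code not in _CIGAR_CODE:
            raise ValueError(
                f"{seg.query_name}: unsupported CIGAR op code {code} "
                "(only M/I/D/N/S are handled)"
            )
        cigar.append((_CIGAR_CODE[code], n))
    mate_pos = None
    if seg.is_paired and not seg.mate_is_unmapped:
        mate_pos = seg.next_reference_start + 1
    return AlignmentRecord(
        read_id=seg.query_name,
        chrom=seg.reference_name,
        pos=seg.reference_start + 1,
        cigar=cigar,
        seq=seg.query_sequence,
        strand="-" if seg.is_reverse else "+",
        mate_pos=mate_pos,
        is_first_mate=not seg.is_read2,
    )


def read_sam(path) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Read mapped records from a SAM file; returns records and @SQ lengths."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        contigs = dict(zip(sam.references, sam.lengths))
        for seg in sam:
            if seg.is_unmapped:
                continue
            records.append(_from_pysam(seg))
    return records, contigs


def write_sam(
    records: Sequence[AlignmentRecord],
    path,
    contigs: dict[str, int],
    genome_tags: dict[str, str] | None = None,
) -> None:
    """Write records as SAM; optional per-read assignment in a ``ga:Z:`` tag."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            seg.reference_name = rec.chrom
            seg.reference_start = rec.pos - 1
            seg.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
            seg.query_sequence = rec.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            seg.mapping_quality = 60
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if rec.mate_pos is not None:
                flag |= 0x1 | 0x2 | (0x40 if rec.is_first_mate else 0x80)
                seg.next_reference_name = rec.chrom
                seg.next_reference_start = rec.mate_pos - 1
                if rec.strand == "+":
                    flag |= 0x20
            seg.flag = flag
            if genome_tags and rec.read_id in genome_tags:
                seg.set_tag("ga", genome_tags[rec.read_id])
            out.write(seg)
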