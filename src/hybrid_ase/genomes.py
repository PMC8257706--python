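"""Strain SNP tables and N-masked reference genomes.

An F1 hybrid carries two parental haplotypes that differ at known SNP
positions. Aligning reads to the standard reference would bias them toward
the reference strain, so the reference is "N-masked": every base at a
strain-discriminating SNP is replaced by ``N``, making both alleles equally
mismatched during alignment. This module reads SNP tables (VCF or a simple
TSV dialect), intersects two tables into a consensus set, and applies the
mask.

Conventions: genome 1 carries ``ref_base`` (the reference-strain, paternal
B6 role) and genome 2 carries ``alt_base`` (the alternate strain, maternal
JF1 role); a ``swap_strains`` flag on the readers accommodates reciprocal
crosses. SNP positions are 1-based as in VCF; sequence indexing is 0-based
internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class SnpRecord:
    """A biallelic single-base difference between the two parental strains."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise ValueError(
                f"SNP alleles must be single bases in ACGT, got "
                f"{self.ref_base!r}>{self.alt_base!r} at {self.chrom}:{self.pos}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError(
                f"ref and alt allele identical at {self.chrom}:{self.pos}"
            )

    def swapped(self) -> "SnpRecord":
        return SnpRecord(self.chrom, self.pos, self.alt_base, self.ref_base)


@dataclass
class GenomeSequence:
    """One chromosome of an uppercase A/C/G/T/N reference."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for {self.name}")
        if set(self.seq) - set("ACGTN"):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"{self.name} contains non-ACGTN characters: {bad}")

    def __len__(self) -> int:
        return len(self.seq)


def _finalize(records: list[SnpRecord], n_dropped: int, source: str) -> list[SnpRecord]:
    records.sort()
    seen: set[tuple[str, int]] = set()
    unique: list[SnpRecord] = []
    for rec in records:
        key = (rec.chrom, rec.pos)
        if key in seen:
            n_dropped += 1
            continue
        seen.add(key)
        unique.append(rec)
    if n_dropped:
        logger.info("%s: dropped %d non-SNP/duplicate records", source, n_dropped)
    return unique


def read_snp_table(path, swap_strains: bool = False) -> list[SnpRecord]:
    """Read SNPs from a VCF (4.x) or 3-column TSV ``chrom\\tpos\\tref>alt``.

    Only biallelic single-base substitutions are retained; indels and
    multi-allelic records are dropped (count logged). Records are returned
    sorted by (chrom, pos) with duplicate positions removed.
    """
    path = Path(path)
    if path.suffix in {".vcf"} or path.name.endswith(".vcf.gz"):
        records, dropped = _read_vcf(path)
    else:
        records, dropped = _read_tsv(path)
    if swap_strains:
        records = [r.swapped() for r in records]
    return _finalize(records, dropped, path.name)


def _read_vcf(path: Path) -> tuple[list[SnpRecord], int]:
    records: list[SnpRecord] = []
    dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in _BASES
                or alts[0].upper() not in _BASES
            ):
                dropped += 1
                continue
            records.append(
                SnpRecord(rec.chrom, rec.pos, rec.ref.upper(), alts[0].upper())
            )
    return records, dropped


def _read_tsv(path: Path) -> tuple[list[SnpRecord], int]:
    records: list[SnpRecord] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 or ">" not in fields[2]:
                raise ValueError(f"{path}:{lineno}: malformed SNP line: {line!r}")
            chrom, pos_s, alleles = fields
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1, got {pos}")
            ref, _, alt = alleles.partition(">")
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                dropped += 1
                continue
            records.append(SnpRecord(chrom, pos, ref, alt))
    return records, dropped


def write_snp_table(snps: Iterable[SnpRecord], path) -> None:
    """Write SNPs in the TSV dialect (round-trips with :func:`read_snp_table`)."""
    with open(path, "w") as fh:
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref_base}>{s.alt_base}\n")


def write_vcf(snps: Sequence[SnpRecord], path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write SNPs as a minimal VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(s.chrom for s in snps):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref_base}\t{s.alt_base}\t.\tPASS\t.\n")


def intersect_snp_sets(
    a: Sequence[SnpRecord], b: Sequence[SnpRecord]
) -> list[SnpRecord]:
    """Consensus of two SNP tables.

    Keeps records whose (chrom, pos) occurs in both sets *and* whose alleles
    agree; positions present in both but with discordant alleles are dropped
    (count logged). Result is sorted by (chrom, pos).
    """
    index = {(r.chrom, r.pos): r for r in b}
    kept: list[SnpRecord] = []
    discordant = 0
    for rec in a:
        other = index.get((rec.chrom, rec.pos))
        if other is None:
            continue
        if (other.ref_base, other.alt_base) == (rec.ref_base, rec.alt_base):
            kept.append(rec)
        else:
            discordant += 1
    if discordant:
        logger.info("intersect_snp_sets: dropped %d allele-discordant positions", discordant)
    kept.sort()
    return kept


def mask_genome(
    genome: Sequence[GenomeSequence], snps: Sequence[SnpRecord]
) -> list[GenomeSequence]:
    """Replace the base at every SNP position with ``N``.

    The output is identical to the input elsewhere. If the genome base does
    not match the SNP's ref allele the position is masked anyway and a
    mismatch warning is counted — unbiased alignment requires the mask even
    when the tables disagree with the assembly.
    """
    by_name = {g.name: g for g in genome}
    masked_seqs: dict[str, bytearray] = {}
    mismatches = 0
    for snp in snps:
        if snp.chrom not in by_name:
            raise ValueError(f"SNP chromosome {snp.chrom!r} not present in genome")
        chrom = by_name[snp.chrom]
        if snp.pos > len(chrom):
            raise ValueError(
                f"SNP {snp.chrom}:{snp.pos} {snp.ref_base}>{snp.alt_base} "
                f"beyond chromosome end ({len(chrom)} bp)"
            )
        buf = masked_seqs.setdefault(snp.chrom, bytearray(chrom.seq, "ascii"))
        if chr(buf[snp.pos - 1]) not in (snp.ref_base, "N"):
            mismatches += 1
        buf[snp.pos - 1] = ord("N")
    if mismatches:
        logger.warning(
            "mask_genome: %d SNP positions where the genome base differed "
            "from the recorded ref allele (masked anyway)",
            mismatches,
        )
    return [
        GenomeSequence(g.name, masked_seqs[g.name].decode("ascii"))
        if g.name in masked_seqs
        else GenomeSequence(g.name, g.seq)
        for g in genome
    ]


def read_fasta(path) -> list[GenomeSequence]:
    return [
        GenomeSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genome: Iterable[GenomeSequence], path) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.name, description="") for g in genome]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
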