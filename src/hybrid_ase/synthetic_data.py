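"""Truth-tagged synthetic data for an F1 hybrid-cross ASE experiment.

The generator emulates the statistical structure the pipeline assumes, with
a known truth manifest at every level:

* a random diploid genome pair differing at SNPs placed at ``snp_rate``
  per bp (default 0.004, i.e. the >4 SNPs/kb divergence of an
  inter-subspecific mouse cross);
* single-exon, non-overlapping genes assigned an allelic class — maternal
  (true maternal fraction rho ~ 0.95), paternal (rho ~ 0.05) or biallelic
  (rho = 0.5) — where imprinted genes optionally lose imprinting
  (rho -> 0.5) in the "mutant" condition;
* per-gene, per-sample total counts drawn NB(mean = s_j * mu_i * 2^(lfc_i *
  x_j), dispersion alpha) with Var = mu + alpha*mu^2, then split maternal
  vs paternal by binomial thinning at the condition's rho, so
  maternal + paternal == bulk by construction;
* paired-end alignments sampled uniformly from gene spans, bases copied
  from the allele-of-origin haplotype, sequencing errors at ``error_rate``;
* ChIP-seq-like peaks placed near imprinted genes and far from a matched
  control set.

All randomness flows from one ``numpy`` Generator seeded by
``SimConfig.seed``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .allele_split import AlignmentRecord
from .genomes import GenomeSequence, SnpRecord, write_fasta, write_vcf
from .peaks import Interval
from .quantify import CountMatrix, GeneModel

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the analysed experiment where it states them: two
    biological replicates per condition, ~4 SNPs/kb strain divergence,
    maternal/paternal true allelic fractions near 0.95/0.05, complete loss
    of imprinting (rho -> 0.5) in the mutant, and moderate NB dispersion.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 500_000
    n_genes: int = 40
    gene_length_bp: int = 2_000
    snp_rate: float = 4e-3
    class_proportions: tuple[tuple[str, float], ...] = (
        ("maternal", 0.15),
        ("paternal", 0.15),
        ("biallelic", 0.70),
    )
    rho_maternal: float = 0.95
    rho_paternal: float = 0.05
    rho_biallelic: float = 0.5
    loss_fraction: float = 1.0  # imprinted genes losing imprinting in mutant
    n_replicates: int = 2
    nb_mean_log2_loc: float = 7.0  # lognormal location of gene means (~128)
    nb_mean_log2_scale: float = 1.5
    nb_dispersion: float = 0.05
    frac_de: float = 0.2
    log2_fc_magnitude: float = 2.0
    library_size_range: tuple[float, float] = (0.7, 1.4)
    read_length_bp: int = 80
    fragment_size_bp: int = 250
    error_rate: float = 0.0
    duplicate_rate: float = 0.0
    spliced: bool = False
    intron_length_bp: int = 200
    peak_width_bp: int = 500
    peak_near_max_bp: int = 50_000
    peak_far_min_bp: int = 1_000_000
    peak_far_span_bp: int = 500_000

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.class_proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        for name, rho in (
            ("rho_maternal", self.rho_maternal),
            ("rho_paternal", self.rho_paternal),
            ("rho_biallelic", self.rho_biallelic),
        ):
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rho}")
        if self.snp_rate < 0 or self.error_rate < 0 or self.nb_dispersion < 0:
            raise ValueError("rates must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def sample_ids(self) -> list[str]:
        return [f"wt_{i + 1}" for i in range(self.n_replicates)] + [
            f"mut_{i + 1}" for i in range(self.n_replicates)
        ]

    @property
    def conditions(self) -> list[str]:
        return ["WT"] * self.n_replicates + ["MUT"] * self.n_replicates

    def rho_for(self, gene_class: str) -> float:
        return {
            "maternal": self.rho_maternal,
            "paternal": self.rho_paternal,
            "biallelic": self.rho_biallelic,
        }[gene_class]


@dataclass
class TruthManifest:
    """Ground truth for every simulated gene and fragment."""

    genes: pd.DataFrame  # index gene_id: chrom,start,end,class,rho_wt,rho_mut,log2_fc,mu
    fragments: pd.DataFrame | None = None  # read_id, gene_id, allele ("mat"/"pat")


def simulate_genomes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenomeSequence], list[SnpRecord]]:
    """Random reference chromosomes plus strain-discriminating SNPs."""
    rng = rng or cfg.rng()
    genome: list[GenomeSequence] = []
    snps: list[SnpRecord] = []
    for c in range(cfg.n_chroms):
        name = f"chr{c + 1}"
        seq_arr = _BASES[rng.integers(0, 4, size=cfg.chrom_length_bp)]
        seq = seq_arr.tobytes().decode("ascii")
        n_snps = rng.binomial(cfg.chrom_length_bp, cfg.snp_rate)
        positions = np.sort(
            rng.choice(cfg.chrom_length_bp, size=n_snps, replace=False)
        )
        for pos0 in positions:
            ref = seq[pos0]
            alt = chr(_BASES[(list(b"ACGT").index(ord(ref)) + rng.integers(1, 4)) % 4][0])
            snps.append(SnpRecord(name, int(pos0) + 1, ref, alt))
        genome.append(GenomeSequence(name, seq))
    return genome, snps


def alternate_genome(
    reference: Sequence[GenomeSequence], snps: Sequence[SnpRecord]
) -> list[GenomeSequence]:
    """The second haplotype: reference with the alt base at every SNP."""
    by_name = {g.name: bytearray(g.seq, "ascii") for g in reference}
    for s in snps:
        by_name[s.chrom][s.pos - 1] = ord(s.alt_base)
    return [GenomeSequence(g.name, by_name[g.name].decode("ascii")) for g in reference]


def place_genes(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Evenly spaced, non-overlapping single-exon genes across chromosomes."""
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    idx = 0
    for c, count in enumerate(per_chrom):
        if count == 0:
            continue
        chrom = f"chr{c + 1}"
        margin = 1_000
        usable = cfg.chrom_length_bp - 2 * margin
        if usable < count * cfg.gene_length_bp:
            raise ValueError(
                f"{chrom}: cannot place {count} genes of {cfg.gene_length_bp} bp "
                f"on {cfg.chrom_length_bp} bp"
            )
        spacing = usable // count
        for k in range(count):
            start = margin + k * spacing
            idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{idx:04d}",
                    chrom=chrom,
                    strand="+" if (idx % 2) else "-",
                    exons=[(start, start + cfg.gene_length_bp)],
                )
            )
    return genes


def assign_gene_truth(
    cfg: SimConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-gene class, condition allelic fractions, mean and fold change."""
    rng = rng or cfg.rng()
    names = [n for n, _ in cfg.class_proportions]
    probs = [p for _, p in cfg.class_proportions]
    classes = rng.choice(names, size=len(genes), p=probs)
    mu = 2.0 ** rng.normal(cfg.nb_mean_log2_loc, cfg.nb_mean_log2_scale, len(genes))
    is_de = rng.random(len(genes)) < cfg.frac_de
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    lfc = np.where(is_de, signs * cfg.log2_fc_magnitude, 0.0)
    rho_wt = np.array([cfg.rho_for(c) for c in classes])
    loses = (classes != "biallelic") & (rng.random(len(genes)) < cfg.loss_fraction)
    rho_mut = np.where(loses, cfg.rho_biallelic, rho_wt)
    return pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "class": classes,
            "rho_wt": rho_wt,
            "rho_mut": rho_mut,
            "log2_fc": lfc,
            "mu": mu,
            "dispersion": cfg.nb_dispersion,
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )


def nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, alpha) with Var = mu + alpha*mu^2, via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    cfg: SimConfig,
    truth_genes: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, CountMatrix, CountMatrix, TruthManifest]:
    """Bulk, maternal and paternal count matrices plus the truth manifest.

    Maternal counts are binomial draws from the bulk total at the
    condition's true maternal fraction; paternal = bulk - maternal, so the
    allelic layers sum to the bulk layer exactly.
    """
    rng = rng or cfg.rng()
    if truth_genes is None:
        genes = place_genes(cfg, rng)
        truth_genes = assign_gene_truth(cfg, genes, rng)
    samples = cfg.sample_ids
    conditions = cfg.conditions
    lo, hi = cfg.library_size_range
    lib = rng.uniform(lo, hi, size=len(samples))
    mu = truth_genes["mu"].to_numpy()
    lfc = truth_genes["log2_fc"].to_numpy()

    bulk = np.zeros((len(truth_genes), len(samples)), dtype=int)
    mat = np.zeros_like(bulk)
    for j, cond in enumerate(conditions):
        x = 1.0 if cond == "MUT" else 0.0
        mean_j = lib[j] * mu * 2.0 ** (lfc * x)
        total = nb_counts(rng, mean_j, cfg.nb_dispersion)
        rho = truth_genes["rho_mut" if cond == "MUT" else "rho_wt"].to_numpy()
        mat[:, j] = rng.binomial(total, rho)
        bulk[:, j] = total
    pat = bulk - mat

    gene_info = truth_genes[["chrom"]].copy()
    index = truth_genes.index

    def _cm(arr: np.ndarray, layer: str) -> CountMatrix:
        return CountMatrix(
            pd.DataFrame(arr, index=index, columns=samples), layer, gene_info
        )

    return (
        _cm(bulk, "BULK"),
        _cm(mat, "MATERNAL"),
        _cm(pat, "PATERNAL"),
        TruthManifest(genes=truth_genes),
    )


def _mutate(seq: list[str], rng: np.random.Generator, error_rate: float) -> None:
    if error_rate <= 0:
        return
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        others = [b for b in "ACGT" if b != seq[i]]
        seq[i] = others[rng.integers(0, 3)]


def _read_record(
    read_id: str,
    chrom: str,
    start0: int,
    length: int,
    source_seq: str,
    strand: str,
    mate_start0: int,
    is_first: bool,
    rng: np.random.Generator,
    cfg: SimConfig,
) -> AlignmentRecord:
    if cfg.spliced and length >= 20:
        half = length // 2
        bases = list(
            source_seq[start0 : start0 + half]
            + source_seq[
                start0 + half + cfg.intron_length_bp : start0
                + half
                + cfg.intron_length_bp
                + (length - half)
            ]
        )
        cigar = [("M", half), ("N", cfg.intron_length_bp), ("M", length - half)]
    else:
        bases = list(source_seq[start0 : start0 + length])
        cigar = [("M", length)]
    _mutate(bases, rng, cfg.error_rate)
    return AlignmentRecord(
        read_id=read_id,
        chrom=chrom,
        pos=start0 + 1,
        cigar=cigar,
        seq="".join(bases),
        strand=strand,
        mate_pos=mate_start0 + 1,
        is_first_mate=is_first,
    )


def simulate_alignments(
    cfg: SimConfig,
    reference: Sequence[GenomeSequence],
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneModel],
    fragment_counts: pd.DataFrame,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Paired-end alignments for one sample, with per-fragment truth.

    ``fragment_counts`` is a genes-indexed DataFrame with integer columns
    ``mat`` and ``pat``. Maternal fragments copy their bases from the
    alternate haplotype (alt base at every SNP), paternal fragments from
    the reference; per-base errors are applied at ``cfg.error_rate``.
    Records are returned coordinate-sorted; the companion DataFrame maps
    read_id to (gene_id, allele).
    """
    rng = rng or cfg.rng()
    ref_by_name = {g.name: g.seq for g in reference}
    alt_by_name = {g.name: g.seq for g in alternate_genome(reference, snps)}
    gene_by_id = {g.gene_id: g for g in genes}

    span_needed = cfg.fragment_size_bp + (
        cfg.intron_length_bp if cfg.spliced else 0
    )
    records: list[AlignmentRecord] = []
    truth_rows: list[tuple[str, str, str]] = []
    counter = 0
    for gene_id, row in fragment_counts.iterrows():
        gene = gene_by_id[gene_id]
        if gene.end - gene.start < span_needed:
            raise ValueError(
                f"{gene_id}: gene too short for fragments of {span_needed} bp"
            )
        for allele, n_frags in (("mat", int(row["mat"])), ("pat", int(row["pat"]))):
            source = alt_by_name if allele == "mat" else ref_by_name
            seq = source[gene.chrom]
            for _ in range(n_frags):
                counter += 1
                read_id = f"{sample_id}.f{counter:07d}"
                start = int(
                    rng.integers(gene.start, gene.end - span_needed + 1)
                )
                r2_start = start + cfg.fragment_size_bp - cfg.read_length_bp
                if cfg.spliced:
                    r2_start += cfg.intron_length_bp
                    r2_cfg = replace(cfg, spliced=False)
                else:
                    r2_cfg = cfg
                r1 = _read_record(
                    read_id, gene.chrom, start, cfg.read_length_bp, seq,
                    "+", r2_start, True, rng, cfg,
                )
                r2 = _read_record(
                    read_id, gene.chrom, r2_start, cfg.read_length_bp, seq,
                    "-", start, False, rng, r2_cfg,
                )
                emit = [r1, r2]
                if cfg.duplicate_rate > 0 and rng.random() < cfg.duplicate_rate:
                    counter += 1
                    dup_id = f"{sample_id}.f{counter:07d}"
                    for r in (r1, r2):
                        emit.append(replace_read_id(r, dup_id))
                    truth_rows.append((dup_id, gene_id, allele))
                records.extend(emit)
                truth_rows.append((read_id, gene_id, allele))
    records.sort(key=lambda r: (r.chrom, r.pos))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "gene_id", "allele"])
    return records, truth


def replace_read_id(rec: AlignmentRecord, read_id: str) -> AlignmentRecord:
    return AlignmentRecord(
        read_id, rec.chrom, rec.pos, list(rec.cigar), rec.seq, rec.strand,
        rec.mate_pos, rec.is_first_mate,
    )


def simulate_peaks(
    cfg: SimConfig,
    truth_genes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> list[Interval]:
    """Peaks near imprinted genes and decoys far from biallelic genes.

    Imprinted genes get a peak whose gap to the gene span is uniform in
    [0, peak_near_max_bp]; biallelic genes get a decoy at least
    peak_far_min_bp away, placed on whichever side of the gene has room.
    On chromosomes too short for the far rule the decoy gap is clamped to
    the largest gap that fits, so tiny fixtures remain valid (the near/far
    contrast then shrinks accordingly).
    """
    rng = rng or cfg.rng()
    peaks: list[Interval] = []
    for gene_id, row in truth_genes.iterrows():
        imprinted = row["class"] in ("maternal", "paternal")
        if imprinted:
            gap = int(rng.integers(0, cfg.peak_near_max_bp + 1))
        else:
            gap = cfg.peak_far_min_bp + int(rng.integers(0, cfg.peak_far_span_bp + 1))
        right_room = cfg.chrom_length_bp - int(row["end"]) - cfg.peak_width_bp
        left_room = int(row["start"]) - cfg.peak_width_bp
        if max(right_room, left_room) < 0:
            raise ValueError(f"{gene_id}: chromosome too short to place any peak")
        gap = min(gap, max(right_room, left_room))
        if gap <= right_room:
            start = int(row["end"]) + gap
        else:
            start = int(row["start"]) - gap - cfg.peak_width_bp
        peaks.append(
            Interval(row["chrom"], start, start + cfg.peak_width_bp, f"peak_{gene_id}")
        )
    return sorted(peaks, key=lambda p: (p.chrom, p.start))


def synthetic_chipseq_catalogs(
    n_a: int = 544,
    n_b: int = 6986,
    n_overlap: int = 457,
    rng: np.random.Generator | None = None,
    chrom: str = "chr1",
) -> tuple[list[Interval], list[Interval]]:
    """Synthetic stand-in for a pair of ChIP-seq peak catalogs.

    Builds two peak sets with the catalog sizes of the analysed ZFP57 /
    KAP1 experiment (544 and 6986 peaks) in which exactly ``n_overlap`` of
    the first set's peaks overlap the second set (457 in that experiment).
    The real deposited coordinates are not redistributable here, so this
    emulates only the set geometry: slot positions are jittered but overlap
    relations are planted exactly.
    """
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed either catalog size")
    rng = rng or np.random.default_rng(0)
    slot = 10_000
    width = 400
    a_peaks: list[Interval] = []
    b_peaks: list[Interval] = []
    n_slots = n_a + (n_b - n_overlap)
    offsets = rng.integers(0, 2_000, size=n_slots)
    s = 0
    for i in range(n_a):
        base = s * slot + int(offsets[s])
        a_peaks.append(Interval(chrom, base, base + width, f"setA_{i + 1}"))
        if i < n_overlap:  # plant a partner peak overlapping this one
            b_peaks.append(
                Interval(chrom, base + width // 2, base + width // 2 + width, f"setB_ov{i + 1}")
            )
        s += 1
    for i in range(n_b - n_overlap):
        base = s * slot + int(offsets[s])
        b_peaks.append(Interval(chrom, base, base + width, f"setB_{i + 1}"))
        s += 1
    return a_peaks, b_peaks


def write_dataset(cfg: SimConfig, out_dir) -> dict[str, Path]:
    """Materialize one full simulated dataset as plain-text files.

    Writes reference FASTA, SNP VCF, per-sample SAM, gene GTF, peak BED,
    sample sheet and truth-manifest TSVs; returns the paths.
    """
    from .allele_split import write_sam

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()
    reference, snps = simulate_genomes(cfg, rng)
    genes = place_genes(cfg, rng)
    truth_genes = assign_gene_truth(cfg, genes, rng)
    bulk, mat, pat, manifest = simulate_counts(cfg, truth_genes, rng)
    peaks_list = simulate_peaks(cfg, truth_genes, rng)

    paths: dict[str, Path] = {}
    paths["fasta"] = out / "reference.fa"
    write_fasta(reference, paths["fasta"])
    paths["vcf"] = out / "snps.vcf"
    write_vcf(snps, paths["vcf"], {g.name: len(g) for g in reference})
    paths["gtf"] = out / "genes.gtf"
    _write_gtf(genes, paths["gtf"])
    paths["bed"] = out / "peaks.bed"
    from .peaks import write_bed

    write_bed(peaks_list, paths["bed"])
    contigs = {g.name: len(g) for g in reference}
    frag_truth_frames = []
    for sample in cfg.sample_ids:
        frag_counts = pd.DataFrame(
            {"mat": mat.counts[sample], "pat": pat.counts[sample]}
        )
        records, truth = simulate_alignments(
            cfg, reference, snps, genes, frag_counts, rng, sample_id=sample
        )
        paths[f"sam_{sample}"] = out / f"{sample}.sam"
        write_sam(records, paths[f"sam_{sample}"], contigs)
        truth["sample"] = sample
        frag_truth_frames.append(truth)
    paths["sample_sheet"] = out / "samples.tsv"
    pd.DataFrame(
        {"sample_id": cfg.sample_ids, "condition": cfg.conditions}
    ).to_csv(paths["sample_sheet"], sep="\t", index=False)
    paths["gene_truth"] = out / "truth_genes.tsv"
    truth_genes.to_csv(paths["gene_truth"], sep="\t")
    paths["fragment_truth"] = out / "truth_fragments.tsv"
    pd.concat(frag_truth_frames).to_csv(paths["fragment_truth"], sep="\t", index=False)
    return paths


def _write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
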