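"""Fragment counting, expression filters and normalization.

Counting follows featureCounts paired-end defaults: a fragment is assigned
to a gene if at least one aligned base of either mate overlaps the gene's
exon union, mates count once together, and fragments hitting the exons of
more than one gene are discarded as ambiguous.

Normalization is the median-of-ratios size factor: for sample j,
``s_j = median_i(K_ij / g_i)`` over reference genes, where ``g_i`` is the
geometric mean of gene i's counts across samples and reference genes are
those with ``g_i > 0`` (i.e. nonzero in every sample). Because maternal and
paternal reads of one library are sequenced together, allele-resolved
counts are divided by the *bulk* size factor of their sample, which leaves
the within-sample allelic ratio unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .allele_split import AlignmentRecord
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """A gene reduced to its exon union on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, disjoint

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        self.exons = union_intervals(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """0-based transcription start: leftmost base on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end - 1


def union_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a disjoint union."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"invalid interval [{start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


@dataclass
class CountMatrix:
    """Genes x samples fragment counts for one layer.

    ``layer`` distinguishes BULK (all fragments) from the allele-resolved
    MATERNAL/PATERNAL matrices, which share the bulk matrix's gene and
    sample indices. ``gene_info`` optionally carries per-gene metadata
    (``chrom`` is needed for the X-chromosome filter).
    """

    counts: pd.DataFrame
    layer: str = "BULK"
    gene_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gene_info is not None:
            self.gene_info = self.gene_info.reindex(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        info = self.gene_info.loc[gene_ids] if self.gene_info is not None else None
        return CountMatrix(self.counts.loc[gene_ids].copy(), self.layer, info)


# --- gene model input -------------------------------------------------------

def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GTF (``gene_id`` attribute) or BED12.

    Exons of transcripts sharing a gene_id are merged into one exon union.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        return _read_gtf(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model format: {path.name} (expected .gtf or .bed)")


def _read_gtf(path: Path) -> list[GeneModel]:
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: GTF lacks gene_id attributes")
    exons = df[df["Feature"] == "exon"]
    if exons.empty:  # gene-only GTF: treat gene spans as single exons
        exons = df[df["Feature"] == "gene"]
    models = []
    for gene_id, grp in exons.groupby("gene_id", sort=True):
        models.append(
            GeneModel(
                gene_id=str(gene_id),
                chrom=str(grp["Chromosome"].iloc[0]),
                strand=str(grp["Strand"].iloc[0]),
                exons=[(int(s), int(e)) for s, e in zip(grp["Start"], grp["End"])],
            )
        )
    return models


def _read_bed12(path: Path) -> list[GeneModel]:
    by_gene: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            if name in by_gene:
                prev = by_gene[name]
                prev.exons = union_intervals(prev.exons + exons)
            else:
                by_gene[name] = GeneModel(name, chrom, strand, exons)
    return sorted(by_gene.values(), key=lambda g: g.gene_id)


# --- counting ---------------------------------------------------------------

def count_fragments(
    fragments: Sequence[tuple[AlignmentRecord, AlignmentRecord | None]],
    genes: Sequence[GeneModel],
    sample_id: str = "sample",
    layer: str = "BULK",
) -> CountMatrix:
    """Count fragments against exon unions (featureCounts -p semantics).

    A fragment counts once for a gene if >= 1 aligned base of either mate
    overlaps the gene's exon union; fragments overlapping exons of more
    than one gene are discarded as ambiguous.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for start, end in gene.exons:
            tree.addi(start, end, gene.gene_id)

    counts = {g.gene_id: 0 for g in genes}
    ambiguous = 0
    for r1, r2 in fragments:
        hit: set[str] = set()
        for rec in (r1, r2):
            if rec is None:
                continue
            tree = trees.get(rec.chrom)
            if tree is None:
                continue
            for s, e in rec.aligned_blocks():
                for iv in tree.overlap(s, e):
                    hit.add(iv.data)
        if len(hit) == 1:
            counts[hit.pop()] += 1
        elif len(hit) > 1:
            ambiguous += 1
    if ambiguous:
        logger.info("count_fragments[%s]: %d ambiguous fragments discarded", sample_id, ambiguous)
    df = pd.DataFrame({sample_id: pd.Series(counts)}).sort_index()
    info = pd.DataFrame(
        {"chrom": {g.gene_id: g.chrom for g in genes}}
    ).sort_index()
    return CountMatrix(df, layer, info)


def combine_samples(matrices: Sequence[CountMatrix]) -> CountMatrix:
    """Column-bind per-sample count matrices sharing one gene index."""
    df = pd.concat([m.counts for m in matrices], axis=1)
    if df.isna().any().any():
        raise ValueError("samples have different gene indices")
    return CountMatrix(df, matrices[0].layer, matrices[0].gene_info)


# --- filters & normalization ------------------------------------------------

def filter_low_expression(bulk: CountMatrix, cfg: PipelineConfig) -> CountMatrix:
    """Drop genes with total count <= min_bulk_count and excluded chromosomes.

    The low-count cutoff is strict: a gene survives only with more than
    ``min_bulk_count`` fragments summed over all samples of the comparison.
    """
    keep = bulk.counts.sum(axis=1) > cfg.min_bulk_count
    if bulk.gene_info is not None and "chrom" in bulk.gene_info:
        keep &= ~bulk.gene_info["chrom"].isin(cfg.excluded_chroms)
    return bulk.subset_genes(list(bulk.counts.index[keep]))


def estimate_size_factors(bulk: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with nonzero counts in every sample (positive
    geometric mean). Raises if no gene qualifies.
    """
    mat = bulk.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(mat)
    finite = np.isfinite(log_counts).all(axis=1)
    if not finite.any():
        raise ValueError(
            "no reference gene: every gene has a zero count in some sample"
        )
    log_geomean = log_counts[finite].mean(axis=1)
    log_ratios = log_counts[finite] - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=bulk.counts.columns, name="size_factor")


def normalize_counts(mat: CountMatrix, size_factors: pd.Series) -> CountMatrix:
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    sf = size_factors.reindex(mat.counts.columns)
    if sf.isna().any():
        raise ValueError("size factors missing for some samples")
    return CountMatrix(mat.counts / sf, mat.layer, mat.gene_info)


def normalize_allelic_counts(
    maternal: CountMatrix, paternal: CountMatrix, size_factors: pd.Series
) -> tuple[CountMatrix, CountMatrix]:
    """Divide both allelic layers by their sample's bulk size factor.

    Both parental alleles of a sample share one divisor, so per-gene
    allelic ratios are unchanged by normalization.
    """
    if list(maternal.counts.columns) != list(paternal.counts.columns):
        raise ValueError("maternal and paternal layers must share sample indices")
    return (
        normalize_counts(maternal, size_factors),
        normalize_counts(paternal, size_factors),
    )


def filter_allelic(
    norm_maternal: CountMatrix,
    norm_paternal: CountMatrix,
    wt_sample_ids: Sequence[str],
    cfg: PipelineConfig,
) -> list[str]:
    """Genes retained for allelic analysis.

    A gene is removed only when maternal+paternal normalized counts fall
    below ``min_allelic_norm`` in *every* wild-type replicate; one
    sufficiently covered replicate keeps it.
    """
    if len(wt_sample_ids) == 0:
        raise ValueError("wt_sample_ids must be non-empty")
    total = norm_maternal.counts[list(wt_sample_ids)] + norm_paternal.counts[
        list(wt_sample_ids)
    ]
    keep = (total >= cfg.min_allelic_norm).any(axis=1)
    return list(total.index[keep])


def marker_zscores(bulk: CountMatrix, reference_gene_id: str) -> pd.DataFrame:
    """Upper-quartile + reference-gene adjusted per-gene Z-scores.

    Per sample: divide counts by the sample's upper quartile over genes
    with nonzero count, then by the adjusted expression of the reference
    gene (e.g. beta-actin) in that sample; finally Z-score each gene across
    samples (ddof=1). Genes with zero spread get a zero row.
    """
    counts = bulk.counts.astype(float)
    if reference_gene_id not in counts.index:
        raise ValueError(f"reference gene {reference_gene_id!r} not in matrix")
    uq = counts.apply(lambda col: np.percentile(col[col > 0], 75), axis=0)
    if (counts.loc[reference_gene_id] <= 0).any():
        raise ValueError(
            f"reference gene {reference_gene_id!r} has a zero count in some sample"
        )
    adj = counts / uq
    adj = adj / adj.loc[reference_gene_id]
    mean = adj.mean(axis=1)
    sd = adj.std(axis=1, ddof=1)
    z = adj.sub(mean, axis=0).div(sd, axis=0)
    flat = sd == 0
    if flat.any():
        logger.warning("marker_zscores: %d gene(s) constant after adjustment; Z set to 0", int(flat.sum()))
        z.loc[flat] = 0.0
    return z


# --- TSV I/O ----------------------------------------------------------------

def write_counts(mat: CountMatrix, path) -> None:
    mat.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path, layer: str = "BULK") -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return CountMatrix(df, layer)
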