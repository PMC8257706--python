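"""Peak-interval operations and distance-distribution statistics.

Supports the ChIP-seq side of the analysis: intersecting two peak catalogs
(e.g. a zinc-finger protein and its corepressor) to obtain high-confidence
binding sites, computing each gene's distance to the nearest peak (0 when
the gene span overlaps a peak; the whole gene span is the anchor, as in
``bedtools closest``), and comparing two distance distributions with the
two-sample Kolmogorov-Smirnov test on their empirical CDFs.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .quantify import GeneModel


@dataclass(frozen=True)
class Interval:
    """A BED-style genomic interval: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )


@dataclass
class DistanceResult:
    gene_id: str
    distance_bp: int | None  # None: no peak on the gene's chromosome
    nearest_peak: Interval | None


@dataclass(frozen=True)
class KsResult:
    D: float
    p_value: float


def read_bed(path) -> list[Interval]:
    """Read BED3/BED6 intervals (name column kept when present)."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = f[3] if len(f) > 3 else None
            intervals.append(Interval(f[0], int(f[1]), int(f[2]), name))
    return intervals


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def intersect_peaks(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[Interval]:
    """Members of ``a`` overlapping >= 1 bp of any member of ``b``.

    Each a-peak is reported at most once (``bedtools intersect -u``
    semantics). Half-open abutment is not overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in b:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return [
        iv
        for iv in a
        if iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end)
    ]


def _gene_span(gene: GeneModel | Interval) -> tuple[str, int, int, str]:
    if isinstance(gene, GeneModel):
        return gene.chrom, gene.start, gene.end, gene.gene_id
    return gene.chrom, gene.start, gene.end, gene.name or f"{gene.chrom}:{gene.start}-{gene.end}"


def nearest_peak_distance(
    genes: Sequence[GeneModel | Interval], peaks: Sequence[Interval]
) -> list[DistanceResult]:
    """Distance from each gene span to its closest peak on the same chromosome.

    Overlap gives distance 0; otherwise the gap in bp between the half-open
    spans. Genes on chromosomes without peaks get distance None.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    starts: dict[str, list[int]] = {}
    pmax_end: dict[str, list[int]] = {}  # prefix max of peak ends, by start order
    argmax_end: dict[str, list[int]] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: (p.start, p.end))
        starts[chrom] = [p.start for p in plist]
        pm, am, best_end, best_i = [], [], -1, -1
        for i, p in enumerate(plist):
            if p.end > best_end:
                best_end, best_i = p.end, i
            pm.append(best_end)
            am.append(best_i)
        pmax_end[chrom] = pm
        argmax_end[chrom] = am

    results: list[DistanceResult] = []
    for gene in genes:
        chrom, g_start, g_end, gene_id = _gene_span(gene)
        plist = by_chrom.get(chrom)
        if not plist:
            results.append(DistanceResult(gene_id, None, None))
            continue
        idx = bisect_left(starts[chrom], g_end)
        best: tuple[int, Interval] | None = None
        if idx > 0:
            # among peaks starting left of the gene end, only the largest end
            # matters: it either overlaps the gene or leaves the smallest gap
            i = argmax_end[chrom][idx - 1]
            p = plist[i]
            best = (max(g_start - p.end, 0), p)
        if idx < len(plist) and (best is None or best[0] > 0):
            p = plist[idx]  # first peak starting at/after the gene end
            gap = p.start - g_end
            if best is None or gap < best[0]:
                best = (gap, p)
        results.append(DistanceResult(gene_id, best[0], best[1]))
    return results


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test on empirical CDFs.

    D is the supremum of |ECDF_x - ECDF_y|; the p-value uses the asymptotic
    Kolmogorov distribution at effective size nx*ny/(nx+ny).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return KsResult(D=float(res.statistic), p_value=float(min(res.pvalue, 1.0)))


def within_distance(
    distances: Sequence[DistanceResult], threshold_bp: int
) -> list[str]:
    """Genes strictly closer than ``threshold_bp`` to a peak (NA excluded)."""
    if threshold_bp <= 0:
        raise ValueError("threshold must be positive")
    return [
        d.gene_id
        for d in distances
        if d.distance_bp is not None and d.distance_bp < threshold_bp
    ]


def distance_table(distances: Sequence[DistanceResult]) -> pd.DataFrame:
    rows = []
    for d in distances:
        rows.append(
            {
                "gene_id": d.gene_id,
                "distance_bp": d.distance_bp if d.distance_bp is not None else np.nan,
                "nearest_peak": (
                    f"{d.nearest_peak.chrom}:{d.nearest_peak.start}-{d.nearest_peak.end}"
                    if d.nearest_peak
                    else ""
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def ecdf_points(sample: Sequence[float]) -> pd.DataFrame:
    """Sorted (value, ECDF) pairs, e.g. for plotting cumulative distances."""
    arr = np.sort(np.asarray(list(sample), dtype=float))
    return pd.DataFrame(
        {"value": arr, "ecdf": np.arange(1, arr.size + 1) / arr.size}
    )
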