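"""End-to-end orchestration from count matrices to the integration table.

`run_ase_workflow` reproduces the analysis chain on any bulk + allelic
count matrices: low-count and X-chromosome filtering, median-of-ratios
size factors from bulk, shared-divisor normalization of the allelic
layers, the wild-type allelic filter, per-condition ASE classification
(significance required for wild-type imprinting calls), wild-type -> mutant
transition calls, NB Wald differential expression, and the joined
integration table of every wild-type imprinted gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import ase as ase_mod
from .ase import AllelicClass, AseResult, ImprintingComparison
from .config import PipelineConfig, DEFAULT_CONFIG
from .de_integration import DeResult, IntegrationRecord, integrate_table, nb_wald_de
from .quantify import (
    CountMatrix,
    estimate_size_factors,
    filter_allelic,
    filter_low_expression,
    normalize_allelic_counts,
)


@dataclass
class AseWorkflowResult:
    size_factors: pd.Series
    tested_genes: list[str]
    wt_ase: dict[str, AseResult]
    mut_ase: dict[str, AseResult]
    comparisons: dict[str, ImprintingComparison]
    de: dict[str, DeResult]
    integration: list[IntegrationRecord]


def run_ase_workflow(
    bulk: CountMatrix,
    maternal: CountMatrix,
    paternal: CountMatrix,
    wt_samples: Sequence[str],
    mut_samples: Sequence[str],
    cfg: PipelineConfig = DEFAULT_CONFIG,
    require_wt_significance: bool = True,
    delta: float = 0.1,
    domain_labels: Mapping[str, str] | None = None,
) -> AseWorkflowResult:
    """Run the full imprinting-loss analysis on one experiment."""
    wt_samples = list(wt_samples)
    mut_samples = list(mut_samples)

    filtered_bulk = filter_low_expression(bulk, cfg)
    kept = filtered_bulk.gene_ids
    maternal = maternal.subset_genes(kept)
    paternal = paternal.subset_genes(kept)

    size_factors = estimate_size_factors(filtered_bulk)
    norm_mat, norm_pat = normalize_allelic_counts(maternal, paternal, size_factors)
    allelic_genes = filter_allelic(norm_mat, norm_pat, wt_samples, cfg)

    nm = norm_mat.counts.loc[allelic_genes]
    np_ = norm_pat.counts.loc[allelic_genes]
    rm = maternal.counts.loc[allelic_genes]
    rp = paternal.counts.loc[allelic_genes]
    wt_ase = ase_mod.compute_ase(
        nm, np_, rm, rp, wt_samples, cfg, require_significance=require_wt_significance
    )
    mut_ase = ase_mod.compute_ase(
        nm, np_, rm, rp, mut_samples, cfg, require_significance=False
    )

    comparisons: dict[str, ImprintingComparison] = {}
    for gene_id, wt in wt_ase.items():
        if wt.allelic_class in (AllelicClass.MATERNAL, AllelicClass.PATERNAL):
            comparisons[gene_id] = ase_mod.compare_conditions(
                wt, mut_ase[gene_id], cfg, delta=delta
            )

    labels = ["WT" if s in wt_samples else "MUT" for s in filtered_bulk.sample_ids]
    de = nb_wald_de(filtered_bulk, labels, size_factors, cfg, reference="WT")

    integration = integrate_table(de, wt_ase, comparisons, domain_labels)
    return AseWorkflowResult(
        size_factors=size_factors,
        tested_genes=allelic_genes,
        wt_ase=wt_ase,
        mut_ase=mut_ase,
        comparisons=comparisons,
        de=de,
        integration=integration,
    )
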