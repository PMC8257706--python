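"""Allelic ratios, imbalance testing and imprinting classification.

The allelic ratio of a gene is maternal / (maternal + paternal) normalized
counts, computed per replicate and averaged; 0.5 means biallelic
expression. Genes with mean ratio <= tau_pat (default 0.33) are classified
paternally expressed, >= tau_mat (default 0.67) maternally expressed —
boundaries inclusive.

Allelic imbalance is tested per gene with a two-sided proportion test of
H0: maternal fraction = 0.5 on the *raw* allelic counts pooled across
replicates (a proportion test needs integers; size-factor normalization
rescales totals but not within-sample proportions), followed by
Benjamini-Hochberg correction across genes. Imprinting loss is called by
comparing the wild-type and mutant classifications of each wild-type
monoallelic gene.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig, DEFAULT_CONFIG


class AllelicClass(enum.Enum):
    MATERNAL = "Maternal"
    PATERNAL = "Paternal"
    BIALLELIC = "Biallelic"
    NA = "NA"


class Transition(enum.Enum):
    """Wild-type -> mutant change in allelic status of an imprinted gene."""

    BIALLELIC_IN_MUTANT = "Biallelic"
    BIAS_REDUCED = "All. bias reduced"
    BIAS_INVERTED = "All. bias inverted"
    UNCHANGED = "Unchanged"
    NOT_TESTABLE = "Not testable"


@dataclass
class AseResult:
    gene_id: str
    per_replicate_ratios: list[float]
    mean_ratio: float  # NaN when no replicate is informative
    pooled_mat: int
    pooled_pat: int
    p_value: float
    q_value: float
    allelic_class: AllelicClass


@dataclass
class ImprintingComparison:
    gene_id: str
    wt_class: AllelicClass
    mut_class: AllelicClass
    transition: Transition


def allelic_ratio(
    mat_counts: Sequence[float], pat_counts: Sequence[float]
) -> tuple[list[float], float]:
    """Per-replicate maternal ratios and their mean.

    Replicates with zero total are excluded from the mean (their ratio is
    NaN); if every replicate is zero the mean is NaN.
    """
    mat = np.asarray(mat_counts, dtype=float)
    pat = np.asarray(pat_counts, dtype=float)
    if mat.shape != pat.shape:
        raise ValueError("maternal and paternal replicate vectors differ in length")
    if (mat < 0).any() or (pat < 0).any():
        raise ValueError("allelic counts must be non-negative")
    total = mat + pat
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(total > 0, mat / total, np.nan)
    informative = ratios[~np.isnan(ratios)]
    mean = float(informative.mean()) if informative.size else float("nan")
    return [float(r) for r in ratios], mean


def classify_allelic(
    mean_ratio: float,
    q_value: float = float("nan"),
    cfg: PipelineConfig = DEFAULT_CONFIG,
    require_significance: bool = False,
) -> AllelicClass:
    """Band classification of a mean allelic ratio.

    Ratios at exactly tau_pat/tau_mat are monoallelic (inclusive bounds).
    With ``require_significance``, a monoallelic call additionally needs
    q < alpha, otherwise it is downgraded to BIALLELIC.
    """
    if mean_ratio is None or math.isnan(mean_ratio):
        return AllelicClass.NA
    if not 0.0 <= mean_ratio <= 1.0:
        raise ValueError(f"mean ratio must be in [0, 1], got {mean_ratio}")
    if mean_ratio <= cfg.tau_pat:
        call = AllelicClass.PATERNAL
    elif mean_ratio >= cfg.tau_mat:
        call = AllelicClass.MATERNAL
    else:
        return AllelicClass.BIALLELIC
    if require_significance and not (q_value < cfg.alpha):
        return AllelicClass.BIALLELIC
    return call


def proportion_test(
    pooled_mat: int,
    pooled_pat: int,
    method: Literal["exact", "chisq"] = "exact",
) -> float:
    """Two-sided test of H0: maternal proportion = 0.5.

    ``exact`` doubles the smaller exact binomial tail (capped at 1);
    ``chisq`` is the one-sample chi-square test with continuity correction.
    Returns NaN for a zero total.
    """
    m, n = int(pooled_mat), int(pooled_mat) + int(pooled_pat)
    if pooled_mat < 0 or pooled_pat < 0:
        raise ValueError("pooled counts must be non-negative integers")
    if n == 0:
        return float("nan")
    if method == "exact":
        lower = stats.binom.cdf(m, n, 0.5)
        upper = stats.binom.sf(m - 1, n, 0.5)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "chisq":
        diff = abs(m - n / 2.0)
        diff = max(diff - 0.5, 0.0)  # continuity correction
        chi2 = diff**2 / (n / 4.0)
        return float(stats.chi2.sf(chi2, df=1))
    raise ValueError(f"unknown method {method!r}")


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    NaN entries (untestable genes) are passed through as NaN and do not
    count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def compute_ase(
    norm_mat: pd.DataFrame,
    norm_pat: pd.DataFrame,
    raw_mat: pd.DataFrame,
    raw_pat: pd.DataFrame,
    sample_ids: Sequence[str],
    cfg: PipelineConfig = DEFAULT_CONFIG,
    require_significance: bool = False,
    method: Literal["exact", "chisq"] = "exact",
) -> dict[str, AseResult]:
    """Per-gene ASE results for one condition's replicates.

    Ratios use normalized allelic counts; the proportion test pools the raw
    integer counts of the same replicates. BH correction runs across all
    genes with a testable p-value.
    """
    samples = list(sample_ids)
    genes = list(norm_mat.index)
    ratios: dict[str, tuple[list[float], float]] = {}
    pooled: dict[str, tuple[int, int]] = {}
    pvals = []
    for g in genes:
        r = allelic_ratio(
            norm_mat.loc[g, samples].to_numpy(), norm_pat.loc[g, samples].to_numpy()
        )
        ratios[g] = r
        pm = int(round(raw_mat.loc[g, samples].sum()))
        pp = int(round(raw_pat.loc[g, samples].sum()))
        pooled[g] = (pm, pp)
        pvals.append(proportion_test(pm, pp, method=method))
    qvals = adjust_bh(pvals)
    results: dict[str, AseResult] = {}
    for g, p, q in zip(genes, pvals, qvals):
        per_rep, mean = ratios[g]
        pm, pp = pooled[g]
        results[g] = AseResult(
            gene_id=g,
            per_replicate_ratios=per_rep,
            mean_ratio=mean,
            pooled_mat=pm,
            pooled_pat=pp,
            p_value=float(p),
            q_value=float(q),
            allelic_class=classify_allelic(mean, q, cfg, require_significance),
        )
    return results


def compare_conditions(
    wt: AseResult,
    mut: AseResult,
    cfg: PipelineConfig = DEFAULT_CONFIG,
    delta: float = 0.1,
) -> ImprintingComparison:
    """Call the wild-type -> mutant imprinting transition for one gene.

    Requires the wild-type call to be monoallelic. A mutant ratio inside
    the biallelic band is full loss of imprinting; outside the band, a
    flip across 0.5 by more than ``delta`` is an inverted bias, a move
    toward 0.5 by more than ``delta`` in the same direction is a reduced
    bias, anything else is unchanged.
    """
    if wt.allelic_class not in (AllelicClass.MATERNAL, AllelicClass.PATERNAL):
        raise ValueError(
            f"{wt.gene_id}: condition comparison requires a monoallelic "
            f"wild-type call, got {wt.allelic_class.value}"
        )
    if mut is None or math.isnan(mut.mean_ratio):
        mut_class = mut.allelic_class if mut is not None else AllelicClass.NA
        return ImprintingComparison(wt.gene_id, wt.allelic_class, mut_class, Transition.NOT_TESTABLE)
    wt_r, mut_r = wt.mean_ratio, mut.mean_ratio
    if cfg.tau_pat < mut_r < cfg.tau_mat:
        transition = Transition.BIALLELIC_IN_MUTANT
    elif (mut_r - 0.5) * (wt_r - 0.5) < 0 and abs(mut_r - 0.5) > delta:
        transition = Transition.BIAS_INVERTED
    elif (mut_r - 0.5) * (wt_r - 0.5) > 0 and abs(mut_r - 0.5) < abs(wt_r - 0.5) - delta:
        transition = Transition.BIAS_REDUCED
    else:
        transition = Transition.UNCHANGED
    return ImprintingComparison(wt.gene_id, wt.allelic_class, mut.allelic_class, transition)


def ase_table(results: dict[str, AseResult]) -> pd.DataFrame:
    """Flatten AseResults into a genes-indexed DataFrame for TSV export."""
    rows = {}
    for g, r in results.items():
        row = {
            f"ratio_rep{i + 1}": v for i, v in enumerate(r.per_replicate_ratios)
        }
        row.update(
            mean_ratio=r.mean_ratio,
            pooled_mat=r.pooled_mat,
            pooled_pat=r.pooled_pat,
            p_value=r.p_value,
            q_value=r.q_value,
            allelic_class=r.allelic_class.value,
        )
        rows[g] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
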