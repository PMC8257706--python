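"""Pipeline-wide thresholds and tunables.

All cutoffs used by the imprinting pipeline live in one dataclass so that
every stage reads the same conventions: bulk low-count filter (strict
``> min_bulk_count`` summed over all samples), allelic normalized-count
filter (``< min_allelic_norm`` in *every* wild-type replicate removes the
gene), the monoallelic classification bands (ratio ``<= tau_pat`` paternal,
``>= tau_mat`` maternal), the FDR level, and the peak-distance threshold.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for filtering, classification and significance.

    Attributes
    ----------
    min_bulk_count:
        A gene is kept only if its raw count summed across all samples is
        strictly greater than this (default 8).
    min_allelic_norm:
        A gene is removed if maternal+paternal normalized counts are below
        this in every wild-type replicate (default 10).
    tau_pat, tau_mat:
        Allelic-ratio bands: ratio <= tau_pat is paternal, >= tau_mat is
        maternal, anything between is biallelic.
    alpha:
        Adjusted-p significance level shared by the allelic proportion test
        and differential expression.
    distance_threshold_bp:
        "Near a binding site" cutoff for gene-to-peak distances (strict <).
    excluded_chroms:
        Chromosomes dropped before analysis (X by default: the hybrid ESC
        lines are male, so X genes have no meaningful allelic ratio).
    """

    min_bulk_count: int = 8
    min_allelic_norm: float = 10.0
    tau_pat: float = 0.33
    tau_mat: float = 0.67
    alpha: float = 0.05
    distance_threshold_bp: int = 100_000
    excluded_chroms: frozenset[str] = frozenset({"chrX"})

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_pat < 0.5 < self.tau_mat < 1.0):
            raise ValueError(
                f"classification bands must satisfy 0 < tau_pat < 0.5 < tau_mat < 1, "
                f"got tau_pat={self.tau_pat}, tau_mat={self.tau_mat}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        """Load thresholds from a TOML file; unspecified keys keep defaults."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "excluded_chroms" in raw:
            raw["excluded_chroms"] = frozenset(raw["excluded_chroms"])
        return cls(**raw)


DEFAULT_CONFIG = PipelineConfig()
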