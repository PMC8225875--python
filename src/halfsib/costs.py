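"""Per-cycle programme cost and cost per percentage genetic gain.

Unit costs are in New Zealand dollars: a destructive herbage cut, a phenomic
(LiDAR) measurement and a single GEBV (DNA isolation through genotyping and
prediction).  The fixed operational cost of running a cycle (trial management,
land, labour) is programme-specific and therefore a required config input with
no default.
"""
from __future__ import annotations

from dataclasses import dataclass

from .components import TrialDesign

__all__ = [
    "CostBook",
    "phenotyping_cost",
    "genotyping_cost",
    "cost_per_percent_gain",
    "program_cost",
]


@dataclass(frozen=True)
class CostBook:
    """Unit costs (NZ$) for the cost-per-gain model."""

    per_sample_cut: float = 7.50
    per_sample_phenomics: float = 0.87
    per_gebv: float = 41.0
    fixed_operational_per_cycle: float = 0.0

    def __post_init__(self) -> None:
        for name in ("per_sample_cut", "per_sample_phenomics", "per_gebv",
                     "fixed_operational_per_cycle"):
            if getattr(self, name) < 0:
                raise ValueError(f"cost {name!r} must be >= 0")


def phenotyping_cost(design: TrialDesign, per_sample: float) -> float:
    """Cost of phenotyping every plot of the trial once per season.

    One sample per family × replicate × location × season × year.
    """
    return design.n_plots * per_sample


def genotyping_cost(n_families_selected: int, n_genotyped_per_family: int,
                    per_gebv: float) -> float:
    """Cost of generating GEBVs for all genotyped candidates."""
    if n_families_selected < 0 or n_genotyped_per_family < 0:
        raise ValueError("counts must be >= 0")
    return n_families_selected * n_genotyped_per_family * per_gebv


def cost_per_percent_gain(total_cost: float, pct_gain: float) -> float:
    """Dollars spent per percentage point of predicted genetic gain."""
    if pct_gain <= 0.0:
        raise ValueError(f"percent gain must be positive, got {pct_gain}")
    return total_cost / pct_gain


def program_cost(
    costs: CostBook,
    design: TrialDesign | None = None,
    phenomics: bool = False,
    n_families_selected: int = 0,
    n_genotyped_per_family: int = 0,
) -> float:
    """Total cycle cost: fixed + phenotyping + genotyping.

    ``design=None`` covers cycles with no field evaluation (purely genomic
    selection on seedlings).
    """
    total = costs.fixed_operational_per_cycle
    if design is not None:
        per_sample = costs.per_sample_phenomics if phenomics else costs.per_sample_cut
        total += phenotyping_cost(design, per_sample)
    total += genotyping_cost(n_families_selected, n_genotyped_per_family, costs.per_gebv)
    return total
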