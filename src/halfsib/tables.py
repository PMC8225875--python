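"""Gain-table assembly: one row per (strategy, pressures, accuracy) grid cell.

Mirrors the layout breeders use to compare schemes: percent gain per cycle,
absolute gain, programme cost, cost per percent gain and the number of
parents generated.
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .components import TrialDesign, VarianceComponents
from .costs import CostBook, genotyping_cost, phenotyping_cost
from .gain import SelectionScheme, Strategy, predict_gain

__all__ = ["gain_table", "scheme_cost"]

log = logging.getLogger("halfsib")


def scheme_cost(scheme: SelectionScheme, design: TrialDesign,
                costs: CostBook) -> float:
    """Per-cycle programme cost of one scheme.

    Field strategies pay the fixed cost plus one phenotype sample per plot
    (cut or phenomic rate); within-GS strategies additionally genotype
    ``n_genotyped_per_family`` candidates in each selected family.  The purely
    genomic ``A_gsWgs`` runs no field trial and genotypes candidates in every
    family before among-family selection.
    """
    s = scheme.strategy
    total = costs.fixed_operational_per_cycle
    if s is not Strategy.A_gsWgs:
        per_sample = (costs.per_sample_phenomics if s.uses_phenomics
                      else costs.per_sample_cut)
        total += phenotyping_cost(design, per_sample)
    if s.uses_within_gs:
        if s is Strategy.A_gsWgs:
            n_genotyped_fams = design.n_families
        else:
            n_genotyped_fams = max(1, round(design.n_families * scheme.p_among))
        total += genotyping_cost(n_genotyped_fams, scheme.n_genotyped_per_family,
                                 costs.per_gebv)
    return total


def gain_table(
    vc: VarianceComponents,
    design: TrialDesign,
    schemes: Iterable[SelectionScheme],
    base_mean: float,
    costs: Optional[CostBook] = None,
) -> pd.DataFrame:
    """Evaluate a grid of selection schemes into a tidy table.

    Invalid grid cells are skipped with a logged warning; if no cost book is
    given the cost columns are left blank.
    """
    schemes = list(schemes)
    if not schemes:
        raise ValueError("empty scheme grid")
    if costs is None:
        log.warning("no cost book supplied; cost columns will be blank")
    rows = []
    for scheme in schemes:
        try:
            res = predict_gain(vc, design, scheme, base_mean,
                               n_families=design.n_families)
        except ValueError as exc:
            log.warning("skipping grid cell %s: %s", scheme, exc)
            continue
        row = {
            "strategy": scheme.strategy.value,
            "p_among": scheme.p_among,
            "p_within": scheme.p_within,
            "r_accuracy": scheme.r_accuracy,
            "pct_gain_cycle": res.delta_g_pct,
            "gain_kg_ha": res.delta_g_abs,
            "pct_gain_year": res.annual_pct,
            "n_parents": res.n_parents,
        }
        if costs is not None:
            total = scheme_cost(scheme, design, costs)
            row["cost"] = total
            row["cost_per_pct"] = (total / res.delta_g_pct
                                   if res.delta_g_pct > 0 else np.inf)
        rows.append(row)
    if not rows:
        raise ValueError("no valid grid cells")
    return pd.DataFrame(rows)
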