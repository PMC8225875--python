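"""Synthetic inputs: mock half-sib trial records and founder populations.

``generate_trial`` simulates balanced long-format plot records under the same
linear mixed model the REML module fits — fixed location/season/year shifts
plus independent normal draws for the family, family×environment, replicate,
row, column and residual terms — so generated data can round-trip through
``fit_reml`` for parameter-recovery checks.

``make_genome``/``generate_founders``/``build_training_population`` create the
stochastic simulator's inputs: a seven-linkage-group map with 1807 biallelic
markers of which 474 are additive QTLs, founders drawn in linkage equilibrium
at uniform(0.1, 0.9) allele frequencies, and half-sib training populations of
196 or 980 plants built by polycrossing 98 founders.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .components import TrialDesign, VarianceComponents
from .genome import GenomeSpec, Population, polycross

__all__ = [
    "MockTrialSpec",
    "generate_trial",
    "make_genome",
    "generate_founders",
    "build_training_population",
]


@dataclass(frozen=True)
class MockTrialSpec:
    """Generating model for a balanced mock half-sib trial.

    ``components`` are the generating variances for family, family×year,
    family×season, family×location and the plot residual; ``rep_variance``,
    ``row_variance`` and ``col_variance`` default to zero.  ``fixed_effects``
    optionally maps ``location``/``season``/``year`` to per-level additive
    shifts (kg ha⁻¹).
    """

    design: TrialDesign
    components: VarianceComponents
    mean: float = 3262.0
    rep_variance: float = 0.0
    row_variance: float = 0.0
    col_variance: float = 0.0
    n_rows: int = 10
    fixed_effects: Optional[Mapping[str, Sequence[float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rep_variance", "row_variance", "col_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_trial(spec: MockTrialSpec, return_effects: bool = False):
    """Simulate balanced complete trial records from the mixed-model spec.

    Returns a long-format DataFrame with columns
    ``family, location, season, year, rep, row, col, value``; one plot per
    family in every (location, season, year, replicate).  With
    ``return_effects`` the drawn family effects are returned alongside, for
    recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.design
    vc = spec.components
    nf, nl, ns, ny, nr = (d.n_families, d.n_locations, d.n_seasons,
                          d.n_years, d.n_reps)

    fam_eff = rng.normal(0, np.sqrt(vc.family), nf)
    fl_eff = rng.normal(0, np.sqrt(vc.family_x_location), (nf, nl))
    fs_eff = rng.normal(0, np.sqrt(vc.family_x_season), (nf, ns))
    fy_eff = rng.normal(0, np.sqrt(vc.family_x_year), (nf, ny))
    rep_eff = rng.normal(0, np.sqrt(spec.rep_variance), (nl, ns, ny, nr))

    fixed = {k: np.zeros(n) for k, n in
             (("location", nl), ("season", ns), ("year", ny))}
    if spec.fixed_effects:
        for k, vals in spec.fixed_effects.items():
            fixed[k] = np.asarray(vals, dtype=float)
            if len(fixed[k]) != len({"location": range(nl), "season": range(ns),
                                     "year": range(ny)}[k]):
                raise ValueError(f"fixed effect {k!r} needs one value per level")

    # field layout: within each replicate, families fill an n_rows × n_cols
    # grid in a freshly randomised order
    n_rows = min(spec.n_rows, nf)
    n_cols = int(np.ceil(nf / n_rows))
    row_eff = rng.normal(0, np.sqrt(spec.row_variance), (nl, ns, ny, nr, n_rows))
    col_eff = rng.normal(0, np.sqrt(spec.col_variance), (nl, ns, ny, nr, n_cols))

    recs = []
    for l in range(nl):
        for s in range(ns):
            for yv in range(ny):
                for r in range(nr):
                    order = rng.permutation(nf)
                    rows, cols = np.divmod(np.arange(nf), n_cols)
                    fam = order
                    val = (
                        spec.mean
                        + fixed["location"][l] + fixed["season"][s] + fixed["year"][yv]
                        + fam_eff[fam] + fl_eff[fam, l] + fs_eff[fam, s] + fy_eff[fam, yv]
                        + rep_eff[l, s, yv, r]
                        + row_eff[l, s, yv, r, rows] + col_eff[l, s, yv, r, cols]
                        + rng.normal(0, np.sqrt(vc.residual), nf)
                    )
                    recs.append(pd.DataFrame({
                        "family": fam, "location": l, "season": s, "year": yv,
                        "rep": r, "row": rows, "col": cols, "value": val,
                    }))
    df = pd.concat(recs, ignore_index=True)
    df = df.sort_values(["family", "location", "season", "year", "rep"],
                        kind="mergesort").reset_index(drop=True)
    if return_effects:
        return df, fam_eff
    return df


def make_genome(
    n_linkage_groups: int = 7,
    n_markers: int = 1807,
    n_qtl: int = 474,
    group_length_cm: float = 100.0,
    target_additive_variance: float = 4.0 * 14170.0,
    freq_low: float = 0.1,
    freq_high: float = 0.9,
    seed: int = 0,
) -> GenomeSpec:
    """Build a synthetic genome with QTL effects scaled to a target variance.

    Markers are placed uniformly at random along equal-length linkage groups;
    ``n_qtl`` of them are QTLs with standard-normal effects rescaled so that
    the linkage-equilibrium additive variance Σ 2p(1−p)a² at the founding
    allele frequencies equals ``target_additive_variance``.  The sign of the
    drawn effect defines the favourable allele.
    """
    if n_qtl > n_markers:
        raise ValueError("n_qtl cannot exceed n_markers")
    rng = np.random.default_rng(seed)
    per_group = np.full(n_linkage_groups, n_markers // n_linkage_groups)
    per_group[: n_markers % n_linkage_groups] += 1
    group = np.repeat(np.arange(n_linkage_groups), per_group)
    position = np.concatenate([
        np.sort(rng.uniform(0.0, group_length_cm, size=c)) for c in per_group
    ])
    freq = rng.uniform(freq_low, freq_high, size=n_markers)
    qtl_index = np.sort(rng.choice(n_markers, size=n_qtl, replace=False))
    raw = rng.standard_normal(n_qtl)
    favourable = (raw > 0).astype(int)
    mag = np.abs(raw)
    p1 = freq[qtl_index]
    p_fav = np.where(favourable == 1, p1, 1.0 - p1)
    var_unscaled = np.sum(2.0 * p_fav * (1.0 - p_fav) * mag ** 2)
    scale = np.sqrt(target_additive_variance / var_unscaled)
    return GenomeSpec(
        group=group, position=position, qtl_index=qtl_index,
        qtl_effect=mag * scale, favourable_allele=favourable,
        founder_freq=freq,
    )


def generate_founders(spec: GenomeSpec, n: int, seed: int) -> Population:
    """Draw ``n`` founders in Hardy–Weinberg and linkage equilibrium."""
    if n < 2:
        raise ValueError("at least two founders are required")
    if spec.founder_freq is None:
        raise ValueError("genome spec carries no founding allele frequencies")
    rng = np.random.default_rng(seed)
    haps = (rng.random((n, spec.n_markers, 2)) < spec.founder_freq[None, :, None])
    return Population(haplotypes=haps.astype(np.int8),
                      family=np.full(n, -1), cycle=0)


def build_training_population(founders: Population, spec: GenomeSpec,
                              draws_per_family: int, seed: int) -> Population:
    """Polycross all founders into half-sib families, keep ``draws_per_family``.

    Every founder mothers one family (pollen pool = all other founders), so 98
    founders with 2 or 10 draws per family give training populations of 196 or
    980 plants.
    """
    if draws_per_family < 1:
        raise ValueError("draws_per_family must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.arange(founders.n_individuals)
    return polycross(founders, idx, idx, draws_per_family, spec, rng, cycle=0)
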