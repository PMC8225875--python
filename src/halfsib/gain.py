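"""Deterministic prediction of genetic gain for half-sib family breeding strategies.

Implements the breeder's-equation family of predictions for one cycle of
truncation selection in a half-sib (HS) recurrent-selection programme, for five
strategies:

``A_p``
    among-family selection on phenotypic family means,
    ΔG = k_f · c_f · σ²_f / σ_PF   (σ²_f = among-HS-family variance = ¼σ²_A);
``A_Ph``
    as ``A_p`` but family means measured with a phenomic (LiDAR) tool of
    accuracy ρ, which scales the predicted gain by ρ;
``A_pWgs``
    among-family phenotypic selection plus within-family genomic selection,
    ΔG = k_f c_f σ²_f/σ_PF + k_w c_w h_X r_A (√3/2) σ_A;
``A_PhWgs``
    as ``A_pWgs`` with the phenomic accuracy multiplying the total;
``A_gsWgs``
    both stages on genomic estimated breeding values,
    ΔG = k_f c_f h_X r_A (1/2) σ_A + k_w c_w h_X r_A (√3/2) σ_A.

Here k are standardized selection intensities, c parental-control factors
(0.5 when selection acts through one gamete source), h_X the square root of the
heritability of the selection criterion (taken as 1 for GEBVs), r_A the
genomic prediction accuracy, σ_A the additive genetic standard deviation and
σ_PF the phenotypic standard deviation of family means.  The √3/2 factor is
sqrt(3/4): three quarters of the additive variance segregates within HS
families.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from scipy.stats import norm

from .components import TrialDesign, VarianceComponents

__all__ = [
    "Strategy",
    "SelectionScheme",
    "GainResult",
    "CycleChain",
    "selection_intensity",
    "family_mean_phenotypic_sd",
    "heritability_family_mean",
    "gain_among_phenotypic",
    "gain_within_gs",
    "predict_gain",
    "apply_phenomics",
    "chain_cycles",
    "parents_count",
]

SQRT3_2 = math.sqrt(3.0) / 2.0


class Strategy(str, enum.Enum):
    """The five half-sib breeding strategies."""

    A_p = "A_p"
    A_Ph = "A_Ph"
    A_pWgs = "A_pWgs"
    A_PhWgs = "A_PhWgs"
    A_gsWgs = "A_gsWgs"

    @property
    def uses_within_gs(self) -> bool:
        return self in (Strategy.A_pWgs, Strategy.A_PhWgs, Strategy.A_gsWgs)

    @property
    def uses_phenomics(self) -> bool:
        return self in (Strategy.A_Ph, Strategy.A_PhWgs)


def selection_intensity(p: float) -> float:
    """Standardized selection differential for truncating the upper fraction ``p``.

    For a standard normal trait, i = φ(Φ⁻¹(1−p)) / p — the mean of the selected
    upper tail.  Infinite-population form, no finite-sample (order-statistic)
    correction.

    Parameters
    ----------
    p : float
        Selected fraction, 0 < p <= 1.

    Returns
    -------
    float
        i >= 0, strictly decreasing in p, 0 at p = 1.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"selected fraction must be in (0, 1], got {p}")
    if p == 1.0:
        return 0.0
    z = norm.ppf(1.0 - p)
    return float(norm.pdf(z) / p)


def family_mean_phenotypic_sd(vc: VarianceComponents, design: TrialDesign) -> float:
    """Phenotypic standard deviation among HS family means, σ_PF (kg ha⁻¹).

    σ²_PF = σ²_f + σ²_fl/n_l + σ²_fs/n_s + σ²_fy/n_y + σ²_ε/(n_l·n_s·n_y·n_r).
    The residual is averaged over every plot of a family, i.e. over all
    locations, seasons, years and replicates.
    """
    var = (
        vc.family
        + vc.family_x_location / design.n_locations
        + vc.family_x_season / design.n_seasons
        + vc.family_x_year / design.n_years
        + vc.residual / (design.n_locations * design.n_seasons * design.n_years * design.n_reps)
    )
    return math.sqrt(var)


def heritability_family_mean(vc: VarianceComponents, design: TrialDesign) -> float:
    """Narrow-sense heritability on a family-mean basis, h²_n = σ²_f / σ²_PF."""
    denom = family_mean_phenotypic_sd(vc, design) ** 2
    if denom <= 0.0:
        raise ValueError("all variance components are zero; heritability undefined")
    return vc.family / denom


@dataclass(frozen=True)
class SelectionScheme:
    """Parameters of one cycle of selection under a given strategy.

    ``p_among``/``p_within`` are selected fractions in (0, 1]; ``r_accuracy``
    the genomic prediction accuracy r_A; ``h_x`` the square root of the
    heritability of the indirect selection criterion (1 for GEBVs);
    ``c_f``/``c_w`` parental-control factors; ``ph_accuracy`` the phenomic-tool
    accuracy used only by the phenomics strategies; ``cycle_years`` the length
    of the cycle in years; ``n_genotyped_per_family`` the number of individuals
    genotyped per selected family for within-family selection.
    """

    strategy: Strategy
    p_among: float
    p_within: Optional[float] = None
    r_accuracy: float = 0.0
    h_x: float = 1.0
    c_f: float = 0.5
    c_w: float = 0.5
    ph_accuracy: float = 0.90
    cycle_years: int = 3
    n_genotyped_per_family: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", Strategy(self.strategy))
        if not (0.0 < self.p_among <= 1.0):
            raise ValueError(f"p_among must be in (0, 1], got {self.p_among}")
        if self.p_within is not None and not (0.0 < self.p_within <= 1.0):
            raise ValueError(f"p_within must be in (0, 1], got {self.p_within}")
        for name in ("r_accuracy", "h_x", "ph_accuracy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cycle_years < 1:
            raise ValueError("cycle_years must be >= 1")
        if self.strategy.uses_within_gs and self.p_within is None:
            raise ValueError(f"strategy {self.strategy.value} requires p_within")


@dataclass(frozen=True)
class GainResult:
    """Predicted response to one cycle of selection.

    ``delta_g_abs`` in kg ha⁻¹, ``delta_g_pct`` as a percentage of
    ``base_mean``, ``annual_pct`` per year of the cycle.
    """

    delta_g_abs: float
    base_mean: float
    cycle_years: int = 3
    n_parents: Optional[int] = None

    @property
    def delta_g_pct(self) -> float:
        return 100.0 * self.delta_g_abs / self.base_mean

    @property
    def annual_pct(self) -> float:
        return self.delta_g_pct / self.cycle_years

    @property
    def next_base_mean(self) -> float:
        """Population mean after this cycle: base mean plus the absolute gain."""
        return self.base_mean + self.delta_g_abs


def gain_among_phenotypic(
    vc: VarianceComponents,
    design: TrialDesign,
    p_among: float,
    c_f: float = 0.5,
) -> float:
    """Absolute gain (kg ha⁻¹) from among-family phenotypic selection.

    ΔG = k_f · c_f · σ²_f / σ_PF, the half-sib family form of the breeder's
    equation (σ²_f being ¼ of the additive variance).
    """
    k_f = selection_intensity(p_among)
    return k_f * c_f * vc.family / family_mean_phenotypic_sd(vc, design)


def gain_within_gs(
    vc: VarianceComponents,
    p_within: float,
    r_accuracy: float,
    h_x: float = 1.0,
    c_w: float = 0.5,
) -> float:
    """Absolute gain (kg ha⁻¹) from within-family genomic selection.

    ΔG = k_w · c_w · h_X · r_A · (√3/2) · σ_A, exploiting the three quarters of
    additive variance segregating within half-sib families; linear in r_A.
    """
    k_w = selection_intensity(p_within)
    return k_w * c_w * h_x * r_accuracy * SQRT3_2 * vc.additive_sd


def _gain_among_gs(vc: VarianceComponents, p_among: float, r_accuracy: float,
                   h_x: float = 1.0, c_f: float = 0.5) -> float:
    """Among-family stage on family-mean GEBVs: k_f c_f h_X r_A (1/2) σ_A."""
    k_f = selection_intensity(p_among)
    return k_f * c_f * h_x * r_accuracy * 0.5 * vc.additive_sd


def predict_gain(
    vc: VarianceComponents,
    design: TrialDesign,
    scheme: SelectionScheme,
    base_mean: float,
    n_families: Optional[int] = None,
) -> GainResult:
    """Predict one cycle of gain for any of the five strategies.

    Parameters
    ----------
    vc, design
        Variance components and trial layout defining σ_PF.
    scheme
        Strategy and selection parameters.
    base_mean
        Population mean (kg ha⁻¹) the percent gain is expressed against —
        the current cycle's starting mean.
    n_families
        If given, the number of candidate families, used to report the number
        of parents generated.
    """
    if base_mean <= 0.0:
        raise ValueError("base_mean must be positive")
    s = scheme.strategy
    if s in (Strategy.A_p, Strategy.A_Ph):
        gain = gain_among_phenotypic(vc, design, scheme.p_among, scheme.c_f)
    elif s in (Strategy.A_pWgs, Strategy.A_PhWgs):
        gain = gain_among_phenotypic(vc, design, scheme.p_among, scheme.c_f)
        gain += gain_within_gs(vc, scheme.p_within, scheme.r_accuracy, scheme.h_x, scheme.c_w)
    else:  # A_gsWgs
        gain = _gain_among_gs(vc, scheme.p_among, scheme.r_accuracy, scheme.h_x, scheme.c_f)
        gain += gain_within_gs(vc, scheme.p_within, scheme.r_accuracy, scheme.h_x, scheme.c_w)
    if s.uses_phenomics:
        # the phenomic accuracy scales the whole predicted response, including
        # the within-family GS term of A_PhWgs
        gain *= scheme.ph_accuracy
    n_parents = None
    if n_families is not None:
        n_parents = parents_count(
            n_families,
            scheme.p_among,
            scheme.n_genotyped_per_family,
            scheme.p_within if s.uses_within_gs else None,
        )
    return GainResult(gain, base_mean, scheme.cycle_years, n_parents)


def apply_phenomics(result: GainResult, accuracy: float) -> GainResult:
    """Scale a predicted gain by the accuracy of a phenomic measurement tool."""
    if not (0.0 <= accuracy <= 1.0):
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    return replace(result, delta_g_abs=result.delta_g_abs * accuracy)


@dataclass(frozen=True)
class CycleChain:
    """Summary of chained selection cycles."""

    total_pct: float
    total_abs: float
    total_cost: Optional[float]
    base_means: tuple[float, ...]  # starting mean of each cycle plus the final mean


def chain_cycles(
    cycles: Sequence[GainResult],
    costs: Optional[Sequence[float]] = None,
    check_means: bool = True,
) -> CycleChain:
    """Chain consecutive selection cycles.

    Each cycle's base mean must equal the previous cycle's base mean plus its
    absolute gain (the progeny mean).  Percent gains are each relative to their
    own cycle's base mean and are summed to give the total percent gain; costs,
    if given, are summed.
    """
    if len(cycles) == 0:
        raise ValueError("at least one cycle is required")
    if costs is not None and len(costs) != len(cycles):
        raise ValueError("costs must align with cycles")
    if check_means:
        for prev, nxt in zip(cycles, cycles[1:]):
            if not math.isclose(nxt.base_mean, prev.next_base_mean, rel_tol=0, abs_tol=1.0):
                raise ValueError(
                    f"cycle base mean {nxt.base_mean} does not follow from "
                    f"previous mean + gain = {prev.next_base_mean:.2f}"
                )
    total_pct = sum(c.delta_g_pct for c in cycles)
    total_abs = sum(c.delta_g_abs for c in cycles)
    total_cost = float(sum(costs)) if costs is not None else None
    means = tuple(c.base_mean for c in cycles) + (cycles[-1].next_base_mean,)
    return CycleChain(total_pct, total_abs, total_cost, means)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def parents_count(
    n_families: int,
    p_among: float,
    n_genotyped_per_family: int = 100,
    p_within: Optional[float] = None,
) -> int:
    """Number of parents generated by one cycle of selection.

    Among-family selection keeps round(n_families × p_among) families.  For
    strategies with within-family selection, round(n_genotyped × p_within)
    individuals are kept per selected family; otherwise each selected family
    contributes one (randomly sampled) parent entry.  Rounding is half-up.
    """
    n_sel_fam = _round_half_up(n_families * p_among)
    if n_sel_fam < 1:
        raise ValueError("selection pressure leaves zero families selected")
    if p_within is None:
        return n_sel_fam
    n_within = _round_half_up(n_genotyped_per_family * p_within)
    if n_within < 1:
        raise ValueError("within-family selection pressure leaves zero individuals selected")
    return n_sel_fam * n_within
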