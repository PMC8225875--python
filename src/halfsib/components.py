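"""Core domain types shared across the deterministic engine, REML estimator and cost model.

Units follow the forage-trial convention: yields in kg ha⁻¹, variance components
in kg² ha⁻².
"""
from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class VarianceComponents:
    """Among-family and family-by-environment variance components of a half-sib trial.

    ``family`` is the among-half-sib-family component σ²_f; with non-inbred
    parents it estimates ¼ of the additive genetic variance.  The interaction
    components are family × year, family × season and family × location, and
    ``residual`` is the plot-level error variance.  All in kg² ha⁻².
    """

    family: float
    family_x_year: float
    family_x_season: float
    family_x_location: float
    residual: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0):
                raise ValueError(f"variance component {f.name!r} must be >= 0, got {v}")

    @property
    def additive_sd(self) -> float:
        """Additive genetic standard deviation σ_A = 2·sqrt(σ²_f).

        For half-sib families of non-inbred parents the among-family variance is
        ¼σ²_A, so σ_A = sqrt(4·σ²_f).
        """
        return 2.0 * self.family ** 0.5

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.family,
            self.family_x_year,
            self.family_x_season,
            self.family_x_location,
            self.residual,
        )


@dataclass(frozen=True)
class TrialDesign:
    """Evaluation layout of a multi-environment half-sib family trial."""

    n_locations: int
    n_seasons: int
    n_years: int
    n_reps: int
    n_families: int = 1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if int(v) != v or v < 1:
                raise ValueError(f"design count {f.name!r} must be an integer >= 1, got {v}")

    @property
    def n_plots_per_family(self) -> int:
        return self.n_locations * self.n_seasons * self.n_years * self.n_reps

    @property
    def n_plots(self) -> int:
        return self.n_plots_per_family * self.n_families
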