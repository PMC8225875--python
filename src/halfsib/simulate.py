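"""Multi-cycle stochastic simulation of half-sib recurrent selection.

Three strategies are simulated over repeated cycles of polycrossing,
family evaluation and truncation selection:

``A_p``     among-family selection on phenotypic family means; within-family
            parents sampled at random (a 3-year cycle);
``A_pWgs``  the same among-family step, but within-family parents ranked on
            their GEBVs from an rrBLUP model (3-year cycle);
``A_gsWgs`` both stages on GEBVs — family means of GEBVs among, individual
            GEBVs within (1-year cycle, no field evaluation).

The genomic prediction model is ridge-regression BLUP trained on the cycle-0
training population and, by default, never retrained, so its accuracy decays
as selection and recombination erode the genetic relationship between
training and selection candidates.  GEBVs carry calibrated noise so that the
squared correlation between the clean and reported score is the GEBV
reliability (default 0.95, representing genotyping error).

Per cycle the simulator tracks the population mean, percent gain per year,
cumulative gain, percent of cycle-0 genetic variance remaining, percent of
QTLs fixed for the favourable allele, and the realized prediction accuracy;
all averaged over independent iterations.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .gain import Strategy
from .genome import (GenomeSpec, Population, TraitModel, family_phenotype_means,
                     polycross, true_breeding_value)

__all__ = [
    "MarkerModel",
    "rrblup_train",
    "gebv",
    "StrategyConfig",
    "CycleRecord",
    "BreedingProgram",
    "SimulationResults",
    "trait_model_for_family_h2",
]


# ---------------------------------------------------------------------------
# rrBLUP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerModel:
    """Fitted ridge-regression BLUP marker model."""

    effects: np.ndarray          # per-marker effect (0 for dropped markers)
    intercept: float
    centre: np.ndarray           # training-dosage column means
    ridge: float                 # shrinkage parameter λ = σ²_e / σ²_marker

    def predict(self, dosage: np.ndarray) -> np.ndarray:
        """Clean linear GEBV score: intercept + centred dosage × effects."""
        base = self.intercept - float(self.centre @ self.effects)
        scores = np.asarray(dosage, np.float32) @ self.effects.astype(np.float32)
        return scores.astype(np.float64) + base


def _reml_ridge(Zc: np.ndarray, yc: np.ndarray) -> float:
    """Estimate λ = σ²_e/σ²_u by REML on the marker kernel (eigen method)."""
    K = Zc @ Zc.T
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    eta = U.T @ yc
    n = len(yc)

    def neg_restricted(log_lam: float) -> float:
        lam = math.exp(log_lam)
        d = w / lam + 1.0           # V/σe² eigenvalues with σu² = σe²/λ
        s2 = float(np.sum(eta ** 2 / d)) / (n - 1)
        return float(np.sum(np.log(d)) + (n - 1) * math.log(s2))

    res = minimize_scalar(neg_restricted, bounds=(-10.0, 14.0), method="bounded")
    return math.exp(res.x)


def rrblup_train(dosage: np.ndarray, y: np.ndarray,
                 ridge: Optional[float] = None) -> MarkerModel:
    """Train ridge-regression BLUP marker effects.

    Solves (Z'Z + λI) u = Z'(y − ȳ) with Z the column-centred dosage matrix.
    Monomorphic markers are dropped (with a warning).  If ``ridge`` is not
    given, λ is estimated by REML on the equivalent marker kernel.
    """
    dosage = np.asarray(dosage, float)
    y = np.asarray(y, float)
    if dosage.shape[0] != len(y) or len(y) < 2:
        raise ValueError("need >= 2 aligned training individuals")
    centre = dosage.mean(axis=0)
    Zc = dosage - centre
    keep = Zc.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} monomorphic markers",
                      stacklevel=2)
    Zk = Zc[:, keep]
    yc = y - y.mean()
    lam = _reml_ridge(Zk, yc) if ridge is None else float(ridge)
    n, m = Zk.shape
    if n <= m:
        # dual (kernel) solution: u = Z'(ZZ' + λI)^{-1} y_c
        alpha = np.linalg.solve(Zk @ Zk.T + lam * np.eye(n), yc)
        u = Zk.T @ alpha
    else:
        u = np.linalg.solve(Zk.T @ Zk + lam * np.eye(m), Zk.T @ yc)
    effects = np.zeros(dosage.shape[1])
    effects[keep] = u
    return MarkerModel(effects=effects, intercept=float(y.mean()),
                       centre=centre, ridge=lam)


def gebv(model: MarkerModel, individuals,
         reliability: float = 0.95,
         rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """GEBVs for a batch of individuals, optionally with calibrated noise.

    ``individuals`` may be a :class:`~halfsib.genome.Population` or a dosage
    matrix.  With ``reliability`` ρ² < 1 and an ``rng``, independent normal
    noise is added so that corr²(clean score, reported score) = ρ² over the
    batch — emulating genotyping error in the realized breeding values.
    """
    dosage = (individuals.dosage_f32() if isinstance(individuals, Population)
              else np.asarray(individuals))
    clean = model.predict(dosage)
    if rng is None or reliability >= 1.0:
        return clean
    if not (0.0 < reliability <= 1.0):
        raise ValueError("reliability must be in (0, 1]")
    v = float(np.var(clean))
    noise_var = v * (1.0 - reliability) / reliability
    return clean + rng.normal(0.0, math.sqrt(noise_var), size=len(clean))


# ---------------------------------------------------------------------------
# trait calibration
# ---------------------------------------------------------------------------

def trait_model_for_family_h2(
    var_additive: float,
    h2_family: float,
    n_env_cells: int,
    n_reps: int,
    plants_per_plot: int = 30,
    ge_variance: float = 0.0,
) -> TraitModel:
    """Choose the plant residual so the family-mean heritability hits a target.

    In a half-sib trial the among-family genetic variance is ¼σ²_A and the
    within-family share (¾σ²_A) joins the plant-level noise, so for a design
    with ``n_env_cells`` location×year cells, ``n_reps`` replicates and
    ``plants_per_plot`` plants per plot,

        h²_fam = (σ²_A/4) / (σ²_A/4 + σ²_GE/cells
                             + (¾σ²_A + σ²_res)/(cells·reps·plants)).

    Solving for σ²_res converts a plot-trial family-mean heritability into the
    single-plant model the simulator draws from.
    """
    if not (0.0 < h2_family < 1.0):
        raise ValueError("family-mean heritability must be in (0, 1)")
    n_plants = n_env_cells * n_reps * plants_per_plot
    between = var_additive / 4.0
    budget = between * (1.0 - h2_family) / h2_family
    resid = (budget - ge_variance / n_env_cells) * n_plants - 0.75 * var_additive
    if resid <= 0:
        raise ValueError("target family-mean heritability is unattainably high "
                         "for this design and GE variance")
    h2_plant = var_additive / (var_additive + ge_variance + resid)
    return TraitModel(h2_plant=h2_plant, ge_variance=ge_variance,
                      residual_variance=resid, plants_per_plot=plants_per_plot)


# ---------------------------------------------------------------------------
# strategy configuration and trackers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyConfig:
    """One stochastic breeding-strategy run.

    ``n_families`` half-sib families per cycle (196 or 980; a multiple of the
    98 founder mothers at cycle 0); ``p_among`` the among-family selected
    fraction (0.20 or 0.02); ``within_selected`` parents kept per selected
    family (5 or 50, restoring ≈``n_families`` parents);
    ``n_candidates_per_family`` genotyping candidates per selected family
    (180, making the within-family selected fractions 2.77% and 27.77%).
    The evaluation design is 2 environments × 2 years × 3 replicates of
    30-plant plots; ``n_eval_per_family`` progeny are drawn per family to
    realize family means.
    """

    strategy: Strategy
    n_families: int = 196
    p_among: float = 0.20
    within_selected: int = 5
    n_candidates_per_family: int = 180
    n_eval_per_family: int = 30
    n_environments: int = 2
    n_years: int = 2
    n_reps: int = 3
    plants_per_plot: int = 30
    n_cycles: int = 10
    n_iterations: int = 250
    h2_family: float = 0.31
    ge_variance: float = 0.0
    gebv_reliability: float = 0.95
    training_envs: int = 3       # the training families are evaluated over
    training_years: int = 3      # 3 locations × 3 years before model fitting
    base_mean: float = 3262.0
    retrain: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategy", Strategy(self.strategy))
        if self.strategy not in (Strategy.A_p, Strategy.A_pWgs, Strategy.A_gsWgs):
            raise ValueError("stochastic simulation covers A_p, A_pWgs and A_gsWgs")
        if not (0.0 < self.p_among <= 1.0):
            raise ValueError("p_among must be in (0, 1]")
        if self.within_selected < 1 or self.n_candidates_per_family < 1:
            raise ValueError("selection counts must be >= 1")
        if self.within_selected > self.n_candidates_per_family:
            raise ValueError("cannot select more candidates than are genotyped")

    @property
    def n_selected_families(self) -> int:
        n = int(math.floor(self.n_families * self.p_among + 0.5))
        if n < 1:
            raise ValueError("among-family pressure selects zero families")
        return n

    @property
    def cycle_years(self) -> int:
        return 1 if self.strategy is Strategy.A_gsWgs else 3


@dataclass(frozen=True)
class CycleRecord:
    """Per-cycle tracker row."""

    cycle: int
    mean: float                  # population mean on family means (BLUP basis)
    pct_gain_per_year: float
    cum_gain: float              # mean relative to cycle 0, trait units
    pct_genetic_variance: float  # var(TBV) relative to cycle 0 (= 100)
    pct_fixed: float             # QTLs fixed for the favourable allele
    accuracy: float              # Pearson r(TBV, GEBV) among candidates


def trackers(pop: Population, spec: GenomeSpec, model: MarkerModel,
             mean_t: float, mean_prev: float, mean_0: float, var_0: float,
             cycle: int, cycle_years: int,
             reliability: float, rng: np.random.Generator,
             gene_pool: Optional[Population] = None) -> CycleRecord:
    """Compute the tracker row for the current cycle's candidate population.

    Fixation is assessed on ``gene_pool`` (the parents that bred this cycle)
    when given: an allele absent from the gene pool stays absent in every
    descendant, which makes the fixation percentage non-decreasing by
    construction.
    """
    if var_0 <= 0:
        raise ValueError("cycle-0 genetic variance is zero")
    tbv = true_breeding_value(pop, spec)
    scores = gebv(model, pop, reliability, rng)
    acc = float(np.corrcoef(tbv, scores)[0, 1]) if np.std(scores) > 0 else 0.0
    pool = pop if gene_pool is None else gene_pool
    dos = pool.dosage()[:, spec.qtl_index].sum(axis=0)
    fav_count = np.where(spec.favourable_allele == 1, dos,
                         2 * pool.n_individuals - dos)
    pct_fixed = 100.0 * float(np.mean(fav_count == 2 * pool.n_individuals))
    pct_var = 100.0 * float(np.var(tbv)) / var_0
    if cycle == 0:
        gain_rate = 0.0
    else:
        gain_rate = 100.0 * (mean_t - mean_prev) / abs(mean_prev) / cycle_years
    return CycleRecord(cycle=cycle, mean=mean_t, pct_gain_per_year=gain_rate,
                       cum_gain=mean_t - mean_0, pct_genetic_variance=pct_var,
                       pct_fixed=pct_fixed, accuracy=acc)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class BreedingProgram:
    """Stochastic multi-cycle recurrent-selection simulator.

    Parameters
    ----------
    config : StrategyConfig
    genome : GenomeSpec
    founders : Population
        Cycle-0 founder plants (e.g. 98); each founder mothers
        ``n_families / n_founders`` half-sib families to build the training
        population.
    """

    def __init__(self, config: StrategyConfig, genome: GenomeSpec,
                 founders: Population):
        if config.n_families % founders.n_individuals != 0:
            raise ValueError("n_families must be a multiple of the founder count")
        self.config = config
        self.genome = genome
        self.founders = founders
        var_a = self._founder_additive_variance()
        self.trait = trait_model_for_family_h2(
            var_a, config.h2_family,
            n_env_cells=config.n_environments * config.n_years,
            n_reps=config.n_reps, plants_per_plot=config.plants_per_plot,
            ge_variance=config.ge_variance,
        )

    def _founder_additive_variance(self) -> float:
        return float(np.var(true_breeding_value(self.founders, self.genome)))

    def simulate(self, n_iterations: Optional[int] = None,
                 seed: int = 0) -> "SimulationResults":
        """Run ``n_iterations`` independent replicates and collect trackers."""
        n_iter = self.config.n_iterations if n_iterations is None else n_iterations
        master = np.random.SeedSequence(seed)
        rows = []
        for it, child in enumerate(master.spawn(n_iter)):
            rng = np.random.default_rng(child)
            for rec in self._run_once(rng):
                rows.append((it,) + tuple(getattr(rec, f) for f in
                            ("cycle", "mean", "pct_gain_per_year", "cum_gain",
                             "pct_genetic_variance", "pct_fixed", "accuracy")))
        df = pd.DataFrame(rows, columns=[
            "iteration", "cycle", "mean", "pct_gain_per_year", "cum_gain",
            "pct_genetic_variance", "pct_fixed", "accuracy"])
        return SimulationResults(self.config, df)

    # -- internals ----------------------------------------------------------

    def _family_means(self, pop: Population, rng) -> tuple[np.ndarray, np.ndarray]:
        c = self.config
        fams, means, _ = family_phenotype_means(
            pop, self.trait, c.n_environments, c.n_years, c.n_reps, rng,
            self.genome)
        return fams, means

    def _run_once(self, rng: np.random.Generator) -> list[CycleRecord]:
        c = self.config
        g = self.genome
        draws = c.n_families // self.founders.n_individuals
        idx_f = np.arange(self.founders.n_individuals)
        training = polycross(self.founders, idx_f, idx_f, draws, g, rng, cycle=0)

        # training phenotypes: the 98 maternal half-sib families are evaluated
        # as a multi-location multi-year trial, and every drawn plant carries
        # its family's mean performance — the prediction model is built from
        # family-trial data plus individual marker genotypes
        fams_t, fam_means_t, _ = family_phenotype_means(
            training, self.trait, c.training_envs, c.training_years,
            c.n_reps, rng, g)
        lookup = np.zeros(int(fams_t.max()) + 1)
        lookup[fams_t] = fam_means_t
        y_train = lookup[training.family]
        model = rrblup_train(training.dosage(), y_train)

        # cycle-0 cohort: the training plants intermated into n_families
        # half-sib families; every later cohort descends from its selections
        parents = training
        idx = np.arange(parents.n_individuals)
        mothers = rng.choice(idx, size=c.n_families, replace=False)
        cohort = polycross(parents, mothers, idx, c.n_eval_per_family, g, rng,
                           cycle=0)
        tbv_c0 = true_breeding_value(cohort, g)
        offset = c.base_mean - float(np.mean(tbv_c0))
        var_0 = float(np.var(tbv_c0))
        mean_0 = mean_prev = float(np.mean(tbv_c0)) + offset

        records: list[CycleRecord] = []
        for cyc in range(c.n_cycles + 1):
            fams, pheno_means = self._family_means(cohort, rng)
            pheno_means = pheno_means + offset
            mean_t = float(np.mean(pheno_means)) if cyc > 0 else mean_0

            if c.retrain and cyc > 0 and c.strategy is not Strategy.A_p:
                tbv_e = true_breeding_value(cohort, g)
                y_new = tbv_e + rng.normal(
                    0.0, math.sqrt(self.trait.ge_variance
                                   + self.trait.residual_variance),
                    len(tbv_e))
                model = rrblup_train(cohort.dosage(), y_new)

            # among-family truncation on phenotypic means or family-mean GEBVs
            n_sel = c.n_selected_families
            if c.strategy is Strategy.A_gsWgs:
                scores = gebv(model, cohort, c.gebv_reliability, rng)
                fam_score = np.bincount(cohort.family, weights=scores)
                fam_score = fam_score / np.bincount(cohort.family)
                sel_fams = fams[np.argsort(fam_score)[::-1][:n_sel]]
            else:
                sel_fams = fams[np.argsort(pheno_means)[::-1][:n_sel]]
            sel_mothers = mothers[sel_fams]

            # within-family step: fresh remnant seed of the selected families
            if c.strategy is Strategy.A_p:
                # random within-family parents; draw extra remnant seed when a
                # family's evaluated sample is smaller than the quota
                if c.within_selected <= c.n_eval_per_family:
                    keep = np.concatenate([
                        rng.choice(np.flatnonzero(cohort.family == f),
                                   size=c.within_selected, replace=False)
                        for f in sel_fams])
                    new_parents = cohort.subset(keep)
                else:
                    new_parents = polycross(parents, sel_mothers, idx,
                                            c.within_selected, g, rng,
                                            cycle=cyc + 1)
            else:
                cands = polycross(parents, sel_mothers, idx,
                                  c.n_candidates_per_family, g, rng,
                                  cycle=cyc + 1)
                scores = gebv(model, cands, c.gebv_reliability, rng)
                keep = np.concatenate([
                    np.flatnonzero(cands.family == f)[
                        np.argsort(scores[cands.family == f])[::-1]
                    ][:c.within_selected]
                    for f in range(len(sel_mothers))])
                new_parents = cands.subset(keep)

            # the tracker's fixation refers to this cycle's breeding
            # population — the parents just selected from the cohort
            records.append(trackers(cohort, g, model, mean_t, mean_prev,
                                    mean_0, var_0, cyc, c.cycle_years,
                                    c.gebv_reliability, rng,
                                    gene_pool=new_parents))
            mean_prev = mean_t
            if cyc == c.n_cycles:
                break

            parents = new_parents
            idx = np.arange(parents.n_individuals)
            mothers = rng.choice(idx, size=c.n_families,
                                 replace=parents.n_individuals < c.n_families)
            cohort = polycross(parents, mothers, idx, c.n_eval_per_family,
                               g, rng, cycle=cyc + 1)
        return records


@dataclass
class SimulationResults:
    """Per-iteration tracker records and their across-iteration averages."""

    config: StrategyConfig
    records: pd.DataFrame = field(repr=False)

    def mean_trackers(self) -> pd.DataFrame:
        """Tracker columns averaged over iterations, one row per cycle."""
        return (self.records.drop(columns="iteration")
                .groupby("cycle").mean().reset_index())

    def summary(self) -> str:
        m = self.mean_trackers()
        lines = [
            f"Stochastic simulation: {self.config.strategy.value}, "
            f"{self.config.n_families} families, "
            f"among pressure {self.config.p_among:.0%}, "
            f"top {self.config.within_selected} within",
            f"iterations: {self.records['iteration'].nunique()}, "
            f"cycles: {self.config.n_cycles} "
            f"({self.config.cycle_years} year(s) each)",
            "-" * 78,
            f"{'cycle':>5}{'mean':>10}{'%dG/yr':>9}{'cum dG':>10}"
            f"{'%var':>8}{'%fixed':>8}{'accuracy':>10}",
        ]
        for _, r in m.iterrows():
            lines.append(
                f"{int(r['cycle']):>5}{r['mean']:>10.1f}"
                f"{r['pct_gain_per_year']:>9.2f}{r['cum_gain']:>10.1f}"
                f"{r['pct_genetic_variance']:>8.1f}{r['pct_fixed']:>8.1f}"
                f"{r['accuracy']:>10.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Line chart of the averaged trackers across cycles."""
        import matplotlib.pyplot as plt

        m = self.mean_trackers()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(m["cycle"], m["pct_genetic_variance"], label="% genetic variance")
        ax.plot(m["cycle"], m["pct_fixed"], label="% favourable alleles fixed")
        ax.plot(m["cycle"], 100 * m["accuracy"], label="accuracy × 100")
        ax.set_xlabel("selection cycle")
        ax.set_title(self.config.strategy.value)
        ax.legend()
        return ax
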