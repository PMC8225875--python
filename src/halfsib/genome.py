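"""Genome representation, meiosis and phenotype simulation for breeding-cycle studies.

The genetic model is a diploid, biallelic, purely additive one: a set of
markers on a small number of linkage groups, a subset of which are QTLs with
an additive effect and a designated favourable allele.  Recombination follows
the Haldane map function (crossovers as a Poisson process, no interference),
which makes meiosis a Markov chain along each linkage group: the copied
parental haplotype switches between adjacent markers at distance ``d`` cM with
probability ``(1 − exp(−2d/100))/2`` and linkage groups assort independently.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "Population",
    "TraitModel",
    "true_breeding_value",
    "additive_variance_le",
    "gametes",
    "polycross",
    "simulate_phenotypes",
    "family_phenotype_means",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Marker map, QTL placement and additive QTL effects.

    ``group``/``position`` give each marker's linkage group and map position in
    cM (non-decreasing within a group).  ``qtl_index`` are the marker indices
    that act as QTLs; ``qtl_effect`` their (positive) additive effects in trait
    units per favourable-allele copy, and ``favourable_allele`` which of the
    two allele codes (0/1) is favourable.  ``founder_freq`` stores the
    allele-1 frequency used to found populations.
    """

    group: np.ndarray
    position: np.ndarray
    qtl_index: np.ndarray
    qtl_effect: np.ndarray
    favourable_allele: np.ndarray
    founder_freq: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        m = len(self.position)
        if len(self.group) != m:
            raise ValueError("group and position must align")
        for g in np.unique(self.group):
            pos = self.position[self.group == g]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions must be non-decreasing in group {g}")
        if np.any(self.qtl_index < 0) or np.any(self.qtl_index >= m):
            raise ValueError("qtl_index out of marker range")
        if len(self.qtl_effect) != len(self.qtl_index):
            raise ValueError("one effect per QTL required")
        if not np.all(np.isfinite(self.qtl_effect)):
            raise ValueError("QTL effects must be finite")
        if np.any(self.qtl_effect < 0):
            raise ValueError("QTL effects are stored as magnitudes (>= 0)")

    @property
    def n_markers(self) -> int:
        return len(self.position)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_index)

    @property
    def n_linkage_groups(self) -> int:
        return len(np.unique(self.group))

    def switch_probabilities(self) -> np.ndarray:
        """Per-marker haplotype switch probabilities of the meiosis Markov chain.

        Entry 0 of each linkage group is 0.5 (random start / independent
        assortment); subsequent entries are the Haldane recombination fraction
        of the distance to the previous marker.
        """
        r = np.empty(self.n_markers)
        d = np.diff(self.position, prepend=self.position[0])
        r[:] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        starts = np.r_[True, np.diff(self.group) != 0]
        r[starts] = 0.5
        return r

    def to_map_file(self, path) -> None:
        """Write a plain-text map: group, position_cM, marker, is_qtl, effect, favourable."""
        df = pd.DataFrame({
            "group": self.group,
            "position_cM": self.position,
            "marker": np.arange(self.n_markers),
            "is_qtl": 0,
            "effect": 0.0,
            "favourable": -1,
        })
        df.loc[self.qtl_index, "is_qtl"] = 1
        df.loc[self.qtl_index, "effect"] = self.qtl_effect
        df.loc[self.qtl_index, "favourable"] = self.favourable_allele
        if self.founder_freq is not None:
            df["founder_freq"] = self.founder_freq
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_map_file(cls, path) -> "GenomeSpec":
        df = pd.read_csv(path, sep="\t")
        qtl = df.index[df["is_qtl"] == 1].to_numpy()
        freq = df["founder_freq"].to_numpy() if "founder_freq" in df else None
        return cls(
            group=df["group"].to_numpy(),
            position=df["position_cM"].to_numpy(float),
            qtl_index=qtl,
            qtl_effect=df.loc[qtl, "effect"].to_numpy(float),
            favourable_allele=df.loc[qtl, "favourable"].to_numpy(int),
            founder_freq=freq,
        )


@dataclass(frozen=True)
class Population:
    """Phased diploid genotypes of individuals grouped into half-sib families.

    ``haplotypes`` has shape (n_individuals, n_markers, 2) with allele codes
    {0, 1}; ``family`` labels each individual's maternal family (-1 for
    founders without family structure); ``cycle`` is the breeding-cycle index.
    """

    haplotypes: np.ndarray
    family: np.ndarray
    cycle: int = 0

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[2] != 2:
            raise ValueError("haplotypes must have shape (n, m, 2)")
        if len(self.family) != self.haplotypes.shape[0]:
            raise ValueError("family labels must align with individuals")
        object.__setattr__(self, "_cache", {})

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self) -> np.ndarray:
        """Allele-1 dosage per individual × marker (0, 1 or 2); memoised."""
        if "dosage" not in self._cache:
            self._cache["dosage"] = (self.haplotypes[:, :, 0].astype(np.int16)
                                     + self.haplotypes[:, :, 1])
        return self._cache["dosage"]

    def dosage_f32(self) -> np.ndarray:
        """Dosage as float32, memoised (the GEBV matvec input)."""
        if "dosage32" not in self._cache:
            self._cache["dosage32"] = self.dosage().astype(np.float32)
        return self._cache["dosage32"]

    def subset(self, idx) -> "Population":
        return replace(self, haplotypes=self.haplotypes[idx], family=self.family[idx])

    def to_genotype_csv(self, path) -> None:
        """One row per individual: family then phased alleles m0_a,m0_b,m1_a,…"""
        n, m, _ = self.haplotypes.shape
        flat = self.haplotypes.reshape(n, 2 * m)
        cols = [f"m{i}_{ab}" for i in range(m) for ab in "ab"]
        df = pd.DataFrame(flat, columns=cols)
        df.insert(0, "family", self.family)
        df.to_csv(path, index=False)


def true_breeding_value(pop: Population, spec: GenomeSpec) -> np.ndarray:
    """Additive true breeding value: Σ over QTLs of favourable-allele count × effect."""
    if "tbv" in pop._cache:
        return pop._cache["tbv"]
    dos = pop.dosage()[:, spec.qtl_index].astype(np.float64)
    # allele-1 dosage → favourable-allele count: flips sign where allele 0 is
    # favourable, adding the constant 2·effect for those QTLs
    signed = np.where(spec.favourable_allele == 1, spec.qtl_effect,
                      -spec.qtl_effect)
    const = float(2.0 * spec.qtl_effect[spec.favourable_allele == 0].sum())
    tbv = dos @ signed + const
    pop._cache["tbv"] = tbv
    return tbv


def additive_variance_le(spec: GenomeSpec, freq: Optional[np.ndarray] = None) -> float:
    """Additive variance Σ 2p(1−p)a² under linkage equilibrium at the given
    favourable-allele frequencies (defaults to the founding frequencies)."""
    if freq is None:
        if spec.founder_freq is None:
            raise ValueError("no allele frequencies available")
        p1 = spec.founder_freq[spec.qtl_index]
        freq = np.where(spec.favourable_allele == 1, p1, 1.0 - p1)
    return float(np.sum(2.0 * freq * (1.0 - freq) * spec.qtl_effect ** 2))


def gametes(pop: Population, parent_idx: np.ndarray, spec: GenomeSpec,
            rng: np.random.Generator, chunk: int = 8192) -> np.ndarray:
    """Draw one gamete per entry of ``parent_idx`` under the Haldane model.

    Returns an (len(parent_idx), n_markers) array of allele codes.
    """
    parent_idx = np.asarray(parent_idx)
    m = spec.n_markers
    # expected crossovers per marker interval (Morgans); crossovers between
    # adjacent markers are Poisson under Haldane, so the per-gamete counts can
    # be drawn as interval totals scattered uniformly over gametes — exactly
    # equivalent to, and much cheaper than, per-(gamete, interval) draws
    lam = np.diff(spec.position, prepend=spec.position[0]) / 100.0
    starts = np.flatnonzero(np.r_[True, np.diff(spec.group) != 0])
    lam[starts] = 0.0
    out = np.empty((len(parent_idx), m), dtype=np.int8)
    for lo in range(0, len(parent_idx), chunk):
        sel = parent_idx[lo:lo + chunk]
        ng = len(sel)
        switch = np.zeros((ng, m), dtype=np.uint8)
        counts = rng.poisson(ng * lam)
        nz = np.flatnonzero(counts)
        gids = rng.integers(0, ng, size=int(counts[nz].sum()))
        mids = np.repeat(nz, counts[nz])
        np.add.at(switch, (gids, mids), 1)
        # random starting haplotype per linkage group (independent assortment)
        switch[:, starts] += rng.integers(0, 2, size=(ng, len(starts)),
                                          dtype=np.uint8)
        # parity of the cumulative crossover count selects the copied
        # haplotype; uint8 overflow is harmless modulo 2
        parity = np.cumsum(switch, axis=1, dtype=np.uint8) & 1
        haps = pop.haplotypes[sel]
        out[lo:lo + chunk] = np.where(parity, haps[:, :, 1], haps[:, :, 0])
    return out


def polycross(pop: Population, mother_idx: np.ndarray, pollen_idx: np.ndarray,
              progeny_per_mother: int, spec: GenomeSpec,
              rng: np.random.Generator, cycle: Optional[int] = None) -> Population:
    """Random intermating: each mother contributes ``progeny_per_mother`` seeds.

    Every progeny receives a maternal gamete from its mother and a paternal
    gamete from a pollen parent drawn uniformly from ``pollen_idx`` excluding
    the mother herself (no selfing).  Progeny of one mother form one half-sib
    family, labelled by the mother's position in ``mother_idx``.
    """
    mother_idx = np.asarray(mother_idx)
    pollen_idx = np.asarray(pollen_idx)
    if len(mother_idx) == 0 or len(pollen_idx) == 0:
        raise ValueError("mother and pollen pools must be non-empty")
    k = int(progeny_per_mother)
    if k < 1:
        raise ValueError("progeny_per_mother must be >= 1")
    mothers = np.repeat(mother_idx, k)
    # uniform father excluding self, by redrawing collisions
    fathers = rng.choice(pollen_idx, size=len(mothers))
    for _ in range(1000):
        clash = fathers == mothers
        if not clash.any():
            break
        if len(pollen_idx) == 1:
            raise ValueError("pollen pool contains only the mother; selfing excluded")
        fathers[clash] = rng.choice(pollen_idx, size=int(clash.sum()))
    else:  # pragma: no cover
        raise RuntimeError("could not draw non-self fathers")
    mat = gametes(pop, mothers, spec, rng)
    pat = gametes(pop, fathers, spec, rng)
    haps = np.stack([mat, pat], axis=2)
    fam = np.repeat(np.arange(len(mother_idx)), k)
    return Population(haplotypes=haps, family=fam,
                      cycle=pop.cycle + 1 if cycle is None else cycle)


@dataclass(frozen=True)
class TraitModel:
    """Single-plant phenotype model: phenotype = TBV + GE deviation + residual.

    ``ge_variance`` is the family-by-environment interaction variance (a
    deviation shared by all plants of a family within one location × year
    cell); ``residual_variance`` is independent plant noise.  Use
    :meth:`calibrate` to choose the residual so that the single-plant
    heritability var(TBV)/var(phenotype) hits a target at cycle 0.
    """

    h2_plant: float
    ge_variance: float
    residual_variance: float
    plants_per_plot: int = 30

    def __post_init__(self) -> None:
        if not (0.0 < self.h2_plant <= 1.0):
            raise ValueError("single-plant heritability must be in (0, 1]")
        if self.ge_variance < 0 or self.residual_variance < 0:
            raise ValueError("variances must be >= 0")

    @classmethod
    def calibrate(cls, var_additive: float, h2_plant: float,
                  ge_variance: float = 0.0, plants_per_plot: int = 30) -> "TraitModel":
        """Set the residual so h² = var_A / (var_A + σ²_GE + σ²_res)."""
        if not (0.0 < h2_plant <= 1.0):
            raise ValueError("single-plant heritability must be in (0, 1]")
        resid = var_additive * (1.0 - h2_plant) / h2_plant - ge_variance
        if resid < 0:
            raise ValueError("GE variance exceeds the non-genetic variance budget")
        return cls(h2_plant, ge_variance, resid, plants_per_plot)


def simulate_phenotypes(pop: Population, trait: TraitModel,
                        n_environments: int, n_years: int, n_reps: int,
                        rng: np.random.Generator, spec: GenomeSpec,
                        ) -> pd.DataFrame:
    """Simulate plot records for a family evaluation trial.

    Each plot holds ``trait.plants_per_plot`` plants sampled (with
    replacement) from the family's members; a plant's value is its TBV plus
    the family × (environment, year) deviation plus independent residual
    noise, and the plot value is the mean over its plants.

    Returns a DataFrame with columns
    ``family, environment, year, rep, plot_mean``.
    """
    tbv = true_breeding_value(pop, spec)
    fams = np.unique(pop.family)
    recs = []
    npp = trait.plants_per_plot
    for f in fams:
        members = np.flatnonzero(pop.family == f)
        ge = rng.normal(0.0, np.sqrt(trait.ge_variance), size=(n_environments, n_years))
        for e in range(n_environments):
            for yv in range(n_years):
                for rep in range(n_reps):
                    plants = rng.choice(members, size=npp, replace=True)
                    vals = tbv[plants] + ge[e, yv] + rng.normal(
                        0.0, np.sqrt(trait.residual_variance), size=npp)
                    recs.append((f, e, yv, rep, vals.mean()))
    return pd.DataFrame(recs, columns=["family", "environment", "year", "rep", "plot_mean"])


def family_phenotype_means(pop: Population, trait: TraitModel,
                           n_environments: int, n_years: int, n_reps: int,
                           rng: np.random.Generator, spec: GenomeSpec,
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Family phenotype means over the whole design, without materialising plants.

    Equivalent in distribution to averaging :func:`simulate_phenotypes` plot
    means per family when each plot draws an independent sample of the
    family's members.  Returns (family labels, family means, noise variance of
    a family mean).
    """
    tbv = true_breeding_value(pop, spec)
    fams, inv = np.unique(pop.family, return_inverse=True)
    sums = np.bincount(inv, weights=tbv)
    counts = np.bincount(inv)
    fam_tbv = sums / counts
    cells = n_environments * n_years
    plots = cells * n_reps
    noise_var = (trait.ge_variance / cells
                 + trait.residual_variance / (plots * trait.plants_per_plot))
    means = fam_tbv + rng.normal(0.0, np.sqrt(noise_var), size=len(fams))
    return fams, means, noise_var
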