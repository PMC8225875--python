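# Methods

This note documents the models, numerical choices and limitations behind
`halfsib`. Units throughout: yields kg ha⁻¹, variances kg² ha⁻², map
distances cM.

## Deterministic gain engine

The engine predicts the response of dry-matter yield to one cycle of
truncation selection in a half-sib (HS) recurrent-selection programme. Its
assumptions are the classical ones: an additive infinitesimal trait, normally
distributed selection criteria, non-inbred parents (F = 0, so the
among-HS-family variance σ²_f = ¼σ²_A), and selection transmitted through the
female gametes only (parental control c = 0.5 per stage).

Conventions that deserve explicit statement:

* **Variance scale.** The among-family component as estimated by REML from an
  HS trial is used *directly* as the numerator of the among-family term
  (it already is ¼σ²_A), and the additive SD entering the within-family and
  genomic terms is σ_A = 2√σ²_f. Mixing these scales up changes every
  prediction by a factor of 4 or 2.
* **Family-mean phenotypic variance.** The residual is divided by the full
  number of plots per family, n_l·n_s·n_y·n_r, i.e. replicates at every
  location × season × year combination all average into a family mean.
* **Selection intensity** is the infinite-population truncated-normal form
  i(p) = φ(Φ⁻¹(1−p))/p, with no finite-sample order-statistic correction.
  Decision-support tools sometimes tabulate slightly different (rounded or
  finite-population) intensities; discrepancies this introduces are below
  0.01 percentage points of gain in the grids we evaluate.
* **Phenomics** (accuracy ρ, default 0.90 for the LiDAR platform) multiplies
  the *total* predicted gain of a strategy, including the within-family
  genomic term of `A_PhWgs`. The alternative — scaling only the among-family
  stage — would break the observed cell-by-cell 0.9 ratio between the
  phenotypic and phenomic columns of a gain table.
* **GEBV criterion heritability** h_X is taken as 1 (genomic estimated
  breeding values treated as noise-free selection criteria); accuracy enters
  only through r_A.
* **Cycle chaining.** Percent gains are computed against the *current*
  cycle's base mean (the previous cycle's mean plus its absolute gain) and
  summed across cycles; annualised gain divides by the cycle length (3 years
  for field-evaluated cycles, 1 year for a purely genomic cycle).
* **Parent counts** round half-up at each stage and error on zero.

## REML variance components

`HalfSibTrialModel` fits the plot model with fixed location, season and year
main effects and independent normal random effects for family, family ×
location, family × season, family × year, and optionally replicate within
(location, season, year), row within replicate and column within replicate,
plus a homoscedastic residual. Note the row/column terms are additive
row-and-column effects within a replicate — a row-column design; a "column
within row" effect would have one level per plot and be confounded with the
residual.

The estimator maximises the restricted log-likelihood directly over the
variance scale with a bounded quasi-Newton method, then polishes with
average-information (AI) scoring steps with step-halving; convergence is
declared when the gradient is numerically zero or the step stalls below
1e-12 relative. This reaches the same optimum as classical AI-REML-with-EM
iterations but is simpler to make robust; on balanced data interior solutions
agree with closed-form ANOVA estimators to better than 1e-6 relative (tested).
Standard errors are from the inverse AI matrix at the optimum; components are
bounded below at 1e-10 × var(y), which is the zero boundary in practice.

Two computational routes share the interface. When all random terms are
family-nested, the marginal covariance is block-diagonal by family; blocks
are grouped by identical design patterns and evaluated batched (a balanced
trial has one pattern), with exact analytic gradients — this fits 1000
families × 36 plots in ~0.1 s. Crossed replicate/row/column terms go through
sparse mixed-model equations with a log-scale quasi-Newton search; that route
is exact but slower, and intended for moderate data sizes.

Family BLUPs are σ²_f·1'V⁻¹(y_i − Xβ̂) per family; "BLUP means" add the grand
fixed-effect mean. Records are canonically sorted (all identifier columns,
then the response) before fitting, making estimates invariant to input
permutation at the bit level.

## Cost model

Cost per cycle = fixed operational cost + phenotyping + genotyping, with unit
costs (NZ$) of 7.50 per destructive herbage cut, 0.87 per phenomic sample and
41 per GEBV. Phenotyping charges one sample per plot (family × rep × location
× season × year); genotyping charges every genotyped candidate
(selected families × candidates per family; for a purely genomic cycle every
family is genotyped before among-family selection). The fixed operational
cost is programme-specific with no defensible default; it is a required
config input, and the package validates cost *patterns* (e.g. phenomics
beats cuts on $ per % gain across pressures for any fixed cost in a broad
band) rather than absolute dollar totals.

## Genome and trait simulation

The genetic model is additive and biallelic: 1807 markers on 7 linkage
groups, 474 of them QTLs (defaults; all configurable). Meiosis uses the
Haldane map function — crossovers are a Poisson process with no
interference — so the copied haplotype switches between adjacent markers at
distance d cM with probability (1−e^(−2d/100))/2 and linkage groups assort
independently. The implementation draws interval crossover *totals* across a
batch of gametes and scatters them uniformly, which is distributionally
identical to per-gamete draws and an order of magnitude faster.

Synthetic founders stand in for the real commercial breeding population the
workflow assumes: allele frequencies Uniform(0.1, 0.9) per marker, sites in
Hardy–Weinberg and linkage equilibrium at founding. QTL effects are drawn
standard normal (the sign fixing the favourable allele) and rescaled so the
linkage-equilibrium additive variance Σ2p(1−p)a² matches a target — default
4 × 14 170, the additive variance implied by the 200-family trial. Real
effect-size distributions estimated by GWAS are out of scope, so the
simulator reproduces the *structure* of multi-cycle response, not any
particular published magnitudes. Map lengths default to 100 cM per linkage
group, a round figure in the range of published ryegrass maps.

Phenotypes are plant value = TBV + family×environment deviation + residual;
plots average 30 plants. The plant residual is calibrated from a family-mean
heritability target: with between-family variance ¼σ²_A and the within-family
¾σ²_A folding into plant-level noise,

    h²_fam = (σ²_A/4) / (σ²_A/4 + σ²_GE/cells + (¾σ²_A + σ²_res)/(cells·reps·plants)),

solved for σ²_res. The default target h²_fam = 0.31 (the 200-family trial)
implies a single-plant heritability below 0.01 at these magnitudes — an
honest consequence of plot-based yield trialling.

## Stochastic breeding-cycle simulator

Each iteration builds a training population by polycrossing 98 founders (2 or
10 draws per family → 196 or 980 plants), evaluates those 98 families in a
3-location × 3-year trial and assigns every drawn plant its family's mean as
training phenotype — the prediction model is trained on family-trial data
plus individual genotypes, as in practical forage GS. Marker effects are
ridge-regression BLUP; the shrinkage λ = σ²_e/σ²_u is estimated by REML on
the marker kernel (eigendecomposition, n ≤ 1000). Reported GEBVs carry
additive noise calibrated so corr²(clean, reported) equals the GEBV
reliability (0.95, representing genotyping error).

The cycle-0 cohort intermates the training plants into 196 (or 980) HS
families of 30 evaluated progeny each; every subsequent cohort descends from
the previous cohort's selections. Among-family selection truncates family
phenotype means (`A_p`, `A_pWgs`) or family-mean GEBVs (`A_gsWgs`) at 20% or
2%; within-family selection keeps the top 5 or 50 of 180 genotyped remnant
seedlings per selected family by GEBV (`*Wgs`), or samples them at random
(`A_p`), restoring ≈196 parents. The prediction model is trained once at
cycle 0 and not retrained by default (a `retrain` flag exists), which is what
drives the observed accuracy decay across cycles.

Trackers per cycle: population mean (mean of family phenotype means, anchored
to a base mean of 3262 at cycle 0), percent gain per year using the
previous-cycle mean as denominator (cycle-to-cycle change; a baseline
denominator is equally computable from the records), cumulative gain,
genetic variance as a percentage of cycle 0, percent of QTLs fixed for the
favourable allele, and the realized accuracy corr(TBV, GEBV) in the cohort.
Fixation is assessed on the cycle's breeding population — the parents
selected from that cycle's cohort: an allele absent there is absent in every
descendant, making the fixation trace non-decreasing by construction. Iterations use independent child seeds
spawned from one master seed, and per-iteration records are retained for
dispersion analysis.

Desk-scale property runs (50 iterations × 5 cycles, 196 families) are the
package's standard evidence: they demonstrate the strategy ordering of
cycle-1 annual gain (A_gsWgs ≥ A_pWgs ≥ A_p), faster fixation under 2% than
20% pressure from cycle 3, variance decay with the GS strategies retaining
the least, and monotone accuracy decay without retraining. They do not — and
cannot, with synthetic founders and synthetic QTL effects — reproduce any
real programme's absolute trajectories, and passing them says nothing about
non-additive inheritance, genotype-calling error structure, or spatial field
trends, none of which are modelled.

## Synthetic trial generator

`generate_trial` draws balanced complete records from exactly the model the
REML module fits: fixed location/season/year shifts (default zero) plus
independent normal family, interaction, replicate, row, column and residual
effects at the requested variances (replicate/row/column default to 0 since
the engine's starting points do not include them). Families are laid on an
n_rows × n_cols grid, re-randomised per replicate. Identical seeds give
byte-identical output. The generator's defaults mirror the two mock trials
the engine's worked examples use: 200 or 1000 families, 2 locations ×
3 seasons × 2 years × 3 replicates, means 3262/3301.

## Known limitations

* No dominance or epistasis anywhere; no mutation, selfing or sex-specific
  recombination in the simulator; no spatial (AR1×AR1) residual models in
  the REML module.
* The deterministic engine predicts expected response only; it carries no
  sampling variance of the prediction itself.
* The sparse REML route's runtime grows quickly with crossed terms; the
  family-nested fast path is the intended workhorse.
* Economic output is a cost ratio, not an optimisation; no discounting.
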