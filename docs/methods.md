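# Methods

## Model

A biallelic autosomal locus with alleles A and a, allele-A frequency
`p_A` (`p_a = 1 − p_A`). Departure from Hardy–Weinberg equilibrium (HWE) is
parameterized by the fixation index `r`, the within-individual allele
correlation:

    P(AA) = (1−r) p_A² + r p_A
    P(Aa) = 2 (1−r) p_A p_a
    P(aa) = (1−r) p_a² + r p_a

`r = 0` is HWE; `r` may be negative (heterozygote excess) down to
`−min(p_A/p_a, p_a/p_A)`, where a genotype frequency reaches zero, and at
most 1 (full fixation). The data unit is a trio — father, mother, child —
sampled by a stratified multistage design with `H` strata, `I_h` sampled
PSUs in stratum `h`, `U = Σ I_h` PSUs in total, and a positive sampling
weight per family. All design-based variances use the with-replacement
first-stage approximation: PSU totals of a linearized variate, centered
within strata, combined as `Σ_h I_h/(I_h−1) Σ_i (z_hi − z̄_h)(z_hi − z̄_h)ᵀ`.
Strata with a single sampled PSU are rejected (the CLI offers
`--collapse-strata` to merge adjacent ones).

## Familial types and the corrected chi-square family

Ignoring parental order, a Mendelian trio falls in one of 10 familial
types with HWE probabilities
`π(p) = (p⁴, 2p³q, 2p³q, 2p²q², p²q², 2p²q², p²q², 2pq³, 2pq³, q⁴)`.
One type table row (aa×aa parents) is printed elsewhere with an impossible
heterozygous child; we use the Mendelian-consistent child aa, whose
probability q⁴ the table itself gives.

The weighted allele frequency is `p̂_Aw = cᵀJ_w/(4T_w)` with
`c = (4,3,3,2,2,2,2,1,1,0)` the per-type count of parental A alleles. This
is the HWE maximum-likelihood estimator from trios — children add no
information given their parents — and the only linear choice that treats
the two AA–Aa types symmetrically and respects allele relabeling (it maps
the uniform count vector to exactly 1/2).

The uncorrected statistic `χ² = θᵀMθ`, `θ = J_w − T_wπ̂`,
`M = [T_w diag(π̂)]⁻¹`, is referred to χ²₈ (10 cells − 1 sum constraint − 1
estimated allele frequency). It is correct only for self-weighting samples
of independent families; note it *scales with the mean weight* (θ ∝ w,
M ∝ 1/w), which is the dominant reason its size collapses under
differential weights — the package deliberately does not normalize weights,
matching the statistic's documented behaviour.

Taylor linearization of θ as a function of the count vector gives the
per-family variate `z = G(w e)` (e the type indicator) with

    G = I − π̂1ᵀ − T_w (dπ/dp)(∂p̂/∂J_w)ᵀ,   ∂p̂/∂J_lw = (c_l − 4p̂)/(4T_w).

G annihilates both 1 and c, so Σ̂ has rank ≤ 8; Σ̂ is validated in the tests
against the analytic multinomial covariance (iid one-family PSUs) and
against a delete-one-PSU jackknife.

Rao–Scott corrections use the 8 algebraically largest real eigenvalues of
`Σ̂M` (the two discarded ones are checked to be numerically zero): the
first-order statistic `χ²/λ̄` vs χ²₈; the second-order statistic
additionally divided by `1 + b̂²` (b̂² the squared CV of the eigenvalues) vs
χ² with `8/(1+b̂²)` df; and the F version, the second-order statistic
divided by its df, vs `F(8/(1+b̂²), U−H)`. Fractional degrees of freedom use
the continuous chi-square/F distributions; all p-values are upper-tail.

## Quasi-score test

Each individual contributes `y = (1{AA}, 1{Aa})` with mean
`μ = ((1−r)p² + rp, 2(1−r)p(1−p))`. The estimating equations sum
`Dᵀ W^{1/2} Var(y_fam)⁻¹ W^{1/2} (y_fam − μ_fam)` over families (D stacks
the per-member 2×2 Jacobian in (p, r)). With family-level weights, W is a
scalar per family and the per-family system is shared, which is what makes
the Monte-Carlo studies fast.

The 6×6 trio covariance at the null is assembled from pairwise
relationships: identical 2×2 diagonal blocks; a zero spouse block (random
mating); parent–child blocks from one-allele identity by descent, e.g.
`Cov(1{AA_parent}, 1{AA_child}) = p³q`. A full-sib block (¼·self + ½·
parent-offspring, by the ¼/½/¼ identity-state mixture) is kept for other
family shapes and for the `literal` covariance arrangement — a
one-parent/two-offspring block layout retained behind a flag for
sensitivity analysis, since block labels can be read either way; the
pairwise arrangement is the genetically correct default for a trio and is
validated against a 200,000-trio empirical covariance.

The null allele frequency `p̃` solves the p-equation with r fixed at 0 by
Newton iteration (finite-difference slope, step halving, start at the
weighted sample allele frequency, tolerance |S_p| < 1e-10 × total weight,
bracketed-root fallback). The variance of the r-score projects out the
nuisance direction family by family, `u = s_r − (A_rp/A_pp) s_p` with A the
aggregated model-based sensitivity `Σ w DᵀV⁻¹D`, and applies the stratified
between-PSU variance to u. This effective-score linearization is the
standard choice where the original variance formulas are not spelled out;
it is validated against the jackknife and by the achieved test size. The
statistic `QS = S_r²/V̂_L` is referred to `F(1, U−H)` — the scalar case of a
Hotelling T² with U−H denominator degrees of freedom.

## Simulators

The study population holds 2,500 PSUs × 40 trio families (300,000 people)
by default. Parents are independent draws from the fixation-index
distribution; children follow Mendelian transmission (one uniformly chosen
allele per parent). The clustered scenario stably sorts families by their
within-family count of genotype aa (ties keep generation order) and
regroups consecutive blocks of 40 into PSUs, giving intra-PSU correlation
of the genetic data (ICC of the family aa count ≈ 1 by construction, ≈ 0
before). Samples are simple random draws of 60 PSUs, all families kept.
Weights are either unit or {1,3,5} assigned to uniformly random exact
thirds — at the family level by default, since the familial-type counts
need a family weight and family-level placement is the only reading that
requires no extra averaging rule; a per-individual mode (family weight =
member mean) is available for sensitivity.

The household-survey demonstration frame carries 307 trio families (921
people) on a synthetic stratified design (10 strata × 3 PSUs by default,
families allocated round-robin). Within-family screening weights are 2 for
the child's age class and 1.33 for the parents' (subsampling rates 50% and
75%); synthetic final weights are lognormal around a stratum-trending base
(an oversampling gradient), noninformative of genotype; the family weight
averages members' final/within-family ratios. Genotypes use the compound
two-step model: a per-family allele frequency drawn from
`Beta((1−r)f_A/r, (1−r)(1−f_A)/r)` (mean `f_A`, variance `r f_A(1−f_A)`,
degenerate at `f_A` when r = 0), then parental allele pairs `Bin(2, p_A)`
and Mendelian children. Drawing the Beta *per family* is what makes the
within-family allele correlation equal r, which the tests verify by an
ANOVA intraclass-correlation estimator; a single population-level draw
would induce no within-sample disequilibrium structure.

What the generators do *not* emulate: genotyping error, missing members,
nonresponse/poststratification weight adjustments, informative
within-family selection by phenotype, real multi-stage geography. Passing
the Monte-Carlo checks therefore demonstrates correctness of the
estimators under the stated sampling model, not robustness to those
real-data features.

## Monte-Carlo study

The study runner regenerates the finite population each replicate (a
fixed-population mode with PSU-only resampling exists for sensitivity;
measured rates agree), samples, weights, runs all five tests, and reports
rejection proportions at α = 0.05 with binomial Monte-Carlo standard
errors. Per-replicate random streams are spawned from the master seed
(`numpy SeedSequence`), so any replicate or scenario is independently
reproducible. Replicates with degenerate samples are excluded and counted;
a run fails if more than 1% are. The acceptance script uses 1,000
replicates per scenario (a few minutes on one CPU); the test suite's
reproduction checks use 200 replicates with correspondingly wider
±3·SE bands.

## Numerical notes and limitations

- Eigenvalues of Σ̂M are computed by a general (non-symmetric) solver; real
  parts are used, and a warning is raised if a discarded eigenvalue exceeds
  1e-6·λ̄.
- Monomorphic samples (p̂ ∈ {0,1}) raise an explicit error: no HWE test is
  defined.
- The QS covariance is evaluated at (p̃, r=0) — the score test works at the
  null-restricted fit.
- Only trios are supported end to end; the sib covariance block exists but
  general pedigrees are out of scope, as are multiallelic loci and
  interval estimation of r.
- Under strong clustering the first-order Rao–Scott correction is known to
  be anticonservative (its size exceeds the nominal level in the clustered
  scenario) and the second-order/F corrections conservative; the
  quasi-score test holds size best in our experiments — consistent with
  the methodological literature this package implements.
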