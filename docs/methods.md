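# Methods

`snppanel` re-implements, as a tested pipeline, a multi-test procedure for
partitioning a SNP panel into putatively **neutral**, **candidate**
(non-neutral) and **ambiguous** loci, and for contrasting the population
structure carried by the neutral and candidate panels. The target system
is a salmonid riverscape — on the order of a hundred populations in
regional groups, genotyped at a few hundred biallelic SNPs, with
per-population climate and geography covariates — but nothing in the code
is specific to fish.

## The decision rule

A locus is *flagged* for scrutiny by any of three criteria:

1. **FST outlier.** Its Weir–Cockerham θ lies above the 99% quantile of a
   neutral envelope conditioned on heterozygosity (FDIST-style test, below).
2. **Precedence.** It appears on a user-supplied list of loci with prior
   evidence of environmental or life-history association.
3. **Environmental regression.** Per-population frequency of the
   panel-minor allele regresses on a physical variable with a slope
   p-value below the Bonferroni threshold α/(number of loci), *and* the
   association survives re-estimation without a configured exclusion
   group (see "Robustness exclusion").

Criterion 4 is the arbiter: for every flagged locus, a distance-based
multivariate regression (DISTLM) ranks environmental variable sets
against neutral-structure control sets on the locus's own pairwise-FST
matrix. A flagged locus becomes **candidate** only when the top-ranked
variable (first forward selection, permutation p < 0.05) is
environmental; if a control set (admixture Q or PCoA eigenvectors) ranks
highest — or nothing is significant — an outlier/precedence-flagged locus
is **ambiguous** and a regression-only flag reverts to **neutral** (a
config switch routes that case to ambiguous instead; the boundary between
those two readings is genuinely open and we chose the stricter
definition of ambiguous). Unflagged loci are neutral.

## Statistics

**Allele statistics.** The minor allele is fixed once, panel-wide, at
load or simulation time (lower overall frequency; ties to the smaller
allele code). Per-population frequencies of that allele are used
*unfolded* in regressions so that cline direction survives; folding to
[0, 0.5] happens only where a MAF summary requires it. Missing calls are
handled pairwise-complete; there is no imputation.

**Hardy–Weinberg.** The exact conditional distribution of the
heterozygote count given the allele counts is enumerated in full — the
distribution that genepop-style MCMC approximates — so p-values are
deterministic. Departure paring removes a locus when the fraction of
populations significant at the Benjamini–Yekutieli threshold
α/Σ(1/i) (i = 1..loci×populations) exceeds `max_departure_frac`
(default 0.08, chosen so that 12 departures in 145 populations — the
situation printed for the published panel — triggers removal while
fewer do not).

**Linkage.** A log-likelihood-ratio G statistic on the 3×3 two-locus
genotype table, with a permutation p-value within each population.
Because all-pairs permutation testing is quadratic, pairs are
pre-screened by genotype correlation across individuals (|r| ≥ 0.3;
background structure at the differentiation scales targeted here
produces correlations an order of magnitude smaller). Flagged pairs are
merged into connected components — so a locus linked to two others forms
a trio — and only the highest-panel-MAF member of each component is
retained, ties broken lexicographically.

**Weir–Cockerham θ.** The 1984 variance components a, b, c per locus;
multilocus θ = Σa/Σ(a+b+c); pairwise population matrices from the same
estimator. Negative estimates are reported as-is in tables, but floored
at zero (and counted) wherever a matrix is used as a distance.

**Outlier scan.** The neutral null is a symmetric finite island model
with 100 demes; sampled demes mirror the observed design (one per
observed population, capped at 100, each at the observed median sample
size). The migration parameter M = 4Nm is calibrated by log-space
bisection until the simulated mean FST of a pilot batch matches the
observed multilocus θ within ±0.005. Each null locus is one structured
coalescent genealogy with a single mutation placed uniformly along the
total branch length (infinite sites; uniform placement on a
sample-spanning genealogy guarantees polymorphism in the total sample).
The coalescent is implemented directly for the island model (numba-compiled
Gillespie simulation exploiting deme exchangeability, ~3 ms per locus at
50 demes × 15 diploids); a general-purpose structured-coalescent engine
(msprime) runs the same model about 500× slower and serves as the
independent distributional cross-check in the test suite. Conditional
p-values use the `k` null loci nearest in He (default k = 2000) rather
than fixed He bins; p ≤ 0.01 flags directional, p ≥ 0.99 balancing.
Balancing flags are computed but do not feed classification by default.
He is mean within-deme expected heterozygosity; a switch exposes
total-sample He instead.

**Neutral-structure controls.** The admixture model (each gene copy
drawn from cluster k with probability q_ik, carrying the counted allele
with probability f_kl) is fitted by EM with random restarts; the
log-likelihood is non-decreasing by construction and the best restart is
kept. This replaces the usual Bayesian MCMC engine for the same model
family — a deliberate trade of the correlated-frequencies prior for
determinism at desk scale. K is chosen by the Evanno Δk statistic over
restart log-likelihoods (Δk = |L''(K)|/sd(L(K)), interior K only);
replicate Q matrices are aligned by exact search over column
permutations (greedy above K = 8). Controls per population are the mean
Q columns (the last dropped — rows sum to one) and the first three PCoA
eigenvectors of the neutral-locus pairwise-θ matrix. The published
procedure computes EV controls from loci that are later re-tested; we
reproduce that, with a flag to use a disjoint locus subsample instead.

**DISTLM.** Response G = Gower-centred −½D² of the locus-specific
pairwise-θ matrix. Single-locus FST matrices are strongly non-Euclidean,
which can push the explained proportion above one and the residual trace
negative; a Lingoes correction (adding −λ_min to every nontrivial
eigenvalue of G) is applied first, leaving Euclidean inputs untouched.
Predictors are per-population values (the canonical DISTLM formulation),
entered individually or in declared sets (temperature, precipitation,
geography, Q, EV). The pseudo-F is the McArdle–Anderson trace ratio with
an n−m−1 denominator over all fitted columns; conditional p-values are
Freedman–Lane permutations of the reduced-model residual matrix. Forward
selection enters, at each step, the candidate giving the model the
largest **adjusted** R² — raw explained variation is biased toward
larger sets, and with sets of 3–10 columns competing that bias decides
rankings; adjusted R² is the standard DISTLM remedy. Controls compete
freely by default; a `force_controls_first` switch conditions every
environmental test on Q+EV instead.

**Robustness exclusion.** When a geographically coherent group dominates
one end of a climate gradient, its shared drift can masquerade as an
association at many loci. The univariate scan is therefore re-run
without a configured exclusion group, and only associations significant
in both runs count toward criterion 3. In the synthetic study the
excluded group is the regional block with the highest mean of the cline
variable — the analogue of excluding the one wet, genetically distinct
river group in the motivating analysis.

**Trees and ranking.** Nei's standard distance (D = −ln(J_xy/√(J_x J_y)),
homozygosities averaged over loci; infinite D capped at 50 and flagged)
feeds Saitou–Nei neighbor joining with the Studier–Keppler criterion;
negative branch lengths are clamped to zero with the deficit moved to the
sibling edge, and clamps are counted. Bootstrap resamples **loci** with
replacement (the units the multilocus distance aggregates); the consensus
keeps bipartitions above 50% replicate frequency and then greedily adds
compatible minority bipartitions (majority-rule extended; strict-only by
switch), with supports as replicate percentages and branch lengths copied
from the full-data tree where edges coincide. The climate ranking
averages five component ranks — spring and summer maximum temperature
descending, elevation ascending, spring and summer precipitation
ascending — with average-rank ties, ordering populations hot/dry to
cold/wet. Mantel tests are one-tailed (positive association), Pearson r
over off-diagonal entries, p = (#{r* ≥ r}+1)/(n_perm+1) with 9999
permutations by default.

## The synthetic riverscape

The generator is the study-condition definition, not a convenience
fixture. Populations sit on a west–east lattice transect; elevation is a
gradient plus Gaussian noise (SD 150 m); monthly maximum temperatures
fall with elevation (6.5 °C/km) and latitude (0.8 °C/degree) and carry
independent per-month station noise so the temperature block is
correlated but not rank-deficient (real climate normals are not);
minimum temperatures sit ~10 °C below with their own noise; annual
precipitation is negatively correlated with summer maximum temperature
(ρ = −0.6) and distributed over a winter-heavy monthly profile with
log-normal jitter. Migration distance is the lattice path length from
the downstream origin.

Genotypes follow the Balding–Nichols F-model: ancestral frequencies
Uniform(0.1, 0.9), regional then population frequencies Beta-distributed
around their parent with variances F_region·p(1−p) and F_pop·p(1−p)
(defaults 0.02 and 0.03, giving multilocus θ ≈ 0.05 — the within-lineage
differentiation scale of the motivating system). Candidate loci receive
a logit-scale shift of β per SD of the cline variable applied to the
population frequency (default β = 1.0 on summer precipitation);
genotypes are Binomial(2, p). QC defects are planted on request:
uniform missingness, individuals with ~15% missing calls, hybrids
carrying alien alleles at appended diagnostic loci, exact duplicate
loci, and heterozygote-excess loci. Closed-form drift expectations
(F_region + (1−F_region)·F_pop between regions) calibrate outlier-scan
targets.

What the generator does **not** emulate: linkage maps and recombination,
within-population spatial substructure, temporal sampling, genotyping
error beyond the planted defects, non-equilibrium demography (bottlenecks,
expansions), and clines in more than one variable at once. Passing the
recovery study therefore shows the decision rule works when its modelling
assumptions hold at realistic effect sizes and noise levels — not that it
is robust to demographic histories the island-model null mis-specifies.

## Problem sizes and numerical choices

Deliberate desk-scale sizes, chosen once: the recovery study runs 20
replicates of the full pipeline at 50 populations × 30 individuals × 200
loci with a 4000-locus null (pilot batches of 400, He window k = 1000),
99 DISTLM permutations and 2 EM restarts (300 iterations, tolerance
1e-4); the single demonstration run uses a 20,000-locus null, 199
permutations, 200 bootstrap replicates and 9999 Mantel permutations.
Null distributions at the published scale (50,000 loci) remain the
library default. Degenerate cases are handled explicitly: monomorphic
loci are excluded from θ sums and skipped (with reasons) by the per-locus
DISTLM; a perfect DISTLM fit (numerically zero residual trace) maps to an
infinite pseudo-F rather than a sign flip; zero-variance predictors are
dropped with warnings; collinear design columns are removed by a greedy
rank screen; permutation p-values are floored at 1/(n_perm+1), and the
linkage-paring threshold cannot fall below that floor.

## Known limitations

- The island-model null assumes symmetric migration among equal demes;
  hierarchical structure inflates FST variance, and the pipeline's answer
  is the control-variable machinery, not a hierarchical null.
- A neutral locus whose regional drift happens to be monotone along the
  environmental gradient is indistinguishable from a weak cline by any
  of the four criteria; the recovery study shows this residual
  false-candidate rate is below 1% of neutral loci under the study
  conditions, but it is not zero, so small candidate panels should be
  read with that base rate in mind.
- The EM admixture engine finds local optima; restarts mitigate but do
  not guarantee the global maximum, and Δk over restart likelihoods is a
  rougher instrument than Δk over long MCMC runs.
- Bonferroni's m is the number of loci (per panel), not loci × variables;
  the printed threshold of the motivating analysis is consistent with
  that reading, and the setting is configurable.
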