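# Methods

## The LD measure

For two biallelic loci, linkage disequilibrium is quantified as

    delta^2 = E[D^2] / E[W]

the ratio of expectations (ratio of sums over locus pairs, never a mean of
ratios) of the squared two-locus covariance `D^2` to the product of
per-locus variances `W = V_i V_j`.  From unphased diploid genotypes the
covariance is the Burrows composite covariance on the per-gamete scale,

    D = cov(x, y) / 2

for dosage vectors `x, y` in {0,1,2}, which needs no phase information.
Per-locus variances are taken on the same scale, `V = var(x)/2`.  Under
Hardy-Weinberg proportions `V` estimates `p(1-p)`; in a pooled sample from
a structured population it additionally carries the Wahlund excess
`p(1-p)(1+F_ST)`.  This variance-based normalisation (Weir's
composite-correlation convention) keeps `delta^2 <= 1` and makes the
measure exact in the fully differentiated limit.

**Finite-sample correction.**  Conditional on the observed values of two
vectors with no real association, their pairing is an exchangeable
permutation, so the sample covariance obeys
`E[cov^2] = s_x^2 s_y^2 / (n-1)` *exactly*, at any allele frequencies and
under any within-sample structure.  Every pair therefore contributes
`D^2 - W/(n-1)` to the numerator sum.  The corrected delta^2 of
independent loci has mean zero (verified by a permutation oracle in the
test suite); real associations are estimated with only `O(rho^2/n)`
relative bias.

**Recombination fractions.**  Pairs on different chromosomes have
`c = 0.5`.  Within chromosomes the Haldane map function (no interference)
converts genetic distance: `c = (1 - exp(-2 d_Morgans))/2`.  This is also
exactly the per-meiosis segregation probability of the discrete-time
Wright-Fisher simulator, keeping estimator and oracle on one scale.

## Drift expectation and contemporary N_e

At drift equilibrium the within-population (panmictic) expectation used
throughout is

    E[delta2_w] = (1-F_ST)^2 ((1-c)^2 + c^2) /
                  (2 N_T (1-(1-c)^2) + 2.2 (1-c)^2)

with `N_T` the summed diploid effective size.  At `c = 0.5` this is
`0.5/(1.5 N + 0.55)`, i.e. approximately `1/(3N)` — the classic unlinked
drift LD — and for small `c` it approaches `1/(4Nc)`.  The form was
verified against discrete-time Wright-Fisher simulation at
`c in {0.05, 0.1, 0.25, 0.5}` (N = 200, n = 100): agreement within
Monte-Carlo error at every point.  The contemporary panmictic estimator
`ne_panmictic` is the exact algebraic inverse at `c = 0.5`
(`N_e = (0.5/delta^2 - 0.55)/1.5`), optionally combined (geometric mean)
with a numerical inversion over the weakly linked set.

Confidence intervals are delete-one-chromosome jackknives on log N_e
(>= 4 chromosomes required); dropping whole chromosomes respects the
correlation of pairs that share a chromosome.

## Island-model structure

A metapopulation of `s` equal demes of size `N` with reciprocal migration
`m` partitions the population-scale LD as

    delta^2 = delta2_w + delta2_b + 2 delta2_bw
    delta2_b  ~= F_ST^2 / (s-1)
    delta2_bw ~= (s/(s-1))^2 delta2_b m / (1 - (1 - (s/(s-1)) m)^2 (1-c))

linked by the finite-island equilibrium differentiation (Takahata's
relation, adopted closed form)

    F_ST = 1 / (1 + 4 N m alpha),   alpha = (s/(s-1))^2

and `N_e = N_T / (1 - F_ST)` with `N_T = s N`.  The adopted `F_ST` form
was checked against island-model coalescent simulation (predicted 0.0588
vs measured Wahlund deficit 0.0590 +- 0.0016 for N=1000, s=2, m=0.001).

**Observation model.**  The partition above is population-scale (single
gametes, variances from metapopulation frequencies).  What the composite
estimator measures in a pooled sample of *individuals* differs in two
systematic ways, both derived from the fact that the two gametes of an
individual come from the same deme:

* the between-deme frequency covariance enters the composite covariance
  twice, so `delta2_b` appears x4 and the cross term x2;
* per-locus variances carry the Wahlund excess, dividing everything by
  `(1+F_ST)^2`.

Hence `E[delta2_obs(c)] = (delta2_w + 4 delta2_b + 4 delta2_bw)/(1+F_ST)^2`.
The factor was validated on simulations (measured unlinked delta^2
1.31e-2 +- 0.06e-2 vs predicted 1.27e-2 in the two-deme benchmark; the
naive population-scale prediction, 3.4e-3, is excluded by ~15 SE) and via
the exact deme-labelled decomposition of the pooled covariance
(`decompose_delta2`).

**Solver.**  Three observables — corrected delta^2 of unlinked pairs,
corrected delta^2 of weakly linked pairs (0.05 < c < 0.5), and the
observed inbreeding coefficient F-hat (small-sample-unbiased expected
heterozygosity) — constrain `(N, s, m)`.  The fit is weighted least
squares in the *decorrelated* basis `(delta2_u, delta2_w - delta2_u,
F-hat)`: the between-deme sampling noise (the realised differentiation of
the particular genome) is common to both delta^2 summaries, so their
difference — the drift signal that identifies `N_T` — is several-fold
less noisy than either summary alone, while `delta2_u` and `F-hat` are
two noisy, mutually redundant measures of differentiation.  Residual
scales are delete-one-chromosome jackknife standard errors of each basis
quantity (inverse-variance weighting estimated from the data, no tuned
constants; relative floors guard against jackknife underestimates, and
the plain observables serve as scales when no per-chromosome parts are
available).  For each integer `s` (2..50 by default) the solver runs
Nelder-Mead over `(ln N, ln 4 N m alpha)` — the second coordinate fixes
the equilibrium F_ST directly, so the near-degenerate ridge
`N m ~ const` of the surface is axis-aligned and the optimiser cannot
drift toward the `N -> inf, m -> 0` corner — from a seeded grid of starts
including one matching the observed F-hat exactly, with warm starts
across s and a restart polish.  The weak observable is predicted by
averaging the model over the W-weighted empirical c distribution of the
included pairs, not a single effective c — the expectation is a ratio of
sums, so this is the faithful aggregation.  F-hat enters as a soft
residual rather than a constraint, for robustness to noisy
heterozygosity.
Panmixia (`s = 1`) is reported when its fit is within 20% of the best
structured fit; ties between structured models go to the smaller `s`
(parsimony).  Haploid input has no F-hat; the solver then uses the two
delta^2 observables only, and `s` is weakly identified (documented
limitation).  A corrected delta^2 at or below zero (pure sampling noise)
is floored with a warning and the resulting N_e is a lower bound.

Known behaviour at the edges, matching theory: when `N m >> 1`
differentiation is tiny and `m` tends to be underestimated; estimates
remain in range and the comparison between the structure-aware and
panmictic N_e (similar => panmixia; panmictic much lower => subdivision)
is the recommended diagnostic.

## Recent historical trajectories

LD at recombination fraction `c` mostly reflects drift about `1/(2c)`
generations before sampling (assuming roughly linear change).  The
trajectory routine inverts the drift expectation per logarithmic c bin
(30 bins over [0.001, 0.5], >= 100 pairs per bin, sparse bins merged
toward larger c), giving `N_e(t)` for `t = 1/(2 c_bin)`.  With structure
estimates available, each bin's composite delta^2 is first mapped to the
population scale and the (c-constant) between-deme floor
`4 delta2_b + 4 delta2_bw` subtracted, removing the spurious
recent-decline artefact of pooled structured samples; bins at or below
the floor are dropped with a warning.  This per-bin substitution yields an
approximate demographic *trend* only — it ignores that each bin's LD
integrates the whole history; no hidden-Markov demographic-history search
is attempted.  An optional moving geometric mean smooths adjacent bins.

X-vs-autosome helpers implement the printed constants: male-sampled X
maps are scaled by 2/3, Drosophila male autosomal maps by 1/2 (achiasmatic
male meiosis), and haploid X-based N_e maps to the autosomal diploid scale
by x(4/3)/2.

## Data-quality corrections

**Base-calling errors** (rate `eps` per allele copy, symmetric): the
covariance attenuates as `D' = D [1 - 4 eps(1-eps)]` and the variance
inflates as `V' = V + eps(1-4V)`.  Both maps are inverted per locus/pair
inside the LD accumulation when an error rate is supplied; the variance
map is singular at `eps = 1/4` (V' = 1/4 regardless of V), so the
correction requires `eps < 0.25` — far above realistic rates.  Without
correction, the shrunken delta^2 reads as an inflated N_e.  The
correction applies to panmictic analyses only and is rejected in
combination with the structure mode (differentiation signals are of the
same order as the error terms).

**Low sequencing depth**: heterozygotes miscalled as homozygotes inflate
dosage variances and thus deflate delta^2.  The non-parametric fix builds
pseudohaploid genomes by drawing one allele at random per observed
heterozygous site.  A miscalled heterozygote is itself a fair draw of one
of its alleles, so the pseudohaploid allele is an unbiased single-gamete
sample at *any* depth profile.  Because the per-site gamete choice is
independent across sites, the pseudohaploid cross-locus covariance is
`cov(x, y)/4`, attenuating delta^2 exactly fourfold; the pipeline rescales
by 4 before inversion.  Estimation is repeated over 50 independent draws
and averaged geometrically (N_e is a log-scale quantity; the choice of
mean is ours).

## The simulator

`island_simulator` generates the study conditions for every estimator:
`s` demes of size `N`, reciprocal migration `m`, multi-chromosome genomes
(default desk scale: 4 chromosomes x 100 cM; the headline benchmark uses
12) with neutral biallelic mutation, and step changes of deme size for
decline/expansion/bottleneck profiles.

The default engine is coalescent, in two phases.  The recent
`dtwf_generations` (default 40-100) generations of the *whole genome* run
under msprime's discrete-time Wright-Fisher model with chromosomes joined
by recombination-probability-1/2 gaps: the shared population pedigree of
those generations is precisely what creates drift LD between unlinked
loci, and discrete meiosis is what the Haldane/`2.2`-term algebra
describes.  Each chromosome's deeper ancestry is then completed in a
separate standard-coalescent continuation (cross-chromosome LD from
beyond the DTWF phase decays as `4^-t` and is negligible after a few
generations; the continuation was validated pairwise against full-DTWF
runs).  A forward discrete-generation Wright-Fisher engine (explicit
migration, Haldane recombination, recurrent mutation on a fixed site
grid) cross-validates the coalescent path at small scale.

What the simulator does *not* emulate: selection, gene conversion,
non-equilibrium mutation spectra, SNP-array ascertainment, map
heterogeneity, overlapping generations, and mating systems other than
random union within demes.  Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to every feature of real data.

Corruption operators add data-quality defects with known truth:
per-allele flips at rate `eps`, and het->hom conversion at a given rate
(rate 1/2 ~ 2x depth).

## Benchmark problem sizes

The headline two-deme benchmark runs 10 replicates of `2 x 1000`
individuals, `m = 0.001`, 100 sampled individuals, ~13k common SNPs over
12 chromosomes of 100 cM (the empirical study design it scales down used
20 such chromosomes and ~50k SNPs; 12 keeps the weak-vs-unlinked
differential that identifies `N_T` adequately replicated while remaining
desk-sized).  The data-quality checks use panmictic `N = 500` with ~5k
SNPs over 4 chromosomes; the oracle-equivalence check uses `N = 200` with
2 chromosomes.  Mutation rates are set to hit these SNP counts at the
chosen physical lengths (20 Mb per chromosome), not taken from any
organism.

## Numerical choices and defaults

* site filters: call rate >= 0.9, sample MAF >= 0.01 (both configurable;
  delta^2 ratios are unstable at extreme frequencies);
* optional minimum chromosome length filter (off by default);
* weakly linked window 0.05 < c < 0.5; 30 log bins on [0.001, 0.5] with
  >= 100 pairs per bin;
* cross-chromosome pair budget 5e7, enforced by seeded uniform column
  subsampling per chromosome pair;
* missing genotypes are masked, never imputed; with missing data an exact
  pairwise-complete path (per-pair n, means, variances from masked matrix
  products) replaces the fast path;
* monomorphic-pair and n < 4 pairs are skipped, contributing to neither
  sum;
* all randomness (subsampling, pseudohaploid draws, simulator) is seeded;
  estimates are invariant to SNP order and allele relabelling.

## Known limitations

* The structure model assumes migration-drift equilibrium of a symmetric
  island metapopulation; asymmetric/stepping-stone migration and unequal
  demes are simulated for robustness checks but not modelled.
* The between-deme and cross closed forms are approximations; at moderate
  F_ST their small systematic deviations propagate into N_T, whose
  geometric mean across benchmark replicates sits within ~15% of truth
  rather than on it.
* `N_T` identification rests on the small difference between weakly
  linked and unlinked LD; with few chromosomes its replicate-to-replicate
  spread is large (hence geometric means over replicates and the 12-
  chromosome benchmark genome).
* Trajectories are approximate trends; depths beyond `1/(2 c_min)`
  generations are not reported.
* Genotyping-error and depth corrections assume panmixia and a known,
  site-independent error rate.
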