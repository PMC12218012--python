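# ldne

Linkage-disequilibrium inference of contemporary and recent-historical
effective population size (N_e) from a single sample of unphased SNP
genotypes — with explicit handling of metapopulation structure,
genotyping errors and low sequencing depth, and a built-in island-model
simulator that makes every estimator testable without external data.

Intended users: population, conservation and evolutionary geneticists with
one genotyped sample (VCF or PLINK PED/TPED) from a possibly subdivided
population, who want contemporary N_e, the differentiation index F_ST,
the migration rate m, the number of subpopulations s, and an approximate
N_e trajectory over the recent past.

## The idea

Linkage disequilibrium is measured as `delta^2 = E[D^2]/E[W]`, the ratio of
expectations of squared Burrows composite covariances to products of
per-locus variances, corrected exactly for finite sampling
(`E[cov^2] = s_x^2 s_y^2/(n-1)` for unassociated loci).  At drift
equilibrium,

    E[delta2] = ((1-c)^2 + c^2) / (2 N_e (1-(1-c)^2) + 2.2 (1-c)^2)

for recombination fraction c, so unlinked loci (c = 1/2, different
chromosomes) give contemporary N_e ~ by inverting `0.5/(1.5 N_e + 0.55)`.

A pooled sample from an island metapopulation (s demes of size N,
migration m) adds a two-locus Wahlund effect: the LD partitions as

    delta^2 = delta2_w + delta2_b + 2 delta2_bw,
    delta2_w  = (1-F_ST)^2 ((1-c)^2+c^2) / (2 N_T (1-(1-c)^2) + 2.2(1-c)^2)
    delta2_b  ~ F_ST^2/(s-1),       F_ST = 1/(1 + 4 N m (s/(s-1))^2)

with `N_T = s N` and `N_e = N_T/(1-F_ST)`.  Three observables from one
sample — delta^2 of unlinked pairs, delta^2 of weakly linked pairs
(c > 0.05), and the heterozygote-deficit F-hat — then jointly determine
(N, s, m).  Ignoring subdivision collapses N_e far below N_T, because
unlinked LD is dominated by F_ST^2 rather than drift.  Binned delta^2(c)
inverted per bin maps to N_e about `1/(2c)` generations ago, sketching the
recent trajectory; structure, base-calling errors (`D' = D[1-4e(1-e)]`,
`V' = V + e(1-4V)`) and ~2x depth (random-allele pseudohaploids, 50 draws)
are corrected where requested.  Details and derivations: `docs/methods.md`.

## Worked example

Simulate a two-deme metapopulation (2 x 1000 diploids, one migrant per
thousand per generation), sample 100 individuals from the pooled
metapopulation, and analyse with and without the structure model:

```python
from ldne import (SimConfig, simulate, summarize_ld, LDConfig,
                  solve_metapop, SolverConfig, filter_sites)

cfg = SimConfig(s=2, N=1000, m=0.001, chromosomes=12,
                chrom_length_cM=100.0, mu=1.45e-9, sample_n=100, seed=11)
g, truth = simulate(cfg)                  # ~14k SNPs, truth.N_T == 2000
g = filter_sites(g, maf_min=0.01, call_rate_min=0.0)
obs = summarize_ld(g, LDConfig(seed=11))
est = solve_metapop(obs, SolverConfig(seed=11))
print(est.report())
```

Output from this exact run:

```
Island-model metapopulation estimate
  subpopulations (s) : 2
  deme size (N)      : 1046.82
  migration rate (m) : 0.0009878
  F_ST               : 0.0569971
  N_T = s*N          : 2093.64
  N_e = N_T/(1-F_ST) : 2220.18
  N_e (panmixia)     : 27.86178889847728
  fit residual       : 0.0917
```

Reading it: the structure-aware estimate recovers the true summed deme
size (N_T = 2000) within ~5% and the migration rate within ~1%, and
correctly identifies s = 2 demes at F_ST ~ 0.057 (theory: 0.0588).  The
panmictic estimate (28) is ~1% of the truth — the expected collapse when
subdivision is ignored, and the practical diagnostic for structure:
when the two options agree the sample is effectively panmictic; when the
default is far lower, trust the structure-aware analysis.  (Single
replicates scatter; across ten seeded replicates the geometric-mean N_T
is within ~15% of 2000.)

The same analyses run from the shell on VCF/PED/TPED input:

```
ldne simulate --s 2 -N 1000 -m 0.001 --sample-n 100 --seed 11 -o pop
ldne contemporary pop.vcf -r 5 -x          # structure analysis
ldne contemporary pop.vcf -r 5             # panmictic + jackknife CI
ldne historical pop.vcf -r 5 -x            # N_e(t) trajectory (TSV)
ldne historical lowdepth.vcf -r 1 -g 3     # pseudohaploid depth fix
ldne historical errs.vcf -r 1 -b 0.05      # known 5% error rate
```

(`-r` is the cM/Mb rate used when the input has physical positions only;
`-g 1` analyses haploid data; `-b` cannot be combined with `-x`.)

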