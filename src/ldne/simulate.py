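"""Island-model genotype simulation with known truth.

Two engines generate samples from a Wright-Fisher island metapopulation
(``s`` demes of size ``N``, reciprocal migration ``m``, multi-chromosome
genomes with recombination, neutral biallelic mutation):

* ``coalescent`` (default): msprime, with all chromosomes in a single
  ancestry so that unlinked loci share the population pedigree.  The
  recent ``dtwf_generations`` generations run under the discrete-time
  Wright-Fisher model (chromosomes joined by recombination-probability-1/2
  gaps), which is what creates the drift LD between unlinked and weakly
  linked loci; the deeper history uses the standard coalescent.  Step
  changes of deme size express the usual demographic profiles (decline,
  expansion, bottleneck).
* ``forward``: an explicit discrete-generation Wright-Fisher simulation
  (random mating within demes, island migration, Haldane recombination,
  symmetric recurrent mutation) on a fixed site grid.  It is slow and
  meant for small cross-validation runs against the coalescent engine.

Corruption operators emulate data-quality problems: ``inject_errors``
flips each allele copy independently (base-calling error),
``depth_corruption`` converts heterozygotes to random homozygotes
(low sequencing depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = ["SimConfig", "SimTruth", "simulate", "demographic_event",
           "inject_errors", "depth_corruption", "decompose_delta2"]


@dataclass
class SimConfig:
    """Simulation design.  Defaults are desk-scale: 4 chromosomes of
    100 cM, deme sizes in the hundreds, ~10^4 segregating sites."""

    s: int = 1
    N: float | tuple = 500
    m: float = 0.0
    chromosomes: int = 4
    chrom_length_cM: float = 100.0
    chrom_length_bp: int = 20_000_000
    mu: float = 1.0e-8
    generations: int | None = None      # forward burn-in; default 10*N
    sample_n: int = 100
    sampling_weights: tuple | None = None
    seed: int = 1
    engine: str = "coalescent"
    size_schedule: tuple = ()           # ((t_ago, N), ...) recent sizes
    dtwf_generations: int = 100
    forward_sites_per_chrom: int = 250
    forward_mu_per_site: float = 1e-5

    def deme_sizes(self) -> np.ndarray:
        n = np.atleast_1d(np.asarray(self.N, dtype=float))
        if len(n) == 1:
            n = np.repeat(n, self.s)
        if len(n) != self.s:
            raise ValueError("N vector length must equal s")
        if (n <= 0).any():
            raise ValueError("deme sizes must be positive")
        return n

    def validate(self):
        sizes = self.deme_sizes()
        if self.s < 1:
            raise ValueError("need s >= 1 demes")
        if self.s > 1 and not 0 <= self.m <= (self.s - 1) / self.s:
            raise ValueError("migration rate outside [0, (s-1)/s]")
        if self.s == 1 and self.m != 0:
            raise ValueError("migration requires s >= 2")
        if self.sample_n < 4:
            raise ValueError("sample at least 4 individuals")
        if self.sample_n > sizes.sum():
            raise ValueError("sample larger than the metapopulation")
        if self.chromosomes < 1 or self.chrom_length_cM <= 0:
            raise ValueError("invalid genome configuration")
        ts = [t for t, _ in self.size_schedule]
        if len(ts) != len(set(ts)) or any(t <= 0 for t in ts):
            raise ValueError("size schedule times must be distinct and > 0")


@dataclass
class SimTruth:
    """Ground truth for oracle tests: generating parameters, realized
    differentiation, and deme labels/frequencies of the sampled
    individuals."""

    s: int
    N: tuple
    m: float
    N_T: float
    expected_fst: float | None
    realized_fst: float | None
    deme_of_origin: np.ndarray
    deme_frequencies: np.ndarray | None  # s x n_sites, sample-based
    seed: int

    def to_json(self) -> str:
        import json
        return json.dumps({
            "s": self.s, "N": list(self.N), "m": self.m, "N_T": self.N_T,
            "expected_fst": self.expected_fst,
            "realized_fst": self.realized_fst,
            "deme_of_origin": self.deme_of_origin.tolist(),
            "seed": self.seed}, indent=2)


def demographic_event(config: SimConfig, schedule) -> SimConfig:
    """Add step changes of deme size.  Each (t_ago, N_new) entry sets the
    per-deme size from ``t_ago`` generations before sampling until the
    present (or until a more recent entry).  ``config.N`` is the base
    (ancient) size.  Non-monotone (duplicated-time) schedules are
    rejected."""
    sched = tuple(sorted(((int(t), float(n)) for t, n in schedule)))
    out = replace(config, size_schedule=sched)
    out.validate()
    return out


def _wahlund_fst(dos, labels, ploidy):
    """Realized F_ST as the Wahlund heterozygosity deficit of deme-labelled
    (haploid-safe: frequency-variance form) sample frequencies."""
    labels = np.asarray(labels)
    demes = np.unique(labels)
    if len(demes) < 2:
        return None
    freqs = np.stack([dos[labels == k].mean(axis=0) / ploidy for k in demes])
    w = np.array([(labels == k).mean() for k in demes])[:, None]
    pbar = (freqs * w).sum(axis=0)
    var = ((freqs - pbar) ** 2 * w).sum(axis=0)
    den = (pbar * (1 - pbar)).sum()
    return float(var.sum() / den) if den > 0 else None


def _sample_counts(cfg: SimConfig, rng) -> np.ndarray:
    sizes = cfg.deme_sizes()
    w = np.asarray(cfg.sampling_weights, dtype=float) if cfg.sampling_weights \
        else sizes / sizes.sum()
    w = w / w.sum()
    counts = rng.multinomial(cfg.sample_n, w)
    # keep draws feasible per deme
    while (counts > sizes).any():
        over = np.where(counts > sizes)[0][0]
        spare = np.where(counts < sizes)[0]
        counts[over] -= 1
        counts[rng.choice(spare)] += 1
    return counts


# ---------------------------------------------------------------------------
# coalescent engine
# ---------------------------------------------------------------------------

def _msprime_demography(cfg: SimConfig):
    import msprime

    sizes = cfg.deme_sizes()
    sched = sorted(cfg.size_schedule)  # ascending t_ago
    base = sizes.copy()
    if cfg.s == 1:
        dem = msprime.Demography()
        dem.add_population(name="pop_0", initial_size=float(base[0]))
    else:
        dem = msprime.Demography.island_model(
            initial_size=[float(x) for x in base], migration_rate=cfg.m)
    if sched:
        # present size = most recent entry; at each entry time switch to the
        # size of the next older interval (ratio-scaled for unequal demes)
        ratios = [n / float(np.asarray(cfg.N).flat[0]) for _, n in sched]
        for k in range(cfg.s):
            dem["pop_" + str(k)].initial_size = base[k] * ratios[0]
        for i, (t, _) in enumerate(sched):
            nxt = ratios[i + 1] if i + 1 < len(sched) else 1.0
            for k in range(cfg.s):
                dem.add_population_parameters_change(
                    time=t, initial_size=base[k] * nxt,
                    population="pop_" + str(k))
        dem.sort_events()
    return dem


def _coalescent_sim(cfg: SimConfig):
    """Two-phase coalescent simulation.

    Phase 1 runs the recent ``dtwf_generations`` generations of the whole
    multi-chromosome genome under the discrete-time Wright-Fisher model,
    with chromosomes joined by recombination-probability-1/2 gaps: this is
    what generates the drift LD between unlinked loci (shared population
    pedigree) and the discrete-meiosis behaviour of tightly sampled recent
    generations.  Phase 2 completes the (essentially independent) deep
    ancestry of each chromosome separately under the standard coalescent,
    which avoids the pathological cost of the Hudson model on free-
    recombination gaps.  Cross-chromosome LD older than the DTWF phase
    decays as (1/2)^(2t) per pair and is negligible beyond a few
    generations.
    """
    import msprime

    rng = np.random.default_rng(cfg.seed)
    L, nc = cfg.chrom_length_bp, cfg.chromosomes
    r = (cfg.chrom_length_cM / 100.0) / L
    pos, rates = [0], []
    for k in range(nc):
        rates.append(r)
        pos.append(pos[-1] + L)
        if k < nc - 1:
            rates.append(np.log(2.0))
            pos.append(pos[-1] + 1)
    rmap = msprime.RateMap(position=pos, rate=rates)
    counts = _sample_counts(cfg, rng)
    samples = {f"pop_{k}": int(c) for k, c in enumerate(counts)}
    seed = int(rng.integers(1, 2**31 - 1))
    dem = _msprime_demography(cfg)
    joint = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        recombination_rate=rmap,
        model=msprime.DiscreteTimeWrightFisher(),
        end_time=cfg.dtwf_generations,
        random_seed=seed)
    dos_parts, chrom_parts, bp_parts = [], [], []
    for k in range(nc):
        lo = k * (L + 1)
        tables = joint.dump_tables()
        tables.keep_intervals([[lo, lo + L]], simplify=False)
        tables.rtrim()
        if lo:
            tables.ltrim()
        ts_k = tables.tree_sequence()
        ts_k = msprime.sim_ancestry(
            initial_state=ts_k,
            demography=dem,
            recombination_rate=r,
            start_time=cfg.dtwf_generations,
            random_seed=seed + 11 * k + 1)
        ts_k = msprime.sim_mutations(ts_k, rate=cfg.mu,
                                     random_seed=seed + 11 * k + 7,
                                     model=msprime.BinaryMutationModel())
        G = ts_k.genotype_matrix()  # sites x 2n
        dos_parts.append((G[:, ::2] + G[:, 1::2]).T.astype(np.int8))
        bp_parts.append(ts_k.tables.sites.position.astype(int) + 1)
        chrom_parts.append(np.full(len(bp_parts[-1]), k))
    dos = np.concatenate(dos_parts, axis=1)
    chrom = np.concatenate(chrom_parts)
    pos_bp = np.concatenate(bp_parts)
    cM = (pos_bp - 1) * r * 100.0
    labels = np.repeat(np.arange(cfg.s), counts)
    return dos, chrom, pos_bp, cM, labels


# ---------------------------------------------------------------------------
# forward Wright-Fisher engine
# ---------------------------------------------------------------------------

def _forward_sim(cfg: SimConfig):
    rng = np.random.default_rng(cfg.seed)
    sizes0 = cfg.deme_sizes().astype(int)
    nsite = cfg.forward_sites_per_chrom
    nc = cfg.chromosomes
    L = nsite * nc
    site_cM = np.tile(np.linspace(0, cfg.chrom_length_cM, nsite,
                                  endpoint=False), nc)
    site_chrom = np.repeat(np.arange(nc), nsite)
    gens = cfg.generations or int(10 * sizes0.max())
    # initial frequencies: U-shaped, kept clear of fixation
    p0 = np.clip(rng.beta(0.3, 0.3, size=L), 0.02, 0.98)
    ntot = int(sizes0.sum())
    H = (rng.random((2 * ntot, L)) < p0).astype(np.int8)
    deme = np.repeat(np.arange(cfg.s), sizes0)

    sched = {gens - t: n for t, n in cfg.size_schedule}
    if any(g < 0 for g in sched):
        raise ValueError("schedule time exceeds run length")
    base_sizes = sizes0.copy()

    def make_gamete(parent_row):
        h0 = H[2 * parent_row]
        h1 = H[2 * parent_row + 1]
        gam = np.empty(L, dtype=np.int8)
        for ch in range(nc):
            lo, hi = ch * nsite, (ch + 1) * nsite
            k = rng.poisson(cfg.chrom_length_cM / 100.0)
            cur = rng.integers(0, 2)
            if k == 0:
                gam[lo:hi] = (h1 if cur else h0)[lo:hi]
                continue
            xo = np.sort(rng.random(k) * cfg.chrom_length_cM)
            cuts = np.searchsorted(site_cM[lo:hi], xo) + lo
            prev = lo
            src = (h0, h1)
            for cut in list(cuts) + [hi]:
                gam[prev:cut] = src[cur][prev:cut]
                cur ^= 1
                prev = cut
        return gam

    sizes = sizes0.copy()
    for gen in range(gens):
        if gen in sched:
            ratio = sched[gen] / float(np.asarray(cfg.N).flat[0])
            sizes = np.maximum((base_sizes * ratio).astype(int), 2)
        new_ntot = int(sizes.sum())
        newH = np.empty((2 * new_ntot, L), dtype=np.int8)
        new_deme = np.repeat(np.arange(cfg.s), sizes)
        deme_members = [np.where(deme == k)[0] for k in range(cfg.s)]
        row = 0
        for k in range(cfg.s):
            for _ in range(sizes[k]):
                for copy in range(2):
                    src_deme = k
                    if cfg.s > 1 and rng.random() < cfg.m:
                        others = [d for d in range(cfg.s) if d != k
                                  and len(deme_members[d])]
                        if others:
                            src_deme = others[rng.integers(len(others))]
                    pool = deme_members[src_deme]
                    parent = pool[rng.integers(len(pool))]
                    newH[row] = make_gamete(parent)
                    row += 1
        if cfg.forward_mu_per_site > 0:
            flips = rng.random(newH.shape) < cfg.forward_mu_per_site
            newH[flips] ^= 1
        H, deme = newH, new_deme

    # sample individuals
    counts = _sample_counts(replace(cfg, N=tuple(sizes)), rng)
    rows = []
    labels = []
    for k in range(cfg.s):
        members = np.where(deme == k)[0]
        pick = rng.choice(members, counts[k], replace=False)
        rows.extend(pick)
        labels.extend([k] * counts[k])
    idx = np.array(rows, dtype=int)
    dos = (H[2 * idx] + H[2 * idx + 1]).astype(np.int8)
    bp_per_site = max(cfg.chrom_length_bp // nsite, 1)
    pos_bp = (np.arange(L) % nsite) * bp_per_site + 1
    return dos, site_chrom, pos_bp, site_cM, np.array(labels)


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate a genotype sample plus ground truth.

    Sites monomorphic in the sample are dropped.  Deterministic for a
    fixed ``config.seed``.
    """
    config.validate()
    if config.engine == "coalescent":
        dos, chrom, pos_bp, cM, labels = _coalescent_sim(config)
    elif config.engine == "forward":
        dos, chrom, pos_bp, cM, labels = _forward_sim(config)
    else:
        raise ValueError(f"unknown engine {config.engine!r}")
    p = dos.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    dos, chrom, pos_bp, cM = dos[:, keep], chrom[keep], pos_bp[keep], cM[keep]
    order = np.lexsort((pos_bp, chrom))
    dos, chrom, pos_bp, cM = dos[:, order], chrom[order], pos_bp[order], cM[order]
    # collapse duplicate physical positions (multiple mutation hits)
    _, uniq = np.unique(np.stack([chrom, pos_bp]), axis=1, return_index=True)
    uniq = np.sort(uniq)
    dos, chrom, pos_bp, cM = dos[:, uniq], chrom[uniq], pos_bp[uniq], cM[uniq]
    sites = pd.DataFrame({"chrom": (chrom + 1).astype(str),
                          "pos_bp": pos_bp, "pos_cM": cM,
                          "ref": "A", "alt": "C"})
    g = GenotypeMatrix(dos, np.zeros_like(dos, dtype=bool), 2, sites)
    sizes = config.deme_sizes()
    demes = np.unique(labels)
    freqs = None
    if config.s > 1:
        freqs = np.stack([dos[labels == k].mean(axis=0) / 2.0
                          if (labels == k).any() else np.full(dos.shape[1], np.nan)
                          for k in range(config.s)])
    equal = np.allclose(sizes, sizes[0])
    exp_fst = None
    if config.s > 1 and equal and config.m > 0:
        from .structure import takahata_fst
        exp_fst = takahata_fst(float(sizes[0]), config.m, config.s)
    truth = SimTruth(
        s=config.s, N=tuple(sizes), m=config.m, N_T=float(sizes.sum()),
        expected_fst=exp_fst,
        realized_fst=_wahlund_fst(dos, labels, 2) if config.s > 1 else None,
        deme_of_origin=np.asarray(labels),
        deme_frequencies=freqs, seed=config.seed)
    return g, truth


# ---------------------------------------------------------------------------
# corruption operators
# ---------------------------------------------------------------------------

def inject_errors(g: GenotypeMatrix, epsilon: float, seed: int = 0) -> GenotypeMatrix:
    """Flip each allele copy independently with probability epsilon
    (base-calling error); missing entries untouched."""
    if not 0 <= epsilon <= 0.5:
        raise ValueError("error rate must be in [0, 0.5]")
    if epsilon == 0:
        return g
    rng = np.random.default_rng(seed)
    dos = g.dosages.astype(np.int16)
    alt_to_ref = rng.binomial(dos, epsilon)
    ref_to_alt = rng.binomial(g.ploidy - dos, epsilon)
    out = (dos - alt_to_ref + ref_to_alt).astype(np.int8)
    out = np.where(g.missing, 0, out).astype(np.int8)
    return GenotypeMatrix(out, g.missing.copy(), g.ploidy, g.sites.copy(),
                          list(g.individuals))


def depth_corruption(g: GenotypeMatrix, rate: float = 0.5, seed: int = 0) -> GenotypeMatrix:
    """Convert heterozygotes to homozygotes (0 or 2 with equal chance) with
    probability ``rate``; emulates ~2x depth at rate 1/2."""
    if g.ploidy != 2:
        raise ValueError("depth corruption applies to diploid data")
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    het = (g.dosages == 1) & ~g.missing
    hit = het & (rng.random(g.dosages.shape) < rate)
    homs = rng.integers(0, 2, size=g.dosages.shape).astype(np.int8) * 2
    out = np.where(hit, homs, g.dosages).astype(np.int8)
    return GenotypeMatrix(out, g.missing.copy(), 2, g.sites.copy(),
                          list(g.individuals))


# ---------------------------------------------------------------------------
# deme-labelled LD decomposition (oracle for the partition identity)
# ---------------------------------------------------------------------------

def decompose_delta2(g: GenotypeMatrix, labels, max_snps_per_chrom: int = 800,
                     seed: int = 0):
    """Split the composite covariance of cross-chromosome pairs into
    within-deme and between-deme parts using deme labels.

    For each pair, cov_pooled = sum_k (n_k/n) cov_k + cov of deme means
    (exact algebra with 1/n normalisation), so with A = within part and
    B = between part the pooled D^2 decomposes as A^2 + 2AB + B^2.  The
    function returns the three ratio-of-sums components and their sum,
    which equals the pooled (uncorrected) delta^2 up to floating-point
    error.
    """
    labels = np.asarray(labels)
    if g.ploidy != 2:
        raise ValueError("decomposition expects diploid input")
    rng = np.random.default_rng(seed)
    chroms = [str(c) for c in pd.unique(g.sites["chrom"])]
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes")
    chrom_arr = g.sites["chrom"].astype(str).to_numpy()
    X = g.dosages.astype(float)
    n = X.shape[0]
    demes = np.unique(labels)
    w_k = np.array([(labels == k).mean() for k in demes])
    cols = {}
    for ch in chroms:
        idx = np.where(chrom_arr == ch)[0]
        if len(idx) > max_snps_per_chrom:
            idx = np.sort(rng.choice(idx, max_snps_per_chrom, replace=False))
        cols[ch] = idx

    sums = np.zeros(5)  # A^2, B^2, AB, W, pooled cov^2
    for i, ci in enumerate(chroms):
        for cj in chroms[i + 1:]:
            A_ = X[:, cols[ci]]
            B_ = X[:, cols[cj]]
            Ac = A_ - A_.mean(0)
            Bc = B_ - B_.mean(0)
            pooled = Ac.T @ Bc / n
            within = np.zeros((A_.shape[1], B_.shape[1]))
            means_a, means_b = [], []
            for k, wk in zip(demes, w_k):
                sel = labels == k
                a = A_[sel]
                b = B_[sel]
                am, bm = a.mean(0), b.mean(0)
                within += wk * ((a - am).T @ (b - bm)) / sel.sum()
                means_a.append(am)
                means_b.append(bm)
            ma = np.stack(means_a) - (w_k[:, None] * np.stack(means_a)).sum(0)
            mb = np.stack(means_b) - (w_k[:, None] * np.stack(means_b)).sum(0)
            between = (ma * w_k[:, None]).T @ mb
            A2 = within ** 2
            B2 = between ** 2
            AB = within * between
            sa = np.einsum("ij,ij->j", Ac, Ac) / n
            sb = np.einsum("ij,ij->j", Bc, Bc) / n
            W = np.outer(sa / 2, sb / 2)
            sums += np.array([A2.sum(), B2.sum(), AB.sum(), W.sum(),
                              (pooled ** 2).sum()])
    A2, B2, AB, W, P2 = sums
    return {
        "within": A2 / 4 / W,
        "between": B2 / 4 / W,
        "cross": AB / 4 / W,
        "total": (A2 + B2 + 2 * AB) / 4 / W,
        "total_direct": P2 / 4 / W,
    }
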