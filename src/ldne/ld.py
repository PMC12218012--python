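"""Composite linkage disequilibrium from unphased genotypes.

The LD measure is delta^2, the ratio of expectations of squared two-locus
covariances (D^2) to products of per-locus variances (W), accumulated as a
ratio of sums over pairs.  For unphased diploids D is the Burrows composite
covariance on the per-gamete scale, D = cov(x, y)/2 for dosage vectors x, y;
the per-locus variance is likewise taken on the per-gamete scale,
V_i = var(x_i)/2, which equals p(1-p) under Hardy-Weinberg proportions and
additionally absorbs the Wahlund variance excess in pooled structured
samples (Weir's composite-correlation convention).

Finite sampling inflates D^2: for two loci with no real association the
sample covariance satisfies E[cov^2] = s_x^2 s_y^2 / (n-1) exactly
(conditioning on the observed values, the pairing of x with y is an
exchangeable permutation).  The corrected numerator D^2 - W/(n-1) therefore
has expectation zero for independent loci at any allele frequencies and any
within-sample structure.

Pairs are classed by recombination fraction c (Haldane map function within
chromosomes, c = 0.5 between chromosomes):

* unlinked:      different chromosomes;
* weakly linked: same chromosome, 0.05 < c < 0.5;
* log-spaced c bins for recent-history inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PairLD:
    """Composite LD for one pair of loci: squared covariance D2, variance
    product W, and (when known) recombination fraction c."""

    D2: float
    W: float
    c: float | None = None


@dataclass
class LDConfig:
    weak_c_min: float = 0.05
    weak_c_max: float = 0.5
    n_bins: int = 30
    c_bin_min: float = 0.001
    c_bin_max: float = 0.5
    min_pairs_per_bin: int = 100
    max_unlinked_pairs: float = 5e7
    block_size: int = 1024
    n_weak_hist: int = 40
    error_rate: float | None = None
    seed: int = 0


@dataclass
class LDSummary:
    """Sample-corrected delta^2 observables plus per-chromosome parts.

    ``delta2_unlinked`` and ``delta2_weak`` are ratio-of-sums estimates.
    ``weak_c_centers`` / ``weak_c_weights`` give the W-weighted distribution
    of c over weakly linked pairs (used to predict the weak observable from
    a model).  ``bins`` is a DataFrame (c_mean, delta2, n_pairs) of
    log-spaced same-chromosome bins.  ``parts`` holds per-chromosome(-pair)
    accumulators so chromosomes can be dropped for jackknifing without
    rescanning genotypes.
    """

    delta2_unlinked: float
    delta2_weak: float
    bins: pd.DataFrame
    F_hat: float | None
    n: int
    n_snps: int
    ploidy: int
    weak_c_centers: np.ndarray
    weak_c_weights: np.ndarray
    parts: dict = field(default_factory=dict, repr=False)

    def drop_chromosome(self, chrom) -> "LDSummary":
        """Summary recomputed without one chromosome (for the jackknife)."""
        if not self.parts:
            raise ValueError("summary carries no per-chromosome parts")
        return _assemble(
            {k: v for k, v in self.parts["unlinked"].items()
             if str(chrom) not in k.split("\x00")},
            {k: v for k, v in self.parts["weak"].items() if k != str(chrom)},
            {k: v for k, v in self.parts["bins"].items() if k != str(chrom)},
            {k: v for k, v in self.parts["fhat"].items() if k != str(chrom)},
            self.n,
            self.n_snps,
            self.ploidy,
            self.parts["config"],
        )

    def jackknife_se(self) -> dict:
        """Delete-one-chromosome jackknife standard errors of the
        observables (and of the weak-unlinked difference, whose sampling
        noise is much smaller than that of either observable alone)."""
        chroms = sorted(self.parts["weak"])
        J = len(chroms)
        if J < 3:
            return {}
        loo = [self.drop_chromosome(ch) for ch in chroms]
        out = {}
        for key, get in [
                ("delta2_unlinked", lambda s: s.delta2_unlinked),
                ("delta2_weak", lambda s: s.delta2_weak),
                ("diff", lambda s: s.delta2_weak - s.delta2_unlinked),
                ("F_hat", lambda s: np.nan if s.F_hat is None else s.F_hat)]:
            vals = np.array([get(s) for s in loo], dtype=float)
            if not np.isfinite(vals).all():
                continue
            out[key] = float(np.sqrt((J - 1) / J
                                     * np.sum((vals - vals.mean()) ** 2)))
        return out

    def to_bin_table(self) -> str:
        return self.bins.to_csv(sep="\t", index=False)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def composite_pair_ld(x, y, ploidy: int = 2) -> PairLD:
    """Raw composite LD for one pair of dosage vectors (no sampling
    correction; see :func:`correct_for_sampling`).

    Missing entries may be flagged as NaN; only shared non-missing
    individuals are used.  Monomorphic loci raise ValueError (callers skip
    such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 shared non-missing individuals")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise ValueError("monomorphic locus among shared individuals")
    cov = np.cov(x, y, ddof=1)[0, 1]
    d = cov / ploidy
    return PairLD(D2=d * d, W=(vx / ploidy) * (vy / ploidy))


def correct_for_sampling(d2_raw: float, w: float, n: int, ploidy: int = 2) -> float:
    """Remove the finite-sampling inflation of a squared composite
    covariance: returns d2_raw - w/(n-1), whose expectation is 0 for loci
    with no real association.  ``n`` is the number of individuals."""
    if n < 4:
        raise ValueError(f"sample size {n} too small for the LD correction")
    return d2_raw - w / (n - 1)


def recombination_fraction(d_cM: float, same_chromosome: bool = True) -> float:
    """Map genetic distance to recombination fraction.

    Different chromosomes segregate independently (c = 0.5); within a
    chromosome the Haldane map function (no interference) is used:
    c = (1 - exp(-2 d_Morgans)) / 2.
    """
    if not same_chromosome:
        return 0.5
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative genetic distance")
    c = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(c) if np.isscalar(d_cM) else c


def inbreeding_coefficient(g: GenotypeMatrix) -> float:
    """Observed inbreeding coefficient F-hat = 1 - sum(H_obs)/sum(H_exp).

    H_exp uses the small-sample-unbiased expected heterozygosity
    2pq * 2n/(2n-1).  In a pooled sample from a subdivided population this
    Wahlund heterozygote deficit approximates F_ST.  Haploid input has no
    heterozygotes, so F-hat is undefined (raises ValueError).
    """
    if g.ploidy != 2:
        raise ValueError("inbreeding coefficient undefined for haploid data")
    called = (~g.missing).sum(axis=0)
    ok = called > 1
    het = ((g.dosages == 1) & ~g.missing).sum(axis=0)[ok]
    nc = called[ok]
    alt = np.where(g.missing, 0, g.dosages).sum(axis=0)[ok]
    p = alt / (2 * nc)
    h_obs = het / nc
    h_exp = 2 * p * (1 - p) * (2 * nc) / (2 * nc - 1)
    tot = h_exp.sum()
    if tot <= 0:
        raise ValueError("all sites monomorphic; F undefined")
    return float(1.0 - h_obs.sum() / tot)


def _het_sums(g: GenotypeMatrix, cols: np.ndarray) -> tuple:
    """(sum H_obs, sum unbiased H_exp) over the given site columns."""
    sub_miss = g.missing[:, cols]
    sub_dos = g.dosages[:, cols]
    called = (~sub_miss).sum(axis=0)
    ok = called > 1
    het = ((sub_dos == 1) & ~sub_miss).sum(axis=0)[ok]
    nc = called[ok]
    alt = np.where(sub_miss, 0, sub_dos).sum(axis=0)[ok]
    p = alt / (2 * nc)
    h_obs = het / nc
    h_exp = 2 * p * (1 - p) * (2 * nc) / (2 * nc - 1)
    return float(h_obs.sum()), float(h_exp.sum())


# ---------------------------------------------------------------------------
# blockwise pair accumulation
# ---------------------------------------------------------------------------

def _error_corrected_variances(s2_per_gamete: np.ndarray, eps: float) -> np.ndarray:
    """Invert the genotyping-error variance inflation V' = V + eps(1-4V)
    per locus, clipping the recovered variance into (0, 0.25]."""
    v = (s2_per_gamete - eps) / (1.0 - 4.0 * eps)
    return np.clip(v, 1e-9, 0.25)


class _PairAccumulator:
    """Accumulates corrected-numerator and W sums for blocks of locus pairs.

    With complete data, covariances come from one centred matrix product.
    With missing data an exact pairwise-complete path computes per-pair n,
    means and variances from masked matrix products.
    """

    def __init__(self, g: GenotypeMatrix, config: LDConfig):
        self.ploidy = g.ploidy
        self.cfg = config
        self.has_missing = bool(g.missing.any())
        self.X = np.where(g.missing, 0.0, g.dosages).astype(np.float64)
        self.M = (~g.missing).astype(np.float64)
        self.eps = config.error_rate
        if self.eps is not None and not (0 <= self.eps < 0.25):
            raise ValueError("error rate must be in [0, 0.25) for the LD "
                             "correction (variance map not invertible "
                             "beyond)")

    def block(self, ai: np.ndarray, bi: np.ndarray):
        """Return per-pair (numerator, W) matrices for columns ai x bi.

        numerator = (cov^2 - sx2 sy2/(n-1)) / ploidy^2, error-corrected when
        an error rate is configured; W = (sx2/ploidy)(sy2/ploidy) with the
        same correction.  Pairs with too few shared calls or a monomorphic
        locus get numerator = W = 0 (skipped, contributing to neither sum).
        """
        A, B = self.X[:, ai], self.X[:, bi]
        if not self.has_missing:
            n = A.shape[0]
            Ac = A - A.mean(axis=0)
            Bc = B - B.mean(axis=0)
            cov = Ac.T @ Bc / (n - 1)
            sa = np.einsum("ij,ij->j", Ac, Ac) / (n - 1)
            sb = np.einsum("ij,ij->j", Bc, Bc) / (n - 1)
            s2prod = np.outer(sa, sb)
            npair = np.full(cov.shape, float(n))
        else:
            MA, MB = self.M[:, ai], self.M[:, bi]
            npair = MA.T @ MB
            Sx = (A * MA).T @ MB
            Sy = MA.T @ (B * MB)
            Sxy = A.T @ B
            Sxx = (A * A).T @ MB
            Syy = MA.T @ (B * B)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = (Sxy - Sx * Sy / npair) / (npair - 1)
                sa2 = (Sxx - Sx * Sx / npair) / (npair - 1)
                sb2 = (Syy - Sy * Sy / npair) / (npair - 1)
            s2prod = sa2 * sb2
        bad = (npair < 4) | (s2prod <= 0) | ~np.isfinite(s2prod)
        cov = np.where(bad, 0.0, cov)
        s2prod = np.where(bad, 1.0, s2prod)
        num = (cov * cov - s2prod / (npair - 1)) / self.ploidy**2
        if self.eps is None:
            W = s2prod / self.ploidy**2
        else:
            att = (1.0 - 4.0 * self.eps * (1.0 - self.eps)) ** 2
            num = num / att
            if not self.has_missing:
                va = _error_corrected_variances(sa / self.ploidy, self.eps)
                vb = _error_corrected_variances(sb / self.ploidy, self.eps)
                W = np.outer(va, vb)
            else:
                W = (_error_corrected_variances(sa2 / self.ploidy, self.eps)
                     * _error_corrected_variances(sb2 / self.ploidy, self.eps))
        num[bad] = 0.0
        W = np.asarray(W, dtype=float)
        W[bad] = 0.0
        return num, W


def _blocks(m: int, size: int):
    for lo in range(0, m, size):
        yield np.arange(lo, min(lo + size, m))


def _assemble(unl, weak, bins, fhat_parts, n, n_snps, ploidy,
              cfg: LDConfig) -> LDSummary:
    """Build an LDSummary from per-chromosome(-pair) accumulator dicts."""
    u_num = sum(v[0] for v in unl.values())
    u_w = sum(v[1] for v in unl.values())
    if not unl:
        d2u = np.nan
    else:
        d2u = u_num / u_w if u_w > 0 else np.nan
    w_num = sum(v[0] for v in weak.values())
    w_w = sum(v[1] for v in weak.values())
    d2w = w_num / w_w if weak and w_w > 0 else np.nan
    nh = cfg.n_weak_hist
    hist_edges = np.linspace(cfg.weak_c_min, cfg.weak_c_max, nh + 1)
    centers = 0.5 * (hist_edges[:-1] + hist_edges[1:])
    hw = np.zeros(nh)
    for v in weak.values():
        hw += v[2]
    nb = cfg.n_bins
    b_num = np.zeros(nb)
    b_w = np.zeros(nb)
    b_np = np.zeros(nb)
    b_wc = np.zeros(nb)
    for v in bins.values():
        b_num += v[0]
        b_w += v[1]
        b_np += v[2]
        b_wc += v[3]
    # merge sparse bins upward (toward larger c) until each kept bin has
    # enough pairs
    rows = []
    acc = np.zeros(4)
    for k in range(nb):
        acc += (b_num[k], b_w[k], b_np[k], b_wc[k])
        if acc[2] >= cfg.min_pairs_per_bin and acc[1] > 0:
            rows.append((acc[3] / acc[1], acc[0] / acc[1], int(acc[2])))
            acc = np.zeros(4)
    bins_df = pd.DataFrame(rows, columns=["c_mean", "delta2", "n_pairs"])
    fhat = None
    if fhat_parts:
        hobs = sum(v[0] for v in fhat_parts.values())
        hexp = sum(v[1] for v in fhat_parts.values())
        fhat = float(1.0 - hobs / hexp) if hexp > 0 else None
    return LDSummary(
        delta2_unlinked=float(d2u),
        delta2_weak=float(d2w),
        bins=bins_df,
        F_hat=fhat,
        n=n,
        n_snps=n_snps,
        ploidy=ploidy,
        weak_c_centers=centers,
        weak_c_weights=hw,
        parts={"unlinked": unl, "weak": weak, "bins": bins,
               "fhat": fhat_parts, "config": cfg},
    )


def summarize_ld(g: GenotypeMatrix, config: LDConfig | None = None) -> LDSummary:
    """Compute sample-corrected delta^2 summaries of a genotype matrix.

    Requires genetic positions (pos_cM) on every site.  The unlinked
    summary needs >= 2 chromosomes; cross-chromosome pairs beyond
    ``config.max_unlinked_pairs`` are uniformly subsampled (seeded) by
    thinning columns per chromosome pair.
    """
    cfg = config or LDConfig()
    if g.n_individuals < 4:
        raise ValueError("need >= 4 individuals")
    if not g.has_genetic_positions:
        raise ValueError("genetic positions (cM) required; use "
                         "assign_genetic_positions with a cM/Mb rate")
    g = g.sort_sites()
    chroms = [str(c) for c in pd.unique(g.sites["chrom"])]
    chrom_arr = g.sites["chrom"].astype(str).to_numpy()
    cm = g.sites["pos_cM"].to_numpy(float)
    acc = _PairAccumulator(g, cfg)
    rng = np.random.default_rng(cfg.seed)

    idx = {ch: np.where(chrom_arr == ch)[0] for ch in chroms}
    unl: dict[str, tuple] = {}
    if len(chroms) >= 2:
        total_pairs = 0
        for i, ci in enumerate(chroms):
            for cj in chroms[i + 1:]:
                total_pairs += len(idx[ci]) * len(idx[cj])
        frac = min(1.0, np.sqrt(cfg.max_unlinked_pairs / max(total_pairs, 1)))
        for i, ci in enumerate(chroms):
            for cj in chroms[i + 1:]:
                ai_all, bi_all = idx[ci], idx[cj]
                if frac < 1.0:
                    ai_all = rng.choice(ai_all, max(2, int(len(ai_all) * frac)),
                                        replace=False)
                    bi_all = rng.choice(bi_all, max(2, int(len(bi_all) * frac)),
                                        replace=False)
                ns, ws = 0.0, 0.0
                for ai in _blocks(len(ai_all), cfg.block_size):
                    for bi in _blocks(len(bi_all), cfg.block_size):
                        num, W = acc.block(ai_all[ai], bi_all[bi])
                        ns += num.sum()
                        ws += W.sum()
                unl[f"{ci}\x00{cj}"] = (ns, ws)

    hist_edges = np.linspace(cfg.weak_c_min, cfg.weak_c_max, cfg.n_weak_hist + 1)
    log_edges = np.geomspace(cfg.c_bin_min, cfg.c_bin_max, cfg.n_bins + 1)
    weak: dict[str, tuple] = {}
    bins: dict[str, tuple] = {}
    for ch in chroms:
        cols = idx[ch]
        w_num = w_w = 0.0
        w_hist = np.zeros(cfg.n_weak_hist)
        b_num = np.zeros(cfg.n_bins)
        b_w = np.zeros(cfg.n_bins)
        b_np = np.zeros(cfg.n_bins)
        b_wc = np.zeros(cfg.n_bins)
        for ai in _blocks(len(cols), cfg.block_size):
            for bi in _blocks(len(cols), cfg.block_size):
                if bi[0] < ai[0]:
                    continue
                num, W = acc.block(cols[ai], cols[bi])
                c = recombination_fraction(
                    np.abs(cm[cols[ai]][:, None] - cm[cols[bi]][None, :]))
                if ai[0] == bi[0]:  # diagonal block: keep upper triangle only
                    keep = np.triu(np.ones_like(num, dtype=bool), k=1)
                    num, W, c = num * keep, W * keep, np.where(keep, c, -1.0)
                cf, numf, Wf = c.ravel(), num.ravel(), W.ravel()
                sel = (cf > cfg.weak_c_min) & (cf < cfg.weak_c_max) & (Wf > 0)
                w_num += numf[sel].sum()
                w_w += Wf[sel].sum()
                if sel.any():
                    w_hist += np.histogram(cf[sel], bins=hist_edges,
                                           weights=Wf[sel])[0]
                ok = (cf >= log_edges[0]) & (cf <= log_edges[-1]) & (Wf > 0)
                if ok.any():
                    which = np.clip(np.searchsorted(log_edges, cf[ok]) - 1,
                                    0, cfg.n_bins - 1)
                    b_num += np.bincount(which, numf[ok], minlength=cfg.n_bins)
                    b_w += np.bincount(which, Wf[ok], minlength=cfg.n_bins)
                    b_np += np.bincount(which, minlength=cfg.n_bins)
                    b_wc += np.bincount(which, Wf[ok] * cf[ok],
                                        minlength=cfg.n_bins)
        weak[ch] = (w_num, w_w, w_hist)
        bins[ch] = (b_num, b_w, b_np, b_wc)

    fhat_parts: dict[str, tuple] = {}
    if g.ploidy == 2:
        for ch in chroms:
            fhat_parts[ch] = _het_sums(g, idx[ch])
    out = _assemble(unl, weak, bins, fhat_parts, g.n_individuals, g.n_sites,
                    g.ploidy, cfg)
    if len(chroms) < 2:
        warnings.warn("single chromosome: unlinked (c=0.5) summary unavailable")
    return out
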