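"""Data-quality corrections: genotyping error and low sequencing depth.

Genotyping error.  With per-base error probability eps, an allele is read
as its alternative with probability eps, independently per copy.  The
two-locus covariance attenuates deterministically,

    D' = D [1 - 4 eps (1 - eps)],

while the per-locus variance inflates, V' = V + eps (1 - 4 V).  Both maps
are invertible for eps < 1/2, so delta^2 components measured on error-prone
genotypes can be corrected exactly in expectation.  Uncorrected, the
shrunken delta^2 masquerades as a larger N_e.

Low depth.  Shallow sequencing miscalls heterozygotes as homozygotes,
inflating dosage variance (hence deflating composite delta^2 and inflating
N_e).  The non-parametric fix draws one allele at random at every observed
heterozygous site to build pseudohaploid genomes.  A miscalled heterozygote
already is a fair draw of one of its two alleles, so the pseudohaploid
allele is an unbiased single-gamete sample at any depth.  The pseudohaploid
per-site choice of gamete is independent across sites, which attenuates the
cross-locus covariance fourfold (cov_z = cov(x, y)/4); delta^2 measured on
pseudohaploids is therefore rescaled by PSEUDOHAPLOID_D2_SCALE = 4 before
inversion.  Estimation is repeated over many pseudohaploid draws
(50 by default) and the partial estimates averaged geometrically.

Both corrections assume panmixia; they are not combined with the island
structure analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix
from .ld import LDConfig, summarize_ld

__all__ = ["ErrorModel", "attenuate_covariance", "inflate_variance",
           "correct_observed_ld", "pseudohaploidize", "ne_pseudohaploid",
           "trajectory_pseudohaploid", "PSEUDOHAPLOID_D2_SCALE"]

# Independent per-site gamete choice halves the pseudohaploid covariance
# relative to the per-gamete composite covariance, so delta^2 scales by 4.
PSEUDOHAPLOID_D2_SCALE = 4.0


@dataclass
class ErrorModel:
    """Per-base genotyping error probability."""

    epsilon: float

    def __post_init__(self):
        if not 0 <= self.epsilon <= 0.5:
            raise ValueError("error rate must be in [0, 0.5]")


def attenuate_covariance(D: float, epsilon: float) -> float:
    """Expected two-locus covariance after genotyping error:
    D' = D [1 - 4 eps (1 - eps)]."""
    ErrorModel(epsilon)
    return D * (1.0 - 4.0 * epsilon * (1.0 - epsilon))


def inflate_variance(V: float, epsilon: float) -> float:
    """Expected per-locus variance after genotyping error:
    V' = V + eps (1 - 4 V).  V = p(1-p) must lie in [0, 1/4]; V = 1/4 is a
    fixed point (errors cannot change a half-frequency site)."""
    ErrorModel(epsilon)
    if not 0 <= V <= 0.25:
        raise ValueError("V = p(1-p) must be in [0, 0.25]")
    return V + epsilon * (1.0 - 4.0 * V)


def correct_observed_ld(d2_obs: float, v_i_obs: float, v_j_obs: float,
                        epsilon: float):
    """Invert the error maps: recover (D^2, W) from observed quantities.

    D^2 = d2_obs / [1 - 4 eps(1-eps)]^2 and each variance
    V = (V' - eps)/(1 - 4 eps); the exact algebraic inverse of
    (:func:`attenuate_covariance`, :func:`inflate_variance`).  Recovered
    variances falling outside [0, 1/4] are clipped with a warning.
    Requires eps < 1/2 strictly (eps = 1/2 erases all signal).
    """
    if not 0 <= epsilon < 0.5:
        raise ValueError("error rate must be in [0, 0.5) for inversion")
    if abs(1.0 - 4.0 * epsilon) < 1e-9:
        raise ValueError("variance inflation is not invertible at eps = 1/4 "
                         "(V' = 1/4 regardless of V)")
    d2 = d2_obs / (1.0 - 4.0 * epsilon * (1.0 - epsilon)) ** 2
    vs = []
    for v in (v_i_obs, v_j_obs):
        vc = (v - epsilon) / (1.0 - 4.0 * epsilon)
        if not 0 <= vc <= 0.25:
            import warnings
            warnings.warn("recovered variance outside [0, 0.25]; clipped")
            vc = float(np.clip(vc, 0.0, 0.25))
        vs.append(vc)
    return d2, vs[0] * vs[1]


def pseudohaploidize(g: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """One pseudohaploid genome per diploid individual: heterozygous sites
    contribute a fair random allele, homozygous sites their allele, missing
    stays missing.  Deterministic for a fixed seed."""
    if g.ploidy != 2:
        raise ValueError("pseudohaploidization requires diploid input")
    rng = np.random.default_rng(seed)
    dos = g.dosages
    draw = rng.integers(0, 2, size=dos.shape).astype(np.int8)
    hap = np.where(dos == 1, draw, (dos // 2).astype(np.int8))
    hap = np.where(g.missing, 0, hap).astype(np.int8)
    return GenotypeMatrix(hap, g.missing.copy(), 1, g.sites.copy(),
                          list(g.individuals))


def _pseudo_replicate_summaries(g, reps, config, seed):
    cfg = config or LDConfig()
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(reps):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        yield summarize_ld(pseudohaploidize(g, seed=s), cfg)


def ne_pseudohaploid(g: GenotypeMatrix, reps: int = 50, estimator=None,
                     config: LDConfig | None = None, seed: int = 0):
    """Low-depth-robust contemporary N_e: estimate on ``reps`` independent
    pseudohaploid draws (delta^2 rescaled fourfold, see module docstring)
    and return the geometric mean as an NeEstimate."""
    from .contemporary import NeEstimate, invert_delta2

    if estimator is None:
        def estimator(summ):
            d2 = summ.delta2_unlinked * PSEUDOHAPLOID_D2_SCALE
            if not d2 > 0:
                return np.nan
            return invert_delta2(d2, 0.5)

    vals = []
    for summ in _pseudo_replicate_summaries(g, reps, config, seed):
        vals.append(estimator(summ))
    vals = np.asarray(vals, dtype=float)
    vals = vals[np.isfinite(vals) & (vals > 0)]
    if len(vals) == 0:
        raise ValueError("no pseudohaploid replicate produced a positive "
                         "delta^2; N_e unbounded")
    ne = float(np.exp(np.mean(np.log(vals))))
    return NeEstimate(Ne=ne, basis=f"pseudohaploid_x{len(vals)}")


def trajectory_pseudohaploid(g: GenotypeMatrix, reps: int = 50,
                             config: LDConfig | None = None, seed: int = 0,
                             min_pairs: int = 100):
    """Low-depth-robust historical trajectory: per-bin geometric mean of
    N_e over ``reps`` pseudohaploid draws."""
    import pandas as pd

    from .historical import NeTrajectory, trajectory

    frames = []
    for summ in _pseudo_replicate_summaries(g, reps, config, seed):
        tr = trajectory(summ, structure=None, min_pairs=min_pairs,
                        d2_scale=PSEUDOHAPLOID_D2_SCALE)
        frames.append(tr.points.set_index("t"))
    if not frames:
        raise ValueError("no pseudohaploid replicates")
    all_t = sorted(set().union(*[f.index for f in frames]))
    rows = []
    for t in all_t:
        nes = [np.log(f.loc[t, "Ne"]) for f in frames if t in f.index]
        if len(nes) < max(1, reps // 2):
            continue
        f0 = next(f for f in frames if t in f.index)
        rows.append((t, float(np.exp(np.mean(nes))), float(f0.loc[t, "c_bin"]),
                     int(f0.loc[t, "n_pairs"])))
    return NeTrajectory(pd.DataFrame(rows, columns=["t", "Ne", "c_bin",
                                                    "n_pairs"]))
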