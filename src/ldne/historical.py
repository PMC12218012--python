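"""Recent historical N_e trajectories from recombination-binned LD.

LD between loci at recombination fraction c mostly reflects drift about
1/(2c) generations before sampling (assuming roughly linear change in N_e),
so inverting the drift-LD expectation bin by bin sketches the recent
trajectory: deep bins (small c) speak for the deeper past.  When island
structure has been estimated, the between-deme and cross components
(constant in c at the composite scale, see :mod:`ldne.structure`) are first
subtracted from each bin so that only within-deme drift is inverted; this
removes the spurious recent-decline artefact that pooled structured samples
otherwise produce.

This is a deliberately simple per-bin substitution; it yields an
approximate demographic trend, not a full demographic-history search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .ld import LDSummary
from .structure import (MetapopEstimate, expected_delta2_between,
                        expected_delta2_between_within, metapop_ne,
                        BETWEEN_COMPOSITE_FACTOR,
                        BETWEEN_WITHIN_COMPOSITE_FACTOR)

__all__ = ["NeTrajectory", "trajectory", "x_to_autosome_scale",
           "sex_map_correction"]


@dataclass
class NeTrajectory:
    """Sequence of (t generations ago, N_e) points, one per c bin."""

    points: pd.DataFrame  # columns: t, Ne, c_bin, n_pairs

    def to_tsv(self) -> str:
        return self.points.to_csv(sep="\t", index=False)

    def smoothed(self, window: int = 3) -> "NeTrajectory":
        """Moving geometric mean over adjacent bins (optional smoothing)."""
        p = self.points.copy()
        p["Ne"] = np.exp(np.log(p["Ne"]).rolling(window, center=True,
                                                 min_periods=1).mean())
        return NeTrajectory(p)


def trajectory(
    obs: LDSummary,
    structure: MetapopEstimate | None = None,
    min_pairs: int = 100,
    d2_scale: float = 1.0,
) -> NeTrajectory:
    """Per-bin N_e(t) with t = 1/(2 c_bin).

    With ``structure`` given (s >= 2), each bin's measured composite
    delta^2 is mapped back to the population scale, the between-deme floor
    is subtracted, and the within-deme formula is inverted for N_T at the
    structure's F_ST; N_e(t) = N_T/(1-F_ST).  Without structure the
    panmictic inversion is used directly.  Bins whose delta^2 does not
    exceed the structure floor are dropped with a warning.

    ``d2_scale`` rescales bin delta^2 before inversion (used by the
    pseudohaploid pipeline, whose measure is attenuated fourfold).
    """
    if obs.bins.empty:
        raise ValueError("no recombination bins available")
    rows = []
    dropped = 0
    for _, b in obs.bins.iterrows():
        if b.n_pairs < min_pairs:
            continue
        c = float(b.c_mean)
        d2 = float(b.delta2) * d2_scale
        if structure is not None and structure.s >= 2:
            F, s, m = structure.F_ST, structure.s, structure.m
            floor = (BETWEEN_COMPOSITE_FACTOR * expected_delta2_between(F, s)
                     + BETWEEN_WITHIN_COMPOSITE_FACTOR * 2.0
                     * expected_delta2_between_within(c, F, s, m))
            d2w = d2 * (1.0 + F) ** 2 - floor
            if d2w <= 0:
                dropped += 1
                continue
            prefac = (1.0 - F) ** 2
        else:
            F = 0.0
            d2w = d2
            prefac = 1.0
        if d2w <= 0:
            dropped += 1
            continue
        q = (1.0 - c) ** 2
        n_t = (prefac * (q + c * c) / d2w - 2.2 * q) / (2.0 * (1.0 - q))
        if n_t <= 0:
            dropped += 1
            continue
        rows.append((1.0 / (2.0 * c), metapop_ne(n_t, F), c, int(b.n_pairs)))
    if dropped:
        warnings.warn(f"{dropped} bins at/below the structure floor dropped")
    pts = pd.DataFrame(rows, columns=["t", "Ne", "c_bin", "n_pairs"])
    pts = pts.sort_values("t").drop_duplicates("t").reset_index(drop=True)
    return NeTrajectory(pts)


def x_to_autosome_scale(ne_haploid_x: float) -> float:
    """Rescale a haploid X-chromosome N_e to the autosomal diploid scale:
    multiply by 4/3 (haploid-equivalent in autosomes with equal sex
    numbers), divide by 2 (restore the diploid number)."""
    if not ne_haploid_x > 0:
        raise ValueError("N_e must be positive")
    return ne_haploid_x * (4.0 / 3.0) / 2.0


def autosome_to_x_scale(ne_autosome: float) -> float:
    """Inverse of :func:`x_to_autosome_scale`."""
    if not ne_autosome > 0:
        raise ValueError("N_e must be positive")
    return ne_autosome * 2.0 / (4.0 / 3.0)


def sex_map_correction(sites_or_g, mode: str | None = None):
    """Adjust genetic map for male meiosis.

    mode 'x_male_sample': X chromosomes sampled in males carry a
    female-meiosis map; scale cM by 2/3 (one copy in three does not
    recombine).  mode 'autosome_male_drosophila': Drosophila male meiosis
    is achiasmatic; scale autosomal cM by 1/2.  mode None returns the input
    unchanged.  Accepts a site DataFrame or a GenotypeMatrix.
    """
    factors = {None: 1.0, "x_male_sample": 2.0 / 3.0,
               "autosome_male_drosophila": 0.5}
    if mode not in factors:
        raise ValueError(f"unknown mode {mode!r}")
    f = factors[mode]
    if isinstance(sites_or_g, GenotypeMatrix):
        sites = sites_or_g.sites.copy()
        sites["pos_cM"] = sites["pos_cM"] * f
        return GenotypeMatrix(sites_or_g.dosages, sites_or_g.missing,
                              sites_or_g.ploidy, sites,
                              list(sites_or_g.individuals))
    sites = sites_or_g.copy()
    sites["pos_cM"] = sites["pos_cM"] * f
    return sites
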