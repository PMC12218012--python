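"""Contemporary N_e under panmixia, with chromosome-jackknife CIs.

The point estimate inverts the drift-LD expectation

    E[delta2] = ((1-c)^2 + c^2) / (2 N_e (1-(1-c)^2) + 2.2 (1-c)^2)

at c = 0.5 (unlinked pairs), giving N_e = (0.5/delta2 - 0.55) / 1.5, or at
the weakly linked set by numerically inverting the pair-weighted model.
This is the exact algebraic inverse of
:func:`ldne.structure.expected_delta2_within` with F_ST = 0.

Confidence intervals use a delete-one-chromosome jackknife on the log
scale; dropping whole chromosomes respects the LD correlation structure
among pairs sharing a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix
from .ld import LDConfig, LDSummary, summarize_ld
from .structure import composite_delta2_observed

__all__ = ["NeEstimate", "ne_panmictic", "invert_delta2", "confidence_interval"]


@dataclass
class NeEstimate:
    Ne: float
    ci90: tuple | None = None
    basis: str = "unlinked_pairs"
    lower_bound_only: bool = False

    def report(self) -> str:
        ci = ""
        if self.ci90 is not None:
            ci = f"  90% CI [{self.ci90[0]:.6g}, {self.ci90[1]:.6g}]"
        lb = "  (lower bound)" if self.lower_bound_only else ""
        return f"N_e = {self.Ne:.6g}{ci}  [{self.basis}]{lb}"


def invert_delta2(delta2: float, c: float = 0.5) -> float:
    """Exact inverse of the panmictic drift-LD expectation at fraction c."""
    if not 0 < c <= 0.5:
        raise ValueError("c must be in (0, 0.5]")
    if not delta2 > 0:
        raise ValueError("delta2 must be positive")
    q = (1.0 - c) ** 2
    return ((q + c * c) / delta2 - 2.2 * q) / (2.0 * (1.0 - q))


def _invert_weak(obs: LDSummary) -> float:
    target = obs.delta2_weak
    w = obs.weak_c_weights

    def f(lnN):
        vals = composite_delta2_observed(obs.weak_c_centers, np.exp(lnN), 1, 0.0)
        return float(np.sum(vals * w) / w.sum()) - target

    return float(np.exp(optimize.brentq(f, np.log(1.5), np.log(1e10))))


def ne_panmictic(obs: LDSummary, basis: str = "unlinked_pairs") -> NeEstimate:
    """Contemporary N_e assuming panmixia.

    basis: 'unlinked_pairs' (c = 0.5, default), 'weak_pairs', or 'combined'
    (geometric mean of the two inversions).  A corrected delta^2 at or
    below the sampling floor yields a lower-bound estimate flagged as such.
    """
    vals = []
    lower_bound = False
    if basis in ("unlinked_pairs", "combined"):
        d2 = obs.delta2_unlinked
        if not np.isfinite(d2):
            raise ValueError("no unlinked (cross-chromosome) summary available")
        if d2 <= 0:
            lower_bound = True
            d2 = 1e-8
        vals.append(invert_delta2(d2, 0.5))
    if basis in ("weak_pairs", "combined"):
        if not np.isfinite(obs.delta2_weak):
            raise ValueError("no weakly-linked summary available")
        if obs.delta2_weak <= 0:
            lower_bound = True
        else:
            vals.append(_invert_weak(obs))
    if basis not in ("unlinked_pairs", "weak_pairs", "combined"):
        raise ValueError(f"unknown basis {basis!r}")
    if not vals:
        raise ValueError("delta2 at the sampling floor; N_e unbounded above")
    ne = float(np.exp(np.mean(np.log(np.maximum(vals, 1e-12)))))
    return NeEstimate(Ne=ne, basis=basis, lower_bound_only=lower_bound)


def confidence_interval(
    g: GenotypeMatrix | LDSummary,
    estimator=None,
    level: float = 0.90,
    config: LDConfig | None = None,
) -> tuple:
    """Delete-one-chromosome jackknife CI for an LD-summary estimator.

    ``estimator`` maps an LDSummary to a positive scalar (default: the
    panmictic N_e point estimate); the jackknife acts on its log.  Requires
    >= 4 chromosomes.  Returns (low, high).
    """
    if estimator is None:
        estimator = lambda s: ne_panmictic(s).Ne
    obs = g if isinstance(g, LDSummary) else summarize_ld(g, config)
    chroms = sorted({k for k in obs.parts["weak"]})
    J = len(chroms)
    if J < 4:
        raise ValueError(f"jackknife needs >= 4 chromosomes, got {J}")
    theta = np.log(estimator(obs))
    loo = np.array([np.log(estimator(obs.drop_chromosome(ch))) for ch in chroms])
    se = np.sqrt((J - 1) / J * np.sum((loo - loo.mean()) ** 2))
    z = stats.norm.ppf(0.5 + level / 2)
    return (float(np.exp(theta - z * se)), float(np.exp(theta + z * se)))
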