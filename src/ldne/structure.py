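"""Island-model metapopulation inference from single-sample LD observables.

A metapopulation of ``s`` equal demes of effective size ``N`` exchanging
migrants at reciprocal rate ``m`` leaves three fingerprints in a pooled
random sample of individuals:

* delta^2 between unlinked loci (different chromosomes, c = 0.5),
* delta^2 between weakly linked loci (same chromosome, c > 0.05),
* the heterozygote deficit F-hat (Wahlund effect), which approximates F_ST
  when demes are internally panmictic.

At migration-drift equilibrium the population-scale LD partitions into a
within-deme drift component, a between-deme component driven by
allele-frequency differentiation, and a between-within cross term:

    delta^2 = delta2_w + delta2_b + 2 * delta2_bw

with closed-form expectations implemented below, linked through the
finite-island equilibrium F_ST (Takahata's relation).  Solving the system
for (N, s, m) yields N_T = s N and the metapopulation effective size
N_e = N_T / (1 - F_ST).

Observation model.  The equilibrium components above are population-scale
quantities (covariances of single-gamete allele states, variances
p(1-p) from metapopulation frequencies).  The estimator in :mod:`ldne.ld`
measures the Burrows composite covariance of genotype dosages, and both
gametes of a sampled individual come from the same deme, so the
between-deme frequency covariance enters the composite covariance twice:
the between component appears multiplied by 4 and the cross term by 2.
The per-locus variances it divides by carry the Wahlund excess (1 + F_ST).
Hence what the estimator is expected to return is

    E[delta2_obs(c)] = (delta2_w + 4 delta2_b + 4 delta2_bw) / (1 + F_ST)^2

These composite factors were verified against discrete-time Wright-Fisher
island-model simulations (see docs/methods.md).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .ld import LDSummary

__all__ = [
    "MetapopEstimate", "SolverConfig", "expected_delta2_within",
    "expected_delta2_between", "expected_delta2_between_within",
    "expected_delta2_total", "takahata_fst", "metapop_ne",
    "composite_delta2_observed", "solve_metapop",
]

# Composite-genotype observation factors (pooled individual sampling):
# both gametes of an individual share a deme, doubling the between-deme
# part of the composite covariance.
BETWEEN_COMPOSITE_FACTOR = 4.0
BETWEEN_WITHIN_COMPOSITE_FACTOR = 2.0


def expected_delta2_within(c: float, N_T: float, F_ST: float = 0.0) -> float:
    """Within-deme (drift) LD component at recombination fraction c.

    E[delta2_w] = (1-F_ST)^2 ((1-c)^2 + c^2) /
                  (2 N_T (1-(1-c)^2) + 2.2 (1-c)^2)

    N_T is the summed (diploid) effective size of all demes; with F_ST = 0
    this is the panmictic drift expectation.
    """
    c = float(c)
    if not 0 < c <= 0.5:
        raise ValueError("c must be in (0, 0.5]")
    if not N_T > 0:
        raise ValueError("N_T must be positive")
    if not 0 <= F_ST <= 1:
        raise ValueError("F_ST must be in [0, 1]")
    q = (1.0 - c) ** 2
    return (1.0 - F_ST) ** 2 * (q + c * c) / (2.0 * N_T * (1.0 - q) + 2.2 * q)


def expected_delta2_between(F_ST: float, s: int) -> float:
    """Between-deme LD component: E[delta2_b] ~= F_ST^2 / (s - 1)."""
    if s < 2:
        raise ValueError("between-deme component requires s >= 2")
    return F_ST * F_ST / (s - 1.0)


def expected_delta2_between_within(c: float, F_ST: float, s: int, m: float) -> float:
    """Between-within cross component:

    E[delta2_bw] ~= (s/(s-1))^2 delta2_b m /
                    (1 - (1 - (s/(s-1)) m)^2 (1 - c))
    """
    if s < 2:
        raise ValueError("cross component requires s >= 2")
    if not 0 <= m <= (s - 1) / s:
        raise ValueError(f"migration rate {m} outside [0, (s-1)/s]")
    if not 0 < c <= 0.5:
        raise ValueError("c must be in (0, 0.5]")
    a = s / (s - 1.0)
    denom = 1.0 - (1.0 - a * m) ** 2 * (1.0 - c)
    if denom <= 0:
        raise ValueError("non-positive denominator in cross component")
    return a * a * expected_delta2_between(F_ST, s) * m / denom


def takahata_fst(N: float, m: float, s: int) -> float:
    """Equilibrium island-model F_ST (finite number of demes):

    F_ST = 1 / (1 + 4 N m alpha),  alpha = (s/(s-1))^2.

    Monotone decreasing in N and m; -> 1 as m -> 0, -> 0 as N m -> inf.
    """
    if not N > 0:
        raise ValueError("N must be positive")
    if s < 2:
        raise ValueError("F_ST requires s >= 2 demes")
    if not 0 <= m <= (s - 1) / s:
        raise ValueError(f"migration rate {m} outside [0, (s-1)/s]")
    alpha = (s / (s - 1.0)) ** 2
    return 1.0 / (1.0 + 4.0 * N * m * alpha)


def metapop_ne(N_T: float, F_ST: float) -> float:
    """Metapopulation effective size N_e = N_T / (1 - F_ST)."""
    if not 0 <= F_ST < 1:
        raise ValueError("F_ST must be in [0, 1)")
    return N_T / (1.0 - F_ST)


def expected_delta2_total(c: float, N: float, s: int, m: float) -> float:
    """Population-scale total LD: delta2_w + delta2_b + 2 delta2_bw, with
    F_ST from :func:`takahata_fst` and N_T = s N.  Reduces to the panmictic
    within-component when s = 1."""
    if s == 1:
        return expected_delta2_within(c, N, 0.0)
    F = takahata_fst(N, m, s)
    return (expected_delta2_within(c, s * N, F)
            + expected_delta2_between(F, s)
            + 2.0 * expected_delta2_between_within(c, F, s, m))


def composite_delta2_observed(c, N: float, s: int, m: float) -> float | np.ndarray:
    """Expected value of the *measured* composite delta^2 at recombination
    fraction c for a pooled random sample from an island metapopulation
    (see module docstring for the composite factors).  Vectorised over c.
    """
    c = np.asarray(c, dtype=float)
    if s == 1:
        q = (1.0 - c) ** 2
        out = (q + c * c) / (2.0 * N * (1.0 - q) + 2.2 * q)
        return float(out) if out.ndim == 0 else out
    F = takahata_fst(N, m, s)
    q = (1.0 - c) ** 2
    d2w = (1.0 - F) ** 2 * (q + c * c) / (2.0 * (s * N) * (1.0 - q) + 2.2 * q)
    d2b = expected_delta2_between(F, s)
    a = s / (s - 1.0)
    denom = 1.0 - (1.0 - a * m) ** 2 * (1.0 - c)
    d2bw = a * a * d2b * m / denom
    out = (d2w + BETWEEN_COMPOSITE_FACTOR * d2b
           + BETWEEN_WITHIN_COMPOSITE_FACTOR * 2.0 * d2bw) / (1.0 + F) ** 2
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# joint solver
# ---------------------------------------------------------------------------

@dataclass
class SolverConfig:
    s_max: int = 50
    n_starts: int = 5
    weights: tuple = (1.0, 1.0, 1.0)  # (unlinked, weak, F-hat) residuals
    f_floor: float = 0.005            # scale floor for the F residual
    d2_floor: float = 1e-8            # floor for noisy delta2 observables
    s1_tolerance: float = 1.2         # accept panmixia if loss_1 <= tol*best
    seed: int = 0
    n_bounds: tuple = (5.0, 1e8)


@dataclass
class MetapopEstimate:
    """Joint island-model estimate.  N_e >= N_T always (equality iff
    F_ST = 0); s = 1 means the sample is best explained by panmixia."""

    N: float
    s: int
    m: float
    F_ST: float
    N_T: float
    N_e: float
    Ne_panmixia: float | None
    residual: float
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("N", "s", "m", "F_ST", "N_T", "N_e", "Ne_panmixia", "residual",
              "converged")}
        d["diagnostics"] = self.diagnostics
        return json.dumps(d, indent=2, default=float)

    def report(self) -> str:
        lines = [
            "Island-model metapopulation estimate",
            f"  subpopulations (s) : {self.s}",
            f"  deme size (N)      : {self.N:.6g}",
            f"  migration rate (m) : {self.m:.6g}",
            f"  F_ST               : {self.F_ST:.6g}",
            f"  N_T = s*N          : {self.N_T:.6g}",
            f"  N_e = N_T/(1-F_ST) : {self.N_e:.6g}",
            f"  N_e (panmixia)     : "
            f"{self.Ne_panmixia if self.Ne_panmixia is not None else 'n/a'}",
            f"  fit residual       : {self.residual:.3g}",
        ]
        return "\n".join(lines)


def _weak_prediction(centers, weights, N, s, m):
    """Model value of the weakly-linked observable: W-weighted average of
    the composite expectation over the c distribution of included pairs."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("empty weak-pair c distribution")
    vals = composite_delta2_observed(np.asarray(centers), N, s, m)
    return float(np.sum(vals * w) / w.sum())


def solve_metapop(obs: LDSummary, config: SolverConfig | None = None) -> MetapopEstimate:
    """Jointly estimate (N, s, m) from the three observables by weighted
    least squares on relative residuals, scanning integer s and optimising
    (log N, logit m) for each.

    F-hat is used as a third (soft) residual against the equilibrium
    island F_ST; with haploid input it is absent and only the two delta^2
    observables constrain the fit (s poorly resolved; documented
    limitation).  Parsimony: panmixia (s = 1) is reported when it fits
    within ``s1_tolerance`` of the best structured model; ties between
    structured models go to the smaller s.
    """
    from .contemporary import ne_panmictic

    cfg = config or SolverConfig()
    d2u, d2w = obs.delta2_unlinked, obs.delta2_weak
    if not np.isfinite(d2u) or not np.isfinite(d2w):
        raise ValueError("solver needs both unlinked and weakly-linked "
                         "delta^2 (>= 2 mapped chromosomes)")
    floored = False
    if d2u <= 0 or d2w <= 0:
        warnings.warn("corrected delta^2 at or below the sampling noise "
                      "floor; estimates are lower bounds")
        d2u, d2w = max(d2u, cfg.d2_floor), max(d2w, cfg.d2_floor)
        floored = True
    fhat = obs.F_hat
    # Fit in the decorrelated basis (delta2_u, delta2_w - delta2_u, F-hat):
    # the between-deme sampling noise is common to both delta^2 summaries,
    # so their difference (the drift signal that identifies N_T) is far
    # less noisy than either alone.  Residual scales are delete-one-
    # chromosome jackknife SEs of each quantity (inverse-variance
    # weighting), with relative floors; without per-chromosome parts the
    # scales fall back to the observables themselves.
    diff = d2w - d2u
    targets = [d2u, diff] + ([fhat] if fhat is not None else [])
    se = obs.jackknife_se() if obs.parts else {}
    scales = [
        max(se.get("delta2_unlinked", abs(d2u)), 0.02 * abs(d2u),
            cfg.d2_floor),
        max(se.get("diff", abs(diff)), 0.1 * abs(diff), cfg.d2_floor),
    ]
    if fhat is not None:
        scales.append(max(se.get("F_hat", abs(fhat)), 0.02 * abs(fhat),
                          cfg.f_floor))
    wts = np.asarray(cfg.weights[:len(targets)], dtype=float)

    centers, cw = obs.weak_c_centers, obs.weak_c_weights

    def theta_to_nm(theta, s):
        """Parameters for s >= 2: theta = (ln N, w) with w = ln(4 N m alpha).
        w controls the equilibrium F_ST directly (F = 1/(1+e^w)), so the
        near-ridge direction N m ~ const of the loss surface is axis-
        aligned and the optimiser cannot drift to the degenerate
        N -> inf, m -> 0 corner while keeping F fixed."""
        alpha = (s / (s - 1.0)) ** 2
        N = float(np.exp(theta[0]))
        m = float(np.exp(theta[1]) / (4.0 * N * alpha))
        m = min(max(m, 1e-12), (s - 1.0) / s * (1.0 - 1e-9))
        return N, m

    def loss_for(s):
        def f(theta):
            if s == 1:
                N = np.exp(theta[0])
                pu = composite_delta2_observed(0.5, N, 1, 0.0)
                pw = _weak_prediction(centers, cw, N, 1, 0.0)
                preds = [pu, pw - pu]
                if fhat is not None:
                    preds.append(0.0)
            else:
                N, m = theta_to_nm(theta, s)
                pu = composite_delta2_observed(0.5, N, s, m)
                pw = _weak_prediction(centers, cw, N, s, m)
                preds = [pu, pw - pu]
                if fhat is not None:
                    preds.append(takahata_fst(N, m, s))
            r = [(p - t) / sc for p, t, sc in zip(preds, targets, scales)]
            return float(np.sum(wts * np.square(r)))
        return f

    try:
        ne_pan = ne_panmictic(obs).Ne
    except ValueError:
        ne_pan = None
    n0_base = ne_pan if (ne_pan and np.isfinite(ne_pan) and ne_pan > 0) else 1000.0

    lnN_lo, lnN_hi = np.log(cfg.n_bounds[0]), np.log(cfg.n_bounds[1])
    results = {}
    for s in range(1, cfg.s_max + 1):
        f = loss_for(s)
        best = None
        if s == 1:
            for mult in (0.2, 1.0, 5.0, 25.0, 125.0):
                x0 = [np.clip(np.log(n0_base * mult), lnN_lo, lnN_hi)]
                r = optimize.minimize(f, x0, method="Nelder-Mead",
                                      options={"xatol": 1e-6, "fatol": 1e-12,
                                               "maxiter": 400})
                if best is None or r.fun < best.fun:
                    best = r
        else:
            # F-informed start: w = ln(1/F - 1) reproduces the observed
            # heterozygote deficit exactly at the starting point
            f_obs = fhat if (fhat is not None and fhat > 1e-4) else None
            if f_obs is None and d2u > 0:
                # fall back on the unlinked delta^2, dominated by the
                # between-deme term ~ 4 F^2/((s-1)(1+F)^2)
                f_obs = min(np.sqrt(max(d2u, 1e-12) * (s - 1)) / 2.0, 0.9)
            f_obs = min(max(f_obs if f_obs else 0.05, 1e-4), 0.95)
            w_mid = np.log(1.0 / f_obs - 1.0)
            if s == 2 or results.get(s - 1) is None or s - 1 == 1:
                starts = [(n0_base / s * kn, w_mid + kw)
                          for kn in (0.5, 1.5, 5.0, 20.0)
                          for kw in (-1.0, 0.0, 1.0)]
            else:
                # warm start: the surface changes smoothly with s
                prev = results[s - 1].x
                starts = [(np.exp(prev[0]) * (s - 1) / s, prev[1]),
                          (n0_base / s * 1.5, w_mid),
                          (n0_base / s * 8.0, w_mid)]
            for n0, w0 in starts:
                x0 = [np.clip(np.log(max(n0, 5.0)), lnN_lo, lnN_hi), w0]
                r = optimize.minimize(f, x0, method="Nelder-Mead",
                                      options={"xatol": 1e-7, "fatol": 1e-14,
                                               "maxiter": 800})
                if best is None or r.fun < best.fun:
                    best = r
            # polish restart from the incumbent
            r = optimize.minimize(f, best.x, method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-15,
                                           "maxiter": 800})
            if r.fun < best.fun:
                best = r
        results[s] = best

    best_s = min((s for s in results if s >= 2),
                 key=lambda s: (results[s].fun, s))
    if results[1].fun <= cfg.s1_tolerance * results[best_s].fun + 1e-12:
        best_s = 1
    r = results[best_s]
    if best_s == 1:
        N = float(np.exp(r.x[0]))
        s_hat, m_hat, F = 1, 0.0, 0.0
    else:
        s_hat = best_s
        N, m_hat = theta_to_nm(r.x, s_hat)
        F = takahata_fst(N, m_hat, s_hat)
    N_T = s_hat * N
    est = MetapopEstimate(
        N=N, s=s_hat, m=m_hat, F_ST=F, N_T=N_T, N_e=metapop_ne(N_T, F),
        Ne_panmixia=ne_pan, residual=float(r.fun),
        converged=bool(np.isfinite(r.fun)),
        diagnostics={
            "observed": {"delta2_unlinked": d2u, "delta2_weak": d2w,
                         "F_hat": fhat},
            "floored": floored,
            "loss_by_s": {s: float(results[s].fun) for s in results},
        },
    )
    return est
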