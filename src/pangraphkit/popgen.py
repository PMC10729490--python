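"""Population-genetic summaries: Hill–Weir LD decay and variant rates.

The decay of linkage disequilibrium (r^2) with physical distance is fitted
with the Hill & Weir (1988) drift–recombination expectation

    E[r^2] = (10 + C) / ((2 + C)(11 + C))
             * (1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C)))

where C = rho * d is the scaled recombination distance (rho per bp, d in bp)
and n the number of sampled chromosomes. The fit minimizes squared residuals
in rho with a log-parameterization enforcing positivity; summary distances
are the half-decay point (where the curve falls to half its value at d = 0)
and the minimum distance at which the expected r^2 drops below a threshold
(default 0.1), both solved by bisection on the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


def hill_weir_expected_r2(C, n: int):
    """Hill–Weir expected r^2 at scaled recombination distance C (array ok)."""
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be >= 0")
    left = (10 + C) / ((2 + C) * (11 + C))
    right = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    out = left * right
    return float(out) if out.ndim == 0 else out


@dataclass
class LDFit:
    rho: float
    n: int
    half_decay_bp: float
    min_decay_bp: float | None
    threshold: float
    sse: float


def _solve_distance(rho: float, n: int, target: float, d_hi: float = 1e12) -> float:
    """Distance where the fitted curve crosses ``target`` (bisection)."""
    f = lambda d: hill_weir_expected_r2(rho * d, n) - target  # noqa: E731
    lo, hi = 0.0, 1.0
    while f(hi) > 0 and hi < d_hi:
        hi *= 2
    if f(hi) > 0:
        raise ValueError("target not reached within the search range")
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def fit_ld_decay(
    pairs: pd.DataFrame,
    n: int,
    rho0: float = 1e-3,
    threshold: float = 0.1,
) -> LDFit:
    """Fit rho to (distance, r2) pairs by nonlinear least squares.

    ``pairs`` needs columns ``distance`` (bp) and ``r2``. Requires at least
    10 pairs over at least 2 distinct distances. Deterministic given inputs:
    rho is log-parameterized and started at ``rho0``.
    """
    d = np.asarray(pairs["distance"], dtype=float)
    r2 = np.asarray(pairs["r2"], dtype=float)
    if len(d) < 10:
        raise ValueError("need >= 10 (distance, r2) pairs")
    if len(np.unique(d)) < 2:
        raise ValueError("need >= 2 distinct distances")

    def resid(log_rho):
        return hill_weir_expected_r2(np.exp(log_rho[0]) * d, n) - r2

    sol = optimize.least_squares(resid, x0=[np.log(rho0)], method="lm")
    if not sol.success:
        raise RuntimeError(f"LD fit did not converge: {sol.message}")
    rho = float(np.exp(sol.x[0]))
    r2_at_0 = hill_weir_expected_r2(0.0, n)
    half = _solve_distance(rho, n, r2_at_0 / 2)
    min_decay = (
        _solve_distance(rho, n, threshold) if r2_at_0 > threshold else None
    )
    return LDFit(
        rho=rho,
        n=n,
        half_decay_bp=half,
        min_decay_bp=min_decay,
        threshold=threshold,
        sse=float(np.sum(sol.fun**2)),
    )


@dataclass
class RateEstimate:
    rate: float
    n_variants: int
    compared_bp: int
    divergence_years: float
    per_lineage: bool


def variant_rate(
    n_variants: int,
    compared_bp: int,
    divergence_years: float,
    per_lineage: bool = False,
) -> RateEstimate:
    """Divergence-normalized variant rate (variants per nucleotide per year).

    rate = n_variants / (compared_bp * 2 * divergence_years); the factor 2
    accounts for the two lineages diverging since the split. Set
    ``per_lineage=True`` to drop it.
    """
    if n_variants < 0 or compared_bp <= 0 or divergence_years <= 0:
        raise ValueError("inputs must be positive (divergence > 0)")
    denom = compared_bp * divergence_years * (1 if per_lineage else 2)
    return RateEstimate(
        rate=n_variants / denom,
        n_variants=n_variants,
        compared_bp=compared_bp,
        divergence_years=divergence_years,
        per_lineage=per_lineage,
    )
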