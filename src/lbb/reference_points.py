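"""Reference points and relative-biomass indices derived from fitted
population parameters.

Given (L_inf, M/K, F/K, L_c, sigma) this module computes:

* ``L_opt = L_inf * 3 / (3 + M/K)`` — the length at which an unexploited
  cohort's biomass peaks;
* ``L_c_opt = L_inf * (2 + 3 F/M) / ((1 + F/M)(3 + M/K))`` — the length
  at first capture that maximises yield for the current F/M;
* the exploitation rate ``E = F/Z = (F/M)/(1 + F/M)``;
* the Beverton-Holt relative yield per recruit Y/R' (knife-edge
  selection at L_c);
* relative biomass ``B/B0`` — exploited-phase biomass (lengths above
  L_c, weight taken as L^b with b = 3 by default) under the current
  fishing pressure divided by the same sum with F = 0, both from the
  survivorship difference equation on a fine relative-length grid;
* ``B/BMSY`` via the proxy ``BMSY/B0`` = relative biomass at F = M with
  L_c set to L_c_opt (evaluated at F/M = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forward_model import PopulationState
from .lf_data import LengthIndicators

__all__ = [
    "ReferencePoints",
    "l_opt",
    "l_c_opt",
    "exploitation_rate",
    "yield_per_recruit",
    "relative_biomass",
    "bmsy_over_b0",
    "b_over_bmsy",
    "compute_reference_points",
]

#: grid resolution for biomass sums: equal steps in relative length (0, 0.9999]
_N_GRID = 200
_R_MAX = 0.9999


def l_opt(l_inf: float, m_over_k: float) -> float:
    """Length of peak cohort biomass, ``L_inf * 3 / (3 + M/K)``."""
    if not l_inf > 0 or not m_over_k > 0:
        raise ValueError("l_inf and m_over_k must be positive")
    return l_inf * 3.0 / (3.0 + m_over_k)


def l_c_opt(l_inf: float, m_over_k: float, f_over_m: float) -> float:
    """Yield-maximising length at first capture for the current F/M."""
    if not l_inf > 0 or not m_over_k > 0:
        raise ValueError("l_inf and m_over_k must be positive")
    if f_over_m < 0:
        raise ValueError("f_over_m must be non-negative")
    return l_inf * (2.0 + 3.0 * f_over_m) / ((1.0 + f_over_m) * (3.0 + m_over_k))


def exploitation_rate(f_over_m: float) -> float:
    """E = F/Z = (F/M) / (1 + F/M); 0.5 marks the classical optimum."""
    if f_over_m < 0:
        raise ValueError("f_over_m must be non-negative")
    return f_over_m / (1.0 + f_over_m)


def yield_per_recruit(state: PopulationState) -> float:
    """Beverton-Holt relative yield per recruit Y/R' (dimensionless).

    Knife-edge selection at L_c: with ``U = 1 - L_c/L_inf``, ``E = F/Z``
    and ``m = K/Z``,

        Y/R' = E * U**(M/K) * (1 - 3U/(1+m) + 3U^2/(1+2m) - U^3/(1+3m))

    which is the closed form of the catch-biomass integral over the
    survivorship curve with weight W proportional to L^3.
    """
    if not state.l_c < state.l_inf:
        raise ValueError("l_c must be below l_inf")
    if state.f_over_k == 0:
        return 0.0
    u = 1.0 - state.l_c / state.l_inf
    zk = state.z_over_k
    e = state.f_over_k / zk
    m = 1.0 / zk  # K/Z
    return (
        e * u ** state.m_over_k
        * (1.0 - 3.0 * u / (1.0 + m) + 3.0 * u**2 / (1.0 + 2.0 * m) - u**3 / (1.0 + 3.0 * m))
    )


def _exploitable_biomass_sum(state: PopulationState, weight_exponent: float,
                             n_grid: int) -> float:
    """Standing exploited-phase biomass per recruit (relative units)."""
    grid = np.linspace(_R_MAX / n_grid, _R_MAX, n_grid)
    # knife-edge fishery: survivorship decays with M/K up to L_c and with
    # Z/K = (M+F)/K above it.  The Gaussian curve describes what the
    # survey gear sees; the fishery is taken to remove fish of every
    # length above first capture.
    rc = state.l_c / state.l_inf
    r = np.concatenate(([rc], grid[grid > rc]))  # exact lower limit
    n = (1.0 - rc) ** state.m_over_k * ((1.0 - r) / (1.0 - rc)) ** state.z_over_k
    # standing-stock density carries the age-per-length Jacobian
    # 1/(L_inf - L): fish accumulate at lengths where growth slows
    dens = n * r**weight_exponent / (1.0 - r)
    return float(np.trapezoid(dens, r))


def relative_biomass(
    state: PopulationState,
    weight_exponent: float = 3.0,
    n_grid: int = _N_GRID,
) -> tuple[float, float, float]:
    """Relative exploited-phase biomass B/B0 and its two components.

    Returns ``(b_over_b0, cpue_prime_over_r, b0_prime_over_r)`` where the
    numerator sums survivors-at-length times weight (L^b) over lengths
    above L_c under the current fishing mortality and the denominator is
    the same sum with F = 0.  Both use the selectivity-modulated
    survivorship difference equation on ``n_grid`` equal steps of
    relative length.
    """
    if not weight_exponent > 0:
        raise ValueError("weight_exponent must be positive")
    if not state.l_c < state.l_inf:
        raise ValueError("l_c must be below l_inf")
    cpue = _exploitable_biomass_sum(state, weight_exponent, n_grid)
    b0 = _exploitable_biomass_sum(state.with_(f_over_k=0.0), weight_exponent, n_grid)
    if not b0 > 0:
        raise ValueError("unexploited biomass sum is zero; check parameters")
    ratio = cpue / b0
    return min(ratio, 1.0), cpue, b0


def bmsy_over_b0(state: PopulationState, weight_exponent: float = 3.0,
                 n_grid: int = _N_GRID) -> float:
    """BMSY/B0 proxy: relative biomass at F = M with L_c = L_c_opt(F/M = 1)."""
    lc_ref = l_c_opt(state.l_inf, state.m_over_k, 1.0)
    ref = state.with_(f_over_k=state.m_over_k, l_c=lc_ref)
    ratio, _, _ = relative_biomass(ref, weight_exponent, n_grid)
    return ratio


def b_over_bmsy(state: PopulationState, weight_exponent: float = 3.0,
                n_grid: int = _N_GRID) -> float:
    """B/BMSY = (B/B0) / (BMSY/B0) at the fitted parameters."""
    bb0, _, _ = relative_biomass(state, weight_exponent, n_grid)
    return bb0 / bmsy_over_b0(state, weight_exponent, n_grid)


@dataclass(frozen=True)
class ReferencePoints:
    """Derived assessment quantities for one fitted stock."""

    l_opt_cm: float
    l_c_opt_cm: float
    exploitation_rate_e: float
    yield_per_recruit: float
    b_over_b0: float
    bmsy_over_b0: float
    b_over_bmsy: float
    f_over_m: float
    z_over_k: float
    l_inf_cm: float
    l_c_cm: float
    ratio_lmean_lopt: float = math.nan
    ratio_lc_lcopt: float = math.nan
    ratio_l95_linf: float = math.nan

    def __post_init__(self) -> None:
        if not 0 <= self.exploitation_rate_e < 1:
            raise ValueError("exploitation rate must lie in [0, 1)")
        if not 0 <= self.b_over_b0 <= 1:
            raise ValueError("b_over_b0 must lie in [0, 1]")


def compute_reference_points(
    state: PopulationState,
    indicators: LengthIndicators | None = None,
    weight_exponent: float = 3.0,
    n_grid: int = _N_GRID,
) -> ReferencePoints:
    """All reference points for a fitted parameter set.

    When catch-length ``indicators`` are supplied, the three indicator
    ratios (L_mean/L_opt, L_c/L_c_opt, L_95th/L_inf) are filled in.
    """
    fm = state.f_over_m
    lopt = l_opt(state.l_inf, state.m_over_k)
    lcopt = l_c_opt(state.l_inf, state.m_over_k, fm)
    bb0, _, _ = relative_biomass(state, weight_exponent, n_grid)
    bmsy = bmsy_over_b0(state, weight_exponent, n_grid)
    ratios = {}
    if indicators is not None:
        ratios = {
            "ratio_lmean_lopt": indicators.l_mean_cm / lopt,
            "ratio_lc_lcopt": state.l_c / lcopt,
            "ratio_l95_linf": indicators.l_95th_cm / state.l_inf,
        }
    return ReferencePoints(
        l_opt_cm=lopt,
        l_c_opt_cm=lcopt,
        exploitation_rate_e=exploitation_rate(fm),
        yield_per_recruit=yield_per_recruit(state),
        b_over_b0=bb0,
        bmsy_over_b0=bmsy,
        b_over_bmsy=bb0 / bmsy,
        f_over_m=fm,
        z_over_k=state.z_over_k,
        l_inf_cm=state.l_inf,
        l_c_cm=state.l_c,
        **ratios,
    )
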