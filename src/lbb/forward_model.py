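"""Deterministic population and gear model for length-structured catches.

A cohort grows along the von Bertalanffy curve, dies at rate Z = M + F,
and is observed through a Gaussian gillnet selectivity curve.  Working
in length rather than age lets mortality enter only through the ratios
M/K and F/K: the fraction of a cohort surviving from length ``L1`` to
``L2`` is ``((L_inf - L2)/(L_inf - L1))**(Z/K)``.  With a
length-dependent fishing mortality ``F * S(L)`` this becomes the
difference equation

    N_i = N_{i-1} * ((L_inf - L_i)/(L_inf - L_{i-1})) ** (M/K + F/K * S_i)

evaluated at bin midpoints, and the expected *catch* composition is
``N_i * S_i`` renormalised over bins (the gear filters what is seen).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PopulationState",
    "ExpectedComposition",
    "vbgf_length_at_age",
    "survival_to_relative_length",
    "gillnet_selectivity",
    "expected_catch_at_length",
]


@dataclass(frozen=True)
class PopulationState:
    """Parameter vector of the length-structured population/gear model.

    Parameters
    ----------
    l_inf : asymptotic length (cm).
    m_over_k : natural mortality over growth coefficient (dimensionless).
    f_over_k : fishing mortality over growth coefficient at full
        selectivity (dimensionless, >= 0).
    l_c : length at maximum gear selectivity (cm), peak of the Gaussian.
    sigma : standard deviation of the selectivity curve (cm).
    """

    l_inf: float
    m_over_k: float
    f_over_k: float
    l_c: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.l_inf > 0:
            raise ValueError("l_inf must be positive")
        if not self.m_over_k > 0:
            raise ValueError("m_over_k must be positive")
        if self.f_over_k < 0:
            raise ValueError("f_over_k must be non-negative")
        if not 0 < self.l_c < self.l_inf:
            raise ValueError("l_c must lie in (0, l_inf)")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def z_over_k(self) -> float:
        """Total mortality ratio Z/K at full selectivity."""
        return self.m_over_k + self.f_over_k

    @property
    def f_over_m(self) -> float:
        return self.f_over_k / self.m_over_k

    def with_(self, **kwargs) -> "PopulationState":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ExpectedComposition:
    """Expected relative numbers and catch proportions on a length grid."""

    bin_midpoints: np.ndarray
    expected_numbers: np.ndarray  # relative population numbers N_L
    proportions: np.ndarray  # gear-filtered catch proportions, sum to 1


def vbgf_length_at_age(l_inf: float, k: float, t_0: float, t) -> float | np.ndarray:
    """Von Bertalanffy length at age: ``L_t = L_inf (1 - exp(-k (t - t_0)))``."""
    if not l_inf > 0 or not k > 0:
        raise ValueError("l_inf and k must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < t_0):
        raise ValueError("age t must be >= t_0")
    out = l_inf * (1.0 - np.exp(-k * (t - t_0)))
    return float(out) if out.ndim == 0 else out


def survival_to_relative_length(rel_length, m_over_k: float, strict: bool = False):
    """Probability of surviving to relative length ``L / L_inf`` unfished.

    Returns ``(1 - L/L_inf) ** (M/K)``.  Relative lengths >= 1 yield 0
    (the limit), or raise when ``strict``.
    """
    if not m_over_k > 0:
        raise ValueError("m_over_k must be positive")
    rel = np.asarray(rel_length, dtype=float)
    if np.any(rel < 0):
        raise ValueError("relative length must be >= 0")
    if np.any(rel >= 1):
        if strict:
            raise ValueError("relative length must be < 1")
    out = np.where(rel < 1, np.power(np.clip(1.0 - rel, 0.0, None), m_over_k), 0.0)
    return float(out) if out.ndim == 0 else out


def gillnet_selectivity(length, l_c: float, sigma: float):
    """Gaussian gillnet selectivity ``exp(-(L - L_c)^2 / (2 sigma^2))``.

    Peaks at 1 for ``length == l_c`` and is symmetric about the peak.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    length = np.asarray(length, dtype=float)
    out = np.exp(-((length - l_c) ** 2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def _log_relative_numbers(state: PopulationState, midpoints: np.ndarray) -> np.ndarray:
    """log N at each midpoint, seeded with N = 1 at the first bin.

    Bins at or beyond l_inf get log N = -inf (no fish reach L_inf).
    """
    l = midpoints
    below = l < state.l_inf
    logn = np.full(l.shape, -np.inf)
    if not below.any():
        return logn
    sel = gillnet_selectivity(l, state.l_c, state.sigma)
    gap = state.l_inf - l[below]
    # log of the survivorship ratio between consecutive midpoints
    logratio = np.diff(np.log(gap))
    expo = state.m_over_k + state.f_over_k * np.asarray(sel)[below][1:]
    logn[below] = np.concatenate([[0.0], np.cumsum(expo * logratio)])
    return logn


def expected_catch_at_length(state: PopulationState, bin_midpoints) -> ExpectedComposition:
    """Expected catch composition of the gear over a length grid.

    The survivorship recursion is seeded with N = 1 at the first bin;
    catch proportions are ``N_L * S_L`` renormalised (proportions are
    invariant to the seed).  Bins with midpoint >= l_inf get expected
    number 0.
    """
    mids = np.asarray(bin_midpoints, dtype=float)
    if mids.ndim != 1 or mids.size < 2:
        raise ValueError("need at least 2 bin midpoints")
    if np.any(np.diff(mids) <= 0):
        raise ValueError("bin midpoints must be strictly increasing")
    logn = _log_relative_numbers(state, mids)
    n = np.exp(logn)
    catch = n * gillnet_selectivity(mids, state.l_c, state.sigma)
    total = catch.sum()
    if not total > 0:
        raise ValueError("expected catch is zero over the whole grid")
    return ExpectedComposition(mids, n, catch / total)
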