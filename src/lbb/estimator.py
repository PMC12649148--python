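"""Scikit-learn style front end to the length-based Bayesian biomass fit.

:class:`LBB` is an estimator in the sklearn sense: construct with
hyper-parameters (priors, MCMC settings, seed), call :meth:`fit` with
length data, and read the results off trailing-underscore attributes.
It composes with sklearn model-selection utilities via
``get_params`` / ``set_params`` and scores held-out length samples by
their multinomial log-likelihood under the fitted composition.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .bayes_fit import MCMCConfig, PriorSet, fit_lbb
from .forward_model import expected_catch_at_length
from .lf_data import LengthFrequency, LengthRecord, build_length_frequency, \
    compute_length_indicators
from .reference_points import compute_reference_points
from .status_classifier import AssessmentRecord

__all__ = ["LBB"]


class LBB(BaseEstimator):
    """Length-based Bayesian biomass assessment of one stock.

    Parameters
    ----------
    priors : PriorSet or None
        Log-normal prior medians/spreads; None derives data-driven
        defaults from the sample.
    chains, iterations, burn_in, thin, seed
        MCMC settings (independent adaptive Metropolis chains).
    weight_exponent : float
        Exponent b of the weight-at-length relation W proportional to
        L**b used in the biomass sums (3 = isometric growth).
    class_interval_cm : float or None
        Bin width when fitting raw lengths; None applies the L_max
        step rule.

    Attributes
    ----------
    lf_ : LengthFrequency
        The (possibly internally binned) fitted composition.
    posterior_ : PosteriorEstimate
        Posterior medians, credible intervals and diagnostics.
    state_ : PopulationState
        Parameter vector at the posterior medians.
    reference_points_ : ReferencePoints
        Derived reference points and indicator ratios.
    assessment_ : AssessmentRecord
        Status label, flags and management advice.
    converged_ : bool
        False when any split-R-hat exceeded 1.05.
    """

    def __init__(
        self,
        priors: PriorSet | None = None,
        chains: int = 3,
        iterations: int = 30_000,
        burn_in: float = 0.5,
        thin: int = 10,
        seed: int = 42,
        weight_exponent: float = 3.0,
        class_interval_cm: float | None = None,
    ):
        self.priors = priors
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.weight_exponent = weight_exponent
        self.class_interval_cm = class_interval_cm

    def _to_lf(self, X, species_id: str = "stock", year: int = 0) -> LengthFrequency:
        if isinstance(X, LengthFrequency):
            return X
        lengths = np.asarray(X, dtype=float).ravel()
        records = [LengthRecord(species_id, year, float(l)) for l in lengths]
        return build_length_frequency(records, species_id, year,
                                      class_interval_cm=self.class_interval_cm)

    def fit(self, X, y=None):
        """Fit the model to a length sample.

        ``X`` is either a :class:`LengthFrequency` or an array of
        individual body lengths (cm), which is binned with the class
        interval rule first.  ``y`` is ignored (unsupervised).
        """
        lf = self._to_lf(X)
        mcmc = MCMCConfig(chains=self.chains, iterations=self.iterations,
                          burn_in=self.burn_in, thin=self.thin, seed=self.seed)
        self.lf_ = lf
        self.posterior_ = fit_lbb(lf, priors=self.priors, mcmc=mcmc)
        self.state_ = self.posterior_.state_at_median()
        self.indicators_ = compute_length_indicators(lf.trimmed(), self.state_.l_c)
        self.reference_points_ = compute_reference_points(
            self.state_, self.indicators_, weight_exponent=self.weight_exponent)
        self.assessment_ = AssessmentRecord(lf.species_id, lf.year, self.reference_points_)
        self.converged_ = self.posterior_.converged
        self.l_inf_ = self.state_.l_inf
        self.m_over_k_ = self.state_.m_over_k
        self.f_over_k_ = self.state_.f_over_k
        self.l_c_ = self.state_.l_c
        self.sigma_ = self.state_.sigma
        return self

    def predict_proportions(self, bin_midpoints) -> np.ndarray:
        """Expected catch proportions over a length grid at the fitted medians."""
        self._check_fitted()
        return expected_catch_at_length(self.state_, bin_midpoints).proportions

    def score(self, X, y=None) -> float:
        """Per-individual multinomial log-likelihood of a length sample
        under the fitted composition (higher is better)."""
        self._check_fitted()
        lf = self._to_lf(X).trimmed()
        q = self.predict_proportions(lf.bin_midpoints)
        counts = np.asarray(lf.counts, dtype=float)
        good = q > 0
        if counts[~good].sum() > 0:
            return -np.inf
        return float(counts[good] @ np.log(q[good] / q[good].sum()) / counts.sum())

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("this LBB instance is not fitted yet; call fit first")
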