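"""Scikit-learn-style estimator front end for the joint efficacy-dropout model.

``ResponderDropoutModel`` wraps the maximum-likelihood machinery of
:mod:`renresp.estimation` behind the familiar ``fit`` / ``predict_proba`` /
``get_params`` surface, so model variants can be configured, cloned, and
compared the way scikit-learn estimators are. The input ``X`` is a dataset in
any of the accepted forms: a sequence of :class:`~renresp.types.SubjectRecord`,
a long-format DataFrame, or a CSV path.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import estimation
from .io import as_records
from .model_core import response_probability
from .types import DEFAULT_SCHEDULE, CovariateSet, ModelSpec, ParameterVector

__all__ = ["ResponderDropoutModel"]


class ResponderDropoutModel(BaseEstimator):
    """Longitudinal logistic responder model with optional informative dropout.

    Parameters
    ----------
    endpoint : {'PERR', 'CRR'}
        Label of the binary renal-response endpoint being modeled.
    dropout_strategy : {'joint', 'impute_nonresponder'}
        'joint' models on-treatment response together with status-dependent
        dropout hazards; 'impute_nonresponder' imputes post-dropout visits as
        non-response (composite estimand).
    prot_on : sequence of {'rr_ss', 'k_rr', 'theta_bel'}
        Structural parameters receiving a baseline-proteinuria covariate term.
    cavg_metric : {'none', 'cavg4', 'cavg12'}
        Early-exposure covariate on the treatment effect.
    n_starts, jitter_scale, random_state, maxiter, tol, clip_floor
        Optimizer controls; see :func:`renresp.estimation.fit`.

    Attributes
    ----------
    theta_ : ParameterVector
        Maximum-likelihood estimates.
    obj_ : float
        Objective function value (-2 log-likelihood) at the optimum.
    covariance_ : ndarray or None
        Asymptotic covariance over the free parameters.
    se_, rse_pct_ : dict
        Standard errors and relative standard errors (percent).
    converged_ : bool
    individual_obj_ : dict
        Per-subject -2 log-likelihood contributions.
    result_ : FitResult
        The full fit record.
    """

    def __init__(
        self,
        endpoint: str = "PERR",
        dropout_strategy: str = "joint",
        prot_on: Sequence[str] = ("rr_ss", "k_rr", "theta_bel"),
        cavg_metric: str = "none",
        prot_ref: float = 2.5,
        cavg4_ref: float = 95.0,
        cavg12_ref: float = 90.0,
        clip_floor: float = 1e-12,
        n_starts: int = 5,
        jitter_scale: float = 0.3,
        random_state: int = 0,
        maxiter: int = 2000,
        tol: float = 1e-8,
    ):
        self.endpoint = endpoint
        self.dropout_strategy = dropout_strategy
        self.prot_on = prot_on
        self.cavg_metric = cavg_metric
        self.prot_ref = prot_ref
        self.cavg4_ref = cavg4_ref
        self.cavg12_ref = cavg12_ref
        self.clip_floor = clip_floor
        self.n_starts = n_starts
        self.jitter_scale = jitter_scale
        self.random_state = random_state
        self.maxiter = maxiter
        self.tol = tol

    def spec(self) -> ModelSpec:
        return ModelSpec(
            endpoint=self.endpoint,
            dropout_strategy=self.dropout_strategy,
            prot_on=frozenset(self.prot_on),
            cavg_metric=self.cavg_metric,
            prot_ref=self.prot_ref,
            cavg4_ref=self.cavg4_ref,
            cavg12_ref=self.cavg12_ref,
        )

    def fit(self, X, y=None, init: Optional[ParameterVector] = None):
        """Maximum-likelihood fit. ``y`` is ignored (responses live in ``X``)."""
        records = as_records(X)
        result = estimation.fit(
            records,
            self.spec(),
            init=init,
            clip_floor=self.clip_floor,
            n_starts=self.n_starts,
            jitter_scale=self.jitter_scale,
            random_state=self.random_state,
            maxiter=self.maxiter,
            tol=self.tol,
        )
        self.result_ = result
        self.theta_ = result.theta_hat
        self.obj_ = result.obj
        self.covariance_ = result.covariance
        self.se_ = result.se
        self.rse_pct_ = result.rse_pct
        self.converged_ = result.converged
        self.individual_obj_ = result.individual_obj
        self.n_subjects_ = result.n_subjects
        self.free_names_ = result.free_names
        return self

    def predict_proba(
        self,
        covariates: Union[CovariateSet, Sequence[CovariateSet]],
        t: Union[float, Sequence[float]] = DEFAULT_SCHEDULE,
    ) -> np.ndarray:
        """On-treatment responder probability at time(s) ``t`` per covariate set.

        Returns an array of shape (n_covariate_sets, n_times).
        """
        check_is_fitted(self, "theta_")
        covs = [covariates] if isinstance(covariates, CovariateSet) else list(covariates)
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        spec = self.spec()
        return np.vstack(
            [np.atleast_1d(response_probability(self.theta_, c, spec, t_arr)) for c in covs]
        )

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per subject on ``X`` (higher is better)."""
        check_is_fitted(self, "theta_")
        from .likelihood import objective

        records = as_records(X)
        return -0.5 * objective(records, self.theta_, self.spec()) / len(records)
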