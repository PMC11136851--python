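"""Structural responder-probability model.

The probability that a subject is a responder at time ``t`` (days since first
dose) follows a logistic curve on the logit scale::

    logit P(t) = RR_SS - DELTA_RR * exp(-K_RR * t) + THETA_BEL * TRT

where RR_SS is the steady-state placebo response, DELTA_RR the overall change
from baseline to steady state, K_RR the rate constant of the time course
(1/day) and THETA_BEL the additional treatment effect. Baseline proteinuria
and (for treated subjects) early average drug concentration shift these
structural parameters additively on the scale of the log ratio to a reference
value::

    RR_SS     = theta1 + theta5 * log(prot_bl / prot_ref)
    DELTA_RR  = theta2
    K_RR      = theta3 + theta6 * log(prot_bl / prot_ref)
    THETA_BEL = theta4 + theta7 * log(prot_bl / prot_ref)
                       + theta8 * log(cavg / cavg_ref)

Natural logarithms throughout. The exposure term is only ever evaluated for
treated subjects (the treatment effect is multiplied by TRT, so placebo
subjects never require a concentration).
"""

from __future__ import annotations

import math
import warnings
from typing import Tuple, Union

import numpy as np
from scipy.special import expit

from .types import CovariateSet, MissingCovariateError, ModelSpec, ParameterVector

__all__ = ["effective_parameters", "logit_response", "response_probability"]


def effective_parameters(
    theta: ParameterVector, cov: CovariateSet, spec: ModelSpec
) -> Tuple[float, float, float, float]:
    """Subject-specific (rr_ss, delta_rr, k_rr, theta_bel) after covariate effects.

    Raises
    ------
    MissingCovariateError
        If the spec requires an exposure metric for a treated subject whose
        value is absent. Missing exposure is never silently imputed.
    """
    log_prot = math.log(cov.prot_bl / spec.prot_ref)

    rr_ss = theta.theta1
    if "rr_ss" in spec.prot_on:
        rr_ss += theta.theta5 * log_prot

    delta_rr = theta.theta2

    k_rr = theta.theta3
    if "k_rr" in spec.prot_on:
        k_rr += theta.theta6 * log_prot
    if k_rr < 0:
        warnings.warn(
            f"effective rate constant k_rr = {k_rr:.3g}/day is negative for "
            f"prot_bl = {cov.prot_bl} g/g; the time course is mathematically "
            "valid but decreasing on the logit scale",
            RuntimeWarning,
            stacklevel=2,
        )

    theta_bel = theta.theta4
    if "theta_bel" in spec.prot_on:
        theta_bel += theta.theta7 * log_prot
    if spec.cavg_metric != "none" and cov.trt == 1:
        cavg = cov.cavg(spec.cavg_metric)
        if cavg is None:
            raise MissingCovariateError(
                f"treated subject lacks {spec.cavg_metric} required by the model "
                "specification"
            )
        theta_bel += theta.theta8 * math.log(cavg / spec.cavg_ref)

    return rr_ss, delta_rr, k_rr, theta_bel


def logit_response(
    theta: ParameterVector,
    cov: CovariateSet,
    spec: ModelSpec,
    t: Union[float, np.ndarray],
) -> Union[float, np.ndarray]:
    """Linear predictor (logit of the response probability) at time(s) ``t``."""
    rr_ss, delta_rr, k_rr, theta_bel = effective_parameters(theta, cov, spec)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    with np.errstate(over="raise"):
        try:
            eta = rr_ss - delta_rr * np.exp(-k_rr * t) + theta_bel * cov.trt
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"non-finite response predictor at t={t} for covariates {cov} "
                f"(k_rr={k_rr:.4g})"
            ) from exc
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError(
            f"non-finite response predictor at t={t} for covariates {cov}"
        )
    return eta if eta.ndim else float(eta)


def response_probability(
    theta: ParameterVector,
    cov: CovariateSet,
    spec: ModelSpec,
    t: Union[float, np.ndarray],
) -> Union[float, np.ndarray]:
    """On-treatment responder probability at time(s) ``t`` (days), in (0, 1)."""
    eta = logit_response(theta, cov, spec, t)
    p = expit(eta)
    return p if isinstance(eta, np.ndarray) else float(p)
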