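"""Forward simulation of responder-probability bands and observed-rate summaries.

The marginal (all-comers) responder probability at time t multiplies the
on-treatment response probability by the probability of still being on
treatment, where the dropout hazard is the response-weighted mixture

    HZ(t)       = HZ_R * P_RESP(t) + HZ_NR * (1 - P_RESP(t))
    P_SURV(t)   = exp(-integral_0^t HZ(s) ds)
    P_SIM(t)    = P_RESP(t) * P_SURV(t)

Parameter uncertainty is propagated by sampling parameter vectors from the
asymptotic multivariate-normal distribution of a fit; per sampled vector the
per-subject curves are summarized within strata (median and 2.5/97.5
percentiles across subjects), and confidence bands for each summary curve are
taken across samples. Observed responder rates carry exact (Clopper-Pearson)
binomial confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import expit
from scipy.stats import beta

from ._design import _structural_arrays, build_design
from .estimation import FitResult
from .likelihood import impute_post_dropout
from .model_core import response_probability
from .types import (
    DEFAULT_SCHEDULE,
    CovariateSet,
    ModelSpec,
    ParameterVector,
    SubjectRecord,
)

__all__ = [
    "marginal_hazard",
    "survival_marginal",
    "simulated_responder_probability",
    "sample_parameters",
    "simulate_bands",
    "SimBand",
    "clopper_pearson",
    "observed_rates",
    "ObservedRate",
    "default_strata",
]

logger = logging.getLogger(__name__)


def marginal_hazard(
    theta: ParameterVector,
    cov: CovariateSet,
    spec: ModelSpec,
    t: Union[float, np.ndarray],
) -> Union[float, np.ndarray]:
    """Response-weighted dropout hazard (1/day) at time(s) ``t``."""
    p = response_probability(theta, cov, spec, t)
    return theta.hz_r * p + theta.hz_nr * (1.0 - np.asarray(p)) if isinstance(
        p, np.ndarray
    ) else theta.hz_r * p + theta.hz_nr * (1.0 - p)


def survival_marginal(
    theta: ParameterVector,
    cov: CovariateSet,
    spec: ModelSpec,
    t: Union[float, np.ndarray],
    step: float = 1.0,
) -> Union[float, np.ndarray]:
    """P(on treatment at ``t``) under the weighted hazard, trapezoidal quadrature.

    The hazard is integrated on a uniform grid of spacing ``step`` days
    (default 1 day; the hazards are of order 1e-4..1e-3/day, so the quadrature
    error is far below any band width) and interpolated at ``t``.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    t_max = float(t_arr.max()) if t_arr.size else 0.0
    if t_max == 0.0:
        out = np.ones_like(t_arr)
    else:
        grid = np.arange(0.0, t_max + step, step)
        grid[-1] = max(grid[-1], t_max)
        hz = np.asarray(marginal_hazard(theta, cov, spec, grid))
        cum = np.concatenate([[0.0], cumulative_trapezoid(hz, grid)])
        out = np.exp(-np.interp(t_arr, grid, cum))
    return out if isinstance(t, np.ndarray) else float(out[0])


def simulated_responder_probability(
    theta: ParameterVector,
    cov: CovariateSet,
    spec: ModelSpec,
    t: Union[float, np.ndarray],
    step: float = 1.0,
) -> Union[float, np.ndarray]:
    """Marginal responder probability: on-treatment response x survival."""
    p = response_probability(theta, cov, spec, t)
    s = survival_marginal(theta, cov, spec, t, step=step)
    return p * s


def _nearest_psd(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (a + a.T))
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def sample_parameters(
    fit: FitResult, n_samples: int, seed: int
) -> List[ParameterVector]:
    """Multivariate-normal parameter draws around the estimates.

    Reproducible under ``seed``; a non-positive-semidefinite covariance is
    repaired to the nearest PSD matrix (eigenvalue clipping) with a warning.
    """
    if fit.covariance is None:
        raise ValueError("fit has no covariance; cannot sample parameter uncertainty")
    cov = np.asarray(fit.covariance, dtype=float)
    eigvals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
        logger.warning(
            "covariance is not PSD (min eigenvalue %.3g); repairing", eigvals.min()
        )
        cov = _nearest_psd(cov)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.x_hat, cov, size=n_samples, method="eigh")
    return [fit.spec.unpack(x, fit.theta_hat) for x in draws]


@dataclass
class SimBand:
    """Simulated responder-probability band for one stratum."""

    stratum: str
    time_grid: np.ndarray
    median: np.ndarray
    pi_low: np.ndarray
    pi_high: np.ndarray
    median_ci: Tuple[np.ndarray, np.ndarray]
    pi_low_ci: Tuple[np.ndarray, np.ndarray]
    pi_high_ci: Tuple[np.ndarray, np.ndarray]
    n_subjects: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "time": self.time_grid,
                "median": self.median,
                "pi_low": self.pi_low,
                "pi_high": self.pi_high,
                "median_ci_low": self.median_ci[0],
                "median_ci_high": self.median_ci[1],
                "pi_low_ci_low": self.pi_low_ci[0],
                "pi_low_ci_high": self.pi_low_ci[1],
                "pi_high_ci_low": self.pi_high_ci[0],
                "pi_high_ci_high": self.pi_high_ci[1],
            }
        )


def default_strata(spec: ModelSpec) -> Callable[[SubjectRecord], str]:
    """Stratify by arm and baseline proteinuria (cut at the reference 2.5 g/g),
    adding an exposure split (cut at the metric reference) for treated subjects
    when the spec carries an exposure covariate."""

    def label(s: SubjectRecord) -> str:
        arm = "belimumab" if s.cov.trt == 1 else "placebo"
        prot = "prot<2.5" if s.cov.prot_bl < spec.prot_ref else "prot>=2.5"
        parts = [arm, prot]
        if spec.cavg_metric != "none" and s.cov.trt == 1:
            cavg = s.cov.cavg(spec.cavg_metric)
            if cavg is not None:
                ref = spec.cavg_ref
                parts.append(
                    f"{spec.cavg_metric}<{ref:g}"
                    if cavg < ref
                    else f"{spec.cavg_metric}>={ref:g}"
                )
        return " ".join(parts)

    return label


def _curves_matrix(
    theta: ParameterVector,
    design,
    time_grid: np.ndarray,
    step: float,
    study_end: float,
) -> np.ndarray:
    """(n_subjects, n_times) matrix of simulated responder probabilities."""
    rr, k, tb = _structural_arrays(theta, design)
    trt = design.trt
    fine = np.arange(0.0, study_end + step, step)
    # eta: subjects x fine grid
    eta = rr[:, None] - theta.theta2 * np.exp(-np.outer(k, fine)) + (tb * trt)[:, None]
    p = expit(eta)
    hz = theta.hz_r * p + theta.hz_nr * (1.0 - p)
    cum = np.concatenate(
        [np.zeros((p.shape[0], 1)), cumulative_trapezoid(hz, fine, axis=1)], axis=1
    )
    idx = np.searchsorted(fine, time_grid)
    idx = np.clip(idx, 0, fine.size - 1)
    return p[:, idx] * np.exp(-cum[:, idx])


def simulate_bands(
    fit: FitResult,
    subjects: Sequence[SubjectRecord],
    time_grid: Sequence[float] = DEFAULT_SCHEDULE,
    n_samples: int = 500,
    seed: int = 0,
    strata: Optional[Callable[[SubjectRecord], str]] = None,
    step: float = 1.0,
    pi_level: float = 0.95,
    ci_level: float = 0.95,
) -> List[SimBand]:
    """Responder-probability bands per stratum under parameter uncertainty.

    For each of ``n_samples`` parameter draws and each subject, the marginal
    responder probability is evaluated on ``time_grid``; within each stratum
    the across-subject median and prediction-interval percentiles are taken,
    and across draws the confidence bands of each summary curve. Percentiles
    use linear interpolation between order statistics.
    """
    if strata is None:
        strata = default_strata(fit.spec)
    time_grid = np.asarray(list(time_grid), dtype=float)
    labels = [strata(s) for s in subjects]
    groups: Dict[str, List[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)

    design = build_design(list(subjects), fit.spec)
    study_end = max(max(s.study_end for s in subjects), float(time_grid.max()))
    thetas = sample_parameters(fit, n_samples, seed)

    a_pi = 100.0 * (1.0 - pi_level) / 2.0
    a_ci = 100.0 * (1.0 - ci_level) / 2.0
    # summaries[label] -> (n_samples, 3, n_times): median, pi_low, pi_high
    summaries = {
        lab: np.empty((len(thetas), 3, time_grid.size)) for lab in groups
    }
    for si, theta in enumerate(thetas):
        curves = _curves_matrix(theta, design, time_grid, step, study_end)
        for lab, idx in groups.items():
            sub = curves[idx]
            summaries[lab][si, 0] = np.median(sub, axis=0)
            summaries[lab][si, 1] = np.percentile(sub, a_pi, axis=0)
            summaries[lab][si, 2] = np.percentile(sub, 100.0 - a_pi, axis=0)

    bands: List[SimBand] = []
    for lab in sorted(groups):
        if not groups[lab]:
            logger.warning("stratum %r is empty; omitted", lab)
            continue
        s = summaries[lab]
        bands.append(
            SimBand(
                stratum=lab,
                time_grid=time_grid,
                median=np.median(s[:, 0], axis=0),
                pi_low=np.median(s[:, 1], axis=0),
                pi_high=np.median(s[:, 2], axis=0),
                median_ci=(
                    np.percentile(s[:, 0], a_ci, axis=0),
                    np.percentile(s[:, 0], 100.0 - a_ci, axis=0),
                ),
                pi_low_ci=(
                    np.percentile(s[:, 1], a_ci, axis=0),
                    np.percentile(s[:, 1], 100.0 - a_ci, axis=0),
                ),
                pi_high_ci=(
                    np.percentile(s[:, 2], a_ci, axis=0),
                    np.percentile(s[:, 2], 100.0 - a_ci, axis=0),
                ),
                n_subjects=len(groups[lab]),
            )
        )
    return bands


def clopper_pearson(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Exact binomial confidence interval by beta-quantile inversion."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"require 0 <= k <= n and n >= 1, got k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


@dataclass(frozen=True)
class ObservedRate:
    """Observed responder rate at one visit with its exact 95% interval."""

    time: float
    k: int
    n: int
    rate: float
    ci_low: float
    ci_high: float


def observed_rates(
    dataset: Sequence[SubjectRecord],
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    strategy: str = "impute_nonresponder",
    level: float = 0.95,
) -> List[ObservedRate]:
    """Observed responder rate at each schedule time.

    ``impute_nonresponder``: every randomized subject counts at every time,
    with off-treatment visits counted as non-response. ``on_treatment``: only
    subjects with an observation at the visit count; visits with no subjects
    on treatment are omitted.
    """
    if strategy not in ("impute_nonresponder", "on_treatment"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "impute_nonresponder":
        records = [impute_post_dropout(s, schedule) for s in dataset]
    else:
        records = list(dataset)
    by_time: Dict[float, Tuple[int, int]] = {float(t): (0, 0) for t in schedule}
    for s in records:
        for obs in s.observations:
            if obs.t in by_time:
                k, n = by_time[obs.t]
                by_time[obs.t] = (k + obs.response, n + 1)
    out: List[ObservedRate] = []
    for t in schedule:
        k, n = by_time[float(t)]
        if n == 0:
            continue
        low, high = clopper_pearson(k, n, level)
        out.append(
            ObservedRate(time=float(t), k=k, n=n, rate=k / n, ci_low=low, ci_high=high)
        )
    return out
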