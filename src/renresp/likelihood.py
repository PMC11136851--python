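"""Individual and dataset log-likelihood under the two estimand strategies.

Composite strategy ("dropout = non-responder"): every scheduled visit after a
subject's last on-treatment visit is imputed as a non-response and the
likelihood is a plain product of Bernoulli terms.

While-on-treatment strategy (joint efficacy-dropout): only on-treatment
observations contribute Bernoulli terms and the dropout process contributes a
piecewise-constant-hazard survival likelihood. The hazard at time t is HZ_R if
the carried-forward responder status is responder and HZ_NR otherwise; the
status before the first visit is non-responder. A subject with last visit at
T1 who drops out at T2 contributes

    P_SURV(T1) = exp(-integral_0^T1 HZ(t) dt)
    P_DROP(T2) = 1 - exp(-(T2 - T1) * HZ(status at T1))

and a completer contributes survival through the end of the study
(right-censoring), with the status at T1 carried to the end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .model_core import response_probability
from .types import (
    DEFAULT_SCHEDULE,
    DataConsistencyError,
    HazardPair,
    ModelSpec,
    ParameterVector,
    SubjectRecord,
    VisitObservation,
)

__all__ = [
    "impute_post_dropout",
    "loglik_imputed",
    "hazard_path",
    "HazardPath",
    "survival_probability",
    "dropout_probability",
    "loglik_joint",
    "loglik",
    "objective",
    "individual_objectives",
    "DEFAULT_CLIP_FLOOR",
]

logger = logging.getLogger(__name__)

#: Bernoulli probabilities are clipped to [floor, 1 - floor] before taking logs.
DEFAULT_CLIP_FLOOR = 1e-12


def impute_post_dropout(
    subject: SubjectRecord, schedule: Sequence[float] = DEFAULT_SCHEDULE
) -> SubjectRecord:
    """Composite-view record: non-responses imputed at every schedule time > t1.

    On-treatment observations are kept unchanged. The returned record is a
    schedule-complete "completer" (the dropout fields are cleared because the
    composite strategy makes no further use of them).
    """
    observed_times = {o.t for o in subject.observations}
    missing_before = [
        t for t in observed_times if t <= subject.t1 and t not in set(schedule)
    ]
    if missing_before:
        raise DataConsistencyError(
            f"subject {subject.id}: attended visits {sorted(missing_before)} are "
            "not in the imputation schedule"
        )
    imputed = list(subject.observations) + [
        VisitObservation(t=float(t), response=0)
        for t in schedule
        if t > subject.t1
    ]
    if not imputed:
        return subject
    return SubjectRecord(
        id=subject.id,
        cov=subject.cov,
        observations=tuple(imputed),
        t1=imputed[-1].t,
        t2=None,
        dropped=False,
        study_end=subject.study_end,
    )


def _bernoulli_loglik(
    subject: SubjectRecord,
    theta: ParameterVector,
    spec: ModelSpec,
    clip_floor: float,
) -> float:
    total = 0.0
    for obs in subject.observations:
        p = response_probability(theta, subject.cov, spec, obs.t)
        if p < clip_floor or p > 1.0 - clip_floor:
            logger.warning(
                "subject %s: response probability %.3g at t=%s clipped to floor %g",
                subject.id,
                p,
                obs.t,
                clip_floor,
            )
            p = min(max(p, clip_floor), 1.0 - clip_floor)
        total += math.log(p) if obs.response else math.log1p(-p)
    return total


def loglik_imputed(
    subject: SubjectRecord,
    theta: ParameterVector,
    spec: ModelSpec,
    clip_floor: float = DEFAULT_CLIP_FLOOR,
) -> float:
    """Bernoulli log-likelihood of a schedule-complete (imputed) record."""
    return _bernoulli_loglik(subject, theta, spec, clip_floor)


@dataclass(frozen=True)
class HazardPath:
    """Piecewise-constant carried-forward status path on [0, upto).

    ``intervals`` is a tuple of (start, end, status) with status 0/1; statuses
    are the last observed response carried forward, non-responder before the
    first visit.
    """

    intervals: Tuple[Tuple[float, float, int], ...]

    def value(self, t: float, hazards: HazardPair) -> float:
        for start, end, status in self.intervals:
            if start <= t < end:
                return hazards.for_status(status)
        # beyond the last breakpoint: carry the final status
        return hazards.for_status(self.intervals[-1][2] if self.intervals else 0)

    def integral(self, hazards: HazardPair) -> float:
        return sum(
            (end - start) * hazards.for_status(status)
            for start, end, status in self.intervals
        )


def hazard_path(subject: SubjectRecord, upto: float) -> HazardPath:
    """Carried-forward status path from 0 to ``upto`` for the dropout hazard."""
    if upto < 0:
        raise ValueError("upto must be non-negative")
    intervals: List[Tuple[float, float, int]] = []
    start, status = 0.0, 0
    for obs in subject.observations:
        if obs.t >= upto:
            break
        if obs.t > start:
            intervals.append((start, obs.t, status))
        start, status = obs.t, obs.response
    if upto > start:
        intervals.append((start, upto, status))
    return HazardPath(tuple(intervals))


def survival_probability(
    subject: SubjectRecord, hazards: HazardPair, upto: float
) -> float:
    """P(still on treatment at ``upto``) given the observed status path."""
    if upto == 0:
        return 1.0
    return math.exp(-hazard_path(subject, upto).integral(hazards))


def dropout_probability(subject: SubjectRecord, hazards: HazardPair) -> float:
    """P(dropout in (t1, t2]) at the status carried forward from t1."""
    if not subject.dropped or subject.t2 is None:
        raise ValueError(f"subject {subject.id} is not a dropout")
    if subject.t2 <= subject.t1:
        raise DataConsistencyError(
            f"subject {subject.id}: t2 must be strictly after t1"
        )
    hz = hazards.for_status(subject.last_status)
    return -math.expm1(-(subject.t2 - subject.t1) * hz)


def loglik_joint(
    subject: SubjectRecord,
    theta: ParameterVector,
    spec: ModelSpec,
    clip_floor: float = DEFAULT_CLIP_FLOOR,
) -> float:
    """Joint efficacy-dropout log-likelihood of one subject.

    Bernoulli terms over on-treatment observations, plus survival to t1, plus
    either the dropout probability for dropouts or the censoring survival from
    t1 to the study end for completers.
    """
    hazards = theta.hazards
    total = _bernoulli_loglik(subject, theta, spec, clip_floor)
    total += -hazard_path(subject, subject.t1).integral(hazards)
    if subject.dropped:
        p_drop = dropout_probability(subject, hazards)
        if p_drop < clip_floor:
            logger.warning(
                "subject %s: dropout probability %.3g clipped", subject.id, p_drop
            )
            p_drop = clip_floor
        total += math.log(p_drop)
    else:
        tail = subject.study_end - subject.t1
        total += -tail * hazards.for_status(subject.last_status)
    return total


def loglik(
    subject: SubjectRecord,
    theta: ParameterVector,
    spec: ModelSpec,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    clip_floor: float = DEFAULT_CLIP_FLOOR,
) -> float:
    """Per-subject log-likelihood under the strategy named in ``spec``."""
    if spec.dropout_strategy == "impute_nonresponder":
        return loglik_imputed(
            impute_post_dropout(subject, schedule), theta, spec, clip_floor
        )
    return loglik_joint(subject, theta, spec, clip_floor)


def individual_objectives(
    dataset: Iterable[SubjectRecord],
    theta: ParameterVector,
    spec: ModelSpec,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    clip_floor: float = DEFAULT_CLIP_FLOOR,
) -> Dict[str, float]:
    """Per-subject -2 log-likelihood contributions, keyed by subject id."""
    out: Dict[str, float] = {}
    for subject in dataset:
        try:
            out[subject.id] = -2.0 * loglik(subject, theta, spec, schedule, clip_floor)
        except Exception as exc:
            raise type(exc)(f"subject {subject.id}: {exc}") from exc
    return out


def objective(
    dataset: Iterable[SubjectRecord],
    theta: ParameterVector,
    spec: ModelSpec,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    clip_floor: float = DEFAULT_CLIP_FLOOR,
) -> float:
    """Dataset objective function value: -2 x total log-likelihood.

    Exactly -2 log L with no additive constants, so differences between nested
    fits are likelihood-ratio statistics. Additive over disjoint subject sets.
    """
    return sum(individual_objectives(dataset, theta, spec, schedule, clip_floor).values())
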