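"""Domain types for longitudinal binary-response / dropout modeling.

The central objects are a subject's covariates (treatment arm, baseline
proteinuria, early average drug concentration), the structural parameter
vector of the longitudinal logistic model with status-dependent dropout
hazards, and the model specification that says which covariates enter which
structural parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

__all__ = [
    "CovariateSet",
    "ParameterVector",
    "ModelSpec",
    "HazardPair",
    "VisitObservation",
    "SubjectRecord",
    "MissingCovariateError",
    "DataConsistencyError",
    "DEFAULT_SCHEDULE",
    "STUDY_END",
]

#: Protocol visit schedule: every 28 days from day 28 through day 728 (26 visits).
DEFAULT_SCHEDULE: Tuple[int, ...] = tuple(range(28, 729, 28))

#: End of the observation period, days.
STUDY_END: float = 728.0


class MissingCovariateError(ValueError):
    """A covariate required by the model specification is absent."""


class DataConsistencyError(ValueError):
    """Dataset rows violate a structural invariant (times, constancy, coding)."""


@dataclass(frozen=True)
class CovariateSet:
    """Subject-level covariates.

    Parameters
    ----------
    trt
        Treatment indicator: 0 placebo, 1 active drug.
    prot_bl
        Baseline proteinuria (urine protein/creatinine ratio), g/g. Must be > 0.
    cavg4, cavg12
        Average drug concentration over the first 4 / 12 weeks of treatment,
        µg/ml. ``None`` for placebo subjects and for treated subjects who
        dropped out before the metric could be computed.
    """

    trt: int
    prot_bl: float
    cavg4: Optional[float] = None
    cavg12: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trt not in (0, 1):
            raise ValueError(f"trt must be 0 or 1, got {self.trt}")
        if not (self.prot_bl > 0 and math.isfinite(self.prot_bl)):
            raise ValueError(f"prot_bl must be finite and > 0, got {self.prot_bl}")
        for name in ("cavg4", "cavg12"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and > 0 when present, got {v}")

    def cavg(self, metric: str) -> Optional[float]:
        """Return the exposure metric named by ``metric`` ('cavg4'/'cavg12'/'none')."""
        if metric == "none":
            return None
        if metric == "cavg4":
            return self.cavg4
        if metric == "cavg12":
            return self.cavg12
        raise ValueError(f"unknown exposure metric {metric!r}")


@dataclass(frozen=True)
class ParameterVector:
    """Full structural parameter set.

    theta1..theta4 are the typical values (steady-state placebo logit response,
    overall logit change from baseline, rate constant [1/day], treatment effect
    on the logit scale); theta5..theta7 are baseline-proteinuria covariate
    coefficients; theta8 is the exposure coefficient. Dropout hazards are
    parameterized as ``log_hz_r`` (log responder hazard, 1/day) and
    ``log_hz_ratio`` (log of the non-responder/responder hazard ratio).
    """

    theta1: float = 0.0
    theta2: float = 0.0
    theta3: float = 0.0
    theta4: float = 0.0
    theta5: float = 0.0
    theta6: float = 0.0
    theta7: float = 0.0
    theta8: float = 0.0
    log_hz_r: float = 0.0
    log_hz_ratio: float = 0.0

    def __post_init__(self) -> None:
        for f in FREE_PARAMETER_ORDER:
            v = getattr(self, f)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f} must be finite, got {v}")

    @property
    def hz_r(self) -> float:
        return math.exp(self.log_hz_r)

    @property
    def hz_nr(self) -> float:
        return math.exp(self.log_hz_r + self.log_hz_ratio)

    @property
    def hazards(self) -> "HazardPair":
        return HazardPair(hz_r=self.hz_r, hz_nr=self.hz_nr)

    def replace(self, **kwargs: float) -> "ParameterVector":
        return replace(self, **kwargs)


FREE_PARAMETER_ORDER: Tuple[str, ...] = (
    "theta1",
    "theta2",
    "theta3",
    "theta4",
    "theta5",
    "theta6",
    "theta7",
    "theta8",
    "log_hz_r",
    "log_hz_ratio",
)


@dataclass(frozen=True)
class HazardPair:
    """Constant dropout hazards for current responders / non-responders, 1/day."""

    hz_r: float
    hz_nr: float

    def __post_init__(self) -> None:
        if self.hz_r < 0 or self.hz_nr < 0:
            raise ValueError("hazards must be non-negative")

    def for_status(self, status: int) -> float:
        return self.hz_r if status else self.hz_nr


_VALID_PROT_ON = frozenset({"rr_ss", "k_rr", "theta_bel"})


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter which structural parameters, and how dropout is handled.

    ``prot_on`` lists the structural parameters receiving a baseline-proteinuria
    term (any subset of {'rr_ss', 'k_rr', 'theta_bel'}); ``cavg_metric``
    selects the exposure covariate on the treatment effect ('none', 'cavg4',
    'cavg12'). Covariates enter as coefficient × log(value / reference), with
    references 2.5 g/g for proteinuria and the study median concentration for
    each exposure metric.
    """

    endpoint: str = "PERR"
    dropout_strategy: str = "joint"
    prot_on: frozenset = field(
        default_factory=lambda: frozenset({"rr_ss", "k_rr", "theta_bel"})
    )
    cavg_metric: str = "none"
    prot_ref: float = 2.5
    cavg4_ref: float = 95.0
    cavg12_ref: float = 90.0

    def __post_init__(self) -> None:
        if self.endpoint not in ("PERR", "CRR"):
            raise ValueError(f"endpoint must be 'PERR' or 'CRR', got {self.endpoint!r}")
        if self.dropout_strategy not in ("impute_nonresponder", "joint"):
            raise ValueError(f"unknown dropout_strategy {self.dropout_strategy!r}")
        object.__setattr__(self, "prot_on", frozenset(self.prot_on))
        if not self.prot_on <= _VALID_PROT_ON:
            raise ValueError(f"prot_on must be a subset of {sorted(_VALID_PROT_ON)}")
        if self.cavg_metric not in ("none", "cavg4", "cavg12"):
            raise ValueError(f"unknown cavg_metric {self.cavg_metric!r}")
        for name in ("prot_ref", "cavg4_ref", "cavg12_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def cavg_ref(self) -> Optional[float]:
        if self.cavg_metric == "cavg4":
            return self.cavg4_ref
        if self.cavg_metric == "cavg12":
            return self.cavg12_ref
        return None

    @property
    def free_names(self) -> Tuple[str, ...]:
        """Names of the parameters estimated under this specification."""
        names = ["theta1", "theta2", "theta3", "theta4"]
        if "rr_ss" in self.prot_on:
            names.append("theta5")
        if "k_rr" in self.prot_on:
            names.append("theta6")
        if "theta_bel" in self.prot_on:
            names.append("theta7")
        if self.cavg_metric != "none":
            names.append("theta8")
        if self.dropout_strategy == "joint":
            names += ["log_hz_r", "log_hz_ratio"]
        return tuple(names)

    def pack(self, theta: ParameterVector):
        """Extract the free-parameter vector (numpy array) from ``theta``."""
        import numpy as np

        return np.array([getattr(theta, n) for n in self.free_names], dtype=float)

    def unpack(self, x, base: Optional[ParameterVector] = None) -> ParameterVector:
        """Rebuild a full ParameterVector from a free-parameter vector."""
        base = base if base is not None else ParameterVector()
        updates = {n: float(v) for n, v in zip(self.free_names, x)}
        return base.replace(**updates)


@dataclass(frozen=True)
class VisitObservation:
    """One per-visit binary response: ``t`` days since first dose, ``response`` 0/1."""

    t: float
    response: int

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"observation time must be >= 0, got {self.t}")
        if self.response not in (0, 1):
            raise ValueError(f"response must be 0 or 1, got {self.response}")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: covariates, on-treatment visit responses, and dropout data.

    ``t1`` is the last on-treatment visit time (0 when no visit was attended);
    ``t2`` the dropout event time for dropouts (strictly after ``t1``);
    completers have ``dropped = False`` and no ``t2``.
    """

    id: str
    cov: CovariateSet
    observations: Tuple[VisitObservation, ...]
    t1: float
    t2: Optional[float] = None
    dropped: bool = False
    study_end: float = STUDY_END

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        times = [o.t for o in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DataConsistencyError(
                f"subject {self.id}: visit times must be strictly increasing"
            )
        if times and abs(self.t1 - times[-1]) > 1e-9:
            raise DataConsistencyError(
                f"subject {self.id}: t1 ({self.t1}) must equal last visit time ({times[-1]})"
            )
        if not times and self.t1 != 0:
            raise DataConsistencyError(
                f"subject {self.id}: t1 must be 0 when no visit was attended"
            )
        if self.dropped:
            if self.t2 is None or not self.t2 > self.t1:
                raise DataConsistencyError(
                    f"subject {self.id}: dropout time t2 must be strictly after t1"
                )
        else:
            if self.t2 is not None:
                raise DataConsistencyError(
                    f"subject {self.id}: t2 present but subject not marked dropped"
                )
            if self.t1 > self.study_end:
                raise DataConsistencyError(
                    f"subject {self.id}: t1 exceeds study end {self.study_end}"
                )

    @property
    def last_status(self) -> int:
        """Carried-forward responder status at t1 (non-responder before any visit)."""
        return self.observations[-1].response if self.observations else 0
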