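import warnings

import numpy as np
import pytest

from renresp.synthetic import (
    CRR_JOINT_PARAMS,
    PERR_JOINT_PARAMS,
    GeneratorConfig,
    simulate_trial,
)
from renresp.types import CovariateSet, ModelSpec, SubjectRecord, VisitObservation


@pytest.fixture(autouse=True)
def _quiet_negative_k_warnings():
    # extreme baseline proteinuria legitimately flips the sign of the rate
    # constant; the warning is informative in interactive use, noise in tests
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*rate constant.*", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def b1_theta():
    return PERR_JOINT_PARAMS


@pytest.fixture(scope="session")
def d1_theta():
    return CRR_JOINT_PARAMS


@pytest.fixture(scope="session")
def joint_spec():
    return ModelSpec(endpoint="PERR", dropout_strategy="joint")


@pytest.fixture(scope="session")
def impute_spec():
    return ModelSpec(endpoint="PERR", dropout_strategy="impute_nonresponder")


@pytest.fixture(scope="session")
def median_cov():
    return CovariateSet(trt=0, prot_bl=2.5)


@pytest.fixture(scope="session")
def small_trial():
    """One modest synthetic trial reused by read-only tests."""
    return simulate_trial(GeneratorConfig(n_placebo=60, n_treated=60, seed=2024))


@pytest.fixture(scope="session")
def full_trial():
    """One default-size synthetic trial (224 + 224) reused by read-only tests."""
    return simulate_trial(GeneratorConfig(seed=77))


def make_subject(
    sid="S1",
    trt=0,
    prot_bl=2.5,
    times=(28, 56),
    responses=(0, 1),
    dropped=False,
    t2=None,
    cavg4=None,
    cavg12=None,
):
    obs = tuple(
        VisitObservation(t=float(t), response=int(r)) for t, r in zip(times, responses)
    )
    return SubjectRecord(
        id=sid,
        cov=CovariateSet(trt=trt, prot_bl=prot_bl, cavg4=cavg4, cavg12=cavg12),
        observations=obs,
        t1=float(times[-1]) if times else 0.0,
        t2=t2,
        dropped=dropped,
    )


def random_small_subjects(rng: np.random.Generator, n: int):
    """Randomized small subjects with integer visit days for oracle checks."""
    subjects = []
    for i in range(n):
        n_vis = int(rng.integers(0, 7))
        times = np.sort(rng.choice(np.arange(7, 700, 7), size=n_vis, replace=False))
        responses = rng.integers(0, 2, size=n_vis)
        dropped = bool(rng.random() < 0.5)
        t1 = float(times[-1]) if n_vis else 0.0
        t2 = t1 + float(rng.integers(1, 60)) if dropped else None
        trt = int(rng.integers(0, 2))
        subjects.append(
            SubjectRecord(
                id=f"R{i}",
                cov=CovariateSet(trt=trt, prot_bl=float(rng.uniform(0.3, 20.0))),
                observations=tuple(
                    VisitObservation(t=float(t), response=int(r))
                    for t, r in zip(times, responses)
                ),
                t1=t1,
                t2=t2,
                dropped=dropped,
            )
        )
    return subjects
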