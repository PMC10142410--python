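"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations


import numpy as np
import pytest

from edvcalc import BeatObservation

# Cohort-mean observation for a healthy young-adult study population.
COHORT_MEANS = dict(sbp=117.0, dbp=73.0, pep=96.0, et=286.0, sv=61.0, edv_ref=91.0)


def bisection_root(
    pad: float,
    pes: float,
    et: float,
    pep: float,
    k_coef: float = 0.53,
    k_exp: float = 0.51,
    hi: float = 100.0,
    iters: int = 200,
) -> float | None:
    """Decreasing-branch root of the coupling residual by plain bisection.

    Independent oracle: shares no code with the package solver.  Returns
    None when the residual never becomes positive (no admissible root).
    """

    def f(x: float) -> float:
        return (pad / pes) * (1.0 + k_coef * x**k_exp * (et / pep)) - 1.0 - x

    c1 = (pad / pes) * k_coef * (et / pep)
    lo = (k_exp * c1) ** (1.0 / (1.0 - k_exp))  # argmax of the concave residual
    f_lo = f(lo)
    if f_lo == 0.0:
        return lo
    if f_lo < 0.0:
        return None
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_admissible_tuples(rng: np.random.Generator, n: int) -> list[tuple]:
    """Random (pad, pes, et, pep) with pad<=pes and ET/PEP in [1, 6]."""
    out = []
    for _ in range(n):
        pad = rng.uniform(50.0, 100.0)
        pes = rng.uniform(pad, 130.0)
        pep = rng.uniform(60.0, 140.0)
        et = pep * rng.uniform(1.0, 6.0)
        out.append((pad, pes, et, pep))
    return out


@pytest.fixture
def cohort_means_obs() -> BeatObservation:
    return BeatObservation(subject_id="means", **COHORT_MEANS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230428)


def make_agreement_pairs(
    bias: float, sd: float, mean_ref: float
) -> tuple[np.ndarray, np.ndarray]:
    """Three paired series whose differences have exactly this bias and
    sample SD (n−1 denominator) and whose reference mean is mean_ref.

    Differences [bias, bias+sd, bias−sd] have squared deviations
    (0, sd², sd²), so the n−1 sample SD is exactly sd without any
    irrational intermediate."""
    d = np.array([bias, bias + sd, bias - sd])
    reference = np.array([mean_ref, mean_ref - 5.0, mean_ref + 5.0])
    return reference, reference - d
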