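"""Delta-method confidence intervals and a Monte Carlo trajectory oracle.

Expectancies are smooth functionals of the multinomial-logit coefficient
vector; their asymptotic variance is g' V g, where V is the fitted
variance-covariance matrix and g the gradient of the functional,
computed here by central finite differences on the coefficient scale.
Negative lower confidence limits are clamped to zero, since negative
expectancies are impossible.

The Monte Carlo oracle simulates individual trajectories through the
age-indexed chain under the same start-of-interval occupancy convention
and serves as an independent check on the fundamental-matrix algebra.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm

from .expectancy import (
    OriginDistribution,
    StateExpectancies,
    TransitionMatrixSet,
    build_matrix_set,
    conditional_expectancies,
    weighted_expectancies,
)
from .model import CovariateProfile, TransitionModelResults
from .states import HealthState, TRANSIENT_STATES

__all__ = ["DeltaCI", "delta_method_ci", "expectancy_functional", "mc_oracle"]


@dataclass(frozen=True)
class DeltaCI:
    """A delta-method confidence interval with zero-clamped lower limit."""

    point: float
    lower: float
    upper: float
    alpha: float = 0.05
    clamped: bool = False
    se: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lower - 1e-12 <= self.point <= self.upper + 1e-12):
            raise ValueError("interval must bracket the point estimate")
        if self.lower < 0:
            raise ValueError("reported lower limit cannot be negative")


def expectancy_functional(
    name: str,
    profile: CovariateProfile,
    dist: OriginDistribution,
    start_age: float = 20.0,
    truncation_age: float = 85.0,
    **expectancy_kwargs,
) -> Callable[[TransitionModelResults], float]:
    """Build the map coefficients -> expectancy used by the delta method.

    ``name`` is ``"weighted_le"``, ``"mmle"``, or ``"conditional:<ORIGIN>:
    <STATE>"`` for a single fundamental-matrix entry (years in STATE given
    ORIGIN).
    """

    def f(results: TransitionModelResults) -> float:
        ms = build_matrix_set(
            results, profile, start_age=start_age, truncation_age=truncation_age
        )
        cond = {
            o: conditional_expectancies(ms, o, cross_check=False, **expectancy_kwargs)
            for o in TRANSIENT_STATES
        }
        if name == "weighted_le":
            return weighted_expectancies(cond, dist).weighted_le
        if name == "mmle":
            return weighted_expectancies(cond, dist).mmle
        if name.startswith("conditional:"):
            _, origin, state = name.split(":")
            return cond[HealthState[origin]].years_by_state[HealthState[state]]
        raise ValueError(f"unknown functional: {name!r}")

    return f


def delta_method_ci(
    results: TransitionModelResults,
    functional: str | Callable[[TransitionModelResults], float],
    profile: CovariateProfile | None = None,
    dist: OriginDistribution | None = None,
    alpha: float = 0.05,
    step: float = 1e-5,
    **functional_kwargs,
) -> DeltaCI:
    """Propagate coefficient uncertainty into an expectancy interval.

    The gradient with respect to the full coefficient vector is computed
    by central finite differences (default step 1e-5 on the coefficient
    scale); the variance is g' V g with V the fitted vcov.  A negative
    raw lower limit is reported as zero with ``clamped=True``.
    """
    if isinstance(functional, str):
        if profile is None or dist is None:
            raise ValueError("profile and dist are required for named functionals")
        f = expectancy_functional(functional, profile, dist, **functional_kwargs)
    else:
        f = functional

    V = results.cov_params
    eig = np.linalg.eigvalsh(0.5 * (V + V.T))
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError("cov_params is not positive semi-definite")

    theta0 = results.coefficients.flatten()
    point = float(f(results))
    g = np.zeros_like(theta0)
    for i in range(theta0.size):
        up = theta0.copy()
        dn = theta0.copy()
        up[i] += step
        dn[i] -= step
        g[i] = (f(results.with_coef_vector(up)) - f(results.with_coef_vector(dn))) / (
            2 * step
        )
        if not np.isfinite(g[i]):
            raise ValueError(
                f"non-finite gradient for coefficient "
                f"{results.coefficients.param_names()[i]}"
            )
    var = float(g @ V @ g)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(1 - alpha / 2)
    lower_raw = point - z * se
    upper = point + z * se
    clamped = lower_raw < 0
    return DeltaCI(
        point=point,
        lower=max(lower_raw, 0.0),
        upper=upper,
        alpha=alpha,
        clamped=bool(clamped),
        se=se,
    )


def mc_oracle(
    ms: TransitionMatrixSet,
    origin: HealthState,
    n_paths: int,
    seed: int = 0,
) -> tuple[StateExpectancies, dict[HealthState, float]]:
    """Monte Carlo estimate of conditional state expectancies.

    Simulates ``n_paths`` trajectories through the age-indexed chain,
    crediting each interval's full step to the state occupied at its
    start, and returns the mean years per transient state together with
    Monte Carlo standard errors of those means.
    """
    origin = HealthState(origin)
    if origin == HealthState.DEAD:
        raise ValueError("origin must be a transient state")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(seed)
    P = ms.matrices
    n = ms.n_intervals
    states = np.full(n_paths, int(origin), dtype=np.int64)
    years = np.zeros((n_paths, 3))
    cum = np.cumsum(P, axis=2)  # (n, 4, 4)
    for k in range(n):
        for s in range(3):
            mask = states == s
            if mask.any():
                years[mask, s] += ms.step
        u = rng.random(n_paths)
        nxt = states.copy()
        for s in range(3):
            mask = states == s
            if mask.any():
                nxt[mask] = np.searchsorted(cum[k, s], u[mask], side="right")
        nxt = np.minimum(nxt, 3)
        states = nxt
    mean = years.mean(axis=0)
    se = years.std(axis=0, ddof=1) / np.sqrt(n_paths) if n_paths > 1 else np.zeros(3)
    by_state = {s: float(mean[int(s)]) for s in TRANSIENT_STATES}
    est = StateExpectancies(
        origin=origin, years_by_state=by_state, total_le=float(mean.sum())
    )
    return est, {s: float(se[int(s)]) for s in TRANSIENT_STATES}
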