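"""Optimisation-based global sensitivity analysis.

For each sensitivity coefficient two particle-swarm optimisations are run
over the parameter hypercube — one minimising and one maximising the
coefficient — giving lower and upper bounds on the values it can attain.
The swarm is the standard global-best formulation (inertia + cognitive +
social velocity terms) with constriction-factor coefficients; positions are
clamped to the domain with the velocity zeroed on the clamped coordinate.
Parameter sets where the output is undefined (lost steady state or
oscillation) score as worst-possible fitness, so swarms retreat from
non-viable regions; the number of such encounters is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .dynamics import OutputSpec
from .errors import ModelInvariantError
from .model import KineticModel, ParameterDomain, ParameterSet
from .sampling import SensitivityRecord
from .sensitivity import scaled_sensitivity


@dataclass
class SwarmSettings:
    """Particle-swarm hyperparameters.

    Inertia 0.7298 with both acceleration coefficients at 1.4962 are the
    constriction-factor values of Clerc & Kennedy; swarm size and iteration
    limit are the knobs to scale with model evaluation cost.
    """

    swarm_size: int = 20
    iteration_limit: int = 100
    inertia: float = 0.7298
    cognitive: float = 1.4962
    social: float = 1.4962
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ModelInvariantError("swarm size must be >= 2")
        if self.iteration_limit < 1:
            raise ModelInvariantError("iteration limit must be >= 1")


@dataclass
class PSOResult:
    value: float | None
    params: ParameterSet | None
    trace: list[float]
    n_evals: int
    n_undefined: int
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def pso_minimize(
    objective: Callable[[ParameterSet], float | None],
    domain: ParameterDomain,
    settings: SwarmSettings,
) -> PSOResult:
    """Global-best particle swarm minimisation over a parameter hypercube.

    ``objective`` may return None (or nan) for non-viable parameter sets;
    those evaluations are treated as worst-possible.  Deterministic given
    ``settings.seed``.  A degenerate (zero-width) domain is evaluated once
    at its only point.
    """
    ids = domain.ids
    lo, hi = domain.bounds()
    width = hi - lo
    free = width > 0

    def to_set(x: np.ndarray) -> ParameterSet:
        return ParameterSet(zip(ids, x))

    def fitness(x: np.ndarray):
        v = objective(to_set(x))
        if v is None or not math.isfinite(v):
            return math.inf, True
        return float(v), False

    centre = np.clip(
        np.array([domain.reference[i] for i in ids], dtype=float), lo, hi
    )
    if not free.any():
        val, undef = fitness(centre)
        if undef:
            return PSOResult(None, None, [], 1, 1, status="failed")
        return PSOResult(val, to_set(centre), [val], 1, 0)

    rng = np.random.default_rng(settings.seed)
    n, d = settings.swarm_size, len(ids)
    pos = lo + rng.random((n, d)) * width
    pos[0] = centre  # the reference point always starts in the swarm
    vel = (rng.random((n, d)) - 0.5) * width
    n_undef = 0
    fit = np.empty(n)
    for k in range(n):
        fit[k], u = fitness(pos[k])
        n_undef += u
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    trace = [gbest_fit]
    n_evals = n

    for _ in range(settings.iteration_limit):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        vel = (
            settings.inertia * vel
            + settings.cognitive * r1 * (pbest - pos)
            + settings.social * r2 * (gbest[None, :] - pos)
        )
        pos = pos + vel
        low_hit = pos < lo
        high_hit = pos > hi
        pos = np.clip(pos, lo, hi)
        vel[low_hit | high_hit] = 0.0
        for k in range(n):
            f, u = fitness(pos[k])
            n_undef += u
            n_evals += 1
            if f < pbest_fit[k]:
                pbest[k], pbest_fit[k] = pos[k].copy(), f
                if f < gbest_fit:
                    gbest, gbest_fit = pos[k].copy(), f
        trace.append(gbest_fit)

    if not math.isfinite(gbest_fit):
        return PSOResult(None, None, trace, n_evals, n_undef, status="failed")
    return PSOResult(gbest_fit, to_set(gbest), trace, n_evals, n_undef)


@dataclass
class SensitivityBounds:
    """Lower/upper bound on one scaled sensitivity over a domain, with the
    parameter sets attaining them and the convergence traces."""

    parameter: str
    band: float
    lower: float | None
    upper: float | None
    argmin: ParameterSet | None
    argmax: ParameterSet | None
    n_evals: int
    n_undefined: int
    trace_min: list[float] = field(default_factory=list)
    trace_max: list[float] = field(default_factory=list)
    local_value: float | None = None
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def sensitivity_bounds(
    model: KineticModel,
    domain: ParameterDomain,
    spec: OutputSpec,
    parameter: str,
    settings: SwarmSettings | None = None,
    rel_step: float = 1e-3,
) -> SensitivityBounds:
    """Bound one scaled sensitivity coefficient over a parameter domain.

    Runs one swarm on the coefficient and one on its negation; the two jobs
    are independent (deterministic sub-seeds from ``settings.seed``), so
    results do not depend on execution order.  Each reported bound is
    re-evaluated at its arg-point as a guard against objective/report
    mismatch.
    """
    settings = settings or SwarmSettings()
    spec.validate_for(model)

    def coefficient(ps: ParameterSet) -> float | None:
        c = scaled_sensitivity(model, ps, spec, parameter, rel_step=rel_step)
        return c.value if c.ok else None

    res_min = pso_minimize(
        coefficient, domain, replace(settings, seed=_sub_seed(settings.seed, 0))
    )
    res_max = pso_minimize(
        lambda ps: (lambda v: None if v is None else -v)(coefficient(ps)),
        domain,
        replace(settings, seed=_sub_seed(settings.seed, 1)),
    )
    if not res_min.ok or not res_max.ok:
        return SensitivityBounds(
            parameter, domain.band, None, None, None, None,
            res_min.n_evals + res_max.n_evals,
            res_min.n_undefined + res_max.n_undefined,
            res_min.trace, [-v for v in res_max.trace],
            status="failed",
        )
    lower, upper = res_min.value, -res_max.value
    argmin, argmax = res_min.params, res_max.params
    if lower > upper:  # both swarms converged to the same one-sided optimum
        lower, upper = upper, lower
        argmin, argmax = argmax, argmin
    for arg, bound in ((argmin, lower), (argmax, upper)):
        replay = coefficient(arg)
        if replay is None or abs(replay - bound) > 1e-9 * max(1.0, abs(bound)):
            raise AssertionError(
                f"bound replay mismatch for {parameter!r}: {replay} != {bound}"
            )
    return SensitivityBounds(
        parameter, domain.band, float(lower), float(upper), argmin, argmax,
        res_min.n_evals + res_max.n_evals,
        res_min.n_undefined + res_max.n_undefined,
        res_min.trace, [-v for v in res_max.trace],
    )


def bounds_vs_sampling(bounds: SensitivityBounds, records: list[SensitivityRecord]) -> dict:
    """Compare optimisation bounds with the extremes a sampling run found.

    Either method can win (the bounds may dominate the sampled extremes, or
    sampling may find values outside poorly converged bounds); the
    comparison is computed and reported, never assumed.
    """
    ok_vals = [r.value for r in records if r.ok]
    if not ok_vals or not bounds.ok:
        return {
            "parameter": bounds.parameter,
            "comparable": False,
            "sampling_min": min(ok_vals) if ok_vals else None,
            "sampling_max": max(ok_vals) if ok_vals else None,
        }
    smin, smax = min(ok_vals), max(ok_vals)
    return {
        "parameter": bounds.parameter,
        "comparable": True,
        "sampling_min": smin,
        "sampling_max": smax,
        "lower_bound": bounds.lower,
        "upper_bound": bounds.upper,
        "bounds_dominate": bounds.lower <= smin and bounds.upper >= smax,
        "lower_shortfall": max(0.0, bounds.lower - smin),
        "upper_shortfall": max(0.0, smax - bounds.upper),
    }
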