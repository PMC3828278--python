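"""Time-course integration, steady-state solving and oscillation-period
measurement.

These are the three system-level output evaluators the sensitivity analyses
differentiate: a steady-state concentration, a steady-state flux, or the
period of a sustained oscillation of a named variable.  All evaluators
return result objects with an explicit status instead of raising, because
Monte-Carlo sampling over wide parameter domains routinely wanders into
regions where the output ceases to exist (lost steady state, lost
oscillation) and those samples must be counted, not crash the batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .errors import ModelInvariantError
from .model import KineticModel, ParameterSet

OK = "ok"
UNDEFINED = "undefined"

#: reason codes carried by undefined evaluations
NO_STEADY_STATE = "no-steady-state"
NO_OSCILLATION = "no-oscillation"
DAMPED = "damped-oscillation"
IRREGULAR = "irregular-oscillation"
INTEGRATION_FAILURE = "integration-failure"
UNSCALABLE = "unscalable"


@dataclass
class Evaluation:
    """A scalar model output, or the reason it is undefined."""

    value: float | None
    status: str = OK
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == OK


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    species_ids: list[str]
    fluxes: np.ndarray | None = None
    complete: bool = True
    message: str = ""

    def __getitem__(self, sid: str) -> np.ndarray:
        return self.states[:, self.species_ids.index(sid)]

    def to_tsv(self, path: str) -> None:
        header = "time\t" + "\t".join(self.species_ids)
        np.savetxt(
            path,
            np.column_stack([self.times, self.states]),
            delimiter="\t",
            header=header,
            comments="",
        )


@dataclass
class SteadyState:
    concentrations: np.ndarray | None
    fluxes: np.ndarray | None
    stable: bool | None
    residual_norm: float
    status: str = OK
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == OK


@dataclass
class OutputSpec:
    """Declaration of the system-level quantity under analysis.

    kind:
        ``"concentration"`` — steady-state concentration of species ``target``;
        ``"flux"``          — steady-state rate of reaction ``target``;
        ``"period"``        — oscillation period of species ``target``.

    The period settings only apply to ``kind == "period"``: the model is
    simulated for ``t_end`` time units, the first ``transient_fraction`` of
    the window is discarded, and at least ``min_maxima`` maxima of the
    observed variable must remain for the period to be defined.
    """

    kind: str
    target: str
    t_end: float = 1000.0
    n_points: int = 4000
    transient_fraction: float = 0.5
    min_maxima: int = 3
    cv_threshold: float = 0.05
    damping_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("concentration", "flux", "period"):
            raise ModelInvariantError(f"unknown output kind {self.kind!r}")
        if self.t_end <= 0:
            raise ModelInvariantError("total simulated time must be > 0")

    def validate_for(self, model: KineticModel) -> None:
        if self.kind == "flux":
            if self.target not in model.reaction_ids:
                raise ModelInvariantError(f"unknown reaction {self.target!r}")
        elif self.target not in model.species_ids:
            raise ModelInvariantError(f"unknown species {self.target!r}")


# ---------------------------------------------------------------------------
# time-course integration

def simulate(
    model: KineticModel,
    params: Mapping[str, float],
    t_end: float,
    n_points: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    with_fluxes: bool = False,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the model over ``[0, t_end]`` on a uniform output grid.

    Integration failures (blow-up, step-size collapse) are returned as an
    incomplete trajectory carrying the last valid time, not raised.
    """
    if t_end <= 0:
        raise ModelInvariantError("t_end must be > 0")
    compiled = model.compiled()
    pvec = ParameterSet(params).vector(model.parameter_ids)
    if y0 is None:
        y0 = model.reference_state()
    t_eval = np.linspace(0.0, t_end, n_points)
    # terminal guard: solutions escaping toward a finite-time singularity
    # are cut off instead of grinding the step size to nothing
    bound = 1e9 * max(1.0, float(np.max(np.abs(y0))))

    def diverged(t, y):
        return bound - float(np.max(np.abs(y)))

    diverged.terminal = True

    try:
        with np.errstate(all="ignore"):
            sol = solve_ivp(
                lambda t, y: compiled.rhs(t, y, pvec),
                (0.0, t_end),
                y0,
                method="LSODA",
                jac=lambda t, y: compiled.jac(t, y, pvec),
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
                events=diverged,
            )
    except (FloatingPointError, OverflowError, ValueError) as exc:
        return Trajectory(
            np.array([0.0]),
            y0[None, :],
            model.species_ids,
            complete=False,
            message=f"integration raised: {exc}",
        )
    states = sol.y.T
    finite = np.all(np.isfinite(states), axis=1)
    if sol.status != 0 or not finite.all():
        n_ok = int(np.argmin(finite)) if not finite.all() else len(sol.t)
        if sol.status == 1:
            message = "state magnitude diverged beyond bound"
        elif not sol.success:
            message = sol.message
        else:
            message = "non-finite state reached"
        return Trajectory(
            sol.t[:n_ok],
            states[:n_ok],
            model.species_ids,
            complete=False,
            message=message,
        )
    fluxes = None
    if with_fluxes:
        fluxes = np.array([compiled.rates(t, y, pvec) for t, y in zip(sol.t, states)])
    return Trajectory(sol.t, states, model.species_ids, fluxes=fluxes)


# ---------------------------------------------------------------------------
# steady states

def _newton(compiled, pvec, y_start, tol, max_iter=60):
    """Damped Newton on the conservation-reduced system.

    Returns the full steady state or None.
    """
    ii = compiled.independent_idx
    if len(ii) == 0:
        return None
    anchor = np.asarray(y_start, dtype=float)
    x = anchor[ii].copy()
    with np.errstate(all="ignore"):
        f = compiled.reduced_residual(x, pvec, anchor)
        if not np.all(np.isfinite(f)):
            return None
        fn = float(np.linalg.norm(f))
        for _ in range(max_iter):
            if fn <= tol:
                return compiled.full_state(x, anchor)
            try:
                J = compiled.reduced_jac(x, pvec, anchor)
                dx = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                return None
            if not np.all(np.isfinite(dx)):
                return None
            lam = 1.0
            while lam >= 1e-10:
                xn = x + lam * dx
                f_new = compiled.reduced_residual(xn, pvec, anchor)
                if np.all(np.isfinite(f_new)):
                    fn_new = float(np.linalg.norm(f_new))
                    if fn_new < fn or fn_new <= tol:
                        x, f, fn = xn, f_new, fn_new
                        break
                lam *= 0.5
            else:
                return None
    return compiled.full_state(x, anchor) if fn <= tol else None


def find_steady_state(
    model: KineticModel,
    params: Mapping[str, float],
    tol: float = 1e-9,
    y0: np.ndarray | None = None,
    relax_times: tuple[float, ...] = (1e2, 1e4, 1e6),
) -> SteadyState:
    """Locate a steady state of the model at the given parameter values.

    Damped Newton iteration from the reference state, with fallback to
    long-time relaxation integration followed by a Newton polish.  Conserved
    moieties are fixed by the starting state (the reduced system is solved).
    The stability flag reports the sign of the dominant eigenvalue real part
    of the reduced Jacobian; unstable steady states are flagged but not
    rejected.
    """
    compiled = model.compiled()
    if len(compiled.independent_idx) == 0:
        raise ModelInvariantError("model has no non-boundary species")
    pvec = ParameterSet(params).vector(model.parameter_ids)
    if y0 is None:
        y0 = model.reference_state()
    y0 = np.asarray(y0, dtype=float)

    def physical(y):
        # reaction-governed species are concentrations and must stay
        # nonnegative; rate-rule variables may legitimately be negative
        if y is None or len(compiled.governed_idx) == 0:
            return y is not None
        floor = -1e-9 * max(1.0, float(np.max(np.abs(y0))))
        return bool(np.all(y[compiled.governed_idx] >= floor))

    y_ss = _newton(compiled, pvec, y0, tol)
    if y_ss is not None and not physical(y_ss):
        y_ss = None  # spurious nonphysical root; try the relaxation route
    if y_ss is None:
        # relaxation: integrate toward the attractor, then polish
        y = y0
        prev_norm = float(np.linalg.norm(compiled.rhs(0.0, y, pvec)))
        for t_relax in relax_times:
            traj = simulate(model, params, t_relax, n_points=50, y0=y, rtol=1e-8, atol=1e-10)
            if len(traj.times) < 2:
                break
            y = traj.states[-1]
            y_ss = _newton(compiled, pvec, y, tol)
            if y_ss is not None and physical(y_ss):
                break
            y_ss = None
            norm = float(np.linalg.norm(compiled.rhs(0.0, y, pvec)))
            if norm <= tol:
                y_ss = y
                break
            if not traj.complete or norm > 0.9 * prev_norm:
                break  # not relaxing; give up early (e.g. unbounded growth)
            prev_norm = norm
    if y_ss is None:
        return SteadyState(None, None, None, math.inf, UNDEFINED, NO_STEADY_STATE)

    res = float(np.linalg.norm(compiled.rhs(0.0, y_ss, pvec)))
    ii = compiled.independent_idx
    try:
        J = compiled.reduced_jac(y_ss[ii], pvec, y_ss)
        eig = np.linalg.eigvals(J)
        stable = bool(np.max(eig.real) < 0.0)
    except np.linalg.LinAlgError:
        stable = None
    fluxes = compiled.rates(0.0, y_ss, pvec)
    return SteadyState(y_ss, fluxes, stable, res)


# ---------------------------------------------------------------------------
# oscillation period

def _refined_peak_times(t: np.ndarray, x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Quadratic refinement of maxima on a uniform grid."""
    dt = t[1] - t[0]
    out = []
    for i in idx:
        if i == 0 or i == len(x) - 1:
            out.append(t[i])
            continue
        denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
        shift = 0.0 if denom == 0 else 0.5 * (x[i - 1] - x[i + 1]) / denom
        out.append(t[i] + shift * dt)
    return np.array(out)


def detect_period(
    model: KineticModel,
    params: Mapping[str, float],
    spec: OutputSpec,
) -> Evaluation:
    """Measure the oscillation period of the observed variable.

    Maxima are located on the interpolated derivative sign change (parabolic
    refinement of the discrete maxima), the transient window is discarded,
    and the period is the mean of successive maximum-to-maximum intervals.
    Undefined when fewer than ``min_maxima`` maxima remain, when the
    intervals are irregular (coefficient of variation above
    ``cv_threshold``), or when peak prominences decay (a damped, not
    sustained, oscillation).
    """
    if spec.kind != "period":
        raise ModelInvariantError("detect_period requires a period output spec")
    spec.validate_for(model)
    traj = simulate(model, params, spec.t_end, n_points=spec.n_points)
    if not traj.complete:
        return Evaluation(None, UNDEFINED, INTEGRATION_FAILURE)
    x = traj[spec.target]
    t = traj.times
    full_range = float(np.max(x) - np.min(x))
    if full_range <= 0 or not np.isfinite(full_range):
        return Evaluation(None, UNDEFINED, NO_OSCILLATION)
    idx, _ = find_peaks(x, prominence=1e-6 * full_range)
    if len(idx) == 0:
        return Evaluation(None, UNDEFINED, NO_OSCILLATION)
    t_peaks = _refined_peak_times(t, x, idx)
    keep = t_peaks >= spec.transient_fraction * spec.t_end
    t_peaks, idx = t_peaks[keep], idx[keep]
    if len(t_peaks) < spec.min_maxima:
        return Evaluation(None, UNDEFINED, NO_OSCILLATION)
    # peak amplitude above the retained-window median; a sustained
    # oscillation keeps it steady, a decaying one does not
    window = x[t >= spec.transient_fraction * spec.t_end]
    amps = x[idx] - float(np.median(window))
    first = float(np.max(amps[:2]))
    last = float(np.max(amps[-2:]))
    if first > 0 and last < spec.damping_ratio * first:
        return Evaluation(None, UNDEFINED, DAMPED)
    intervals = np.diff(t_peaks)
    period = float((t_peaks[-1] - t_peaks[0]) / (len(t_peaks) - 1))
    cv = float(np.std(intervals) / period) if period > 0 else math.inf
    if cv > spec.cv_threshold:
        return Evaluation(None, UNDEFINED, IRREGULAR)
    return Evaluation(period)


# ---------------------------------------------------------------------------
# dispatch

def evaluate_output(
    model: KineticModel,
    params: Mapping[str, float],
    spec: OutputSpec,
) -> Evaluation:
    """Evaluate the declared system-level output at one parameter set."""
    spec.validate_for(model)
    if spec.kind == "period":
        return detect_period(model, params, spec)
    ss = find_steady_state(model, params)
    if not ss.ok:
        return Evaluation(None, UNDEFINED, ss.reason)
    if spec.kind == "concentration":
        return Evaluation(float(ss.concentrations[model.species_index(spec.target)]))
    j = model.reaction_ids.index(spec.target)
    return Evaluation(float(ss.fluxes[j]))
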