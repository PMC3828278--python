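"""Synthetic kinetic models with independent analytic oracles.

Every stage of the analysis pipeline is testable against these fixtures with
no model download: the oracles are computed by closed form or symbolic
linear algebra, never by the numerical machinery they are used to check.

Fixtures
--------
``make_irreversible_chain``
    X0 -> S1 -> ... -> sink, mass action, X0 a fixed boundary pool.  The
    steady flux is ``k1*X0`` regardless of downstream constants, so all flux
    control sits on the first step — closed-form control coefficients.
``make_reversible_chain``
    A linear reversible chain between two fixed boundary pools; steady state
    and control coefficients from a symbolic solve of the linear system.
``make_linear_oscillator``
    A pure centre ``du/dt = w*v, dv/dt = -w*u`` in rate-rule form with exact
    period ``2*pi/w`` (and scaled period sensitivity to ``w`` of exactly -1).
``make_bimodal_control_toy``
    A branch point whose flux-control coefficient switches between ~0 and ~1
    depending on which branch dominates, so wide uniform sampling of the
    branch capacities produces a bimodal control distribution while a narrow
    band stays unimodal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

from .dynamics import OutputSpec
from .errors import FixtureError
from .model import (
    Compartment,
    KineticModel,
    Parameter,
    Reaction,
    Species,
    assign_limiting_rate_roles,
)


@dataclass
class ChainOracle:
    """Closed-form steady state of the irreversible chain."""

    flux: float
    concentrations: dict[str, float]
    flux_control: dict[str, float]
    concentration_control: dict[str, dict[str, float]]


def make_irreversible_chain(
    n_steps: int = 2,
    rates: Sequence[float] = (2.0, 4.0),
    boundary_concentration: float = 1.0,
) -> tuple[KineticModel, ChainOracle]:
    """Mass-action chain ``X0 ->k1 S1 ->k2 ... ->kn sink`` with X0 fixed."""
    if n_steps < 2:
        raise FixtureError("chain needs at least 2 steps")
    rates = [float(k) for k in rates]
    if len(rates) != n_steps:
        raise FixtureError(f"expected {n_steps} rate constants, got {len(rates)}")
    if any(k <= 0 for k in rates):
        raise FixtureError("all rate constants must be positive")
    if boundary_concentration <= 0:
        raise FixtureError("boundary concentration must be positive")

    species = [Species("X0", boundary_concentration, "cell", boundary=True)]
    internal = [f"S{i}" for i in range(1, n_steps)]
    flux = rates[0] * boundary_concentration
    species += [
        Species(sid, flux / rates[i + 1], "cell") for i, sid in enumerate(internal)
    ]
    subst = ["X0"] + internal
    reactions = []
    for i in range(n_steps):
        stoich = {subst[i]: -1.0}
        if i + 1 < len(subst):
            stoich[subst[i + 1]] = 1.0
        reactions.append(
            Reaction(
                f"step{i + 1}",
                stoich,
                sp.Symbol(f"k{i + 1}") * sp.Symbol(subst[i]),
            )
        )
    model = KineticModel(
        species=species,
        compartments=[Compartment("cell", 1.0)],
        reactions=reactions,
        parameters=[Parameter(f"k{i + 1}", rates[i]) for i in range(n_steps)],
        name=f"irreversible-chain-{n_steps}",
    )
    model.validate()
    model = assign_limiting_rate_roles(model)

    flux_control = {f"step{i + 1}": (1.0 if i == 0 else 0.0) for i in range(n_steps)}
    conc_control: dict[str, dict[str, float]] = {}
    for i, sid in enumerate(internal):
        row = {f"step{j + 1}": 0.0 for j in range(n_steps)}
        row["step1"] = 1.0
        row[f"step{i + 2}"] = -1.0
        conc_control[sid] = row
    oracle = ChainOracle(
        flux=flux,
        concentrations={sid: flux / rates[i + 1] for i, sid in enumerate(internal)},
        flux_control=flux_control,
        concentration_control=conc_control,
    )
    return model, oracle


@dataclass
class ReversibleChainOracle:
    """Symbolic steady-state solution of the reversible chain.

    ``flux_control_at`` / ``concentration_control_at`` evaluate the exact
    control coefficients at an arbitrary parameter set — derived from the
    symbolic linear solve, independent of the finite-difference pipeline.
    """

    flux: float
    concentrations: dict[str, float]
    flux_control: dict[str, float]
    concentration_control: dict[str, dict[str, float]]
    flux_control_at: Callable[[Mapping[str, float]], dict[str, float]]
    concentration_control_at: Callable[[Mapping[str, float]], dict[str, dict[str, float]]]


def make_reversible_chain(
    n_steps: int = 2,
    rate_constants: Sequence[float] = (1.0, 1.0),
    equilibrium_constants: Sequence[float] | None = None,
    boundary_pools: tuple[float, float] = (1.0, 0.0),
) -> tuple[KineticModel, ReversibleChainOracle]:
    """Linear reversible chain between two fixed boundary pools.

    Step ``i`` has rate ``k_i * (S_{i-1} - S_i / q_i)`` with the equilibrium
    constants ``q_i`` folded in as fixed numbers, so the model has exactly
    ``n_steps`` free parameters (each scaling its rate linearly).
    """
    if n_steps < 2:
        raise FixtureError("chain needs at least 2 steps")
    ks = [float(k) for k in rate_constants]
    if len(ks) != n_steps or any(k <= 0 for k in ks):
        raise FixtureError("need one positive rate constant per step")
    qs = [1.0] * n_steps if equilibrium_constants is None else [float(q) for q in equilibrium_constants]
    if len(qs) != n_steps or any(q <= 0 for q in qs):
        raise FixtureError("need one positive equilibrium constant per step")
    b0, bn = boundary_pools

    internal = [f"S{i}" for i in range(1, n_steps)]
    pool = ["X0"] + internal + ["Xn"]
    k_syms = [sp.Symbol(f"k{i + 1}") for i in range(n_steps)]
    s_syms = {sid: sp.Symbol(sid) for sid in pool}
    rate_exprs = [
        k_syms[i] * (s_syms[pool[i]] - s_syms[pool[i + 1]] / sp.Rational(qs[i]).limit_denominator(10**9))
        for i in range(n_steps)
    ]
    reactions = [
        Reaction(
            f"step{i + 1}",
            {pool[i]: -1.0, pool[i + 1]: 1.0},
            rate_exprs[i],
        )
        for i in range(n_steps)
    ]

    # symbolic steady state of the linear system (the oracle route)
    conc_syms = [s_syms[sid] for sid in internal]
    bsubs = {s_syms["X0"]: sp.Rational(b0).limit_denominator(10**9),
             s_syms["Xn"]: sp.Rational(bn).limit_denominator(10**9)}
    balance = [
        sp.expand((rate_exprs[i] - rate_exprs[i + 1]).xreplace(bsubs))
        for i in range(n_steps - 1)
    ]
    sol = sp.solve(balance, conc_syms, dict=True)
    if not sol:
        raise FixtureError("singular linear system: no unique steady state")
    sol = sol[0]
    flux_expr = sp.simplify(rate_exprs[0].xreplace(bsubs).xreplace(sol))
    conc_exprs = {sid: sp.simplify(sol[s_syms[sid]]) for sid in internal}

    # exact control coefficients: parameters scale the rates linearly, so
    # C^J_i = (k_i / J) dJ/dk_i etc.
    cj_exprs = {
        f"step{i + 1}": sp.simplify(k_syms[i] / flux_expr * sp.diff(flux_expr, k_syms[i]))
        for i in range(n_steps)
    }
    cs_exprs = {
        sid: {
            f"step{i + 1}": sp.simplify(k_syms[i] / conc_exprs[sid] * sp.diff(conc_exprs[sid], k_syms[i]))
            for i in range(n_steps)
        }
        for sid in internal
    }
    cj_fns = {rid: sp.lambdify(k_syms, e, modules="numpy") for rid, e in cj_exprs.items()}
    cs_fns = {
        sid: {rid: sp.lambdify(k_syms, e, modules="numpy") for rid, e in row.items()}
        for sid, row in cs_exprs.items()
    }
    conc_fns = {sid: sp.lambdify(k_syms, e, modules="numpy") for sid, e in conc_exprs.items()}

    def _kvec(params: Mapping[str, float]) -> list[float]:
        return [float(params[f"k{i + 1}"]) for i in range(n_steps)]

    def flux_control_at(params: Mapping[str, float]) -> dict[str, float]:
        kv = _kvec(params)
        return {rid: float(fn(*kv)) for rid, fn in cj_fns.items()}

    def concentration_control_at(params: Mapping[str, float]) -> dict[str, dict[str, float]]:
        kv = _kvec(params)
        return {
            sid: {rid: float(fn(*kv)) for rid, fn in row.items()}
            for sid, row in cs_fns.items()
        }

    ref = {f"k{i + 1}": ks[i] for i in range(n_steps)}
    conc_ref = {sid: float(fn(*[ks[i] for i in range(n_steps)])) for sid, fn in conc_fns.items()}
    model = KineticModel(
        species=(
            [Species("X0", b0, "cell", boundary=True)]
            + [Species(sid, conc_ref[sid], "cell") for sid in internal]
            + [Species("Xn", bn, "cell", boundary=True)]
        ),
        compartments=[Compartment("cell", 1.0)],
        reactions=reactions,
        parameters=[Parameter(f"k{i + 1}", ks[i]) for i in range(n_steps)],
        name=f"reversible-chain-{n_steps}",
    )
    model.validate()
    model = assign_limiting_rate_roles(model)
    oracle = ReversibleChainOracle(
        flux=float(sp.lambdify(k_syms, flux_expr)(*ks)),
        concentrations=conc_ref,
        flux_control=flux_control_at(ref),
        concentration_control=concentration_control_at(ref),
        flux_control_at=flux_control_at,
        concentration_control_at=concentration_control_at,
    )
    return model, oracle


@dataclass
class OscillatorOracle:
    period: float
    period_sensitivity_to_omega: float  # scaled; exactly -1


def make_linear_oscillator(omega: float = np.pi) -> tuple[KineticModel, OscillatorOracle]:
    """Harmonic centre in rate-rule form: exact period ``2*pi/omega``.

    Rate rules (rather than reactions) are used on purpose: mass-action
    centres are structurally fragile, and this also exercises the raw-ODE
    code path.
    """
    if omega <= 0:
        raise FixtureError("omega must be positive")
    w = sp.Symbol("omega")
    model = KineticModel(
        species=[Species("u", 1.0, "default"), Species("v", 0.0, "default")],
        compartments=[Compartment("default", 1.0)],
        reactions=[],
        parameters=[Parameter("omega", float(omega))],
        rate_rules={"u": w * sp.Symbol("v"), "v": -w * sp.Symbol("u")},
        name="linear-oscillator",
    )
    model.validate()
    return model, OscillatorOracle(period=2.0 * np.pi / omega, period_sensitivity_to_omega=-1.0)


def make_bimodal_control_toy() -> tuple[KineticModel, str]:
    """Branch-point toy whose control distribution turns bimodal under wide
    parameter sampling.

    A substrate S is produced at a constant rate ``Vin`` and drained by a
    cooperative (Hill-4) branch of capacity ``V1`` plus a weak linear leak
    ``k2*S``.  When ``V1 < Vin`` the cooperative branch saturates and carries
    a fixed flux, so its own capacity controls its flux completely
    (coefficient ~1); when ``V1 > Vin`` the branch is unsaturated and the
    input controls the flux (coefficient ~0).  Sampling the capacities
    within a wide band mixes both regimes, giving two modes near 0 and 1 for
    the flux-control coefficient of the cooperative branch; a narrow band
    stays in one regime and is unimodal.  The linear leak guarantees a
    steady state at every sampled parameter set.
    """
    S, Vin, V1, K1, k2 = sp.symbols("S Vin V1 K1 k2")
    model = KineticModel(
        species=[Species("S", 0.57, "cell")],
        compartments=[Compartment("cell", 1.0)],
        reactions=[
            Reaction("input", {"S": 1.0}, Vin),
            Reaction("branch1", {"S": -1.0}, V1 * S**4 / (K1**4 + S**4)),
            Reaction("branch2", {"S": -1.0}, k2 * S),
        ],
        parameters=[
            Parameter("Vin", 1.0),
            Parameter("V1", 1.5),
            Parameter("K1", 0.5),
            Parameter("k2", 0.1),
        ],
        name="bimodal-control-toy",
    )
    model.validate()
    model = assign_limiting_rate_roles(model)
    description = (
        "flux-control of branch1 on its own flux (sensitivity of the branch1 "
        "steady-state flux to V1) is ~0 at the reference and switches to ~1 "
        "when sampled V1 falls below Vin; analyse OutputSpec('flux', "
        "'branch1') against parameter 'V1'."
    )
    return model, description


def toy_output_spec() -> OutputSpec:
    """The output analysed on the bimodal toy (branch1 steady-state flux)."""
    return OutputSpec("flux", "branch1")


#: name -> zero-argument constructor returning (model, oracle/description)
FIXTURES: dict[str, Callable[[], tuple[KineticModel, object]]] = {
    "chain": make_irreversible_chain,
    "reversible-chain": make_reversible_chain,
    "oscillator": make_linear_oscillator,
    "bimodal-toy": make_bimodal_control_toy,
}
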