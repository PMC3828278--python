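"""Kinetic ODE model representation.

A :class:`KineticModel` holds the reaction network (or raw rate-rule system),
its species with reference initial concentrations, compartments, and a flat
list of parameters with reference values.  All analyses in this package act on
this object; the heavy numerical work goes through :class:`CompiledModel`,
which lambdifies the symbolic rate laws once and exposes fast right-hand-side,
Jacobian and reaction-rate evaluators.

State is expressed in concentrations.  Reaction rate laws are extensive
(amount per time, as in SBML), so the concentration derivative of a species in
compartment ``c`` is ``sum(nu * v) / volume(c)``.  Boundary species have zero
derivative; explicit rate rules override reaction-derived derivatives.

Conserved moieties (closed cycles such as the phosphorylation cycles of
signalling cascades) make the stoichiometric matrix rank-deficient; the
compiled model detects the conservation relations exactly (rational
arithmetic on the stoichiometry) and exposes a reduced system over independent
species for steady-state solving.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

from .errors import (
    CompletenessError,
    ModelInvariantError,
    SymbolResolutionError,
)

#: symbol reserved for model time in rate expressions
TIME = sp.Symbol("time")


@dataclass(frozen=True)
class Species:
    id: str
    initial_concentration: float
    compartment: str = "default"
    boundary: bool = False


@dataclass(frozen=True)
class Compartment:
    id: str
    volume: float = 1.0


@dataclass(frozen=True)
class Parameter:
    """A model parameter with its reference (published) value.

    ``role`` is ``"limiting-rate"`` when the parameter scales some reaction
    rate linearly (a V in enzyme-kinetic terms), ``"other"`` otherwise.
    """

    id: str
    value: float
    role: str = "other"


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    rate_law: sp.Expr
    name: str | None = None


class ParameterSet(dict):
    """Mapping parameter id -> value; the model's operating point."""

    def vector(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self[i] for i in ids], dtype=float)
        except KeyError:
            raise CompletenessError([i for i in ids if i not in self]) from None

    def require_complete(self, ids: Iterable[str]) -> None:
        missing = [i for i in ids if i not in self]
        if missing:
            raise CompletenessError(missing)


@dataclass
class ParameterDomain:
    """Fractional hypercube around a reference parameter set.

    Each parameter ranges over ``[ref*(1-band), ref*(1+band)]`` (endpoints
    swapped for negative references so the interval is always well ordered);
    ``overrides`` pins explicit (lower, upper) intervals for named parameters.
    ``band == 0`` collapses the domain to the reference point.
    """

    reference: ParameterSet
    band: float
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.band < 0:
            raise ModelInvariantError(f"band must be >= 0, got {self.band}")
        for pid, (lo, hi) in self.overrides.items():
            if pid not in self.reference:
                raise ModelInvariantError(f"override for unknown parameter {pid!r}")
            if lo > hi:
                raise ModelInvariantError(f"override for {pid!r} has lower > upper")

    @property
    def ids(self) -> list[str]:
        return list(self.reference.keys())

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        ref = np.array([self.reference[i] for i in self.ids], dtype=float)
        lo = ref * (1.0 - self.band)
        hi = ref * (1.0 + self.band)
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
        for k, pid in enumerate(self.ids):
            if pid in self.overrides:
                lo[k], hi[k] = self.overrides[pid]
        return lo, hi

    def contains(self, params: Mapping[str, float], rtol: float = 1e-9) -> bool:
        lo, hi = self.bounds()
        slack = rtol * np.maximum(1.0, np.abs(hi - lo))
        for k, pid in enumerate(self.ids):
            v = params[pid]
            if v < lo[k] - slack[k] or v > hi[k] + slack[k]:
                return False
        return True

    def sample_at(self, seed: int, index: int) -> ParameterSet:
        """Draw sample ``index`` of the stream defined by ``seed``.

        Counter-based: the draw depends only on (seed, index), never on how
        the stream is chunked, so chunked or parallel execution reproduces
        the sequential result exactly.
        """
        lo, hi = self.bounds()
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))
        u = rng.random(len(lo))
        vals = lo + u * (hi - lo)
        return ParameterSet(zip(self.ids, vals))


@dataclass
class KineticModel:
    species: list[Species]
    compartments: list[Compartment]
    reactions: list[Reaction]
    parameters: list[Parameter]
    rate_rules: dict[str, sp.Expr] = field(default_factory=dict)
    name: str = "model"

    # -- basic accessors -------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def parameter_ids(self) -> list[str]:
        return [p.id for p in self.parameters]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_index(self, sid: str) -> int:
        return self.species_ids.index(sid)

    def reference_parameters(self) -> ParameterSet:
        return ParameterSet({p.id: p.value for p in self.parameters})

    def reference_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], dtype=float)

    def compartment_volume(self, cid: str) -> float:
        for c in self.compartments:
            if c.id == cid:
                return c.volume
        raise ModelInvariantError(f"unknown compartment {cid!r}")

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        sids = self.species_ids
        if len(set(sids)) != len(sids):
            raise ModelInvariantError("species ids are not unique")
        pids = self.parameter_ids
        if len(set(pids)) != len(pids):
            raise ModelInvariantError("parameter ids are not unique")
        if not self.reactions and not self.rate_rules:
            raise ModelInvariantError("model has neither reactions nor rate rules")
        for p in self.parameters:
            if not math.isfinite(p.value):
                raise ModelInvariantError(f"parameter {p.id!r} has non-finite reference value")
        known = set(sids) | set(pids) | {c.id for c in self.compartments} | {TIME.name}
        exprs = [(f"reaction {r.id!r}", r.rate_law) for r in self.reactions]
        exprs += [(f"rate rule for {t!r}", e) for t, e in self.rate_rules.items()]
        for where, expr in exprs:
            for sym in expr.free_symbols:
                if sym.name not in known:
                    raise SymbolResolutionError(
                        f"{where} references unknown symbol {sym.name!r}"
                    )
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelInvariantError(f"reaction {r.id!r} has empty stoichiometry")
            for sid in r.stoichiometry:
                if sid not in sids:
                    raise SymbolResolutionError(
                        f"reaction {r.id!r} stoichiometry references unknown species {sid!r}"
                    )
        for t in self.rate_rules:
            if t not in sids:
                raise SymbolResolutionError(f"rate rule targets unknown species {t!r}")
        # rate laws must evaluate finitely at the reference state
        compiled = self.compiled()
        y0, p0 = self.reference_state(), self.reference_parameters()
        pvec = p0.vector(self.parameter_ids)
        rates = compiled.rates(0.0, y0, pvec)
        if not np.all(np.isfinite(rates)):
            bad = [self.reactions[i].id for i in np.flatnonzero(~np.isfinite(rates))]
            raise ModelInvariantError(
                f"rate law(s) non-finite at the reference state: {', '.join(bad)}"
            )
        if not np.all(np.isfinite(compiled.rhs(0.0, y0, pvec))):
            raise ModelInvariantError("RHS non-finite at the reference state")

    # -- compilation -----------------------------------------------------
    _compiled: "CompiledModel | None" = field(default=None, repr=False, compare=False)

    def compiled(self) -> "CompiledModel":
        if self._compiled is None:
            self._compiled = CompiledModel(self)
        return self._compiled

    # -- serialisation ---------------------------------------------------
    def to_json(self) -> str:
        """Serialise to an SBML-like JSON document (round-trips exactly)."""
        doc = {
            "name": self.name,
            "compartments": [{"id": c.id, "volume": c.volume} for c in self.compartments],
            "species": [
                {
                    "id": s.id,
                    "initial_concentration": s.initial_concentration,
                    "compartment": s.compartment,
                    "boundary": s.boundary,
                }
                for s in self.species
            ],
            "parameters": [
                {"id": p.id, "value": p.value, "role": p.role} for p in self.parameters
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": dict(r.stoichiometry),
                    "rate_law": sp.srepr(r.rate_law),
                    "rate_law_text": str(r.rate_law),
                }
                for r in self.reactions
            ],
            "rate_rules": {
                t: {"expr": sp.srepr(e), "text": str(e)} for t, e in self.rate_rules.items()
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "KineticModel":
        doc = json.loads(text)
        model = cls(
            name=doc.get("name", "model"),
            compartments=[Compartment(c["id"], c["volume"]) for c in doc["compartments"]],
            species=[
                Species(
                    s["id"],
                    s["initial_concentration"],
                    s["compartment"],
                    s["boundary"],
                )
                for s in doc["species"]
            ],
            parameters=[
                Parameter(p["id"], p["value"], p.get("role", "other"))
                for p in doc["parameters"]
            ],
            reactions=[
                Reaction(
                    r["id"],
                    {k: float(v) for k, v in r["stoichiometry"].items()},
                    sp.sympify(r["rate_law"]),
                    r.get("name"),
                )
                for r in doc["reactions"]
            ],
            rate_rules={t: sp.sympify(e["expr"]) for t, e in doc.get("rate_rules", {}).items()},
        )
        model.validate()
        return model

    def summary(self) -> dict:
        """JSON-serialisable summary: species, parameters, reference values."""
        return {
            "name": self.name,
            "n_species": len(self.species),
            "n_reactions": len(self.reactions),
            "n_parameters": len(self.parameters),
            "species": {s.id: s.initial_concentration for s in self.species},
            "parameters": {p.id: p.value for p in self.parameters},
            "limiting_rate_parameters": [
                p.id for p in self.parameters if p.role == "limiting-rate"
            ],
        }


class CompiledModel:
    """Lambdified evaluators for one :class:`KineticModel`.

    Signature convention: ``f(t, y, pvec)`` where ``y`` is the full
    concentration vector in model species order and ``pvec`` the parameter
    vector in model parameter order.
    """

    def __init__(self, model: KineticModel):
        self.model = model
        sids = model.species_ids
        pids = model.parameter_ids
        self.species_syms = [sp.Symbol(s) for s in sids]
        self.param_syms = [sp.Symbol(p) for p in pids]
        comp_subs = {sp.Symbol(c.id): sp.Float(c.volume) for c in model.compartments}
        self.volumes = np.array(
            [model.compartment_volume(s.compartment) for s in model.species], dtype=float
        )

        self.rate_exprs = [r.rate_law.xreplace(comp_subs) for r in model.reactions]

        n_s, n_r = len(sids), len(model.reactions)
        # amount-stoichiometry matrix (species x reactions), exact rationals
        self.stoich = sp.zeros(n_s, n_r)
        for j, r in enumerate(model.reactions):
            for sid, nu in r.stoichiometry.items():
                self.stoich[sids.index(sid), j] = sp.nsimplify(nu, rational=True)
        self.stoich_f = np.array(self.stoich.tolist(), dtype=float)

        self.rule_targets = set(model.rate_rules)
        ode_exprs = []
        for i, s in enumerate(model.species):
            if s.id in model.rate_rules:
                ode_exprs.append(model.rate_rules[s.id].xreplace(comp_subs))
            elif s.boundary:
                ode_exprs.append(sp.Integer(0))
            else:
                total = sp.Integer(0)
                for j in range(n_r):
                    if self.stoich[i, j] != 0:
                        total += self.stoich[i, j] * self.rate_exprs[j]
                ode_exprs.append(total / sp.Float(self.volumes[i]))
        self.ode_exprs = ode_exprs

        args = (TIME, *self.species_syms, *self.param_syms)
        self._rhs = sp.lambdify(args, ode_exprs, modules="numpy")
        jac_mat = sp.Matrix(ode_exprs).jacobian(self.species_syms)
        self._jac = sp.lambdify(args, jac_mat, modules="numpy")
        self._rates = sp.lambdify(args, self.rate_exprs or [0], modules="numpy")
        # elasticities: d(rate)/d(species), used by the MCA matrix route
        if self.rate_exprs:
            elast = sp.Matrix(self.rate_exprs).jacobian(self.species_syms)
            self._elasticities = sp.lambdify(args, elast, modules="numpy")
        else:
            self._elasticities = None

        # dynamic species = not boundary; among reaction-governed dynamic
        # species, detect conserved moieties from the stoichiometry
        self.dynamic_idx = np.array(
            [i for i, s in enumerate(model.species) if not s.boundary], dtype=int
        )
        self.boundary_idx = np.array(
            [i for i, s in enumerate(model.species) if s.boundary], dtype=int
        )
        self._analyse_conservation()

    # -- conservation analysis ------------------------------------------
    def _analyse_conservation(self) -> None:
        model = self.model
        gov = [
            i
            for i, s in enumerate(model.species)
            if not s.boundary and s.id not in self.rule_targets
        ]
        rule_idx = [
            i
            for i, s in enumerate(model.species)
            if not s.boundary and s.id in self.rule_targets
        ]
        self.governed_idx = np.array(gov, dtype=int)
        if not gov:
            self.independent_idx = np.array(rule_idx, dtype=int)
            self.dependent_idx = np.array([], dtype=int)
            self.dep_coeffs = np.zeros((0, 0))
            return
        N = self.stoich[gov, :]
        # pivot columns of rref(N^T) are the independent species rows of N
        R, pivots = N.T.rref()
        ind_local = list(pivots)
        dep_local = [k for k in range(len(gov)) if k not in ind_local]
        # amount of dependent species j is an affine function of independent
        # amounts: N_row(dep_j) = sum_k coeff[k, j] * N_row(ind_k)
        coeff = np.array(
            [[float(R[k, j]) for j in dep_local] for k in range(len(ind_local))]
        ).reshape(len(ind_local), len(dep_local))
        self.independent_idx = np.array(sorted([gov[k] for k in ind_local] + rule_idx), dtype=int)
        self._gov_ind = np.array([gov[k] for k in ind_local], dtype=int)
        self.dependent_idx = np.array([gov[k] for k in dep_local], dtype=int)
        self.dep_coeffs = coeff  # shape (n_gov_ind, n_dep)

    @property
    def has_conservation(self) -> bool:
        return len(self.dependent_idx) > 0

    # -- evaluators ------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, pvec: np.ndarray) -> np.ndarray:
        return np.asarray(self._rhs(t, *y, *pvec), dtype=float)

    def jac(self, t: float, y: np.ndarray, pvec: np.ndarray) -> np.ndarray:
        return np.asarray(self._jac(t, *y, *pvec), dtype=float)

    def rates(self, t: float, y: np.ndarray, pvec: np.ndarray) -> np.ndarray:
        if not self.model.reactions:
            return np.zeros(0)
        out = self._rates(t, *y, *pvec)
        return np.asarray(out, dtype=float).reshape(-1)

    def elasticities(self, t: float, y: np.ndarray, pvec: np.ndarray) -> np.ndarray:
        if self._elasticities is None:
            return np.zeros((0, len(y)))
        return np.asarray(self._elasticities(t, *y, *pvec), dtype=float)

    # -- reduced system for steady-state solving -------------------------
    def full_state(self, y_ind: np.ndarray, anchor: np.ndarray) -> np.ndarray:
        """Reconstruct the full state from independent coordinates.

        Boundary species keep their anchor values; dependent (conserved)
        species follow from the conservation totals evaluated at ``anchor``.
        """
        y = np.array(anchor, dtype=float)
        y[self.independent_idx] = y_ind
        if self.has_conservation:
            v = self.volumes
            gi, di = self._gov_ind, self.dependent_idx
            offset = anchor[di] * v[di] - (anchor[gi] * v[gi]) @ self.dep_coeffs
            y[di] = (offset + (y[gi] * v[gi]) @ self.dep_coeffs) / v[di]
        return y

    def reduced_residual(self, y_ind: np.ndarray, pvec: np.ndarray, anchor: np.ndarray) -> np.ndarray:
        y = self.full_state(y_ind, anchor)
        return self.rhs(0.0, y, pvec)[self.independent_idx]

    def reduced_jac(self, y_ind: np.ndarray, pvec: np.ndarray, anchor: np.ndarray) -> np.ndarray:
        y = self.full_state(y_ind, anchor)
        J = self.jac(0.0, y, pvec)
        ii = self.independent_idx
        Jr = J[np.ix_(ii, ii)].copy()
        if self.has_conservation:
            v = self.volumes
            gi, di = self._gov_ind, self.dependent_idx
            # d c_dep / d c_ind(gov) = coeff^T * V_ind / V_dep
            dcd = (self.dep_coeffs * v[gi][:, None]).T / v[di][:, None]  # (n_dep, n_gov_ind)
            cols = np.searchsorted(ii, gi)
            Jr[:, cols] += J[np.ix_(ii, di)] @ dcd
        return Jr


# -- module-level operations ---------------------------------------------

def build_rhs(model: KineticModel) -> Callable[[np.ndarray, Mapping[str, float], float], np.ndarray]:
    """Return ``f(state, params, t=0) -> dstate/dt`` for the model.

    Symbol resolution problems surface here (at build time), not at the
    first call.
    """
    model.validate()
    compiled = model.compiled()
    pids = model.parameter_ids

    def f(state: np.ndarray, params: Mapping[str, float], t: float = 0.0) -> np.ndarray:
        pvec = ParameterSet(params).vector(pids)
        return compiled.rhs(t, np.asarray(state, dtype=float), pvec)

    return f


class ModelView:
    """A model with parameter values bound; the base model is untouched."""

    def __init__(self, model: KineticModel, params: Mapping[str, float]):
        ps = ParameterSet(params)
        ps.require_complete(model.parameter_ids)
        self.model = model
        self.params = ps
        self._pvec = ps.vector(model.parameter_ids)
        self._compiled = model.compiled()

    def rhs(self, state: np.ndarray, t: float = 0.0) -> np.ndarray:
        return self._compiled.rhs(t, np.asarray(state, dtype=float), self._pvec)

    def rates(self, state: np.ndarray, t: float = 0.0) -> np.ndarray:
        return self._compiled.rates(t, np.asarray(state, dtype=float), self._pvec)


def apply_parameters(model: KineticModel, params: Mapping[str, float]) -> ModelView:
    """Bind a complete parameter set to a model for evaluation."""
    return ModelView(model, params)


def assign_limiting_rate_roles(model: KineticModel) -> KineticModel:
    """Tag parameters that scale some reaction rate linearly.

    A parameter is tagged ``limiting-rate`` when every rate law it appears in
    is homogeneous of degree 1 in it (numerically tested by doubling and
    tripling the value at the reference state).  These are the V parameters
    through which control coefficients are defined.
    """
    compiled = model.compiled()
    y0 = model.reference_state()
    p0 = model.reference_parameters()
    pids = model.parameter_ids
    pvec0 = p0.vector(pids)
    base = compiled.rates(0.0, y0, pvec0)
    roles: dict[str, str] = {}
    for k, pid in enumerate(pids):
        psym = sp.Symbol(pid)
        appears = [j for j, e in enumerate(compiled.rate_exprs) if psym in e.free_symbols]
        if not appears or pvec0[k] == 0.0:
            roles[pid] = "other"
            continue
        linear = True
        for factor in (2.0, 3.0):
            pv = pvec0.copy()
            pv[k] *= factor
            scaled = compiled.rates(0.0, y0, pv)
            for j in appears:
                ref = abs(base[j]) if base[j] != 0 else 1.0
                if not math.isclose(scaled[j], factor * base[j], rel_tol=1e-9, abs_tol=1e-12 * ref):
                    linear = False
        roles[pid] = "limiting-rate" if linear else "other"
    return replace(
        model,
        parameters=[replace(p, role=roles[p.id]) for p in model.parameters],
        _compiled=None,
    )
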