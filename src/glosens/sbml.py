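"""SBML import.

Reads SBML Level 2/3 core models into :class:`~glosens.model.KineticModel`
via libsbml.  Scope is the constructs kinetic ODE analyses need:

* global and reaction-local parameters — local parameters are lifted into the
  flat parameter list under ``"<reaction name>.<parameter id>"`` (the naming
  convention used for published sensitivity tables);
* assignment rules and function definitions are inlined at load time;
* rate rules (on species, or on parameters, which are then promoted to
  state variables) are kept as explicit time-derivative expressions;
* events in the file are ignored with a warning — oscillation-period events
  are generated by this package, not read from models;
* algebraic rules and delay expressions raise
  :class:`~glosens.errors.UnsupportedFeatureError` naming the construct.

Species state is concentration; initial amounts are converted using the
compartment volume at load time.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Dict

import sympy as sp

from .errors import ModelFormatError, UnsupportedFeatureError
from .model import (
    Compartment,
    KineticModel,
    Parameter,
    Reaction,
    Species,
    TIME,
    assign_limiting_rate_roles,
)

log = logging.getLogger(__name__)

try:  # pragma: no cover - import guard
    import libsbml
except ImportError as _exc:  # pragma: no cover
    libsbml = None
    _libsbml_error = _exc


def _require_libsbml():
    if libsbml is None:  # pragma: no cover
        raise ImportError("python-libsbml is required for SBML input") from _libsbml_error


# ---------------------------------------------------------------------------
# MathML AST -> sympy

def _ast_to_sympy(node, rename: Dict[str, str], functions: Dict[str, tuple] | None = None) -> sp.Expr:
    functions = functions or {}
    if node is None:
        raise ModelFormatError("empty math element")
    t = node.getType()
    kids = [
        _ast_to_sympy(node.getChild(i), rename, functions)
        for i in range(node.getNumChildren())
    ]

    if t == libsbml.AST_FUNCTION:  # user-defined function: inline its body
        fid = node.getName()
        if fid not in functions:
            raise UnsupportedFeatureError(f"call to unknown function {fid!r}")
        argnames, body_ast = functions[fid]
        if len(kids) != len(argnames):
            raise ModelFormatError(f"function {fid!r} called with wrong arity")
        body = _ast_to_sympy(body_ast, {}, functions)
        return body.xreplace({sp.Symbol(a): k for a, k in zip(argnames, kids)})

    if t == libsbml.AST_INTEGER:
        return sp.Integer(node.getInteger())
    if t in (libsbml.AST_REAL, libsbml.AST_REAL_E):
        return sp.Float(node.getReal())
    if t == libsbml.AST_RATIONAL:
        return sp.Rational(node.getNumerator(), node.getDenominator())
    if t == libsbml.AST_NAME:
        name = node.getName()
        return sp.Symbol(rename.get(name, name))
    if t == libsbml.AST_NAME_TIME:
        return TIME
    if t == libsbml.AST_NAME_AVOGADRO:
        return sp.Float(6.02214179e23)
    if t == libsbml.AST_CONSTANT_PI:
        return sp.pi
    if t == libsbml.AST_CONSTANT_E:
        return sp.E
    if t == libsbml.AST_CONSTANT_TRUE:
        return sp.true
    if t == libsbml.AST_CONSTANT_FALSE:
        return sp.false

    if t == libsbml.AST_PLUS:
        return sp.Add(*kids) if kids else sp.Integer(0)
    if t == libsbml.AST_MINUS:
        return -kids[0] if len(kids) == 1 else kids[0] - kids[1]
    if t == libsbml.AST_TIMES:
        return sp.Mul(*kids) if kids else sp.Integer(1)
    if t == libsbml.AST_DIVIDE:
        return kids[0] / kids[1]
    if t in (libsbml.AST_POWER, libsbml.AST_FUNCTION_POWER):
        return kids[0] ** kids[1]

    if t == libsbml.AST_FUNCTION_DELAY:
        raise UnsupportedFeatureError("delay expressions are not supported")
    if t == libsbml.AST_FUNCTION_PIECEWISE:
        # libsbml order: value1, cond1, value2, cond2, ..., [otherwise]
        pairs = []
        i = 0
        while i + 1 < len(kids):
            pairs.append((kids[i], kids[i + 1]))
            i += 2
        if i < len(kids):
            pairs.append((kids[i], sp.true))
        return sp.Piecewise(*pairs)

    unary = {
        libsbml.AST_FUNCTION_EXP: sp.exp,
        libsbml.AST_FUNCTION_LN: sp.log,
        libsbml.AST_FUNCTION_ABS: sp.Abs,
        libsbml.AST_FUNCTION_FLOOR: sp.floor,
        libsbml.AST_FUNCTION_CEILING: sp.ceiling,
        libsbml.AST_FUNCTION_FACTORIAL: sp.factorial,
        libsbml.AST_FUNCTION_SIN: sp.sin,
        libsbml.AST_FUNCTION_COS: sp.cos,
        libsbml.AST_FUNCTION_TAN: sp.tan,
        libsbml.AST_FUNCTION_ARCSIN: sp.asin,
        libsbml.AST_FUNCTION_ARCCOS: sp.acos,
        libsbml.AST_FUNCTION_ARCTAN: sp.atan,
        libsbml.AST_FUNCTION_SINH: sp.sinh,
        libsbml.AST_FUNCTION_COSH: sp.cosh,
        libsbml.AST_FUNCTION_TANH: sp.tanh,
    }
    if t in unary:
        return unary[t](kids[0])
    if t == libsbml.AST_FUNCTION_LOG:
        if len(kids) == 2:  # log(base, x)
            return sp.log(kids[1], kids[0])
        return sp.log(kids[0], 10)
    if t == libsbml.AST_FUNCTION_ROOT:
        if len(kids) == 2:
            return kids[1] ** (sp.Integer(1) / kids[0])
        return sp.sqrt(kids[0])

    relational = {
        libsbml.AST_RELATIONAL_EQ: sp.Eq,
        libsbml.AST_RELATIONAL_NEQ: sp.Ne,
        libsbml.AST_RELATIONAL_GEQ: sp.Ge,
        libsbml.AST_RELATIONAL_GT: sp.Gt,
        libsbml.AST_RELATIONAL_LEQ: sp.Le,
        libsbml.AST_RELATIONAL_LT: sp.Lt,
    }
    if t in relational:
        return relational[t](*kids)
    if t == libsbml.AST_LOGICAL_AND:
        return sp.And(*kids)
    if t == libsbml.AST_LOGICAL_OR:
        return sp.Or(*kids)
    if t == libsbml.AST_LOGICAL_NOT:
        return sp.Not(kids[0])

    raise UnsupportedFeatureError(
        f"unsupported MathML construct: {libsbml.SBML_formulaToL3String(node)}"
    )


def _fresh_id(base: str, taken: set) -> str:
    if base not in taken:
        return base
    k = 2
    while f"{base}_{k}" in taken:
        k += 1
    log.warning("id collision: %r renamed to %r", base, f"{base}_{k}")
    return f"{base}_{k}"


def _inline(exprs: Dict[str, sp.Expr], assignments: Dict[str, sp.Expr]):
    """Substitute assignment expressions into ``exprs`` until fixed point."""
    if not assignments:
        return exprs
    subs = {sp.Symbol(k): v for k, v in assignments.items()}
    out = {}
    for key, e in exprs.items():
        for _ in range(len(assignments) + 1):
            new = e.xreplace(subs)
            if new == e:
                break
            e = new
        else:
            raise UnsupportedFeatureError("cyclic assignment rules cannot be inlined")
        out[key] = e
    return out


# ---------------------------------------------------------------------------

def load_sbml(path: str) -> KineticModel:
    """Load an SBML Level 2/3 file into a :class:`KineticModel`.

    All global and reaction-local parameters are lifted into a single flat
    parameter list; species initial values become the reference state.
    """
    _require_libsbml()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) or doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        first = doc.getError(0)
        raise ModelFormatError(
            f"cannot parse {path!r} as SBML: {first.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path!r} contains no SBML model")

    if sbml_model.getNumInitialAssignments():
        props = libsbml.ConversionProperties()
        props.addOption("expandInitialAssignments", True)
        doc.convert(props)
        sbml_model = doc.getModel()
        if sbml_model.getNumInitialAssignments():
            raise UnsupportedFeatureError("initial assignments could not be expanded")

    # user-defined functions are inlined during math conversion
    functions: Dict[str, tuple] = {}
    for i in range(sbml_model.getNumFunctionDefinitions()):
        fd = sbml_model.getFunctionDefinition(i)
        argnames = [fd.getArgument(j).getName() for j in range(fd.getNumArguments())]
        functions[fd.getId()] = (argnames, fd.getBody())

    if sbml_model.getNumEvents():
        log.warning(
            "%s: %d event(s) in the SBML file are ignored; period-detection "
            "events are generated internally",
            path,
            sbml_model.getNumEvents(),
        )
    for i in range(sbml_model.getNumRules()):
        if sbml_model.getRule(i).isAlgebraic():
            raise UnsupportedFeatureError("algebraic rules are not supported")

    compartments = []
    volumes = {}
    for i in range(sbml_model.getNumCompartments()):
        c = sbml_model.getCompartment(i)
        vol = c.getSize() if c.isSetSize() else 1.0
        if not math.isfinite(vol):
            vol = 1.0
        compartments.append(Compartment(c.getId(), vol))
        volumes[c.getId()] = vol
    if not compartments:
        compartments = [Compartment("default", 1.0)]
        volumes["default"] = 1.0

    # rules, classified
    assign_targets: Dict[str, sp.Expr] = {}
    rate_targets: Dict[str, sp.Expr] = {}
    for i in range(sbml_model.getNumRules()):
        rule = sbml_model.getRule(i)
        expr = _ast_to_sympy(rule.getMath(), {}, functions)
        if rule.isAssignment():
            assign_targets[rule.getVariable()] = expr
        elif rule.isRate():
            rate_targets[rule.getVariable()] = expr

    species = []
    amount_compartments = set()
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        cid = s.getCompartment() or compartments[0].id
        if s.isSetInitialConcentration():
            conc = s.getInitialConcentration()
        elif s.isSetInitialAmount():
            conc = s.getInitialAmount() / volumes.get(cid, 1.0)
        else:
            conc = 0.0
        boundary = bool(s.getBoundaryCondition() or s.getConstant())
        if s.getId() in assign_targets:
            # algebraically determined: inlined below, frozen in the state
            boundary = True
        if s.getHasOnlySubstanceUnits() and volumes.get(cid, 1.0) != 1.0:
            # symbol refers to an amount: park the species in a unit volume
            amount_cid = f"__amount_{cid}"
            if amount_cid not in amount_compartments:
                compartments.append(Compartment(amount_cid, 1.0))
                amount_compartments.add(amount_cid)
            conc = s.getInitialAmount() if s.isSetInitialAmount() else conc * volumes[cid]
            cid = amount_cid
        species.append(Species(s.getId(), float(conc), cid, boundary))

    parameters = []
    taken = {sp_.id for sp_ in species} | set(volumes) | {p.id for p in parameters}
    for i in range(sbml_model.getNumParameters()):
        p = sbml_model.getParameter(i)
        pid = p.getId()
        if pid in assign_targets:
            continue  # inlined, not a free parameter
        if pid in rate_targets:
            # a parameter governed by a rate rule is a state variable
            species.append(Species(pid, p.getValue() if p.isSetValue() else 0.0, compartments[0].id, False))
            continue
        parameters.append(Parameter(pid, float(p.getValue()) if p.isSetValue() else 0.0))
        taken.add(pid)

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        kl = r.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise ModelFormatError(f"reaction {r.getId()!r} has no kinetic law")
        label = r.getName() or r.getId()
        rename = {}
        n_local = kl.getNumLocalParameters() or kl.getNumParameters()
        for j in range(n_local):
            lp = kl.getLocalParameter(j) or kl.getParameter(j)
            flat = _fresh_id(f"{label}.{lp.getId()}", taken)
            taken.add(flat)
            rename[lp.getId()] = flat
            parameters.append(Parameter(flat, float(lp.getValue())))
        expr = _ast_to_sympy(kl.getMath(), rename, functions)
        stoich: Dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - (
                ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            )
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + (
                ref.getStoichiometry() if ref.isSetStoichiometry() else 1.0
            )
        reactions.append(Reaction(r.getId(), stoich, expr, name=label))

    # inline assignment rules everywhere they can appear
    if assign_targets:
        assign_targets = _inline(assign_targets, assign_targets)
        rate_laws = _inline({r.id: r.rate_law for r in reactions}, assign_targets)
        reactions = [
            Reaction(r.id, r.stoichiometry, rate_laws[r.id], r.name) for r in reactions
        ]
        rate_targets = _inline(rate_targets, assign_targets)

    model = KineticModel(
        species=species,
        compartments=compartments,
        reactions=reactions,
        parameters=parameters,
        rate_rules=rate_targets,
        name=sbml_model.getName() or sbml_model.getId() or os.path.basename(path),
    )
    model.validate()
    return assign_limiting_rate_roles(model)
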