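"""Symbolic representation of nonlinear time-invariant ODE state-space models.

Models follow the standard control-theoretic form

    dx/dt = f(x, p, u),    y = h(x, p),    optionally  x0 = xi(p),

with states ``x``, constant parameters ``p``, known time-dependent inputs
``u`` and measured outputs ``y``.  Outputs are functions of states and
parameters only (no direct feed-through of the input).  Models are declared
in a small text format (YAML sections for states, parameters, inputs,
dynamics, observables, constraints) with expressions written in conventional
infix math, using ``^`` for powers.  Non-rational expressions such as
``(8.4/G)^1.7`` are first class; strict-positivity constraints on the base
symbols keep differentiation and evaluation well defined.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import sympy as sp
import yaml
from sympy.parsing.sympy_parser import (
    convert_xor,
    rationalize,
    standard_transformations,
)

__all__ = [
    "ModelDefinitionError",
    "ConfigurationError",
    "OdeModel",
    "ModelConfiguration",
    "define_model",
    "load_model",
    "parse_expression",
    "configure",
]


class ModelDefinitionError(ValueError):
    """Raised when a declarative model description is inconsistent."""


class ConfigurationError(ValueError):
    """Raised when an analysis configuration does not fit its model."""


_TRANSFORMATIONS = standard_transformations + (convert_xor, rationalize)

# Curated namespace for expression parsing.  Deliberately small: it shadows
# sympy's single-letter constants (I, E, ...) and special functions (beta,
# gamma, ...) so that model symbols with those names mean what the model
# declares, not what sympy's global namespace happens to export.
_PARSE_GLOBALS: dict[str, Any] = {
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    "Symbol": sp.Symbol,
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "tanh": sp.tanh,
    "Abs": sp.Abs,
    "pi": sp.pi,
}


def parse_expression(text: str, symbols: Mapping[str, sp.Symbol]) -> sp.Expr:
    """Parse an infix math expression over a declared symbol table.

    ``^`` denotes exponentiation and decimal literals are converted to exact
    rationals (``1.7`` becomes ``17/10``) so that downstream exact-arithmetic
    rank computations stay exact whenever the model itself is rational.

    Raises
    ------
    ModelDefinitionError
        If the expression does not parse or references an undeclared symbol.
    """
    try:
        expr = sp.parsing.sympy_parser.parse_expr(
            str(text),
            local_dict=dict(symbols),
            global_dict=_PARSE_GLOBALS,
            transformations=_TRANSFORMATIONS,
            evaluate=True,
        )
    except (SyntaxError, TypeError, sp.SympifyError) as err:
        raise ModelDefinitionError(f"cannot parse expression {text!r}: {err}") from err
    declared = set(symbols.values())
    stray = sorted(str(s) for s in expr.free_symbols - declared)
    if stray:
        raise ModelDefinitionError(
            f"expression {text!r} references undeclared symbol(s): {', '.join(stray)}"
        )
    return expr


def _format_expr(expr: sp.Expr) -> str:
    return sp.sstr(expr).replace("**", "^")


def _as_exact(value: Any) -> sp.Expr:
    """Convert a numeric literal to an exact sympy number."""
    if isinstance(value, sp.Expr):
        return value
    if isinstance(value, numbers.Integral):
        return sp.Integer(int(value))
    return sp.Rational(str(value))


@dataclass(frozen=True)
class OdeModel:
    """A validated nonlinear time-invariant ODE model.

    Attributes
    ----------
    states, params, inputs
        Ordered tuples of sympy symbols, in declaration order.
    dynamics
        One expression per state, over states, parameters and inputs.
    outputs
        Named observable expressions over states and parameters only.
    constraints
        Domain constraints (e.g. ``G > 0``) used to restrict random
        specialization points and to police simulated trajectories.
    defaults
        Default parameter values (exact sympy numbers).
    steady_state_guess
        Optional per-state initial guess used when solving for the
        steady-state initial map xi(p).
    """

    name: str
    states: tuple[sp.Symbol, ...]
    params: tuple[sp.Symbol, ...]
    inputs: tuple[sp.Symbol, ...]
    dynamics: tuple[sp.Expr, ...]
    outputs: dict[str, sp.Expr]
    constraints: tuple[sp.Basic, ...] = ()
    defaults: dict[str, sp.Expr] = field(default_factory=dict)
    steady_state_guess: dict[str, float] | None = None
    description: str = ""
    provenance: str = ""

    # -- basic dimensions ---------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.states)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.params)

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.inputs)

    @property
    def output_names(self) -> tuple[str, ...]:
        return tuple(self.outputs)

    def symbol(self, name: str) -> sp.Symbol:
        for s in self.states + self.params + self.inputs:
            if str(s) == name:
                return s
        raise KeyError(f"model {self.name!r} declares no symbol {name!r}")

    def param_values(self, overrides: Mapping[str, Any] | None = None) -> dict[str, float]:
        """Default parameter values as floats, optionally overridden."""
        values = {k: float(v) for k, v in self.defaults.items()}
        for k, v in (overrides or {}).items():
            if k not in self.param_names:
                raise KeyError(f"unknown parameter {k!r} for model {self.name!r}")
            values[k] = float(v)
        missing = set(self.param_names) - set(values)
        if missing:
            raise ConfigurationError(
                f"no value for parameter(s) {sorted(missing)} of model {self.name!r}"
            )
        return values

    def positivity_required(self) -> dict[str, bool]:
        """Map symbol name -> True when a strict positivity constraint applies."""
        strict: dict[str, bool] = {}
        for rel in self.constraints:
            if isinstance(rel, sp.StrictGreaterThan) and rel.rhs == 0:
                strict[str(rel.lhs)] = True
            if isinstance(rel, sp.StrictLessThan) and rel.lhs == 0:
                strict[str(rel.rhs)] = True
        return strict

    # -- serialization ------------------------------------------------------
    def to_spec(self) -> dict[str, Any]:
        """Serialize back to the declarative format (round-trip safe)."""
        spec: dict[str, Any] = {
            "name": self.name,
            "states": list(self.state_names),
            "params": list(self.param_names),
            "inputs": list(self.input_names),
            "dynamics": {
                str(s): _format_expr(e) for s, e in zip(self.states, self.dynamics)
            },
            "observables": {k: _format_expr(e) for k, e in self.outputs.items()},
        }
        if self.constraints:
            spec["constraints"] = [_format_expr(c) for c in self.constraints]
        if self.defaults:
            spec["defaults"] = {k: str(v) for k, v in self.defaults.items()}
        if self.steady_state_guess is not None:
            spec["initial_map"] = {
                "kind": "steady_state",
                "guess": dict(self.steady_state_guess),
            }
        if self.description:
            spec["description"] = self.description
        if self.provenance:
            spec["provenance"] = self.provenance
        return spec

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_spec(), sort_keys=False))

    def configure(
        self,
        measured: Iterable[str],
        unknown: Iterable[str] = (),
        known_values: Mapping[str, Any] | None = None,
    ) -> "ModelConfiguration":
        return configure(self, measured, unknown, known_values)


def _unique_names(kind: str, names: Sequence[str]) -> list[str]:
    names = [str(n) for n in names]
    if len(set(names)) != len(names):
        raise ModelDefinitionError(f"duplicate {kind} name in {names}")
    return names


def define_model(spec: Mapping[str, Any]) -> OdeModel:
    """Build and validate an :class:`OdeModel` from a declarative description.

    The description is a mapping with keys ``name``, ``states``, ``params``,
    ``inputs`` (optional), ``constants`` (optional, substituted at parse
    time), ``dynamics`` (one expression per state), ``observables`` (named
    output expressions; defaults to the full state), ``constraints``,
    ``defaults`` and ``initial_map``.
    """
    if not isinstance(spec, Mapping):
        raise ModelDefinitionError("model spec must be a mapping")
    name = str(spec.get("name") or "model")
    state_names = _unique_names("state", spec.get("states") or [])
    param_names = _unique_names("parameter", spec.get("params") or [])
    input_names = _unique_names("input", spec.get("inputs") or [])
    if not state_names:
        raise ModelDefinitionError("model declares no states")
    all_names = state_names + param_names + input_names
    if len(set(all_names)) != len(all_names):
        raise ModelDefinitionError(
            "states, params and inputs must use disjoint symbol names"
        )

    symtab = {n: sp.Symbol(n, real=True) for n in all_names}
    constants = {
        str(k): _as_exact(v) for k, v in (spec.get("constants") or {}).items()
    }
    parse_tab: dict[str, Any] = dict(symtab)
    parse_tab.update(constants)

    dynamics_spec = spec.get("dynamics")
    if dynamics_spec is None:
        raise ModelDefinitionError("model declares no dynamics")
    if isinstance(dynamics_spec, Mapping):
        missing = [n for n in state_names if n not in dynamics_spec]
        extra = [str(k) for k in dynamics_spec if str(k) not in state_names]
        if missing or extra:
            raise ModelDefinitionError(
                f"dynamics must give exactly one expression per state; "
                f"missing {missing}, extraneous {extra}"
            )
        dyn_exprs = [dynamics_spec[n] for n in state_names]
    else:
        dyn_exprs = list(dynamics_spec)
        if len(dyn_exprs) != len(state_names):
            raise ModelDefinitionError(
                f"got {len(dyn_exprs)} dynamics expressions for "
                f"{len(state_names)} states"
            )
    dynamics = tuple(parse_expression(e, parse_tab) for e in dyn_exprs)

    obs_spec = spec.get("observables")
    if obs_spec is None:
        obs_spec = spec.get("outputs")
    if obs_spec is None:
        obs_spec = {n: n for n in state_names}
    if not isinstance(obs_spec, Mapping):
        obs_spec = {str(e): str(e) for e in obs_spec}
    if not obs_spec:
        raise ModelDefinitionError("model declares an empty output set")
    input_syms = {symtab[n] for n in input_names}
    outputs: dict[str, sp.Expr] = {}
    for key, e in obs_spec.items():
        expr = parse_expression(e, parse_tab)
        bad = sorted(str(s) for s in expr.free_symbols & input_syms)
        if bad:
            raise ModelDefinitionError(
                f"output {key!r} references input symbol(s) {bad}; outputs "
                "must be functions of states and parameters only"
            )
        outputs[str(key)] = expr

    constraints = tuple(
        parse_expression(c, parse_tab) for c in (spec.get("constraints") or [])
    )
    defaults = {
        str(k): _as_exact(v) for k, v in (spec.get("defaults") or {}).items()
    }
    bad_defaults = set(defaults) - set(param_names)
    if bad_defaults:
        raise ModelDefinitionError(
            f"defaults given for undeclared parameter(s) {sorted(bad_defaults)}"
        )

    guess = None
    imap = spec.get("initial_map")
    if imap:
        if str(imap.get("kind", "steady_state")) != "steady_state":
            raise ModelDefinitionError(
                f"unsupported initial_map kind {imap.get('kind')!r}"
            )
        raw = imap.get("guess") or {}
        guess = {n: float(raw.get(n, 1.0)) for n in state_names}

    return OdeModel(
        name=name,
        states=tuple(symtab[n] for n in state_names),
        params=tuple(symtab[n] for n in param_names),
        inputs=tuple(symtab[n] for n in input_names),
        dynamics=dynamics,
        outputs=outputs,
        constraints=constraints,
        defaults=defaults,
        steady_state_guess=guess,
        description=str(spec.get("description") or ""),
        provenance=str(spec.get("provenance") or ""),
    )


def load_model(path: str | Path) -> OdeModel:
    """Load a model from a declarative YAML file."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if spec is None:
        raise ModelDefinitionError(f"empty model file {path}")
    spec.setdefault("name", Path(path).stem)
    return define_model(spec)


@dataclass(frozen=True)
class ModelConfiguration:
    """An analysis-ready configuration of a model.

    Fixes which outputs are measured and which parameters are unknown;
    remaining parameters are substituted by their known numeric values.  The
    augmented state appends the unknown parameters (as constant states with
    zero dynamics) after the model states, which recasts structural
    identifiability of the parameters as observability of the augmented
    state.
    """

    model: OdeModel
    measured: tuple[str, ...]
    unknown: tuple[str, ...]
    known_values: dict[str, sp.Expr]

    @property
    def aug_symbols(self) -> tuple[sp.Symbol, ...]:
        unknown_syms = tuple(s for s in self.model.params if str(s) in self.unknown)
        return self.model.states + unknown_syms

    @property
    def aug_names(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.aug_symbols)

    @property
    def n_aug(self) -> int:
        return self.model.n_states + len(self.unknown)

    @property
    def _known_subs(self) -> dict[sp.Symbol, sp.Expr]:
        return {self.model.symbol(k): v for k, v in self.known_values.items()}

    @property
    def aug_dynamics(self) -> tuple[sp.Expr, ...]:
        """f with known parameters substituted, extended by zero dynamics."""
        subs = self._known_subs
        f = tuple(e.xreplace(subs) for e in self.model.dynamics)
        return f + (sp.Integer(0),) * len(self.unknown)

    @property
    def output_exprs(self) -> tuple[sp.Expr, ...]:
        subs = self._known_subs
        return tuple(self.model.outputs[k].xreplace(subs) for k in self.measured)

    def describe(self) -> dict[str, Any]:
        return {
            "model": self.model.name,
            "measured": list(self.measured),
            "unknown": list(self.unknown),
            "known_values": {k: float(v) for k, v in self.known_values.items()},
        }


def configure(
    model: OdeModel,
    measured: Iterable[str],
    unknown: Iterable[str] = (),
    known_values: Mapping[str, Any] | None = None,
) -> ModelConfiguration:
    """Fix measured outputs and unknown parameters for one analysis.

    ``known_values`` must cover every parameter not listed in ``unknown``;
    parameters with declared defaults fall back to those.
    """
    measured = tuple(dict.fromkeys(str(m) for m in measured))
    unknown = tuple(dict.fromkeys(str(u) for u in unknown))
    if not measured:
        raise ConfigurationError("measured output set must be non-empty")
    bad = [m for m in measured if m not in model.output_names]
    if bad:
        raise ConfigurationError(
            f"measured output(s) {bad} not among declared observables "
            f"{list(model.output_names)}"
        )
    bad = [u for u in unknown if u not in model.param_names]
    if bad:
        raise ConfigurationError(
            f"unknown parameter(s) {bad} not among declared parameters "
            f"{list(model.param_names)}"
        )
    known: dict[str, sp.Expr] = {}
    supplied = {str(k): v for k, v in (known_values or {}).items()}
    for p in model.param_names:
        if p in unknown:
            continue
        if p in supplied:
            known[p] = _as_exact(supplied[p])
        elif p in model.defaults:
            known[p] = model.defaults[p]
        else:
            raise ConfigurationError(
                f"parameter {p!r} is declared known but has no supplied or "
                "default value"
            )
    return ModelConfiguration(
        model=model, measured=measured, unknown=unknown, known_values=known
    )
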