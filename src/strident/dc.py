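"""Simulation-based testing of dynamical compensation (DC).

A model output ``y_i`` has dynamical compensation with respect to a
parameter ``p_i`` (in the identifiability-aware sense) when two conditions
hold:

1. *Exact adaptation*: starting from the steady state under ``p_i = k1``
   and switching to ``p_i = k2`` with zero input, the output returns
   asymptotically to its pre-switch baseline.
2. *Output invariance*: from the two adapted steady states, the output
   response to any time-dependent input is identical for ``k1`` and ``k2``.

Both conditions are checked numerically: steady states by root finding on
the vector field, trajectories by stiff-capable integration at tight
tolerances, invariance on at least two structurally distinct input signals.
Verdicts are reported per (output, parameter) pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import OdeModel
from .signals import InputSignal, meal_pulse_input

__all__ = [
    "SteadyStateError",
    "SimulationError",
    "Trajectory",
    "AdaptationResult",
    "DCVerdict",
    "SymmetryReport",
    "find_steady_state",
    "simulate",
    "check_exact_adaptation",
    "check_dc_invariance",
    "scaling_symmetry_experiment",
]


class SteadyStateError(RuntimeError):
    """Root finding for the steady state failed or the root is inadmissible."""


class SimulationError(RuntimeError):
    """The integrator failed or a domain constraint was violated."""


# ---------------------------------------------------------------------------
# compiled right-hand sides, cached per model instance
_RHS_CACHE: dict[int, tuple[Any, Any]] = {}


def _compiled(model: OdeModel):
    key = id(model)
    if key not in _RHS_CACHE:
        args = list(model.states) + list(model.params) + list(model.inputs)
        f = sp.lambdify(args, list(model.dynamics), modules="numpy")
        h = sp.lambdify(args, list(model.outputs.values()), modules="numpy")
        _RHS_CACHE[key] = (f, h)
    return _RHS_CACHE[key]


def _param_vector(model: OdeModel, values: Mapping[str, float]) -> list[float]:
    return [float(values[n]) for n in model.param_names]


def rhs_value(
    model: OdeModel,
    x: Sequence[float],
    param_values: Mapping[str, float],
    u: float | Sequence[float] = 0.0,
) -> np.ndarray:
    """Evaluate f(x, p, u) numerically."""
    f, _ = _compiled(model)
    uvals = [u] * model.n_inputs if np.ndim(u) == 0 else list(u)
    return np.asarray(
        f(*x, *_param_vector(model, param_values), *uvals), dtype=float
    )


def find_steady_state(
    model: OdeModel,
    param_values: Mapping[str, float] | None = None,
    guess: Sequence[float] | Mapping[str, float] | None = None,
    tol: float = 1e-10,
    max_retries: int = 30,
) -> np.ndarray:
    """Solve f(x, p, 0) = 0 for an admissible steady state.

    The returned state satisfies ``||f||_inf < tol`` and the model's
    positivity constraints; inadmissible roots trigger retries from a
    perturbed guess.  This realizes the steady-state initial map xi(p) used
    by the DC definitions.
    """
    values = model.param_values(param_values)
    if guess is None:
        guess = model.steady_state_guess or {n: 1.0 for n in model.state_names}
    if isinstance(guess, Mapping):
        guess = [float(guess.get(n, 1.0)) for n in model.state_names]
    base = np.asarray(guess, dtype=float)
    x0 = base.copy()
    strict = model.positivity_required()
    rng = np.random.default_rng(0)
    def fun(x):
        # multi-start iterates may wander outside the domain (negative
        # bases under real exponents); hybr recovers from the NaNs
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            return rhs_value(model, x, values, 0.0)

    last_residual = np.inf
    for attempt in range(max_retries):
        sol = root(fun, x0, method="hybr")
        residual = float(np.max(np.abs(fun(sol.x))))
        last_residual = min(last_residual, residual)
        # a strictly-positive state collapsing to ~0 marks a degenerate
        # (boundary) equilibrium, not the physiological one
        positive_ok = all(
            sol.x[i] > max(1e-9, 1e-9 * abs(base[i]))
            for i, n in enumerate(model.state_names)
            if strict.get(n)
        )
        if residual < tol and positive_ok:
            return sol.x
        # multiplicative multi-start: the admissible equilibrium may sit
        # decades away from the stored guess when parameters change a lot
        scale = 10.0 ** rng.uniform(-1.5, 1.5, size=len(base))
        x0 = np.where(base == 0, 0.1 * scale - 0.05, np.abs(base) * scale)
    raise SteadyStateError(
        f"no admissible steady state for model {model.name!r} after "
        f"{max_retries} attempts (best residual {last_residual:.3e})"
    )


@dataclass
class Trajectory:
    """Time grid, states and outputs from one numerical integration."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), n_states)
    state_names: tuple[str, ...]
    outputs: dict[str, np.ndarray]
    param_segments: list[tuple[float, dict[str, float]]]
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    def output(self, name: str) -> np.ndarray:
        return self.outputs[name]

    def to_dataframe(self):
        import pandas as pd

        data = {"t": self.t}
        for i, n in enumerate(self.state_names):
            data[n] = self.states[:, i]
        for n, v in self.outputs.items():
            if n not in data:
                data[f"y_{n}"] = v
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate(
    model: OdeModel,
    param_values: Mapping[str, float] | None = None,
    x0: Sequence[float] | None = None,
    input_signal: InputSignal | None = None,
    t_span: tuple[float, float] = (0.0, 1000.0),
    t_eval: np.ndarray | None = None,
    switches: Sequence[tuple[float, Mapping[str, float]]] = (),
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
    check_domain: bool = True,
) -> Trajectory:
    """Integrate the model with pulse inputs and parameter-switch events.

    ``switches`` is a sequence of ``(time, {param: value})`` events applied
    cumulatively; integration restarts at each switch (and at pulse edges)
    with a continuous state, which is how an abrupt environmental change to
    a constant parameter is modelled.
    """
    values = model.param_values(param_values)
    if x0 is None:
        x0 = find_steady_state(model, values)
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise SimulationError("initial state must be finite")
    signal = input_signal or InputSignal.zero()
    t0, tf = map(float, t_span)
    if not tf > t0:
        raise SimulationError("t_span must be increasing")
    if t_eval is None:
        t_eval = np.linspace(t0, tf, 2001)
    t_eval = np.asarray(t_eval, dtype=float)
    if np.any(np.diff(t_eval) <= 0):
        raise SimulationError("time grid must be strictly increasing")

    switch_list = sorted(
        ((float(ts), dict(vals)) for ts, vals in switches), key=lambda s: s[0]
    )
    boundaries = sorted(
        {t0, tf}
        | {ts for ts, _ in switch_list if t0 < ts < tf}
        | {b for b in signal.breakpoints() if t0 < b < tf}
    )

    f, h = _compiled(model)
    n_in = model.n_inputs

    current = dict(values)
    segments: list[tuple[float, dict[str, float]]] = [(t0, dict(current))]
    ts_all: list[np.ndarray] = []
    xs_all: list[np.ndarray] = []
    seg_params: list[dict[str, float]] = []
    nfev = 0
    x_now = x0.copy()

    for a, b in zip(boundaries, boundaries[1:]):
        for ts, vals in switch_list:
            if np.isclose(ts, a) and ts > t0 or (ts == t0 == a):
                current.update({k: float(v) for k, v in vals.items()})
                segments.append((a, dict(current)))
        pvec = _param_vector(model, current)

        def seg_rhs(t, x, pvec=pvec):
            u = signal(t)
            uvals = [u] * n_in
            return f(*x, *pvec, *uvals)

        pts = t_eval[(t_eval >= a) & (t_eval <= b)]
        pts = np.unique(np.concatenate(([a], pts, [b])))
        sol = solve_ivp(
            seg_rhs,
            (a, b),
            x_now,
            method=method,
            t_eval=pts,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{a}, {b}]: {sol.message}"
            )
        nfev += sol.nfev
        keep = np.isin(sol.t, t_eval) if len(ts_all) == 0 else (
            np.isin(sol.t, t_eval) & (sol.t > a)
        )
        ts_all.append(sol.t[keep])
        xs_all.append(sol.y.T[keep])
        seg_params.extend([dict(current)] * int(keep.sum()))
        x_now = sol.y[:, -1].copy()

    t_out = np.concatenate(ts_all)
    x_out = np.vstack(xs_all)

    if check_domain:
        strict = model.positivity_required()
        for i, n in enumerate(model.state_names):
            if strict.get(n) and np.any(x_out[:, i] <= 0):
                j = int(np.argmax(x_out[:, i] <= 0))
                raise SimulationError(
                    f"state {n!r} violated its positivity constraint at "
                    f"t={t_out[j]:.6g}"
                )

    out_names = model.output_names
    outputs = {n: np.empty_like(t_out) for n in out_names}
    for j in range(len(t_out)):
        pv = _param_vector(model, seg_params[j])
        vals = h(*x_out[j], *pv, *([0.0] * n_in))
        for n, v in zip(out_names, vals):
            outputs[n][j] = v

    return Trajectory(
        t=t_out,
        states=x_out,
        state_names=model.state_names,
        outputs=outputs,
        param_segments=segments,
        diagnostics={"nfev": nfev, "method": method, "rtol": rtol, "atol": atol},
    )


@dataclass
class AdaptationResult:
    """Outcome of the exact-adaptation test for one (output, parameter) pair."""

    output: str
    param: str
    k1: float
    k2: float
    xi1: dict[str, float]
    asymptotic_state: dict[str, float]
    output_rel_deviation: float
    state_ratios: dict[str, float]
    horizon_used: float
    settled: bool
    residual_at_horizon: float
    tol: float
    adapted: bool

    def to_dict(self) -> dict[str, Any]:
        return {k: v for k, v in self.__dict__.items()}


def check_exact_adaptation(
    model: OdeModel,
    output_id: str,
    param_id: str,
    k1: float,
    k2: float,
    horizon: float = 2e5,
    tol: float = 1e-3,
    param_values: Mapping[str, float] | None = None,
    settle_tol: float = 1e-8,
    max_extensions: int = 3,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> AdaptationResult:
    """Exact adaptation: does the output baseline recover after a switch?

    The model is put at its steady state under ``param_id = k1``, the
    parameter is switched to ``k2`` with zero input, and the system is
    integrated until the vector field has settled (the horizon is doubled,
    up to ``max_extensions`` times, while ``||f||_inf`` at the horizon
    exceeds ``settle_tol``; adaptation of the slow mode can take months of
    model time).  The adapted flag is true when the relative output
    deviation at the horizon is below ``tol``.
    """
    values = model.param_values(param_values)
    values[param_id] = float(k1)
    xi1 = find_steady_state(model, values)
    values2 = dict(values, **{param_id: float(k2)})

    _, h = _compiled(model)
    names = list(model.output_names)
    idx = names.index(output_id)

    def output_at(x: np.ndarray, vals: Mapping[str, float]) -> float:
        res = h(*x, *_param_vector(model, vals), *([0.0] * model.n_inputs))
        return float(res[idx])

    y0 = output_at(xi1, values)
    x_now = xi1.copy()
    t_done = 0.0
    span = float(horizon)
    settled = False
    residual = np.inf
    for _ in range(max_extensions + 1):
        traj = simulate(
            model,
            values2,
            x_now,
            t_span=(t_done, t_done + span),
            t_eval=np.linspace(t_done, t_done + span, 1001),
            rtol=rtol,
            atol=atol,
        )
        x_now = traj.states[-1]
        t_done += span
        residual = float(np.max(np.abs(rhs_value(model, x_now, values2, 0.0))))
        if residual < settle_tol:
            settled = True
            break
        span *= 2.0

    y_end = output_at(x_now, values2)
    scale = abs(y0) if abs(y0) > 1e-12 else 1.0
    deviation = abs(y_end - y0) / scale
    ratios = {
        n: float(x_now[i] / xi1[i]) if xi1[i] != 0 else float("nan")
        for i, n in enumerate(model.state_names)
    }
    return AdaptationResult(
        output=output_id,
        param=param_id,
        k1=float(k1),
        k2=float(k2),
        xi1={n: float(v) for n, v in zip(model.state_names, xi1)},
        asymptotic_state={n: float(v) for n, v in zip(model.state_names, x_now)},
        output_rel_deviation=float(deviation),
        state_ratios=ratios,
        horizon_used=t_done,
        settled=settled,
        residual_at_horizon=residual,
        tol=tol,
        adapted=bool(deviation < tol),
    )


@dataclass
class DCVerdict:
    """Outcome of the two DC conditions for one (output, parameter) pair."""

    output: str
    param: str
    k1: float
    k2: float
    adaptation: AdaptationResult
    signals: list[dict[str, Any]]
    max_abs_deviation: float
    max_rel_deviation: float
    tol: float
    has_dc: bool

    def to_dict(self) -> dict[str, Any]:
        return {
            "output": self.output,
            "param": self.param,
            "k1": self.k1,
            "k2": self.k2,
            "adaptation": self.adaptation.to_dict(),
            "signals": self.signals,
            "max_abs_deviation": self.max_abs_deviation,
            "max_rel_deviation": self.max_rel_deviation,
            "tol": self.tol,
            "has_dc": self.has_dc,
        }

    def to_json(self, **kw: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def default_dc_signals() -> list[InputSignal]:
    """Two structurally distinct meal-like pulse trains."""
    return [
        meal_pulse_input(n_pulses=3, spacing=360.0, amplitude=0.5, width=30.0),
        meal_pulse_input(n_pulses=2, spacing=300.0, amplitude=0.9, width=20.0),
    ]


def check_dc_invariance(
    model: OdeModel,
    output_id: str,
    param_id: str,
    k1: float,
    k2: float,
    input_signals: Sequence[InputSignal] | None = None,
    tol: float = 1e-6,
    t_span: tuple[float, float] = (0.0, 1440.0),
    param_values: Mapping[str, float] | None = None,
    adaptation_kwargs: Mapping[str, Any] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> DCVerdict:
    """Full DC test: exact adaptation plus output invariance.

    For every input signal the output is simulated under ``k1`` from its
    steady state and under ``k2`` from *its own* adapted steady state, on a
    shared time grid; the verdict is positive only if adaptation held and
    the maximum relative output deviation stays below ``tol`` for every
    signal.  At least two structurally distinct signals are required, since
    the property quantifies over arbitrary inputs.
    """
    signals = list(input_signals) if input_signals is not None else default_dc_signals()
    if len(signals) < 2:
        raise ValueError("at least two input signals are required")
    if not any(
        a.structurally_distinct_from(b)
        for i, a in enumerate(signals)
        for b in signals[i + 1 :]
    ):
        raise ValueError(
            "input signals must include two structurally distinct ones "
            "(different pulse counts or amplitudes)"
        )

    adaptation = check_exact_adaptation(
        model, output_id, param_id, k1, k2,
        param_values=param_values, rtol=rtol, atol=atol,
        **dict(adaptation_kwargs or {}),
    )
    values1 = model.param_values(param_values)
    values1[param_id] = float(k1)
    values2 = dict(values1, **{param_id: float(k2)})
    xi1 = find_steady_state(model, values1)
    xi2 = find_steady_state(
        model, values2, guess=adaptation.asymptotic_state
    )

    t_eval = np.linspace(t_span[0], t_span[1], 1501)
    max_abs = 0.0
    max_rel = 0.0
    tested = []
    for sig in signals:
        tr1 = simulate(model, values1, xi1, sig, t_span, t_eval,
                       rtol=rtol, atol=atol)
        tr2 = simulate(model, values2, xi2, sig, t_span, t_eval,
                       rtol=rtol, atol=atol)
        y1 = tr1.output(output_id)
        y2 = tr2.output(output_id)
        dev = float(np.max(np.abs(y1 - y2)))
        scale = max(float(np.max(np.abs(y1))), float(np.max(np.abs(y2))), 1e-12)
        max_abs = max(max_abs, dev)
        max_rel = max(max_rel, dev / scale)
        tested.append(sig.describe())

    return DCVerdict(
        output=output_id,
        param=param_id,
        k1=float(k1),
        k2=float(k2),
        adaptation=adaptation,
        signals=tested,
        max_abs_deviation=max_abs,
        max_rel_deviation=max_rel,
        tol=tol,
        has_dc=bool(adaptation.adapted and max_rel < tol),
    )


@dataclass
class SymmetryReport:
    """Paired-trajectory comparison under a scaling symmetry."""

    mode: str
    k: float
    params_ref: dict[str, float]
    params_alt: dict[str, float]
    expected_scale: dict[str, float]
    max_rel_deviation: dict[str, float]       # raw deviation per state
    max_scaled_deviation: dict[str, float]    # after undoing expected scaling
    trajectory_ref: Trajectory
    trajectory_alt: Trajectory
    scenario: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "mode": self.mode,
            "k": self.k,
            "params_ref": self.params_ref,
            "params_alt": self.params_alt,
            "expected_scale": self.expected_scale,
            "max_rel_deviation": self.max_rel_deviation,
            "max_scaled_deviation": self.max_scaled_deviation,
            "scenario": self.scenario,
        }

    def to_json(self, **kw: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def scaling_symmetry_experiment(
    model: OdeModel,
    k: float,
    mode: str = "param_state",
    input_signal: InputSignal | None = None,
    t_span: tuple[float, float] = (0.0, 2e5),
    switch_time: float | None = 1e5,
    switch_factor: float = 0.5,
    param_values: Mapping[str, float] | None = None,
    sensitivity_param: str = "si",
    gain_param: str = "p",
    controller_state: str = "I",
    mass_state: str = "beta",
    n_grid: int = 2001,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SymmetryReport:
    """Compensation symmetries of the glucose homeostasis circuit.

    ``param_param`` compares ``{si, p}`` against ``{si/k, k*p}`` with the
    insulin initial condition scaled by ``k`` (glucose and beta-cell mass
    trajectories coincide, insulin differs by the factor ``k``);
    ``param_state`` keeps ``p`` fixed and compares ``{si}`` against
    ``{si/k}`` with both unmeasured states (insulin and beta-cell mass)
    scaled by ``k`` (only glucose coincides).  A mid-run switch multiplying
    the sensitivity parameter by ``switch_factor`` is applied to both
    members of the pair, so the symmetry is exercised across the slow
    adaptation as well.
    """
    if k <= 0:
        raise ValueError("scaling factor k must be positive")
    if mode not in ("param_param", "param_state"):
        raise ValueError(f"unknown symmetry mode {mode!r}")

    values = model.param_values(param_values)
    xi = find_steady_state(model, values)
    state_names = model.state_names
    x_ref = xi.copy()

    scale = {n: 1.0 for n in state_names}
    alt = dict(values)
    alt[sensitivity_param] = values[sensitivity_param] / k
    scale[controller_state] = k
    if mode == "param_param":
        alt[gain_param] = values[gain_param] * k
    else:
        scale[mass_state] = k
    x_alt = np.array(
        [x_ref[i] * scale[n] for i, n in enumerate(state_names)]
    )

    if input_signal is None:
        input_signal = meal_pulse_input(
            n_pulses=3, spacing=360.0, amplitude=0.5, width=30.0
        )
    switches_ref: list[tuple[float, dict[str, float]]] = []
    switches_alt: list[tuple[float, dict[str, float]]] = []
    if switch_time is not None and t_span[0] < switch_time < t_span[1]:
        switches_ref = [
            (switch_time,
             {sensitivity_param: values[sensitivity_param] * switch_factor})
        ]
        switches_alt = [
            (switch_time,
             {sensitivity_param: alt[sensitivity_param] * switch_factor})
        ]

    t_eval = np.linspace(t_span[0], t_span[1], n_grid)
    tr_ref = simulate(model, values, x_ref, input_signal, t_span, t_eval,
                      switches=switches_ref, rtol=rtol, atol=atol)
    tr_alt = simulate(model, alt, x_alt, input_signal, t_span, t_eval,
                      switches=switches_alt, rtol=rtol, atol=atol)

    raw: dict[str, float] = {}
    scaled: dict[str, float] = {}
    for i, n in enumerate(state_names):
        a = tr_ref.states[:, i]
        b = tr_alt.states[:, i]
        denom = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))), 1e-12)
        raw[n] = float(np.max(np.abs(a - b))) / denom
        expected = a * scale[n]
        denom_s = max(float(np.max(np.abs(expected))), 1e-12)
        scaled[n] = float(np.max(np.abs(b - expected))) / denom_s

    return SymmetryReport(
        mode=mode,
        k=float(k),
        params_ref={n: float(v) for n, v in values.items()},
        params_alt={n: float(v) for n, v in alt.items()},
        expected_scale=scale,
        max_rel_deviation=raw,
        max_scaled_deviation=scaled,
        trajectory_ref=tr_ref,
        trajectory_alt=tr_alt,
        scenario={
            "t_span": list(map(float, t_span)),
            "switch_time": switch_time,
            "switch_factor": switch_factor,
            "input": input_signal.describe(),
        },
    )
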