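"""Structural identifiability via the nonlinear observability rank condition.

Structural identifiability is analysed as generalized observability: unknown
parameters are appended to the state vector as constant states with zero
dynamics, and the observability-identifiability matrix is assembled by
stacking Jacobians of extended Lie derivatives of the measured outputs with
respect to the augmented state.  If the matrix reaches full rank ``n + q'``
at a generic point, the configuration satisfies the generalized
observability-identifiability condition (OIC) and is locally observable and
identifiable.  Individual symbols are classified by column deletion: if
removing the column of a symbol leaves the rank unchanged, that parameter is
structurally unidentifiable (that state unobservable).

Rank is evaluated by randomized specialization: all free symbols (augmented
states and retained input derivatives) are replaced by random admissible
rational values, and the rank of the resulting numeric matrix is taken,
maximized over several draws.  Rational models are handled in exact rational
arithmetic; non-rational models (real exponents, transcendental terms) fall
back to a high-precision floating SVD.  A random specialization yields the
generic rank with overwhelming probability, so the verdicts are those of the
generic (local) analysis.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import mpmath
import sympy as sp

from ._taylor import taylor_oi_rows
from .model import ConfigurationError, ModelConfiguration, OdeModel

__all__ = [
    "EvaluationError",
    "SpecializationPolicy",
    "OIMatrix",
    "IdentifiabilityReport",
    "SweepReport",
    "extended_lie_derivative",
    "build_oi_matrix",
    "evaluate_rank",
    "check_oic",
    "classify_symbols",
    "sweep_configurations",
]


class EvaluationError(RuntimeError):
    """Raised when no admissible random specialization point can be found."""


@dataclass(frozen=True)
class SpecializationPolicy:
    """How free symbols are specialized when evaluating numeric rank.

    Parameters
    ----------
    draws
        Number of independent random evaluation points; the reported rank is
        the maximum over draws (a random point underestimates the generic
        rank only on a measure-zero set, so the max is the generic rank with
        overwhelming probability).
    value_domain
        Integer range ``(lo, hi)`` from which numerators and denominators of
        the random rationals are drawn, giving values roughly in
        ``[lo/hi, hi/lo]``.  Values are strictly positive, which satisfies
        the positivity constraints biological models declare.
    seed
        Seed for the draw stream; identical policy and configuration give
        identical reports.
    arithmetic
        ``"exact"`` (rational rank over Q), ``"float"`` (high-precision SVD)
        or ``"auto"`` (exact when the specialized matrix is rational).
    input_mode
        ``"generic"`` keeps input derivatives ``u, u', u'', ...`` as free
        nonzero symbols up to the current derivative level, modelling an
        arbitrarily exciting input; ``"constant"`` sets all derivatives of
        the input to zero.
    dps
        Decimal precision of the floating pipeline.
    """

    draws: int = 3
    value_domain: tuple[int, int] = (5, 40)
    seed: int = 0
    arithmetic: str = "auto"
    input_mode: str = "generic"
    dps: int = 50
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if self.arithmetic not in ("auto", "exact", "float"):
            raise ValueError(f"unknown arithmetic mode {self.arithmetic!r}")
        if self.input_mode not in ("generic", "constant"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        lo, hi = self.value_domain
        if not (0 < lo < hi):
            raise ValueError("value_domain must satisfy 0 < lo < hi")

    def escalated(self) -> "SpecializationPolicy":
        """Tie-break policy for borderline ranks: more draws, more precision."""
        return replace(self, draws=self.draws * 3, dps=self.dps * 2)


def _chain_symbol(input_sym: sp.Symbol, order: int) -> sp.Symbol:
    if order == 0:
        return input_sym
    return sp.Symbol(f"{input_sym}_d{order}", real=True)


def _is_rational_expr(expr: sp.Expr) -> bool:
    """True when the expression is rational with rational coefficients."""
    for node in sp.preorder_traversal(expr):
        if isinstance(node, sp.Float):
            return False
        if isinstance(node, sp.Pow) and not node.exp.is_Integer:
            return False
        if isinstance(node, sp.Function):
            return False
    return True


def extended_lie_derivative(
    exprs: Sequence[sp.Expr],
    config: ModelConfiguration,
    current_level: int | None = None,
    policy: SpecializationPolicy | None = None,
) -> list[sp.Expr]:
    """One step of the extended Lie derivative along the augmented dynamics.

    For each expression ``v`` returns ``dv/dx~ . f~ + sum_j dv/du^(j) .
    u^(j+1)`` where ``x~`` is the augmented state (parameters have zero
    dynamics, so their terms vanish) and ``u^(j)`` are the retained input
    derivative symbols.  The input sum is truncated at the highest derivative
    order actually present in ``v`` plus one; in constant-input mode it is
    dropped entirely.
    """
    policy = policy or SpecializationPolicy()
    f_aug = config.aug_dynamics
    x_aug = config.aug_symbols
    allowed = set(x_aug) | set(config.model.inputs)
    out: list[sp.Expr] = []
    for expr in exprs:
        expr = sp.sympify(expr)
        free = expr.free_symbols
        chain_syms = {
            s for s in free if str(s).rpartition("_d")[0] in config.model.input_names
        }
        stray = free - allowed - chain_syms
        if stray:
            raise ConfigurationError(
                f"expression references symbols outside the augmented state "
                f"and input chain: {sorted(map(str, stray))}"
            )
        d = sp.Integer(0)
        for x_i, f_i in zip(x_aug, f_aug):
            if f_i == 0 or x_i not in free:
                continue
            d = d + sp.diff(expr, x_i) * f_i
        if policy.input_mode == "generic":
            for u in config.model.inputs:
                order = 0
                while _chain_symbol(u, order) in free:
                    s_j = _chain_symbol(u, order)
                    d = d + sp.diff(expr, s_j) * _chain_symbol(u, order + 1)
                    order += 1
                # orders can be skipped if the expression is independent of
                # some intermediate derivative; scan the remaining chain syms
                for s_j in sorted(chain_syms & free, key=str):
                    name, _, idx = str(s_j).rpartition("_d")
                    if name == str(u) and int(idx) > order:
                        d = d + sp.diff(expr, s_j) * _chain_symbol(u, int(idx) + 1)
        out.append(d)
    return out


@dataclass
class OIMatrix:
    """Observability-identifiability matrix stacked level by level.

    ``blocks[i]`` is the Jacobian of the i-th extended Lie derivative of the
    measured outputs with respect to the augmented state; ``blocks[0]`` is
    exactly ``dh/dx~``.
    """

    config: ModelConfiguration
    blocks: list[sp.Matrix]
    column_symbols: tuple[sp.Symbol, ...]
    input_chain_symbols: tuple[sp.Symbol, ...]
    ranks_by_level: list[int] = field(default_factory=list)
    policy: SpecializationPolicy = field(default_factory=SpecializationPolicy)
    total_levels: int = 0
    _evaluator: Any = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.total_levels == 0:
            self.total_levels = len(self.blocks)

    @property
    def derivative_levels(self) -> int:
        """Derivative levels represented, counting the numeric continuation.

        ``blocks`` holds the symbolically assembled levels; for deep
        matrices the remaining levels are carried numerically (Taylor-jet
        rows at the specialization points) and counted here.
        """
        return self.total_levels

    @property
    def symbolic_levels(self) -> int:
        return len(self.blocks)

    @property
    def column_labels(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.column_symbols)

    @property
    def n_rows(self) -> int:
        return len(self.config.output_exprs) * self.total_levels

    @property
    def n_cols(self) -> int:
        return len(self.column_symbols)

    def stacked(self) -> sp.Matrix:
        """The symbolically assembled part, stacked level by level."""
        return sp.Matrix.vstack(*self.blocks)

    def free_symbols(self) -> set[sp.Symbol]:
        out: set[sp.Symbol] = set()
        for b in self.blocks:
            out |= b.free_symbols
        return out


class _RankEvaluator:
    """Specializes a symbolic matrix at random admissible points.

    Caches the numeric matrix per draw so that rank-after-column-deletion
    queries reuse the same evaluation points as the full-rank query.
    """

    def __init__(
        self,
        config: ModelConfiguration | None,
        symbols: Sequence[sp.Symbol],
        policy: SpecializationPolicy,
    ) -> None:
        self.policy = policy
        self.symbols = tuple(symbols)
        self.config = config
        self._rng = random.Random(policy.seed)
        self._constraints = self._active_constraints()
        self.points = [self._draw_point() for _ in range(policy.draws)]
        # numeric rows per draw, grown lazily block by block
        self._numeric: list[list[list[Any]]] = [[] for _ in self.points]
        # "exact": requested; "auto-exact": provisional, demoted to "float"
        # as soon as a non-rational block appears
        self._mode = {
            "exact": "exact", "auto": "auto-exact", "float": "float"
        }[policy.arithmetic]
        self.taylor_levels = 0

    def _active_constraints(self) -> list[sp.Basic]:
        if self.config is None:
            return []
        subs = {
            self.config.model.symbol(k): v
            for k, v in self.config.known_values.items()
        }
        symset = set(self.symbols)
        out = []
        for rel in self.config.model.constraints:
            rel = rel.xreplace(subs)
            if rel.free_symbols and rel.free_symbols <= symset:
                out.append(rel)
        return out

    def _draw_point(self) -> dict[sp.Symbol, sp.Rational]:
        lo, hi = self.policy.value_domain
        for _ in range(self.policy.max_retries):
            point = {
                s: sp.Rational(self._rng.randint(lo, hi), self._rng.randint(lo, hi))
                for s in self.symbols
            }
            ok = True
            for rel in self._constraints:
                val = rel.xreplace(point)
                if val is sp.false or val == False:  # noqa: E712
                    ok = False
                    break
            if ok:
                return point
        names = [str(c) for c in self._constraints]
        raise EvaluationError(
            f"could not draw an admissible specialization point satisfying "
            f"constraints {names} after {self.policy.max_retries} attempts"
        )

    def add_block(self, block: sp.Matrix) -> None:
        """Specialize one Jacobian block at every draw point."""
        entries = list(block)
        if self._mode != "float" and not all(
            _is_rational_expr(e) for e in entries
        ):
            if self._mode == "exact" and self.policy.arithmetic == "exact":
                raise EvaluationError(
                    "exact arithmetic requested but the matrix is not "
                    "rational; use arithmetic='float' or 'auto'"
                )
            self._demote_to_float()
        if self._mode in ("exact", "auto-exact"):
            for point, rows in zip(self.points, self._numeric):
                num = [e.xreplace(point) for e in entries]
                rows.extend(
                    num[i * block.cols : (i + 1) * block.cols]
                    for i in range(block.rows)
                )
            return
        fns = sp.lambdify(list(self.symbols), entries, modules="mpmath")
        with mpmath.workdps(self.policy.dps):
            for point, rows in zip(self.points, self._numeric):
                vals = [
                    mpmath.mpf(point[s].p) / mpmath.mpf(point[s].q)
                    for s in self.symbols
                ]
                num = fns(*vals)
                rows.extend(
                    num[i * block.cols : (i + 1) * block.cols]
                    for i in range(block.rows)
                )

    def set_taylor_levels(self, levels: int) -> None:
        """Replace all stored rows by Taylor-jet rows for ``levels`` levels.

        Used when deep symbolic Jacobians become too large: the same matrix
        entries are recomputed at the same specialization points from the
        Taylor coefficients of the outputs along the flow.
        """
        if self.config is None:
            raise EvaluationError("Taylor evaluation requires a configuration")
        self._numeric = taylor_oi_rows(
            self.config,
            self.points,
            levels,
            self.policy.dps,
            input_mode=self.policy.input_mode,
            chain_symbol=_chain_symbol,
        )
        self._mode = "float"
        self.taylor_levels = levels

    def trim_rows(self, n_rows: int) -> None:
        self._numeric = [rows[:n_rows] for rows in self._numeric]

    def _demote_to_float(self) -> None:
        """Convert any stored exact rows to the floating representation."""
        with mpmath.workdps(self.policy.dps):
            for rows in self._numeric:
                for i, row in enumerate(rows):
                    rows[i] = [
                        mpmath.mpf(v.p) / mpmath.mpf(v.q)
                        if isinstance(v, sp.Rational)
                        else mpmath.mpf(str(v))
                        for v in row
                    ]
        self._mode = "float"

    def rank(
        self, drop_column: int | None = None, max_rows: int | None = None
    ) -> int:
        """Maximum rank over draws, optionally with one column deleted."""
        best = 0
        for rows in self._numeric:
            if not rows:
                continue
            r = self._rank_one(rows, drop_column, max_rows)
            best = max(best, r)
        return best

    def ranks_per_draw(self, drop_column: int | None = None) -> list[int]:
        return [
            self._rank_one(rows, drop_column, None) if rows else 0
            for rows in self._numeric
        ]

    def _rank_one(
        self,
        rows: list[list[Any]],
        drop_column: int | None,
        max_rows: int | None = None,
    ) -> int:
        if max_rows is not None:
            rows = rows[:max_rows]
        if drop_column is None:
            data = rows
        else:
            data = [r[:drop_column] + r[drop_column + 1 :] for r in rows]
        if not data or not data[0]:
            return 0
        if isinstance(data[0][0], sp.Basic):
            return sp.Matrix(data).rank()
        with mpmath.workdps(self.policy.dps):
            a = mpmath.matrix(data)
            sv = mpmath.mp.svd_r(a, compute_uv=False)
            smax = max(abs(s) for s in sv)
            if smax == 0:
                return 0
            tol = smax * max(a.rows, a.cols) * mpmath.mpf(10) ** (
                -(self.policy.dps - 12)
            )
            return sum(1 for s in sv if abs(s) > tol)

    @property
    def arithmetic_used(self) -> str:
        return "float" if self._mode == "float" else "exact"


def build_oi_matrix(
    config: ModelConfiguration,
    max_levels: int | None = None,
    stop_policy: str = "rank-plateau",
    policy: SpecializationPolicy | None = None,
    symbolic_ops_limit: int = 300,
) -> OIMatrix:
    """Stack Jacobians of extended Lie derivatives of the measured outputs.

    Under ``rank-plateau`` stopping, one more derivative level is added until
    the numeric rank fails to increase (or the theoretical sufficient depth
    ``n + q'`` derivative levels is reached); under ``fixed`` stopping
    exactly ``max_levels`` levels are stacked.  Level 0 is ``h`` itself, so
    level count L means derivative orders 0..L-1.

    Deep Lie derivatives of non-trivial models grow exponentially; once the
    running derivative exceeds ``symbolic_ops_limit`` operations, further
    levels are carried numerically (Taylor-jet rows at the specialization
    points) instead of symbolically.  The rank evidence is identical, only
    the symbolic ``blocks`` stop growing.
    """
    if stop_policy not in ("fixed", "rank-plateau"):
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    policy = policy or SpecializationPolicy()
    cap = config.n_aug
    if stop_policy == "fixed":
        if max_levels is None or max_levels < 1:
            raise ValueError("fixed stopping requires max_levels >= 1")
        cap = max_levels
    elif max_levels is not None:
        if max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        cap = min(cap, max_levels)
    cap = max(cap, 1)

    x_aug = config.aug_symbols
    m_out = len(config.output_exprs)
    current = list(config.output_exprs)
    blocks: list[sp.Matrix] = []
    ranks: list[int] = []
    evaluator: _RankEvaluator | None = None
    symbolic = True
    total_levels = 0

    universe = list(x_aug) + list(config.model.inputs) + [
        _chain_symbol(u, j)
        for u in config.model.inputs
        for j in range(1, cap + 3)
    ]
    for level in range(cap):
        total_levels = level + 1
        if symbolic:
            block = sp.Matrix(
                [[sp.diff(e, s) for s in x_aug] for e in current]
            )
            blocks.append(block)
        if stop_policy == "rank-plateau":
            if evaluator is None:
                evaluator = _RankEvaluator(config, universe, policy)
            if symbolic:
                evaluator.add_block(block)
                r = evaluator.rank()
            else:
                if evaluator.taylor_levels < cap:
                    # one batch for the full theoretical depth; per-level
                    # ranks then come from row prefixes
                    evaluator.set_taylor_levels(cap)
                r = evaluator.rank(max_rows=total_levels * m_out)
            ranks.append(r)
            if (level > 0 and r == ranks[-2]) or r == config.n_aug:
                break
        if level < cap - 1 and symbolic:
            if sum(sp.count_ops(e) for e in current) > symbolic_ops_limit:
                symbolic = False
                if stop_policy == "fixed":
                    if evaluator is None:
                        evaluator = _RankEvaluator(config, universe, policy)
                    evaluator.set_taylor_levels(cap)
                    total_levels = cap
                    break
            else:
                current = extended_lie_derivative(
                    current, config, level + 1, policy
                )
    if (
        evaluator is not None
        and evaluator.taylor_levels > total_levels
    ):
        evaluator.trim_rows(total_levels * m_out)
        evaluator.taylor_levels = total_levels
    chain = sorted(
        set().union(*(b.free_symbols for b in blocks)) - set(x_aug)
        - set(config.model.inputs),
        key=str,
    )
    return OIMatrix(
        config=config,
        blocks=blocks,
        column_symbols=x_aug,
        input_chain_symbols=tuple(config.model.inputs) + tuple(chain),
        ranks_by_level=ranks,
        policy=policy,
        total_levels=total_levels,
        _evaluator=evaluator,
    )


def _evaluator_for(matrix: OIMatrix, policy: SpecializationPolicy) -> _RankEvaluator:
    if matrix._evaluator is not None and policy == matrix.policy:
        return matrix._evaluator
    cfg = matrix.config
    universe = (
        list(matrix.column_symbols)
        + list(cfg.model.inputs)
        + [
            _chain_symbol(u, j)
            for u in cfg.model.inputs
            for j in range(1, matrix.total_levels + 3)
        ]
    )
    ev = _RankEvaluator(cfg, universe, policy)
    if matrix.total_levels > matrix.symbolic_levels:
        ev.set_taylor_levels(matrix.total_levels)
    else:
        for block in matrix.blocks:
            ev.add_block(block)
    return ev


def evaluate_rank(
    matrix: OIMatrix | sp.Matrix,
    policy: SpecializationPolicy | None = None,
    symbols: Sequence[sp.Symbol] | None = None,
) -> int:
    """Numeric rank of a (specialized) symbolic matrix, max over draws.

    Accepts either an :class:`OIMatrix` or a plain sympy matrix (in which
    case the free symbols are specialized without domain constraints).
    """
    policy = policy or SpecializationPolicy()
    if isinstance(matrix, OIMatrix):
        return _evaluator_for(matrix, policy).rank()
    if matrix.rows == 0 or matrix.cols == 0:
        raise ValueError("matrix must be non-empty")
    syms = tuple(symbols) if symbols is not None else tuple(
        sorted(matrix.free_symbols, key=str)
    )
    ev = _RankEvaluator(None, syms, policy)
    ev.add_block(sp.Matrix(matrix))
    return ev.rank()


@dataclass
class IdentifiabilityReport:
    """Rank evidence and per-symbol verdicts for one configuration.

    Verdicts are local: full rank of the observability-identifiability
    matrix at a generic point certifies local observability/identifiability.
    """

    configuration: dict[str, Any]
    rank: int
    full_dimension: int
    oic_satisfied: bool
    derivative_levels_used: int
    ranks_by_level: list[int]
    per_symbol: dict[str, str] | None = None
    arithmetic_used: str = "float"
    draws_used: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def unidentifiable_params(self) -> list[str]:
        if self.per_symbol is None:
            return []
        return [k for k, v in self.per_symbol.items() if v == "unidentifiable"]

    @property
    def identifiable_params(self) -> list[str]:
        if self.per_symbol is None:
            return []
        return [k for k, v in self.per_symbol.items() if v == "identifiable"]

    @property
    def unobservable_states(self) -> list[str]:
        if self.per_symbol is None:
            return []
        return [k for k, v in self.per_symbol.items() if v == "unobservable"]

    def to_dict(self) -> dict[str, Any]:
        return {
            "configuration": self.configuration,
            "rank": self.rank,
            "full_dimension": self.full_dimension,
            "oic_satisfied": self.oic_satisfied,
            "derivative_levels_used": self.derivative_levels_used,
            "ranks_by_level": self.ranks_by_level,
            "per_symbol": self.per_symbol,
            "unidentifiable_params": self.unidentifiable_params,
            "unobservable_states": self.unobservable_states,
            "arithmetic_used": self.arithmetic_used,
            "draws_used": self.draws_used,
            "flags": self.flags,
        }

    def to_json(self, **kw: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def check_oic(
    config: ModelConfiguration,
    policy: SpecializationPolicy | None = None,
    max_levels: int | None = None,
) -> IdentifiabilityReport:
    """Observability-identifiability condition: is the rank full?"""
    policy = policy or SpecializationPolicy()
    matrix = build_oi_matrix(config, max_levels=max_levels, policy=policy)
    ev = _evaluator_for(matrix, policy)
    rank, flags = _settled_rank(matrix, ev, policy)
    return IdentifiabilityReport(
        configuration=config.describe(),
        rank=rank,
        full_dimension=config.n_aug,
        oic_satisfied=rank == config.n_aug,
        derivative_levels_used=matrix.derivative_levels,
        ranks_by_level=matrix.ranks_by_level,
        arithmetic_used=ev.arithmetic_used,
        draws_used=policy.draws,
        flags=flags,
    )


def _settled_rank(
    matrix: OIMatrix,
    ev: _RankEvaluator,
    policy: SpecializationPolicy,
) -> tuple[int, list[str]]:
    """Max-over-draws rank with one escalation pass on borderline results."""
    per_draw = ev.ranks_per_draw()
    flags: list[str] = []
    if len(set(per_draw)) > 1:
        flags.append(f"rank varied across draws {per_draw}; escalated")
        ev2 = _evaluator_for(matrix, policy.escalated())
        per_draw = per_draw + ev2.ranks_per_draw()
        if len(set(per_draw)) > 1:
            flags.append(
                f"rank still inconsistent after escalation {per_draw}; "
                "reporting the larger value"
            )
    return max(per_draw), flags


def classify_symbols(
    config: ModelConfiguration,
    policy: SpecializationPolicy | None = None,
    max_levels: int | None = None,
) -> IdentifiabilityReport:
    """Per-symbol verdicts by the column-deletion criterion.

    Each column of the plateaued matrix is deleted in turn and the rank is
    recomputed at the same specialization points: an unchanged rank means the
    corresponding parameter is structurally unidentifiable (state
    unobservable); a rank drop of one means identifiable (observable).
    """
    policy = policy or SpecializationPolicy()
    matrix = build_oi_matrix(config, max_levels=max_levels, policy=policy)
    ev = _evaluator_for(matrix, policy)
    rank, flags = _settled_rank(matrix, ev, policy)
    if len(set(ev.ranks_per_draw())) > 1:
        ev = _evaluator_for(matrix, policy.escalated())

    n_states = config.model.n_states
    per_symbol: dict[str, str] = {}
    for j, name in enumerate(matrix.column_labels):
        is_state = j < n_states
        if rank == config.n_aug:
            # full rank: every column deletion necessarily drops the rank
            per_symbol[name] = "observable" if is_state else "identifiable"
            continue
        r_j = ev.rank(drop_column=j)
        if r_j == rank:
            per_symbol[name] = "unobservable" if is_state else "unidentifiable"
        else:
            per_symbol[name] = "observable" if is_state else "identifiable"
    return IdentifiabilityReport(
        configuration=config.describe(),
        rank=rank,
        full_dimension=config.n_aug,
        oic_satisfied=rank == config.n_aug,
        derivative_levels_used=matrix.derivative_levels,
        ranks_by_level=matrix.ranks_by_level,
        per_symbol=per_symbol,
        arithmetic_used=ev.arithmetic_used,
        draws_used=policy.draws,
        flags=flags,
    )


@dataclass
class SweepReport:
    """Grid of per-configuration identifiability results.

    Rows are measured-output subsets, columns are unknown-parameter
    scenarios; each cell records the structurally unidentifiable parameter
    set (empty shown as ``-`` in rendered tables).
    """

    model_name: str
    output_subsets: list[tuple[str, ...]]
    unknown_scenarios: list[tuple[str, ...]]
    cells: dict[tuple[tuple[str, ...], tuple[str, ...]], IdentifiabilityReport | str]

    @property
    def n_configurations(self) -> int:
        return len(self.cells)

    @staticmethod
    def _key(items: Iterable[str]) -> str:
        return ", ".join(items)

    def cell(self, outputs: Sequence[str], unknown: Sequence[str]):
        return self.cells[(tuple(outputs), tuple(unknown))]

    def unidentifiable_sets(self) -> dict[str, dict[str, list[str] | None]]:
        """Nested mapping row-label -> column-label -> unidentifiable set."""
        table: dict[str, dict[str, list[str] | None]] = {}
        for subset in self.output_subsets:
            row: dict[str, list[str] | None] = {}
            for scen in self.unknown_scenarios:
                res = self.cells[(subset, scen)]
                row[self._key(scen)] = (
                    sorted(res.unidentifiable_params)
                    if isinstance(res, IdentifiabilityReport)
                    else None
                )
            table[self._key(subset)] = row
        return table

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": self.model_name,
            "n_configurations": self.n_configurations,
            "output_subsets": [list(s) for s in self.output_subsets],
            "unknown_scenarios": [list(s) for s in self.unknown_scenarios],
            "unidentifiable": self.unidentifiable_sets(),
            "cells": [
                {
                    "measured": list(subset),
                    "unknown": list(scen),
                    "result": (
                        res.to_dict()
                        if isinstance(res, IdentifiabilityReport)
                        else {"error": res}
                    ),
                }
                for (subset, scen), res in self.cells.items()
            ],
        }

    def to_json(self, **kw: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_markdown(self) -> str:
        cols = [self._key(s) for s in self.unknown_scenarios]
        lines = ["| Measured outputs | " + " | ".join(f"{{{c}}}" for c in cols) + " |"]
        lines.append("|" + "---|" * (len(cols) + 1))
        table = self.unidentifiable_sets()
        for subset in self.output_subsets:
            row = table[self._key(subset)]
            rendered = []
            for c in cols:
                val = row[c]
                if val is None:
                    rendered.append("ERROR")
                elif not val:
                    rendered.append("-")
                else:
                    rendered.append("{" + ", ".join(val) + "}")
            lines.append(
                "| " + self._key(subset) + " | " + " | ".join(rendered) + " |"
            )
        return "\n".join(lines) + "\n"

    def to_dataframe(self):
        import pandas as pd

        table = self.unidentifiable_sets()
        cols = [self._key(s) for s in self.unknown_scenarios]
        data = {
            self._key(subset): [
                "-"
                if table[self._key(subset)][c] == []
                else (
                    "ERROR"
                    if table[self._key(subset)][c] is None
                    else "{" + ", ".join(table[self._key(subset)][c]) + "}"
                )
                for c in cols
            ]
            for subset in self.output_subsets
        }
        return pd.DataFrame.from_dict(
            data, orient="index", columns=cols
        ).rename_axis("measured outputs")


def sweep_configurations(
    model: OdeModel,
    output_subsets: Sequence[Sequence[str]],
    unknown_scenarios: Sequence[Sequence[str]],
    policy: SpecializationPolicy | None = None,
    known_values: Mapping[str, Any] | None = None,
) -> SweepReport:
    """Classify every (output subset, unknown-parameter scenario) pair.

    Ordering is deterministic: output subsets outer, scenarios inner.  A
    per-cell failure is recorded in place without aborting the sweep.
    """
    if not output_subsets or not unknown_scenarios:
        raise ConfigurationError("output subsets and scenarios must be non-empty")
    policy = policy or SpecializationPolicy()
    subsets = [tuple(str(o) for o in s) for s in output_subsets]
    scenarios = [tuple(str(p) for p in s) for s in unknown_scenarios]
    cells: dict[
        tuple[tuple[str, ...], tuple[str, ...]], IdentifiabilityReport | str
    ] = {}
    for subset in subsets:
        for scen in scenarios:
            try:
                cfg = model.configure(subset, scen, known_values)
                cells[(subset, scen)] = classify_symbols(cfg, policy)
            except Exception as err:  # recorded in place, sweep continues
                cells[(subset, scen)] = f"{type(err).__name__}: {err}"
    return SweepReport(
        model_name=model.name,
        output_subsets=subsets,
        unknown_scenarios=scenarios,
        cells=cells,
    )
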