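"""Truncated Taylor-series (jet) arithmetic for numeric Lie derivatives.

The i-th extended Lie derivative of an output ``h`` along ``f`` equals the
i-th time derivative of ``y(t) = h(x(t))`` along the flow of
``dx/dt = f(x, u(t))`` when the input is the polynomial
``u(t) = sum_j u^(j) t^j / j!`` built from the retained input-derivative
values.  Propagating truncated Taylor series through ``f`` therefore yields
all Lie-derivative values at a point in polynomial time, avoiding the
exponential swell of deep symbolic differentiation.  Entries of the
observability-identifiability matrix are obtained by complex-step
directional differentiation of those values, which is free of subtractive
cancellation.
"""

from __future__ import annotations

import math
from typing import Any, Callable, Mapping, Sequence

import mpmath
import sympy as sp

__all__ = ["Jet", "taylor_oi_rows"]


class Jet:
    """Truncated Taylor series with mpmath coefficients.

    ``c[k]`` is the coefficient of ``t^k``; all operations truncate at the
    jet's fixed order.  Coefficients may be ``mpf`` or ``mpc`` (the latter
    during complex-step differentiation).
    """

    __slots__ = ("c",)

    def __init__(self, coeffs: Sequence[Any]):
        self.c = list(coeffs)

    @classmethod
    def constant(cls, value, order: int) -> "Jet":
        c = [mpmath.mpf(0)] * (order + 1)
        c[0] = value
        return cls(c)

    @property
    def order(self) -> int:
        return len(self.c) - 1

    # -- ring operations ----------------------------------------------------
    def _coerce(self, other) -> "Jet | None":
        if isinstance(other, Jet):
            return other
        if isinstance(other, (int, float, mpmath.mpf, mpmath.mpc)):
            return Jet.constant(mpmath.mpmathify(other), self.order)
        return None

    def __add__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        return Jet([a + b for a, b in zip(self.c, o.c)])

    __radd__ = __add__

    def __neg__(self):
        return Jet([-a for a in self.c])

    def __sub__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        return Jet([a - b for a, b in zip(self.c, o.c)])

    def __rsub__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        return Jet([b - a for a, b in zip(self.c, o.c)])

    def __mul__(self, other):
        if isinstance(other, (int, float, mpmath.mpf, mpmath.mpc)):
            return Jet([a * other for a in self.c])
        if not isinstance(other, Jet):
            return NotImplemented
        K = self.order
        out = [mpmath.mpf(0)] * (K + 1)
        for i, a in enumerate(self.c):
            if a == 0:
                continue
            for j in range(K + 1 - i):
                b = other.c[j]
                if b != 0:
                    out[i + j] += a * b
        return Jet(out)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float, mpmath.mpf, mpmath.mpc)):
            return Jet([a / other for a in self.c])
        if not isinstance(other, Jet):
            return NotImplemented
        K = self.order
        b0 = other.c[0]
        out = [mpmath.mpf(0)] * (K + 1)
        for k in range(K + 1):
            s = self.c[k]
            for j in range(k):
                s -= out[j] * other.c[k - j]
            out[k] = s / b0
        return Jet(out)

    def __rtruediv__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        return o.__truediv__(self)

    def __pow__(self, a):
        if isinstance(a, Jet):
            # general series exponent: u^v = exp(v*log(u))
            return (a * self.log()).exp()
        a = mpmath.mpmathify(a)
        K = self.order
        u0 = self.c[0]
        out = [mpmath.mpf(0)] * (K + 1)
        out[0] = u0**a
        for k in range(1, K + 1):
            s = mpmath.mpf(0)
            for j in range(1, k + 1):
                s += (a * j - (k - j)) * self.c[j] * out[k - j]
            out[k] = s / (k * u0)
        return Jet(out)

    def __rpow__(self, base):
        # base**jet = exp(jet * log(base))
        return (self * mpmath.log(mpmath.mpmathify(base))).exp()

    # -- elementary functions (standard Taylor recurrences) ------------------
    def exp(self) -> "Jet":
        K = self.order
        out = [mpmath.mpf(0)] * (K + 1)
        out[0] = mpmath.exp(self.c[0])
        for k in range(1, K + 1):
            s = mpmath.mpf(0)
            for j in range(1, k + 1):
                s += j * self.c[j] * out[k - j]
            out[k] = s / k
        return Jet(out)

    def log(self) -> "Jet":
        K = self.order
        u0 = self.c[0]
        out = [mpmath.mpf(0)] * (K + 1)
        out[0] = mpmath.log(u0)
        for k in range(1, K + 1):
            s = self.c[k]
            for j in range(1, k):
                s -= (mpmath.mpf(j) / k) * out[j] * self.c[k - j]
            out[k] = s / u0
        return Jet(out)

    def sqrt(self) -> "Jet":
        return self.__pow__(mpmath.mpf(1) / 2)

    def _sincos(self) -> tuple["Jet", "Jet"]:
        K = self.order
        s = [mpmath.mpf(0)] * (K + 1)
        co = [mpmath.mpf(0)] * (K + 1)
        s[0] = mpmath.sin(self.c[0])
        co[0] = mpmath.cos(self.c[0])
        for k in range(1, K + 1):
            a = mpmath.mpf(0)
            b = mpmath.mpf(0)
            for j in range(1, k + 1):
                a += j * self.c[j] * co[k - j]
                b += j * self.c[j] * s[k - j]
            s[k] = a / k
            co[k] = -b / k
        return Jet(s), Jet(co)

    def sin(self) -> "Jet":
        return self._sincos()[0]

    def cos(self) -> "Jet":
        return self._sincos()[1]

    def tan(self) -> "Jet":
        s, c = self._sincos()
        return s / c

    def tanh(self) -> "Jet":
        e2 = (self * 2).exp()
        return (e2 - 1) / (e2 + 1)


def _fn(name: str) -> Callable:
    def wrapper(x, _name=name):
        if isinstance(x, Jet):
            return getattr(x, _name)()
        return getattr(mpmath, _name)(x)

    return wrapper


_JET_NAMESPACE = {
    n: _fn(n) for n in ("exp", "log", "sqrt", "sin", "cos", "tan", "tanh")
}
_JET_NAMESPACE["Abs"] = lambda x: abs(x)
_JET_NAMESPACE["pi"] = mpmath.pi


def _lambdify_jet(args, exprs):
    return sp.lambdify(args, exprs, modules=[_JET_NAMESPACE, "mpmath"])


def taylor_oi_rows(
    config,
    points: Sequence[Mapping[sp.Symbol, sp.Rational]],
    levels: int,
    dps: int,
    input_mode: str = "generic",
    chain_symbol=None,
) -> list[list[list[Any]]]:
    """Rows of the observability-identifiability matrix at several points.

    For each point returns ``levels * m`` rows (level-major, outputs within
    a level) with ``n + q'`` columns, computed by complex-step
    differentiation of the Taylor coefficients of the outputs along the
    flow.  Each point must assign values to every augmented state, input
    and retained input-derivative symbol.
    """
    model = config.model
    x_aug = config.aug_symbols
    n_states = model.n_states
    n_aug = config.n_aug
    K = levels - 1  # highest Taylor order needed

    f_exprs = list(config.aug_dynamics[:n_states])
    h_exprs = list(config.output_exprs)
    args = list(x_aug) + list(model.inputs)
    f_num = _lambdify_jet(args, f_exprs)
    h_num = _lambdify_jet(args, h_exprs)
    m = len(h_exprs)

    out: list[list[list[Any]]] = []
    with mpmath.workdps(dps):
        delta = mpmath.mpf(10) ** (-max(dps // 2, 12))
        for point in points:
            base_vals = [
                mpmath.mpf(point[s].p) / mpmath.mpf(point[s].q) for s in x_aug
            ]
            # input Taylor coefficients u^(j)/j! from the chain symbol values
            u_jets = []
            for u in model.inputs:
                c = [mpmath.mpf(0)] * (K + 2)
                pu = point.get(u)
                c[0] = (
                    mpmath.mpf(pu.p) / mpmath.mpf(pu.q)
                    if pu is not None
                    else mpmath.mpf(0)
                )
                if input_mode == "generic" and chain_symbol is not None:
                    for j in range(1, K + 2):
                        ps = point.get(chain_symbol(u, j))
                        if ps is not None:
                            c[j] = (
                                mpmath.mpf(ps.p) / mpmath.mpf(ps.q)
                            ) / mpmath.factorial(j)
                u_jets.append(Jet(c))

            rows: list[list[Any]] = [[None] * n_aug for _ in range(levels * m)]
            for col in range(n_aug):
                vals = [mpmath.mpc(v) for v in base_vals]
                vals[col] = vals[col] + mpmath.mpc(0, 1) * delta
                # propagate state jets; parameters stay constant scalars
                xj = [Jet.constant(vals[i], K + 1) for i in range(n_states)]
                pj = list(vals[n_states:])
                for k in range(K + 1):
                    fv = f_num(*xj, *pj, *u_jets)
                    for i in range(n_states):
                        fi = fv[i]
                        coeff = fi.c[k] if isinstance(fi, Jet) else (
                            fi if k == 0 else mpmath.mpf(0)
                        )
                        xj[i].c[k + 1] = coeff / (k + 1)
                hv = h_num(*xj, *pj, *u_jets)
                for out_i in range(m):
                    hi = hv[out_i]
                    for lev in range(levels):
                        if isinstance(hi, Jet):
                            value = hi.c[lev] * mpmath.factorial(lev)
                        else:
                            value = hi if lev == 0 else mpmath.mpf(0)
                        rows[lev * m + out_i][col] = (
                            value.imag / delta
                            if isinstance(value, mpmath.mpc)
                            else mpmath.mpf(0)
                        )
            out.append(rows)
    return out
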