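"""Catalog of bundled circuit models.

Four physiological feedback circuits (two linear exact-adaptation circuits,
a nonlinear hormonal circuit and the glucose homeostasis ``betaIG`` model)
plus two toy systems, all shipped in the declarative YAML model format with
default parameter values and provenance notes.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import sympy as sp

from ..model import OdeModel, define_model, load_model

__all__ = [
    "CATALOG",
    "CatalogError",
    "load_circuit",
    "list_circuits",
    "catalog_manifest",
    "lti_model",
    "random_lti_model",
]

CATALOG = (
    "linear_integral",
    "linear_PI",
    "hormone_nonlinear",
    "betaIG",
    "toy_product",
    "toy_LTI",
)


class CatalogError(KeyError):
    """Unknown circuit name."""


def _data_path(name: str):
    return resources.files(__package__) / "data" / f"{name}.yaml"


def load_circuit(name: str) -> OdeModel:
    """Load a bundled circuit by name, with its default parameter values."""
    if name not in CATALOG:
        raise CatalogError(
            f"unknown circuit {name!r}; available: {', '.join(CATALOG)}"
        )
    with resources.as_file(_data_path(name)) as path:
        return load_model(path)


def list_circuits() -> tuple[str, ...]:
    return CATALOG


def catalog_manifest() -> dict[str, dict[str, str]]:
    """Name -> {description, provenance} for every catalog entry."""
    out = {}
    for name in CATALOG:
        m = load_circuit(name)
        out[name] = {"description": m.description, "provenance": m.provenance}
    return out


def lti_model(A, B, C, name: str = "lti") -> OdeModel:
    """Build an LTI model dx/dt = Ax + Bu, y = Cx from numeric matrices.

    Entries are taken as exact rationals, so the identifiability engine can
    analyse the result in exact arithmetic.
    """
    A = sp.Matrix([[sp.Rational(str(v)) for v in row] for row in np.atleast_2d(A)])
    n = A.rows
    B = sp.Matrix([[sp.Rational(str(v)) for v in row] for row in np.atleast_2d(B)])
    C = sp.Matrix([[sp.Rational(str(v)) for v in row] for row in np.atleast_2d(C)])
    states = [f"x{i + 1}" for i in range(n)]
    inputs = [f"v{j + 1}" for j in range(B.cols)] if B.cols else []
    xs = sp.Matrix([sp.Symbol(s, real=True) for s in states])
    us = sp.Matrix([sp.Symbol(s, real=True) for s in inputs]) if inputs else None
    fx = A * xs + (B * us if us is not None else sp.zeros(n, 1))
    hx = C * xs
    spec = {
        "name": name,
        "states": states,
        "params": [],
        "inputs": inputs,
        "dynamics": {s: sp.sstr(fx[i]).replace("**", "^") for i, s in enumerate(states)},
        "observables": {
            f"y{i + 1}": sp.sstr(hx[i]).replace("**", "^") for i in range(C.rows)
        },
    }
    return define_model(spec)


def random_lti_model(rng: np.random.Generator, n_max: int = 4) -> tuple[OdeModel, np.ndarray, np.ndarray]:
    """Random small integer LTI system; returns (model, A, C) for oracles."""
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(1, 3))
    r = int(rng.integers(0, 2))
    A = rng.integers(-3, 4, size=(n, n))
    C = rng.integers(-2, 3, size=(m, n))
    B = rng.integers(-2, 3, size=(n, max(r, 1)))
    if r == 0:
        B = np.zeros((n, 0), dtype=int)
    return lti_model(A, B, C, name="random_lti"), A, C
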