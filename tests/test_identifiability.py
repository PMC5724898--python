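"""Lie-derivative matrix construction, rank evaluation and classification."""

import numpy as np
import pytest
import sympy as sp

import strident as st
from strident.fixtures import lti_model, random_lti_model
from strident.identifiability import EvaluationError, SpecializationPolicy


def _model(spec):
    return st.define_model(spec)


class TestExtendedLieDerivative:
    def test_linear_decay(self):
        m = _model({"states": ["w"], "dynamics": {"w": "-w"}})
        cfg = m.configure(["w"])
        (d,) = st.extended_lie_derivative(list(cfg.output_exprs), cfg)
        assert d == -m.symbol("w")

    def test_harmonic_pair(self):
        m = _model(
            {"states": ["x1", "x2"], "dynamics": {"x1": "x2", "x2": "-x1"}}
        )
        cfg = m.configure(["x1"])
        first = st.extended_lie_derivative(list(cfg.output_exprs), cfg)
        second = st.extended_lie_derivative(first, cfg)
        assert first == [m.symbol("x2")]
        assert second == [-m.symbol("x1")]

    def test_input_derivative_chain(self):
        """d/dt propagates input derivatives: the second extended Lie
        derivative of w along -p*w + v is p^2*w - p*v + v'."""
        m = _model(
            {
                "states": ["w"],
                "params": ["p"],
                "inputs": ["v"],
                "dynamics": {"w": "-p*w + v"},
            }
        )
        cfg = m.configure(["w"], ["p"])
        w, p, v = (m.symbol(n) for n in ("w", "p", "v"))
        v1 = sp.Symbol("v_d1", real=True)
        first = st.extended_lie_derivative(list(cfg.output_exprs), cfg)
        assert sp.expand(first[0] - (-p * w + v)) == 0
        second = st.extended_lie_derivative(first, cfg)
        assert sp.expand(second[0] - (p**2 * w - p * v + v1)) == 0

    def test_constant_input_mode_drops_chain(self):
        m = _model(
            {
                "states": ["w"],
                "params": ["p"],
                "inputs": ["v"],
                "dynamics": {"w": "-p*w + v"},
            }
        )
        cfg = m.configure(["w"], ["p"])
        policy = SpecializationPolicy(input_mode="constant")
        first = st.extended_lie_derivative(list(cfg.output_exprs), cfg, policy=policy)
        second = st.extended_lie_derivative(first, cfg, policy=policy)
        assert not any(str(s).startswith("v_d") for s in second[0].free_symbols)

    def test_stray_symbol_rejected(self):
        m = _model({"states": ["w"], "dynamics": {"w": "-w"}})
        cfg = m.configure(["w"])
        with pytest.raises(st.ConfigurationError, match="outside"):
            st.extended_lie_derivative([sp.Symbol("zzz")], cfg)


class TestOIMatrix:
    def test_level_one_is_output_jacobian(self, betaIG):
        cfg = betaIG.configure(["G", "I"], ["si"])
        mat = st.build_oi_matrix(cfg, max_levels=1, stop_policy="fixed")
        assert mat.derivative_levels == 1
        expected = sp.Matrix(
            [[sp.diff(h, s) for s in cfg.aug_symbols] for h in cfg.output_exprs]
        )
        assert mat.stacked() == expected

    def test_toy_product_rows(self, toy_product):
        cfg = toy_product.configure(["w"], ["p1", "p2"])
        mat = st.build_oi_matrix(cfg, max_levels=2, stop_policy="fixed")
        w, p1, p2 = cfg.aug_symbols
        assert list(mat.blocks[0]) == [1, 0, 0]
        row1 = mat.blocks[1]
        assert sp.expand(row1[0] + p1 * p2) == 0
        assert sp.expand(row1[1] + p2 * w) == 0
        assert sp.expand(row1[2] + p1 * w) == 0

    def test_row_and_column_counts(self, hormone):
        cfg = hormone.configure(["x"], ["p", "s"])
        mat = st.build_oi_matrix(cfg, max_levels=3, stop_policy="fixed")
        assert mat.n_rows == 3 * 1
        assert mat.n_cols == cfg.n_aug == 5

    def test_max_levels_validation(self, toy_product):
        cfg = toy_product.configure(["w"], [])
        with pytest.raises(ValueError):
            st.build_oi_matrix(cfg, max_levels=0, stop_policy="fixed")


class TestEvaluateRank:
    def test_identity_matrix(self):
        assert st.evaluate_rank(sp.eye(3)) == 3

    def test_outer_product_rank_one(self):
        a = sp.Matrix(sp.symbols("a1:4", real=True))
        b = sp.Matrix(sp.symbols("b1:4", real=True))
        assert st.evaluate_rank(a * b.T) == 1

    def test_toy_product_rank_two_any_depth(self, toy_product):
        cfg = toy_product.configure(["w"], ["p1", "p2"])
        for levels in (2, 3, 4):
            mat = st.build_oi_matrix(cfg, max_levels=levels, stop_policy="fixed")
            assert st.evaluate_rank(mat) == 2

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            st.evaluate_rank(sp.Matrix(0, 0, []))

    def test_exact_arithmetic_refuses_non_rational(self, betaIG):
        cfg = betaIG.configure(["beta"], [])
        policy = SpecializationPolicy(arithmetic="exact")
        with pytest.raises(EvaluationError, match="not rational"):
            mat = st.build_oi_matrix(
                cfg, max_levels=2, stop_policy="fixed"
            )
            st.evaluate_rank(mat, policy)

    def test_float_and_auto_agree_on_non_rational(self, betaIG):
        cfg = betaIG.configure(["G"], ["si"])
        r_auto = st.check_oic(cfg).rank
        r_float = st.check_oic(cfg, SpecializationPolicy(arithmetic="float")).rank
        assert r_auto == r_float


class TestRankProperties:
    def test_rank_monotone_in_levels(self, hormone):
        cfg = hormone.configure(["x"], ["p", "s"])
        ranks = []
        for levels in range(1, 6):
            mat = st.build_oi_matrix(cfg, max_levels=levels, stop_policy="fixed")
            ranks.append(st.evaluate_rank(mat))
        assert ranks == sorted(ranks)
        assert ranks[-1] <= cfg.n_aug

    def test_plateau_respects_theoretical_cap(self, hormone):
        cfg = hormone.configure(["x"], ["p", "s"])
        mat = st.build_oi_matrix(cfg)
        assert mat.derivative_levels <= cfg.n_aug

    def test_determinism_same_seed(self, hormone):
        cfg = hormone.configure(["x"], ["p", "s"])
        r1 = st.classify_symbols(cfg, SpecializationPolicy(seed=7))
        r2 = st.classify_symbols(cfg, SpecializationPolicy(seed=7))
        assert r1.to_dict() == r2.to_dict()

    def test_verdict_stable_across_seeds(self, hormone):
        cfg = hormone.configure(["x"], ["p", "s"])
        verdicts = {
            tuple(sorted(st.classify_symbols(
                cfg, SpecializationPolicy(seed=s)
            ).unidentifiable_params))
            for s in (0, 1, 2)
        }
        assert verdicts == {("p", "s")}

    def test_lti_matches_kalman_observability(self):
        """The Lie-derivative matrix of an LTI system spans [C; CA; ...]."""
        rng = np.random.default_rng(1234)
        for _ in range(20):
            model, A, C = random_lti_model(rng)
            cfg = model.configure(model.output_names)
            n = A.shape[0]
            for levels in (1, n):
                mat = st.build_oi_matrix(
                    cfg, max_levels=levels, stop_policy="fixed"
                )
                kalman = np.vstack(
                    [C @ np.linalg.matrix_power(A, i) for i in range(levels)]
                )
                assert st.evaluate_rank(mat) == np.linalg.matrix_rank(kalman)

    def test_full_state_measurement_observable(self):
        rng = np.random.default_rng(5)
        A = rng.integers(-3, 4, size=(3, 3))
        model = lti_model(A, np.zeros((3, 0), dtype=int), np.eye(3, dtype=int))
        rep = st.classify_symbols(model.configure(model.output_names))
        assert rep.oic_satisfied
        assert set(rep.per_symbol.values()) == {"observable"}


class TestClassification:
    def test_hormone_column_deletion(self, hormone):
        rep = st.classify_symbols(hormone.configure(["x"], ["p", "s"]))
        assert rep.unidentifiable_params == ["p", "s"]
        assert rep.unobservable_states == ["y", "z"]
        assert rep.per_symbol["x"] == "observable"

    def test_deletion_count_bound(self, hormone):
        """Rank-preserving deletions are at least full_dim - rank."""
        rep = st.classify_symbols(hormone.configure(["x"], ["p", "s"]))
        n_preserving = len(rep.unidentifiable_params) + len(rep.unobservable_states)
        assert n_preserving >= rep.full_dimension - rep.rank

    def test_oic_report_consistency(self, hormone):
        cfg = hormone.configure(["x", "y", "z"], ["p", "s"])
        rep = st.check_oic(cfg)
        assert rep.oic_satisfied is (rep.rank == rep.full_dimension)
        assert rep.oic_satisfied  # full state measured pins both gains


class TestSweep:
    def test_degenerate_single_cell(self, toy_product):
        sweep = st.sweep_configurations(toy_product, [["w"]], [["p1", "p2"]])
        assert sweep.n_configurations == 1
        cell = sweep.cell(["w"], ["p1", "p2"])
        direct = st.classify_symbols(toy_product.configure(["w"], ["p1", "p2"]))
        assert cell.per_symbol == direct.per_symbol

    def test_cell_error_recorded_in_place(self, toy_product):
        sweep = st.sweep_configurations(
            toy_product, [["w"], ["nope"]], [["p1"]]
        )
        assert sweep.n_configurations == 2
        assert isinstance(sweep.cell(["nope"], ["p1"]), str)

    def test_markdown_rendering(self, toy_product):
        sweep = st.sweep_configurations(toy_product, [["w"]], [["p1", "p2"]])
        md = sweep.to_markdown()
        assert "{p1, p2}" in md
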