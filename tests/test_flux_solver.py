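"""BVLS flux solver: exactness, oracle equivalence, KKT, invariances."""

import numpy as np
import pandas as pd
import pytest

import chondroflux as cf
from chondroflux.flux_solver import kkt_violation

from .oracles import active_set_bvls


def two_metabolite_problem(reversible: bool, delta):
    lb = np.array([-np.inf if reversible else 0.0])
    return cf.FluxProblem(
        S=np.array([[-1.0], [1.0]]), delta=np.asarray(delta, float),
        weights=np.ones(2), lower_bounds=lb, upper_bounds=np.array([np.inf]),
        metabolite_ids=["A", "B"], reaction_ids=["R"],
    )


class TestSolveFlux:
    def test_consistent_reversible_system_exact(self):
        prof = cf.solve_flux(two_metabolite_problem(True, [-1.0, 1.0]))
        assert prof.v[0] == pytest.approx(1.0, abs=1e-10)
        assert prof.objective == pytest.approx(0.0, abs=1e-10)

    def test_irreversible_bound_active(self):
        prof = cf.solve_flux(two_metabolite_problem(False, [1.0, -1.0]))
        assert prof.v[0] == pytest.approx(0.0, abs=1e-12)
        assert prof.objective**2 == pytest.approx(2.0, rel=1e-9)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_active_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, n = 6, 4
        A = rng.normal(size=(m, n))
        b = rng.normal(size=m)
        w = rng.uniform(0.5, 2.0, size=m) if seed % 2 else np.ones(m)
        irr = rng.random(n) < 0.5
        lb = np.where(irr, 0.0, -np.inf)
        ub = np.full(n, np.inf)
        prob = cf.FluxProblem(S=A, delta=b, weights=w, lower_bounds=lb, upper_bounds=ub)
        prof = cf.solve_flux(prob)
        oracle_obj, _ = active_set_bvls(A * w[:, None], b * w, lb, ub)
        assert prof.objective == pytest.approx(oracle_obj, abs=1e-6)
        assert kkt_violation(prob, prof.v) <= 1e-8 * max(1.0, oracle_obj)

    def test_weight_scaling_leaves_argmin(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(6, 4))
        b = rng.normal(size=6)
        w = rng.uniform(0.5, 2.0, size=6)
        lb = np.array([0.0, 0.0, -np.inf, -np.inf])
        ub = np.full(4, np.inf)
        p1 = cf.solve_flux(cf.FluxProblem(S=A, delta=b, weights=w,
                                          lower_bounds=lb, upper_bounds=ub))
        p2 = cf.solve_flux(cf.FluxProblem(S=A, delta=b, weights=7.5 * w,
                                          lower_bounds=lb, upper_bounds=ub))
        np.testing.assert_allclose(p1.v, p2.v, atol=1e-8)
        assert p2.objective == pytest.approx(7.5 * p1.objective, rel=1e-8)

    def test_zero_vector_feasible_objective_bound(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(5, 3))
        b = rng.normal(size=5)
        prob = cf.FluxProblem(S=A, delta=b, weights=np.ones(5),
                              lower_bounds=np.zeros(3), upper_bounds=np.full(3, np.inf))
        prof = cf.solve_flux(prob)
        assert prof.objective <= np.linalg.norm(b) + 1e-12

    def test_noise_free_recovery_full_column_rank(self, reduced_net, protein_flux):
        S = reduced_net.S
        v_true = protein_flux
        delta = S @ v_true
        prob = cf.FluxProblem(
            S=S, delta=delta, weights=np.ones(S.shape[0]),
            lower_bounds=np.where(reduced_net.irreversible_mask, 0.0, -np.inf),
            upper_bounds=np.full(S.shape[1], np.inf))
        prof = cf.solve_flux(prob)
        assert np.linalg.norm(prof.v - v_true) <= 1e-6

    def test_repeat_runs_identical_under_full_rank(self, reduced_net, protein_flux):
        S = reduced_net.S
        delta = S @ protein_flux + 0.01
        prob = cf.FluxProblem(
            S=S, delta=delta, weights=np.ones(S.shape[0]),
            lower_bounds=np.where(reduced_net.irreversible_mask, 0.0, -np.inf),
            upper_bounds=np.full(S.shape[1], np.inf))
        v1, v2 = cf.solve_flux(prob).v, cf.solve_flux(prob).v
        np.testing.assert_allclose(v1, v2, atol=1e-8)


class TestAssembleProblem:
    def _acc(self, net, delta, var):
        df = pd.DataFrame({
            "delta": delta, "variance": var,
            "constrained_zero": [m.constrained_zero for m in net.metabolites],
            "lowest_weight": [m.lowest_weight for m in net.metabolites],
            "weight": np.nan,
        }, index=net.metabolite_ids)
        return cf.compute_weights(cf.AccumulationVector((0.0, 15.0), df))

    def test_unit_weights_leave_matrix(self, toy_chain):
        acc = self._acc(toy_chain, [1.0, 0.0, -1.0], [1.0, 1.0, 1.0])
        prob = cf.assemble_problem(toy_chain, acc)
        np.testing.assert_array_equal(prob.S_w, toy_chain.S)
        np.testing.assert_array_equal(prob.delta_w, acc.delta)

    def test_doubling_one_weight_scales_one_row(self, toy_chain):
        acc1 = self._acc(toy_chain, [1.0, 0.0, -1.0], [1.0, 1.0, 1.0])
        acc2 = self._acc(toy_chain, [1.0, 0.0, -1.0], [0.5, 1.0, 1.0])
        p1 = cf.assemble_problem(toy_chain, acc1)
        p2 = cf.assemble_problem(toy_chain, acc2)
        np.testing.assert_allclose(p2.S_w[0], 2.0 * p1.S_w[0])
        np.testing.assert_allclose(p2.delta_w[0], 2.0 * p1.delta_w[0])
        np.testing.assert_allclose(p2.S_w[1:], p1.S_w[1:])

    def test_paper_shaped_problem(self, simulated):
        table, _, net = simulated
        acc = cf.compute_weights(cf.estimate_accumulation(table, net, "compressed", 0, 15))
        prob = cf.assemble_problem(net, acc)
        assert prob.S.shape == (48, 39)
        assert (prob.delta[prob.equality_rows] == 0).all()
        # constrained rows get the median measured weight by default
        cz = acc.constrained_zero & ~acc.lowest_weight
        measured_w = acc.weight[~acc.constrained_zero]
        assert np.allclose(prob.weights[cz], np.median(measured_w))

    def test_hard_zero_rows_respected(self, simulated):
        table, _, net = simulated
        acc = cf.compute_weights(cf.estimate_accumulation(table, net, "compressed", 0, 15))
        prob = cf.assemble_problem(net, acc, hard_zero=True)
        assert len(prob.equality_rows) == int(acc.constrained_zero.sum())
        prof = cf.solve_flux(prob)
        assert np.max(np.abs(prob.S[prob.equality_rows] @ prof.v)) <= 1e-6

    def test_misaligned_rows_rejected(self, toy_chain, reduced_net):
        acc = self._acc(toy_chain, [1.0, 0.0, -1.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="align"):
            cf.assemble_problem(reduced_net, acc)


class TestResidualReport:
    def test_consistent_system_near_zero(self):
        prof = cf.solve_flux(two_metabolite_problem(True, [-1.0, 1.0]))
        rep = cf.residual_report(prof)
        assert (rep["residual_raw"].abs() <= 1e-8).all()

    def test_perturbed_row_dominates(self):
        rng = np.random.default_rng(7)
        m = 20  # strongly overdetermined so leverage cannot absorb the spike
        A = rng.normal(size=(m, 3))
        x = rng.normal(size=3)
        b = A @ x
        b[2] += 5.0  # single-row perturbation
        prob = cf.FluxProblem(S=A, delta=b, weights=np.ones(m),
                              lower_bounds=np.full(3, -np.inf),
                              upper_bounds=np.full(3, np.inf),
                              metabolite_ids=[f"M{i}" for i in range(m)])
        rep = cf.residual_report(cf.solve_flux(prob))
        assert rep.index[0] == "M2"

    def test_weighted_equals_weight_times_raw(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(5, 2))
        b = rng.normal(size=5)
        w = rng.uniform(0.5, 3.0, 5)
        prof = cf.solve_flux(cf.FluxProblem(
            S=A, delta=b, weights=w, lower_bounds=np.full(2, -np.inf),
            upper_bounds=np.full(2, np.inf)))
        np.testing.assert_allclose(prof.residuals_weighted, w * prof.residuals_raw)


class TestFluxBVLSEstimator:
    def test_sklearn_contract(self):
        from sklearn.utils.validation import check_is_fitted
        est = cf.FluxBVLS(lower_bounds=0.0)
        params = est.get_params()
        assert params["lower_bounds"] == 0.0
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(8, 3)), rng.normal(size=8)
        est.fit(X, y)
        check_is_fitted(est)
        assert est.flux_.shape == (3,)
        assert (est.flux_ >= 0).all()
        assert est.predict(X).shape == (8,)
        est2 = cf.FluxBVLS(**params).fit(X, y)
        np.testing.assert_allclose(est.flux_, est2.flux_)

    def test_objective_recomputable_from_coefficients(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(10, 4)), rng.normal(size=10)
        w = rng.uniform(0.5, 2, 10)
        est = cf.FluxBVLS(lower_bounds=[0, 0, -np.inf, -np.inf]).fit(X, y, sample_weight=w)
        recomputed = np.linalg.norm((X * w[:, None]) @ est.flux_ - y * w)
        assert est.objective_ == pytest.approx(recomputed, rel=1e-8)
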