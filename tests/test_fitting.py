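"""Multigroup fitting: exactness, recovery, constraints, pruning, bootstrap."""

import numpy as np
import pytest
from scipy.optimize import minimize

import nettemp as nt
from nettemp.fitting import (_Objective, _ParameterMap, _fd_hessian,
                             _panel_stats, edge_wald_pvalues)
from conftest import random_params


def make_panel(values, age=10.0, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"item_{i+1}" for i in range(values.shape[1])]
    return nt.BinaryPanel(values, names, age=age)


class TestSaturatedExactness:
    def test_two_by_two_cells_reproduced(self):
        """Saturated exponential-family MLE matches observed cell moments."""
        vals = ([[-1, -1]] * 40 + [[-1, 1]] * 10
                + [[1, -1]] * 10 + [[1, 1]] * 40)
        fit = nt.fit_multigroup(
            [make_panel(vals)],
            nt.MultigroupModelSpec(nt.ConstraintLevel.SATURATED))
        probs = nt.state_distribution(fit.groups[0]).probs
        assert np.allclose(probs, [0.4, 0.1, 0.1, 0.4], atol=1e-6)
        assert fit.k == 3  # 2 thresholds + 1 edge, beta fixed
        assert fit.groups[0].beta == 1.0

    def test_free_parameter_counts(self, recovery_panels):
        _, panels = recovery_panels
        G, p, E = 4, 6, 15
        expected = {
            nt.ConstraintLevel.SATURATED: G * (p + E),
            nt.ConstraintLevel.EQUAL_EDGES: E + G * p + (G - 1),
            nt.ConstraintLevel.EQUAL_EDGES_THRESHOLDS: E + p + (G - 1),
            nt.ConstraintLevel.EQUAL_ALL: E + p,
        }
        for level, k in expected.items():
            fit = nt.fit_multigroup(panels[:G],
                                    nt.MultigroupModelSpec(level),
                                    nt.FitOptions(compute_se=False))
            assert fit.k == k, level


class TestFitMultigroup:
    def test_beta_recovery_single_seed(self, recovery_panels, recovery_fit):
        design, _ = recovery_panels
        assert np.all(np.abs(recovery_fit.betas - design.betas) < 0.03)
        assert recovery_fit.converged

    def test_wave1_beta_is_exactly_one(self, recovery_fit):
        assert recovery_fit.betas[0] == 1.0

    def test_equal_all_on_replicated_panel(self):
        rng = np.random.default_rng(6)
        params = random_params(rng, 3, beta=1.0)
        pan = nt.sample_ising(params, 400, seed=12)
        single = nt.fit_multigroup(
            [pan], nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_ALL))
        copies = [make_panel(pan.values.copy(), age=10.0 + g)
                  for g in range(3)]
        joint = nt.fit_multigroup(
            copies, nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_ALL))
        assert joint.loglik == pytest.approx(3 * single.loglik, abs=1e-8)

    def test_nesting_of_constraint_levels(self, recovery_panels):
        _, panels = recovery_panels
        lls = []
        for level in (nt.ConstraintLevel.SATURATED,
                      nt.ConstraintLevel.EQUAL_EDGES,
                      nt.ConstraintLevel.EQUAL_EDGES_THRESHOLDS,
                      nt.ConstraintLevel.EQUAL_ALL):
            fit = nt.fit_multigroup(panels, nt.MultigroupModelSpec(level),
                                    nt.FitOptions(compute_se=False))
            lls.append(fit.loglik)
        assert lls[0] >= lls[1] >= lls[2] >= lls[3]

    def test_gradient_norm_small_at_optimum(self, recovery_fit):
        assert recovery_fit.gradient_norm < 1e-5

    def test_single_group_with_free_beta_rejected(self):
        pan = nt.sample_ising(random_params(np.random.default_rng(1), 3),
                              100, seed=1)
        with pytest.raises(ValueError, match="unidentified"):
            nt.fit_multigroup(
                [pan], nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_EDGES))

    def test_near_zero_edges_warn_about_beta(self):
        params = nt.IsingParameters(np.zeros((3, 3)),
                                    np.array([-0.2, 0.1, 0.0]))
        panels = [nt.sample_ising(params, 800, seed=s, age=10.0 + s)
                  for s in range(2)]
        with pytest.warns(RuntimeWarning, match="weakly identified"):
            nt.fit_multigroup(
                panels,
                nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_EDGES))

    def test_incomplete_panel_rejected(self):
        pan = make_panel([[1, -1], [-1, 1]])
        bad = nt.inject_mcar(pan, 0.5, seed=3)
        if not bad.has_missing:  # tiny panel may escape masking
            bad = nt.BinaryPanel(np.array([[1.0, np.nan]]), ["item_1",
                                                             "item_2"], 10.0)
        with pytest.raises(ValueError, match="complete"):
            nt.fit_multigroup(
                [bad], nt.MultigroupModelSpec(nt.ConstraintLevel.SATURATED))

    def test_encoding_invariance_of_fit(self):
        design = nt.recovery_design(seed=77, n_per_wave=1500)
        panels = nt.generate_longitudinal(design)
        spec = nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_EDGES)
        f1 = nt.fit_multigroup(panels, spec)
        f2 = nt.fit_multigroup([p.relabel(nt.Encoding.ZO) for p in panels],
                               spec)
        assert np.max(np.abs(f1.betas - f2.betas)) < 1e-4
        for g in range(4):
            d1 = nt.state_distribution(f1.groups[g]).probs
            d2 = nt.state_distribution(f2.groups[g]).probs
            assert np.max(np.abs(d1 - d2)) < 1e-8

    def test_optimum_matches_derivative_free_search(self):
        """Independent Powell restarts cannot beat the reported optimum."""
        rng = np.random.default_rng(14)
        params = random_params(rng, 3, beta=1.0)
        panels = [nt.sample_ising(params, 300, seed=s, age=10.0 + s)
                  for s in range(2)]
        spec = nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_EDGES)
        fit = nt.fit_multigroup(panels, spec)
        pmap = _ParameterMap(spec, 2, 3)
        obj = _Objective(_panel_stats(panels), pmap, nt.Encoding.PM1)
        best = np.inf
        for s in range(10):
            x0 = np.random.default_rng(s).normal(0, 0.5, pmap.k)
            res = minimize(lambda t: obj(t)[0], x0, method="Powell",
                           options=dict(maxiter=20_000, xtol=1e-10,
                                        ftol=1e-12))
            best = min(best, res.fun)
        assert -fit.loglik <= best + 1e-6

    def test_analytic_hessian_matches_finite_differences(self):
        rng = np.random.default_rng(23)
        params = random_params(rng, 4, beta=1.0)
        panels = [nt.sample_ising(params, 200, seed=s, age=9.0 + s)
                  for s in range(3)]
        spec = nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_EDGES)
        pmap = _ParameterMap(spec, 3, 4)
        obj = _Objective(_panel_stats(panels), pmap, nt.Encoding.PM1)
        theta = np.random.default_rng(0).normal(0, 0.2, pmap.k)
        Ha, Hf = obj.hessian(theta), _fd_hessian(obj, theta)
        assert np.max(np.abs(Ha - Hf)) / np.max(np.abs(Hf)) < 1e-6


class TestPruneEdges:
    def test_recovers_single_strong_edge(self):
        p = 5
        om = np.zeros((p, p))
        om[0, 1] = om[1, 0] = 0.8
        params = [nt.IsingParameters(om, np.full(p, -0.1), b)
                  for b in (1.0, 1.0)]
        panels = [nt.sample_ising(pa, 4000, seed=s, age=10.0 + s)
                  for s, pa in enumerate(params)]
        spec = nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_ALL)
        sparse = nt.prune_edges(panels, spec)
        iu, ju = np.triu_indices(p, k=1)
        retained = {(int(i), int(j)) for i, j, m in
                    zip(iu, ju, sparse.edge_mask) if m}
        assert (0, 1) in retained

    def test_no_pruning_when_all_edges_strong(self):
        p = 4
        om = np.full((p, p), 0.5)
        np.fill_diagonal(om, 0.0)
        params = nt.IsingParameters(om, np.zeros(p))
        panels = [nt.sample_ising(params, 4000, seed=s, age=10.0 + s)
                  for s in range(2)]
        sparse = nt.prune_edges(
            panels, nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_ALL))
        assert sparse.edge_mask.all()
        assert sparse.structure is nt.Structure.SPARSE

    def test_independence_data_prunes_everything(self):
        params = nt.IsingParameters(np.zeros((3, 3)),
                                    np.array([-0.3, 0.2, 0.0]))
        panels = [nt.sample_ising(params, 3000, seed=s, age=10.0 + s)
                  for s in range(2)]
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # 'all edges pruned'
            sparse = nt.prune_edges(
                panels, nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_ALL,
                                               sparse_alpha=0.01))
        assert sparse.edge_mask.sum() <= 1  # at most a chance retention

    def test_wald_pvalues_need_se(self, recovery_panels):
        _, panels = recovery_panels
        fit = nt.fit_multigroup(
            panels, nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_ALL),
            nt.FitOptions(compute_se=False))
        with pytest.raises(ValueError, match="standard errors"):
            edge_wald_pvalues(fit)


class TestBootstrap:
    def test_seed_determinism(self):
        design = nt.recovery_design(seed=31, n_per_wave=500,
                                    betas=(1.0, 0.8))
        panels = nt.generate_longitudinal(design)
        spec = nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_EDGES)
        a = nt.bootstrap_beta(panels, spec, B=2, seed=5)
        b = nt.bootstrap_beta(panels, spec, B=2, seed=5)
        assert np.array_equal(a.beta_ci, b.beta_ci)
        assert np.array_equal(a.t_ci, b.t_ci)

    def test_analytic_and_bootstrap_widths_agree(self, recovery_panels,
                                                 recovery_fit):
        _, panels = recovery_panels
        boot = nt.bootstrap_beta(panels, recovery_fit.spec, B=100, seed=9)
        sl = recovery_fit.beta_free_indices()
        se_log = recovery_fit.se[sl]
        for g in range(1, 4):
            b = recovery_fit.betas[g]
            half = 1.96 * se_log[g - 1]
            analytic_width = b * (np.exp(half) - np.exp(-half))
            boot_width = boot.beta_ci[g, 1] - boot.beta_ci[g, 0]
            assert 0.5 < boot_width / analytic_width < 2.0

    def test_minimum_replicates(self, recovery_panels):
        _, panels = recovery_panels
        with pytest.raises(ValueError):
            nt.bootstrap_beta(
                panels,
                nt.MultigroupModelSpec(nt.ConstraintLevel.EQUAL_EDGES), B=1)
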