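"""Grid-filter tests: belief operations, filtering dynamics, EM fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flexcontrol as fc
from flexcontrol.beliefs import GridConfig, make_propagation_kernel


@pytest.fixture(scope="module")
def experiment_o():
    """A full 768-trial congruency sequence."""
    return fc.make_experiment(123)["congruency"].to_numpy()


class TestInitGrid:
    def test_uniform_normalized_symmetric(self):
        g = fc.init_grid(50, 50)
        assert g.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert g.f_mean == pytest.approx(0.5, abs=1e-12)
        assert g.alpha_mean == pytest.approx(0.5, abs=1e-12)

    def test_nodes_strictly_inside_unit_interval(self):
        g = fc.init_grid(13, 17)
        for nodes in (g.alpha_nodes, g.f_nodes):
            assert np.all(np.diff(nodes) > 0)
            assert nodes[0] > 0 and nodes[-1] < 1

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            fc.init_grid(0, 50)


class TestTransitionAlpha:
    def test_sticky_limit_keeps_belief(self):
        g = fc.init_grid(20, 20)
        g.mass = np.random.default_rng(0).dirichlet(np.ones(400)).reshape(20, 20)
        out = fc.transition_alpha(g.copy(), 1 - 1e-12)
        assert np.allclose(out.mass, g.mass, atol=1e-9)

    def test_full_mixing_limit_uniformizes_alpha(self):
        g = fc.init_grid(20, 20)
        g.mass = np.random.default_rng(1).dirichlet(np.ones(400)).reshape(20, 20)
        out = fc.transition_alpha(g, 1e-12)
        am = out.alpha_marginal
        assert np.allclose(am, am[0], atol=1e-9)

    def test_point_mass_hand_value(self):
        """A point mass at one alpha node keeps 0.9 + 0.1/10 = 0.91 of its mass."""
        g = fc.init_grid(10, 10)
        g.mass[:] = 0.0
        g.mass[3, 5] = 1.0
        out = fc.transition_alpha(g, 0.9)
        assert out.mass[3, 5] == pytest.approx(0.91, abs=1e-12)

    def test_f_marginal_preserved(self):
        g = fc.init_grid(15, 15)
        g.mass = np.random.default_rng(2).dirichlet(np.ones(225)).reshape(15, 15)
        before = g.f_marginal.copy()
        out = fc.transition_alpha(g, 0.7)
        assert np.allclose(out.f_marginal, before, atol=1e-12)

    @pytest.mark.parametrize("k", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_k_stay(self, k):
        with pytest.raises(ValueError):
            fc.transition_alpha(fc.init_grid(10, 10), k)


class TestPropagateF:
    def test_wider_kernel_for_higher_alpha(self):
        """From a fixed conflict level, propagated variance grows with alpha."""
        g = fc.init_grid(10, 50)
        g.mass[:] = 0.0
        g.mass[:, 35] = 0.1  # point mass in f at every alpha slice
        out = fc.propagate_f(g)
        f = out.f_nodes
        variances = []
        for row in out.mass:  # per alpha slice
            p = row / row.sum()
            mu = p @ f
            variances.append(p @ (f - mu) ** 2)
        assert np.all(np.diff(variances) > 0)

    def test_mode_kernel_peaks_at_previous_conflict_level(self):
        """The mode-parameterized kernel's argmax is the f_old node itself."""
        cfg = GridConfig(n_alpha=10, n_f=50, kernel_param="mode", kernel_scale=1.0)
        g = fc.init_grid(10, 50)
        K = make_propagation_kernel(g.alpha_nodes, g.f_nodes, cfg.s_of_alpha, "mode")
        for ai in range(10):
            assert np.array_equal(np.argmax(K[ai], axis=1), np.arange(50))

    def test_mean_kernel_preserves_row_mean(self):
        g = fc.init_grid(10, 200)
        K = make_propagation_kernel(g.alpha_nodes, g.f_nodes)
        means = K[4] @ g.f_nodes
        interior = slice(40, 160)  # away from boundary truncation
        assert np.allclose(means[interior], g.f_nodes[interior], atol=0.01)

    def test_narrow_limit_is_identity(self):
        g = fc.init_grid(5, 50)
        K = make_propagation_kernel(g.alpha_nodes, g.f_nodes, lambda a: 1e6)
        assert np.allclose(K[0], np.eye(50), atol=1e-3)

    def test_degenerate_sum_rejected(self):
        g = fc.init_grid(5, 10)
        with pytest.raises(ValueError, match="<= 2"):
            make_propagation_kernel(g.alpha_nodes, g.f_nodes, lambda a: 2.0, "mode")
        with pytest.raises(ValueError):
            GridConfig(kernel_scale=0.0, s_min=2.0)


class TestCongruencyUpdate:
    def test_incongruent_observation_raises_conflict_belief(self):
        g = fc.init_grid(10, 50)
        before = g.f_mean
        out = fc.update_congruency(g, 1)
        assert out.f_mean > before

    def test_uniform_prior_single_observation_matches_beta_posterior(self):
        """One incongruent trial on a flat prior: posterior mean -> Beta(2,1) mean 2/3."""
        g = fc.init_grid(10, 200)
        out = fc.update_congruency(g, 1)
        assert out.f_mean == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_observation_order_commutes(self):
        g = fc.init_grid(10, 40)
        g.mass = np.random.default_rng(3).dirichlet(np.ones(400)).reshape(10, 40)
        ab = fc.update_congruency(fc.update_congruency(g.copy(), 0), 1)
        ba = fc.update_congruency(fc.update_congruency(g.copy(), 1), 0)
        assert np.allclose(ab.mass, ba.mass, atol=1e-12)


class TestRSUpdate:
    def test_flat_likelihood_limits_leave_belief_unchanged(self):
        g = fc.init_grid(10, 40)
        g.mass = np.random.default_rng(4).dirichlet(np.ones(400)).reshape(10, 40)
        wide = fc.Hyperparameters(sigma_con=1e6, sigma_inc=1e6)
        out = fc.update_rs(g.copy(), 2.0, 1, wide)
        assert np.allclose(out.mass, g.mass, atol=1e-9)
        flat = fc.Hyperparameters(b_con=0.0, b_inc=0.0)
        out = fc.update_rs(g.copy(), 2.0, 1, flat)
        assert np.allclose(out.mass, g.mass, atol=1e-12)

    def test_fast_incongruent_response_raises_conflict_belief(self):
        """With b_inc > 0, an RS far above a_inc pulls f upward."""
        g = fc.init_grid(10, 50)
        hyper = fc.Hyperparameters()
        out = fc.update_rs(g.copy(), hyper.a_inc + 2.0, 1, hyper)
        assert out.f_mean > g.f_mean

    def test_missing_rs_is_identity(self):
        g = fc.init_grid(10, 40)
        out = fc.update_rs(g, np.nan, 0, fc.Hyperparameters())
        assert out is g


class TestEstimationUncertainty:
    def test_uniform_marginal_matches_continuous_sd(self):
        g = fc.init_grid(10, 200)
        assert fc.estimation_uncertainty(g) == pytest.approx(np.sqrt(1 / 12), abs=0.005)

    def test_point_mass_has_zero_uncertainty(self):
        g = fc.init_grid(10, 50)
        g.mass[:] = 0.0
        g.mass[0, 20] = 1.0
        assert fc.estimation_uncertainty(g) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounded_by_half(self, seed):
        g = fc.init_grid(10, 30)
        g.mass = np.random.default_rng(seed).dirichlet(np.ones(300)).reshape(10, 30)
        assert 0.0 <= fc.estimation_uncertainty(g) <= 0.5


@given(st.integers(0, 2**31 - 1), st.lists(st.sampled_from(["t", "p", "c0", "c1", "r"]),
                                           min_size=1, max_size=8))
@settings(max_examples=30, deadline=None)
def test_normalization_after_any_operation_sequence(seed, ops):
    """Total belief mass stays 1 within 1e-10 under arbitrary update sequences."""
    g = fc.init_grid(12, 16)
    g.mass = np.random.default_rng(seed).dirichlet(np.ones(12 * 16)).reshape(12, 16)
    hyper = fc.Hyperparameters()
    kernel = make_propagation_kernel(g.alpha_nodes, g.f_nodes)
    rng = np.random.default_rng(seed + 1)
    for op in ops:
        if op == "t":
            g = fc.transition_alpha(g, 0.9)
        elif op == "p":
            g = fc.propagate_f(g, kernel)
        elif op == "c0":
            g = fc.update_congruency(g, 0)
        elif op == "c1":
            g = fc.update_congruency(g, 1)
        else:
            g = fc.update_rs(g, float(rng.normal(2.3, 0.5)), int(rng.integers(2)), hyper)
        g.check_normalized()


class TestFilterSubject:
    def test_trace_length_and_bounds(self, experiment_o):
        trace = fc.filter_subject(experiment_o[:100], None, fc.Hyperparameters())
        assert len(trace) == 100
        assert trace["alpha_hat"].between(0, 1).all()
        assert trace["f_hat"].between(0, 1).all()
        assert trace["cpe"].between(0, 1).all()
        assert (trace["est_uncertainty"] >= 0).all()

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fc.filter_subject([], None, fc.Hyperparameters())

    def test_stationary_tracking(self):
        """On a stationary 80%-incongruent stream the conflict prediction
        settles near 0.8 (long-run tracking of proportion congruency)."""
        rng = np.random.default_rng(0)
        o = np.concatenate([fc.make_block(20, 0.8, rng) for _ in range(20)])
        trace = fc.filter_subject(o, None, fc.Hyperparameters())
        assert trace["f_hat"].tail(100).mean() == pytest.approx(0.8, abs=0.05)

    def test_rl_form_consistency(self, experiment_o):
        """Congruency-only belief updates move f_hat toward the observation on
        every trial, with alpha_hat acting as the learning rate (slope of the
        implied delta rule within [0.5, 1.5])."""
        trace = fc.filter_subject(experiment_o, None, fc.Hyperparameters())
        f = trace["f_hat"].to_numpy()
        a = trace["alpha_hat"].to_numpy()
        o = experiment_o.astype(float)
        delta = f[1:] - f[:-1]
        pe = o[:-1] - f[:-1]
        assert np.all(np.sign(delta) == np.sign(pe))
        slope = np.polyfit(a[:-1] * pe, delta, 1)[0]
        assert 0.5 <= slope <= 1.5

    def test_volatile_runs_raise_learning_rate(self):
        """Mean flexible LR is higher in volatile than stable runs."""
        table = fc.make_experiment(9)
        o = table["congruency"].to_numpy()
        trace = fc.filter_subject(o, None, fc.Hyperparameters())
        post = (table["block_index"] > 1).to_numpy()
        vol = table["run_type"].eq("volatile").to_numpy()
        a = trace["alpha_hat"].to_numpy()
        assert a[post & vol].mean() > a[post & ~vol].mean()

    def test_grid_refinement_stability(self, experiment_o):
        """Doubling both grid sizes changes the conflict trace by < 0.02 RMS."""
        hyper = fc.Hyperparameters()
        coarse = fc.filter_subject(experiment_o, None, hyper, GridConfig(50, 50))
        fine = fc.filter_subject(experiment_o, None, hyper, GridConfig(100, 100))
        rms = np.sqrt(np.mean((coarse["f_hat"] - fine["f_hat"]) ** 2))
        assert rms < 0.02

    def test_volatility_and_uncertainty_weakly_coupled(self):
        """Trial-wise flexible LR and estimation uncertainty share well under
        half their variance (the two quantities are dissociable)."""
        table = fc.make_experiment(11)
        sim = fc.simulate_subject(table, fc.GeneratorParams(), np.random.default_rng(11))
        trace = fc.filter_subject(
            sim["congruency"].to_numpy(), sim["rs"].to_numpy(), fc.Hyperparameters()
        )
        r = np.corrcoef(trace["alpha_hat"], trace["est_uncertainty"])[0, 1]
        assert r**2 < 0.5


class TestEMFitting:
    def test_constant_rs_gives_flat_emission(self):
        o = fc.make_experiment(2)["congruency"].to_numpy()[:200]
        rs = np.full(200, 2.3)
        with pytest.warns(UserWarning, match="degenerate"):
            hyper, _, _ = fc.fit_hyperparameters_em(o, rs)
        assert hyper.b_con == 0.0 and hyper.b_inc == 0.0
        assert hyper.sigma_con == pytest.approx(1e-3)  # floored

    def test_objective_non_decreasing(self):
        table = fc.make_experiment(21)
        sim = fc.simulate_subject(table, fc.GeneratorParams(), np.random.default_rng(21))
        _, _, obj = fc.fit_hyperparameters_em(
            sim["congruency"].to_numpy(), sim["rs"].to_numpy()
        )
        assert len(obj) >= 1
        assert np.all(np.diff(obj) >= -1e-6)

    def test_requires_both_congruency_conditions(self):
        with pytest.raises(ValueError, match="per congruency"):
            fc.fit_hyperparameters_em([1, 1, 1, 1], [2.0, 2.1, 2.2, 2.3])

    def test_parameter_recovery(self):
        """Emission intercepts and slopes recovered within 20% median relative
        error over 20 simulated subjects with known (jittered) parameters."""
        errs = {"a_con": [], "b_con": [], "a_inc": [], "b_inc": []}
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            true = fc.Hyperparameters().jittered(rng, 0.1)
            table = fc.make_experiment(rng)
            sim = fc.simulate_subject(table, fc.GeneratorParams(hyper=true), rng)
            est, _, _ = fc.fit_hyperparameters_em(
                sim["congruency"].to_numpy(), sim["rs"].to_numpy()
            )
            for k in errs:
                errs[k].append(
                    abs(getattr(est, k) - getattr(true, k)) / abs(getattr(true, k))
                )
        for k, v in errs.items():
            assert np.median(v) < 0.20, f"{k}: median relative error {np.median(v):.3f}"
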