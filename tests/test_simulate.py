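"""Simulator analytics: closed forms, sampling marginals, SDE limits."""

import numpy as np
import pytest
from scipy import stats

import sticcc as st
from sticcc.grn import Edge, GRNTopology
from sticcc.simulate import ParameterRanges, sample_parameters, shifted_hill


@pytest.fixture(scope="module")
def isolated_gene():
    return GRNTopology(genes=["A"], edges=[])


@pytest.fixture(scope="module")
def rep():
    return st.builtin_circuit("REP")


class TestShiftedHill:
    @pytest.mark.parametrize("lam", [0.02, 0.5, 1.0, 4.0, 80.0])
    def test_closed_form_anchors(self, lam):
        # B = 0 -> exactly 1; B = B0 -> (1+lam)/2; B >> B0 -> lam.
        assert shifted_hill(0.0, 2.0, 3, lam) == pytest.approx(1.0, abs=0)
        assert shifted_hill(2.0, 2.0, 3, lam) == pytest.approx((1 + lam) / 2, rel=1e-12)
        assert shifted_hill(2e6, 2.0, 2, lam) == pytest.approx(lam, abs=1e-9)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            shifted_hill(-1.0, 1.0, 2, 2.0)
        with pytest.raises(ValueError):
            shifted_hill(1.0, 0.0, 2, 2.0)
        with pytest.raises(ValueError):
            shifted_hill(1.0, 1.0, 0, 2.0)


class TestParameterSampling:
    def test_marginals_match_uniform_ranges(self, rep):
        params = sample_parameters(rep, seed=5, n_models=10_000)
        G = params.production.ravel()
        k = params.degradation.ravel()
        n = params.hill.ravel()
        lam = params.fold_change.ravel()
        assert G.min() >= 1 and G.max() <= 100
        assert k.min() >= 0.1 and k.max() <= 1
        assert np.array_equal(n, np.round(n)) and n.min() >= 1 and n.max() <= 6
        # all REP edges are inhibitory: lam = 1/U[1,100]
        assert lam.min() > 0.01 - 1e-12 and lam.max() < 1
        ks = stats.kstest(G, stats.uniform(loc=1, scale=99).cdf)
        assert ks.pvalue > 1e-3
        ks_inv = stats.kstest(1.0 / lam, stats.uniform(loc=1, scale=99).cdf)
        assert ks_inv.pvalue > 1e-3

    def test_activation_fold_above_one(self):
        topo = GRNTopology.from_edges([Edge("A", "B", 1), Edge("B", "A", 1)])
        params = sample_parameters(topo, seed=5, n_models=2000)
        assert params.fold_change.min() > 1

    def test_threshold_tracks_half_functional_level(self, rep):
        params = sample_parameters(rep, seed=5, n_models=5000)
        src, _, _ = rep.edge_arrays()
        M = params.production[:, src] / (2 * params.degradation[:, src])
        ratio = params.threshold / M
        assert ratio.min() >= 0.02 - 1e-12 and ratio.max() <= 1.98 + 1e-12

    def test_reproducible_from_seed(self, rep):
        a = sample_parameters(rep, seed=9, n_models=10)
        b = sample_parameters(rep, seed=9, n_models=10)
        assert np.array_equal(a.production, b.production)
        assert np.array_equal(a.threshold, b.threshold)


class TestDerivative:
    def test_isolated_gene_linear_dynamics(self, isolated_gene):
        params = sample_parameters(isolated_gene, seed=1)
        G, k = params.production[0, 0], params.degradation[0, 0]
        rate = st.derivative(np.array([[0.0]]), isolated_gene, params)
        assert rate[0, 0] == pytest.approx(G)
        at_fp = st.derivative(np.array([[G / k]]), isolated_gene, params)
        assert at_fp[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_rep_at_zero_regulators_gives_maximum_production(self, rep):
        # With every (inhibitory) regulator at 0 each shifted Hill factor
        # is 1 and no activating-edge normalization applies: the rate is G.
        params = sample_parameters(rep, seed=2)
        rate = st.derivative(np.zeros((1, 3)), rep, params)
        assert rate[0] == pytest.approx(params.production[0], rel=1e-12)

    def test_activating_edges_normalize_to_maximum_production(self):
        # A fully activated target produces at exactly G; a half-activated
        # one at G·H/λ.
        topo = GRNTopology.from_edges([Edge("B", "A", 1), Edge("A", "B", 1)])
        params = sample_parameters(topo, seed=3)
        lam = params.fold_change[0]
        big = np.array([[1e9, 1e9]])
        production = st.derivative(big, topo, params)[0] + params.degradation[0] * big[0]
        assert production == pytest.approx(params.production[0], rel=1e-6)

    def test_rejects_negative_state(self, rep):
        params = sample_parameters(rep, seed=2)
        with pytest.raises(ValueError):
            st.derivative(np.array([[-1.0, 0, 0]]), rep, params)

    def test_unknown_signal_target(self, rep):
        params = sample_parameters(rep, seed=2)
        sig = st.SignalSchedule("Z", 5.0, 1, 1, 1)
        with pytest.raises(KeyError):
            st.derivative(np.zeros((1, 3)), rep, params, signal=sig, t=0.5)


class TestSignalSchedule:
    def test_trapezoid_shape(self):
        sig = st.SignalSchedule("D", fold=50.0, t_rise=20, t_hold=20, t_fall=20)
        assert sig.value(0) == pytest.approx(1.0)
        assert sig.value(10) == pytest.approx(25.5)
        assert sig.value(30) == pytest.approx(50.0)
        assert sig.value(50) == pytest.approx(25.5)
        assert sig.value(90) == pytest.approx(1.0)


class TestSteadyStates:
    def test_isolated_gene_reaches_analytic_fixed_point(self, isolated_gene):
        cfg = st.SimulationConfig(n_models=50, total_time=200.0, seed=3)
        mat = st.simulate_steady_states(isolated_gene, cfg)
        params = sample_parameters(isolated_gene, np.random.default_rng(3), n_models=50)
        target = params.production[:, 0] / params.degradation[:, 0]
        assert np.allclose(mat.values()[:, 0], target, rtol=1e-4)

    def test_deterministic_given_seed(self, rep):
        cfg = st.SimulationConfig(n_models=30, total_time=20.0, seed=7)
        a = st.simulate_steady_states(rep, cfg)
        b = st.simulate_steady_states(rep, cfg)
        assert np.array_equal(a.values(), b.values())

    def test_cts_snapshots_cluster(self, cts_dataset):
        # The coupled toggle switch is multistable: 2-means on the PCA
        # coordinates separates cleanly.
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        coords = cts_dataset["space"].coordinates
        labels = KMeans(2, n_init=10, random_state=0).fit_predict(coords)
        assert silhouette_score(coords, labels) > 0.3

    def test_limit_cycle_snapshots_are_annular(self, rep_limit_cycle):
        # Snapshots of one oscillatory model trace a ring in PC1-2: points
        # concentrate near the median radius far more than a Gaussian with
        # the same covariance would. (The random-kinetics ensemble mixes
        # cycles of many amplitudes, so the ring lives at the single-model
        # level.)
        coords = rep_limit_cycle["space"].coordinates
        centered = coords - coords.mean(axis=0)
        r = np.linalg.norm(centered, axis=1)
        med = np.median(r)
        frac = np.mean(np.abs(r - med) < 0.2 * med)
        rng = np.random.default_rng(0)
        gauss = rng.multivariate_normal(
            np.zeros(2), np.cov(centered.T), size=20_000
        )
        rg = np.linalg.norm(gauss, axis=1)
        frac_gauss = np.mean(np.abs(rg - np.median(rg)) < 0.2 * np.median(rg))
        assert frac > frac_gauss


class TestTrajectories:
    def test_zero_noise_equals_deterministic_euler(self, rep):
        params = sample_parameters(rep, seed=4)
        cfg = st.SimulationConfig(
            n_models=1, noise_level=0.0, total_time=5.0, print_interval=0.1, seed=4
        )
        traj = st.simulate_trajectory_sde(rep, params, cfg)
        # replay plain Euler from the same initial condition
        state = traj.states[0].copy()[None, :]
        h = cfg.step_size
        for step in range(int(round(cfg.total_time / h))):
            state = np.maximum(
                state + h * st.derivative(state, rep, params, t=step * h), 0.0
            )
        assert traj.states[-1] == pytest.approx(state[0], rel=1e-12)

    def test_isolated_gene_relaxation_closed_form(self, isolated_gene):
        params = sample_parameters(isolated_gene, seed=6)
        G, k = params.production[0, 0], params.degradation[0, 0]
        cfg = st.SimulationConfig(
            n_models=1, noise_level=0.0, step_size=0.005,
            total_time=10.0, print_interval=0.5, seed=6,
        )
        traj = st.simulate_trajectory_sde(
            isolated_gene, params, cfg, initial_state=np.array([0.0])
        )
        expected = (G / k) * (1 - np.exp(-k * traj.times))
        assert np.allclose(traj.states[:, 0], expected, rtol=0.02)

    def test_noisy_cts_crosses_between_basins(self, cts_topology):
        # With strong noise a multistable model revisits several basins.
        from sklearn.cluster import KMeans

        cfg_ss = st.SimulationConfig(n_models=40, seed=8)
        params = st.sample_parameters(cts_topology, seed=8, n_models=40)
        raw = st.simulate_steady_states(cts_topology, cfg_ss, params=params)
        # choose a model whose ensemble shows a clear bistable split
        i = 0
        cfg = st.SimulationConfig(
            n_models=1, noise_level=0.4, total_time=2000.0,
            print_interval=2.0, seed=8, step_size=0.05,
        )
        traj = st.simulate_trajectory_sde(cts_topology, params.model(i), cfg)
        states = np.log2(traj.states + 1)
        labels = KMeans(2, n_init=10, random_state=0).fit_predict(states)
        crossings = int(np.sum(labels[1:] != labels[:-1]))
        assert crossings >= 1

    def test_reproducible_from_seed(self, rep):
        params = sample_parameters(rep, seed=4)
        cfg = st.SimulationConfig(
            n_models=1, noise_level=0.2, total_time=5.0, print_interval=0.1, seed=4
        )
        a = st.simulate_trajectory_sde(rep, params, cfg)
        b = st.simulate_trajectory_sde(rep, params, cfg)
        assert np.array_equal(a.states, b.states)


class TestSplicing:
    def test_stationary_point_of_isolated_gene(self, isolated_gene):
        params = sample_parameters(isolated_gene, seed=10)
        G, k = params.production[0, 0], params.degradation[0, 0]
        beta = 0.7
        cfg = st.SimulationConfig(
            n_models=1, total_time=300.0, print_interval=5.0, seed=10
        )
        traj = st.simulate_with_splicing(isolated_gene, params, cfg, beta=beta)
        assert traj.unspliced[-1, 0] == pytest.approx(G / beta, rel=1e-3)
        assert traj.states[-1, 0] == pytest.approx(G / k, rel=1e-3)

    def test_fast_splicing_limit_recovers_base_model(self, rep):
        params = sample_parameters(rep, seed=12)
        k_max = params.degradation.max()
        cfg = st.SimulationConfig(
            n_models=1, total_time=30.0, print_interval=0.5,
            step_size=0.001, seed=12,
        )
        base = st.simulate_trajectory_sde(rep, params, cfg,
                                          initial_state=np.full(3, 5.0))
        fast = st.simulate_with_splicing(rep, params, cfg, beta=1e3 * k_max,
                                         initial_state=np.full(3, 5.0))
        scale = np.abs(base.states).max()
        assert np.allclose(fast.states, base.states, atol=0.05 * scale)


class TestNormalization:
    def test_log2_pseudocount(self, rng):
        import pandas as pd

        df = pd.DataFrame({"g1": [0.0, 1.0, 3.0], "g2": [7.0, 15.0, 31.0]})
        mat = st.ExpressionMatrix(df, scale="raw")
        out = st.normalize_log(mat)
        assert out.scale == "log"
        assert out.values()[0, 0] == 0.0
        assert out.values()[1, 0] == 1.0
        back = 2 ** out.values() - 1
        assert np.allclose(back, mat.values(), atol=1e-12)

    def test_zscore_definition_and_constant_drop(self):
        import pandas as pd

        df = pd.DataFrame({"g1": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        mat = st.ExpressionMatrix(df, scale="raw")
        with pytest.warns(UserWarning, match="flat"):
            out = st.zscore(mat)
        assert out.genes == ["g1"]
        assert out.values()[:, 0] == pytest.approx([-1.0, 0.0, 1.0])
        assert abs(out.values()[:, 0].mean()) < 1e-12


class TestDropout:
    def test_zero_probability_is_identity(self, rep_dataset):
        out = st.apply_dropout(rep_dataset["raw"], 0.0, 0.2, seed=1)
        assert np.array_equal(out.values(), rep_dataset["raw"].values())

    def test_certain_dropout_zeroes_exactly_the_subthreshold_entries(self):
        import pandas as pd

        vals = np.arange(1.0, 11.0)
        mat = st.ExpressionMatrix(pd.DataFrame({"g": vals}), scale="raw")
        out = st.apply_dropout(mat, 1.0, 0.2, seed=0)
        thresh = np.quantile(vals, 0.2)  # same linear-interpolation rule
        expected = np.where(vals < thresh, 0.0, vals)
        assert np.array_equal(out.values()[:, 0], expected)

    def test_zeroed_fraction_matches_binomial_expectation(self, rng):
        import pandas as pd

        n = 10_000
        vals = rng.uniform(1.0, 2.0, size=n)  # strictly positive, all distinct
        mat = st.ExpressionMatrix(pd.DataFrame({"g": vals}), scale="raw")
        p, q = 0.5, 0.4
        out = st.apply_dropout(mat, p, q, seed=3)
        zeroed = np.sum(out.values() == 0.0)
        expect = p * q * n
        sigma = np.sqrt(n * p * q * (1 - p * q))
        assert abs(zeroed - expect) < 3 * sigma
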