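import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitnet import gp, optimize
from traitnet.gp import ArdHyper, SamplerConfig, fit_node_gp
from traitnet.optimize import (GpSurrogate, build_pc_basis, exceedance_probability,
                               expected_improvement, maximise_acquisition,
                               optimise_in_pc_space, propose_batch_constant_liar)

from conftest import make_table


class TestExpectedImprovement:
    def test_degenerate_sd_zero(self):
        assert expected_improvement(0.5, 0.0, 1.0) == 0.0
        assert expected_improvement(2.0, 0.0, 1.0) == 1.0

    def test_known_values(self):
        assert expected_improvement(1.0, 1.0, 0.0) == pytest.approx(1.08332, abs=1e-4)
        assert expected_improvement(0.0, 1.0, 0.0) == pytest.approx(0.39894, abs=1e-4)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            expected_improvement(0.0, -1.0, 0.0)

    @given(mean=st.floats(-5, 5), sd=st.floats(0, 5), best=st.floats(-5, 5))
    @settings(deadline=None, max_examples=200)
    def test_non_negative_everywhere(self, mean, sd, best):
        assert expected_improvement(mean, sd, best) >= 0.0

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(10**6)
        for mean, sd, best in [(1.0, 1.0, 0.0), (0.0, 0.5, 0.3), (-1.0, 2.0, 1.0)]:
            mc = np.maximum(mean + sd * draws - best, 0.0)
            se = mc.std() / 1000.0
            assert abs(expected_improvement(mean, sd, best) - mc.mean()) < 3 * se

    def test_exceedance_probability_matches_mc(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(10**6)
        p = exceedance_probability(0.4, 1.3, 1.0)
        mc = (0.4 + 1.3 * draws > 1.0).mean()
        assert abs(p - mc) < 0.002
        assert 0.0 <= p <= 1.0


def fit_surrogate(x, y, seed=0):
    tbl = make_table({"x": np.asarray(x), "y": np.asarray(y)})
    model = fit_node_gp("y", ["x"], tbl, SamplerConfig(mode="map", seed=seed))
    return GpSurrogate.from_node_model(model)


class TestAcquisition:
    def test_proposal_in_sampling_gap(self):
        # y = -(x-0.5)^2 observed with a hole around the optimum: EI should
        # propose inside the gap near 0.5
        x = np.concatenate([np.linspace(0, 0.3, 10), np.linspace(0.7, 1.0, 10)])
        rng = np.random.default_rng(2)
        y = -(x - 0.5) ** 2 + 0.01 * rng.standard_normal(len(x))
        sur = fit_surrogate(x, y)
        bounds = np.array([[0.0, 1.0]])
        pt, ei = maximise_acquisition(sur, float(y.max()), bounds, restarts=20, seed=0)
        assert 0.35 <= pt[0] <= 0.65
        # dense-grid oracle: found EI within 1% of the grid maximum
        grid = np.linspace(0, 1, 5000)[:, None]
        m, s = sur.predict(grid)
        grid_max = expected_improvement(m, s, float(y.max())).max()
        assert ei >= 0.99 * grid_max

    def test_degenerate_bounds_return_point(self):
        sur = fit_surrogate(np.linspace(0, 1, 12), np.linspace(0, 1, 12))
        pt, _ = maximise_acquisition(sur, 0.5, np.array([[0.7, 0.7]]), seed=0)
        assert pt[0] == 0.7

    def test_proposals_always_in_bounds(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            x = rng.uniform(-2, 2, 15)
            y = rng.normal(size=15)
            sur = fit_surrogate(x, y, seed=seed)
            lo, hi = x.min(), x.max()
            pt, _ = maximise_acquisition(sur, float(y.max()),
                                         np.array([[lo, hi]]), restarts=5, seed=seed)
            assert lo <= pt[0] <= hi


class TestConstantLiar:
    def test_q1_equals_single_acquisition(self):
        x = np.linspace(-1, 1, 15)
        y = x**2
        sur = fit_surrogate(x, y)
        bounds = np.array([[-1.0, 1.0]])
        pt, _ = maximise_acquisition(sur, float(y.max()), bounds, restarts=10, seed=42)
        batch = propose_batch_constant_liar(sur, float(y.max()), bounds, q=1,
                                            seed=42, restarts=10)
        assert batch[0].trait_values["x0"] == pytest.approx(pt[0], abs=1e-8)

    def test_batch_distinct_and_ranked(self, tradeoff_panel):
        model = fit_node_gp("yield", ["a", "b"], tradeoff_panel,
                            SamplerConfig(mode="map", seed=0))
        sur = GpSurrogate.from_node_model(model)
        X = tradeoff_panel.values[["a", "b"]].to_numpy()
        bounds = np.column_stack([X.min(0), X.max(0)])
        best = float(tradeoff_panel.values["yield"].max())
        batch = propose_batch_constant_liar(sur, best, bounds, q=5, seed=0,
                                            restarts=15, trait_names=["a", "b"])
        P = np.array([[p.trait_values["a"], p.trait_values["b"]] for p in batch])
        std = (P - X.mean(0)) / X.std(0)
        dists = [np.linalg.norm(std[i] - std[j])
                 for i in range(5) for j in range(i + 1, 5)]
        assert min(dists) > 0.05
        ranks = [p.rank for p in sorted(batch, key=lambda p: p.rank)]
        assert ranks == [1, 2, 3, 4, 5]
        exc = [p.exceedance_probability for p in sorted(batch, key=lambda p: p.rank)]
        assert exc == sorted(exc, reverse=True)

    def test_lie_removes_improvement_mass(self):
        # between two observations the surrogate is uncertain, so EI is large;
        # inserting the lie (= incumbent best) there collapses the local
        # predictive sd and must reduce EI at that point
        X = np.array([[-1.0], [1.0]])
        y = np.array([1.0, 1.0])
        sur = GpSurrogate(X, y, ArdHyper(2.0, np.array([1.5]), 0.1))
        best = 1.0
        x_star = np.array([[0.0]])
        m, s = sur.predict(x_star)
        ei_before = expected_improvement(m, s, best)[0]
        lied = sur.with_point(x_star[0], best)
        m2, s2 = lied.predict(x_star)
        ei_after = expected_improvement(m2, s2, best)[0]
        assert ei_after < ei_before

    def test_batch_deterministic_given_seed(self):
        x = np.linspace(-1, 1, 12)
        y = -x**2
        sur = fit_surrogate(x, y)
        bounds = np.array([[-1.0, 1.0]])
        a = propose_batch_constant_liar(sur, 0.0, bounds, q=3, seed=5, restarts=8)
        b = propose_batch_constant_liar(sur, 0.0, bounds, q=3, seed=5, restarts=8)
        for pa, pb in zip(a, b):
            assert pa.trait_values == pb.trait_values


class TestPcBasis:
    def test_perfectly_correlated_pair_gives_one_component(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=100)
        basis = build_pc_basis(pd.DataFrame({"a": t, "b": 2 * t}), threshold=0.95)
        assert basis.n_components == 1

    def test_full_reconstruction_exact(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 4))
        df = pd.DataFrame(X, columns=list("abcd"))
        basis = build_pc_basis(df, threshold=1.0)
        Z = (X - basis.centre) / basis.scale
        scores_full = Z @ basis.loadings
        back = basis.inverse(scores_full, n_components=4)
        assert np.abs(back - X).max() < 1e-10

    def test_scores_uncorrelated(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3)) @ rng.normal(size=(3, 3))
        basis = build_pc_basis(pd.DataFrame(X, columns=list("abc")), threshold=1.0)
        Z = (X - basis.centre) / basis.scale
        scores = Z @ basis.loadings
        c = np.corrcoef(scores, rowvar=False)
        assert np.abs(c[~np.eye(3, dtype=bool)]).max() < 1e-10

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"a": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            build_pc_basis(df)


class TestPcConstrainedOptimisation:
    def test_proposals_respect_tradeoff_line(self, tradeoff_panel):
        X = tradeoff_panel.values[["a", "b"]].to_numpy()
        yld = tradeoff_panel.values["yield"].to_numpy()
        basis = build_pc_basis(tradeoff_panel.values[["a", "b"]], threshold=0.95)
        assert basis.n_components == 1  # the trade-off is effectively 1-D
        scores = basis.transform(X)
        pctbl = make_table({"PC1": scores[:, 0], "yield": yld})
        model = fit_node_gp("yield", ["PC1"], pctbl, SamplerConfig(mode="map", seed=0))
        sur = GpSurrogate.from_node_model(model)
        bounds = np.column_stack([X.min(0), X.max(0)])
        props = optimise_in_pc_space(sur, basis, bounds, float(yld.max()),
                                     q=3, seed=0, restarts=10)
        resid_sd = (X[:, 0] + X[:, 1]).std()
        for p in props:
            s = p.trait_values["a"] + p.trait_values["b"]
            assert abs(s - (X[:, 0] + X[:, 1]).mean()) < 2 * resid_sd
            for trait, lo, hi in zip(["a", "b"], bounds[:, 0], bounds[:, 1]):
                assert lo - 1e-9 <= p.trait_values[trait] <= hi + 1e-9

    def test_uncorrelated_traits_identity_rotation(self):
        # with uncorrelated inputs and all components kept, the PC basis is a
        # rotation: back-transformed proposals still span the same box
        rng = np.random.default_rng(7)
        a = rng.normal(size=80)
        b = rng.normal(size=80)
        yld = a + 0.5 * b + 0.05 * rng.normal(size=80)
        tbl = make_table({"a": a, "b": b, "yield": yld})
        basis = build_pc_basis(tbl.values[["a", "b"]], threshold=1.0)
        assert basis.n_components == 2
        scores = basis.transform(np.column_stack([a, b]))
        pctbl = make_table({"PC1": scores[:, 0], "PC2": scores[:, 1], "yield": yld})
        model = fit_node_gp("yield", ["PC1", "PC2"], pctbl,
                            SamplerConfig(mode="map", seed=0))
        sur = GpSurrogate.from_node_model(model)
        bounds = np.column_stack([np.column_stack([a, b]).min(0),
                                  np.column_stack([a, b]).max(0)])
        props = optimise_in_pc_space(sur, basis, bounds, float(yld.max()),
                                     q=2, seed=0, restarts=10)
        for p in props:
            assert bounds[0, 0] <= p.trait_values["a"] <= bounds[0, 1]
            assert bounds[1, 0] <= p.trait_values["b"] <= bounds[1, 1]
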