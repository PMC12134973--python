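"""Buffer covariates, VIF filtering, model averaging and diversity indices."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import trophicrange as tr
from trophicrange.dietenv import buffer_offsets
from trophicrange.grids import GridStack


def brute_force_buffer_count(radius_km: float) -> int:
    count = 0
    r = int(radius_km) + 1
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy * dy + dx * dx <= radius_km * radius_km:
                count += 1
    return count


class TestBufferCovariates:
    def test_interior_cell_count_matches_brute_force(self, small_landscape):
        sites = pd.DataFrame({"row": [40], "col": [40]})
        out = tr.extract_buffer_covariates(small_landscape, sites, radius_km=18)
        assert out.loc[0, "n_cells"] == brute_force_buffer_count(18)

    def test_constant_layer_mean_is_constant(self):
        g = GridStack({"c": np.full((50, 50), 3.25)})
        out = tr.extract_buffer_covariates(g, pd.DataFrame({"row": [25], "col": [25]}), 10)
        assert out.loc[0, "c"] == pytest.approx(3.25)

    def test_edge_site_buffer_is_truncated(self, small_landscape):
        interior = tr.extract_buffer_covariates(
            small_landscape, pd.DataFrame({"row": [40], "col": [40]}), 18
        )
        edge = tr.extract_buffer_covariates(
            small_landscape, pd.DataFrame({"row": [40], "col": [5]}), 18
        )
        assert edge.loc[0, "n_cells"] < interior.loc[0, "n_cells"]

    def test_site_outside_grid_rejected(self, small_landscape):
        with pytest.raises(ValueError):
            tr.extract_buffer_covariates(
                small_landscape, pd.DataFrame({"row": [200], "col": [0]}), 18
            )

    def test_offsets_symmetric(self):
        offs = buffer_offsets(7)
        assert len(offs) % 2 == 1  # center plus symmetric pairs
        assert {tuple(o) for o in offs} == {tuple(-o) for o in offs}


class TestVifFilter:
    def test_orthogonal_predictors_all_retained_with_unit_vif(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(60, 4)))
        X = pd.DataFrame(q, columns=list("abcd"))
        res = tr.vif_filter(X, threshold=10)
        assert res.retained == list("abcd")
        assert res.dropped == []

    def test_duplicated_column_drops_exactly_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        res = tr.vif_filter(X)
        assert len(res.dropped) == 1
        assert res.dropped[0][0] in {"a", "b"}
        assert "c" in res.retained

    def test_near_collinear_pair_dropped_by_r2_oracle(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=300)
        noise = rng.normal(size=300)
        # calibrate noise for R^2 ~ 0.95 => VIF ~ 20
        x2 = x1 + noise * np.sqrt(np.var(x1) * 0.05 / np.var(noise))
        X = pd.DataFrame({"x1": x1, "x2": x2, "z": rng.normal(size=300)})
        r2 = sm.OLS(x2, sm.add_constant(np.column_stack([x1, X["z"]]))).fit().rsquared
        assert 1 / (1 - r2) > 10  # oracle: the pair exceeds the threshold
        res = tr.vif_filter(X, threshold=10)
        assert len(res.dropped) == 1 and res.dropped[0][0] in {"x1", "x2"}

    def test_shape_requirements(self):
        with pytest.raises(ValueError):
            tr.vif_filter(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError):
            tr.vif_filter(pd.DataFrame(np.eye(3), columns=list("abc")))


class TestAveragedModels:
    def test_noise_free_slope_equals_ols(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = 1.5 + 2.0 * X["x"]
        res = tr.fit_averaged_models(y, X)
        ols = sm.OLS(y.to_numpy(), sm.add_constant(X["x"].to_numpy())).fit().params[1]
        assert res.coefficients.loc["x", "estimate"] == pytest.approx(ols, abs=1e-9)

    def test_pure_noise_keeps_intercept_only_in_subset(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(200):
            X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
            y = rng.normal(size=40)
            res = tr.fit_averaged_models(y, X)
            in_subset = res.model_table[res.model_table["in_subset"]]["terms"]
            hits += any(t == () for t in in_subset)
        assert hits >= 160  # intercept-only competitive in the large majority

    def test_best_model_always_in_subset_and_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = 0.8 * X["a"] + rng.normal(size=50) * 0.5
        res = tr.fit_averaged_models(y, X)
        assert res.model_table.loc[0, "delta"] == 0
        assert bool(res.model_table.loc[0, "in_subset"])
        assert res.model_table["weight"].dropna().sum() == pytest.approx(1.0)

    def test_sign_recovery_on_synthetic_diet_gradient(self):
        # a category share that increases with one layer: the averaged model
        # should recover a positive coefficient at 31 sites
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            X = pd.DataFrame(rng.normal(size=(31, 3)), columns=["grad", "n1", "n2"])
            share = 0.4 + 0.12 * X["grad"] + rng.normal(size=31) * 0.08
            res = tr.fit_averaged_models(share, X)
            hits += (
                "grad" in res.coefficients.index
                and res.coefficients.loc["grad", "estimate"] > 0
            )
        assert hits >= 80

    def test_averaged_coefficient_within_member_model_hull(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = 0.5 * X["a"] - 0.3 * X["b"] + rng.normal(size=60) * 0.7
        res = tr.fit_averaged_models(y, X)
        subset = res.model_table[res.model_table["in_subset"]]
        for term in res.coefficients.index:
            estimates = []
            for t in subset["terms"]:
                if term in t:
                    Xm = sm.add_constant(X[list(t)].to_numpy())
                    estimates.append(
                        sm.OLS(y.to_numpy(), Xm).fit().params[list(t).index(term) + 1]
                    )
            est = res.coefficients.loc[term, "estimate"]
            assert min(estimates) - 1e-9 <= est <= max(estimates) + 1e-9


class TestDiversity:
    def test_closed_forms_for_equal_shares(self):
        shares = pd.DataFrame([[0.2] * 5])
        d = tr.diet_diversity(shares)
        assert d.loc[0, "shannon"] == pytest.approx(np.log(5))
        assert d.loc[0, "simpson"] == pytest.approx(0.8)
        assert d.loc[0, "inv_simpson"] == pytest.approx(5.0)

    def test_single_category_extremes(self):
        d = tr.diet_diversity(pd.DataFrame([[1.0, 0.0, 0.0]]))
        assert d.loc[0, "shannon"] == pytest.approx(0.0)
        assert d.loc[0, "simpson"] == pytest.approx(0.0)
        assert d.loc[0, "inv_simpson"] == pytest.approx(1.0)

    def test_permutation_invariance_and_bounds(self):
        rng = np.random.default_rng(8)
        p = rng.dirichlet(np.ones(5), size=20)
        d1 = tr.diet_diversity(pd.DataFrame(p))
        d2 = tr.diet_diversity(pd.DataFrame(p[:, ::-1]))
        assert np.allclose(d1.to_numpy(), d2.to_numpy())
        assert (d1["shannon"] <= np.log(5) + 1e-9).all()
        assert (d1["simpson"] <= 1 - 1 / 5 + 1e-9).all()
        assert ((d1["inv_simpson"] >= 1) & (d1["inv_simpson"] <= 5 + 1e-9)).all()

    def test_negative_share_rejected(self):
        with pytest.raises(ValueError):
            tr.diet_diversity(pd.DataFrame([[1.2, -0.2]]))
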