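"""Food-species SDMs: gridding, annulus sampling, selection, ensembles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import trophicrange as tr
from trophicrange.foodsdm import make_pa_table


def clustered_presences(seed=0, shape=(80, 80), n_centers=4, spread=3.0, n_points=300):
    rng = np.random.default_rng(seed)
    centers = rng.integers(10, 70, size=(n_centers, 2))
    pts = (
        centers[rng.integers(0, n_centers, n_points)]
        + rng.normal(0, spread, size=(n_points, 2))
    ).round().astype(int).clip(0, 79)
    return pd.DataFrame({"species_id": "sp", "row": pts[:, 0], "col": pts[:, 1]})


class TestGridPresences:
    def test_points_in_one_cell_collapse_to_one_presence(self):
        occ = pd.DataFrame({"species_id": "sp", "row": [3] * 10, "col": [4] * 10})
        pg = tr.grid_presences(occ, "sp", (10, 10))
        assert pg.count == 1

    def test_below_threshold_species_flagged_excluded(self):
        occ = pd.DataFrame(
            {"species_id": "sp", "row": np.arange(49), "col": np.arange(49)}
        )
        pg = tr.grid_presences(occ, "sp", (60, 60))
        assert pg.count == 49 and pg.excluded
        pg50 = tr.grid_presences(
            pd.DataFrame({"species_id": "sp", "row": np.arange(50), "col": np.arange(50)}),
            "sp",
            (60, 60),
        )
        assert not pg50.excluded

    def test_no_occurrences_rejected(self):
        with pytest.raises(ValueError):
            tr.grid_presences(pd.DataFrame({"species_id": [], "row": [], "col": []}), "sp", (5, 5))

    def test_gridding_is_idempotent(self):
        occ = clustered_presences()
        pg = tr.grid_presences(occ, "sp", (80, 80))
        again = tr.grid_presences(
            pd.DataFrame({"species_id": "sp", "row": pg.cells[:, 0], "col": pg.cells[:, 1]}),
            "sp",
            (80, 80),
        )
        assert np.array_equal(pg.cells, again.cells)


class TestAnnulus:
    def test_sampled_cells_respect_annulus_by_brute_force(self):
        pg = tr.grid_presences(clustered_presences(1), "sp", (80, 80))
        absences = tr.sample_pseudoabsences_annulus(pg, seed=3)
        assert len(absences) == pg.count  # equal numbers of absences
        pres = pg.cells.astype(float)
        for cell in absences:
            d = np.sqrt(((pres - cell) ** 2).sum(axis=1)).min()
            assert 3.0 < d <= 10.0

    def test_absences_never_coincide_with_presences(self):
        pg = tr.grid_presences(clustered_presences(2), "sp", (80, 80))
        absences = tr.sample_pseudoabsences_annulus(pg, seed=4)
        pres_set = {tuple(c) for c in pg.cells}
        assert not any(tuple(c) in pres_set for c in absences)

    def test_truncated_annulus_raises_with_shortfall(self):
        occ = pd.DataFrame({"species_id": "sp", "row": [1], "col": [1]})
        pg = tr.grid_presences(occ, "sp", (4, 4), min_presences=1)
        with pytest.raises(ValueError, match="candidate"):
            tr.sample_pseudoabsences_annulus(pg, seed=0)

    def test_same_seed_identical_sample(self):
        pg = tr.grid_presences(clustered_presences(3), "sp", (80, 80))
        a = tr.sample_pseudoabsences_annulus(pg, seed=5)
        b = tr.sample_pseudoabsences_annulus(pg, seed=5)
        assert np.array_equal(a, b)


def _pa_from_layers(seed, n=500, beta=2.0, n_layers=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_layers))
    y = (rng.random(n) < expit(beta * X[:, 0] - 0.5 * beta * X[:, 0] ** 2)).astype(float)
    df = pd.DataFrame(X, columns=[f"v{k}" for k in range(n_layers)])
    df["presence"] = y
    return df


class TestVariableSelection:
    def test_few_candidates_all_retained(self):
        pa = _pa_from_layers(0)
        out = tr.select_species_variables(pa, ["v0", "v1", "v2"])
        assert set(out) == {"v0", "v1", "v2"}

    def test_identical_layers_keep_exactly_one(self):
        pa = _pa_from_layers(1)
        pa["v0_copy"] = pa["v0"]
        out = tr.select_species_variables(pa, ["v0", "v0_copy", "v1"])
        assert ("v0" in out) != ("v0_copy" in out)

    def test_generating_gradient_ranks_first_in_most_replicates(self):
        hits = 0
        for rep in range(100):
            pa = _pa_from_layers(rep, n=400)
            out = tr.select_species_variables(pa, [f"v{k}" for k in range(4)])
            hits += out[0] == "v0"
        assert hits >= 95

    def test_single_class_rejected(self):
        pa = _pa_from_layers(0)
        pa["presence"] = 1.0
        with pytest.raises(ValueError):
            tr.select_species_variables(pa, ["v0"])


class TestEnsemble:
    def test_separable_species_reaches_high_tss(self):
        rng = np.random.default_rng(0)
        n = 600
        x = rng.normal(size=n)
        df = pd.DataFrame({"v0": x, "v1": rng.normal(size=n), "presence": (x > 0).astype(float)})
        model = tr.fit_ensemble(df, ["v0", "v1"], seed=1)
        assert model.tss >= 0.95

    def test_shuffled_labels_give_no_skill_on_average(self):
        rng = np.random.default_rng(1)
        base = _pa_from_layers(7, n=300, n_layers=2)
        tsses = []
        for seed in range(50):
            df = base.copy()
            df["presence"] = rng.permutation(df["presence"].to_numpy())
            tsses.append(tr.fit_ensemble(df, ["v0", "v1"], seed=seed).tss)
        assert abs(np.mean(tsses)) <= 0.1

    def test_probabilities_bounded_and_weights_normalized(self):
        pa = _pa_from_layers(2)
        model = tr.fit_ensemble(pa, ["v0", "v1"], seed=2)
        assert model.weights.sum() == pytest.approx(1.0)
        layers = {f"v{k}": np.random.default_rng(3).normal(size=(20, 20)) for k in range(2)}
        grid = model.predict_grid(layers)
        assert np.nanmin(grid) >= 0 and np.nanmax(grid) <= 1

    def test_tss_identity_holds(self):
        pa = _pa_from_layers(3)
        model = tr.fit_ensemble(pa, ["v0"], seed=3)
        assert model.tss == pytest.approx(model.sensitivity + model.specificity - 1.0)


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self, small_landscape):
        niche = tr.TrueNiche("sp", {"Clim_8": (1.2, -0.9)}, intercept=-1.5)
        occ, _ = tr.generate_food_species([niche], small_landscape, seed=5)
        pg = tr.grid_presences(occ, "sp", small_landscape.shape)
        absences = tr.sample_pseudoabsences_annulus(pg, seed=6)
        pa = make_pa_table(pg.cells, absences, small_landscape.layers)
        return tr.fit_ensemble(pa, ["Clim_8", "Clim_4"], seed=7)

    def test_current_scenario_identical_to_current(self, fitted, small_landscape):
        a = tr.predict_suitability(fitted, small_landscape, None)
        b = tr.predict_suitability(fitted, small_landscape, "current")
        assert np.array_equal(a, b, equal_nan=True)

    def test_constant_layers_give_constant_map(self, fitted):
        layers = {"Clim_8": np.full((15, 15), 10.0), "Clim_4": np.full((15, 15), 600.0)}
        out = fitted.predict_grid(layers)
        assert np.nanstd(out) == pytest.approx(0.0, abs=1e-12)

    def test_member_bounds_bracket_ensemble(self, fitted, small_landscape):
        lo, hi = tr.member_prediction_bounds(fitted, small_landscape.layers)
        ens = fitted.predict_grid(small_landscape.layers)
        ok = np.isfinite(ens)
        assert (lo[ok] <= ens[ok] + 1e-9).all() and (ens[ok] <= hi[ok] + 1e-9).all()

    def test_missing_layer_rejected(self, fitted):
        with pytest.raises(KeyError):
            fitted.predict_grid({"Clim_8": np.zeros((5, 5))})
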