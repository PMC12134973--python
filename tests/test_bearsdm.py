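"""Focal-species model: stratified sampling, priors, occurrence prep, WAIC,
prior transfer and thresholding."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import trophicrange as tr
from trophicrange.bayes import SamplerSettings, fit_logistic_mcmc
from trophicrange.bearsdm import (
    _largest_remainder_split,
    climate_terms,
    fit_historical_model,
    sampling_intensity,
)
from trophicrange.grids import RangeGrid

FAST = SamplerSettings(seed=0, n_adapt=350, adapt_discard=150, n_steps=600, n_discard=80)


def coarse_world(seed=0, shape=(30, 30)):
    rng = np.random.default_rng(seed)
    layers = {v: rng.normal(size=shape) for v in tr.CLIMATE_VARS}
    return layers


class TestStratifiedSampling:
    @pytest.fixture(scope="class")
    def world(self):
        layers = coarse_world(1)
        rng = np.random.default_rng(2)
        eta = 0.8 * layers["Clim_8"] - 0.5 * layers["Clim_4"]
        status = (rng.random((30, 30)) < expit(eta)).astype(np.int8)
        return RangeGrid(status=status, coarse_factor=10), layers

    def test_equal_presences_and_absences_per_stratum(self, world):
        rg, layers = world
        out = tr.stratified_sample_range(rg, layers, n_bins=2, seed=3)
        counts = out.groupby(["stratum", "presence"]).size().unstack(fill_value=0)
        assert (counts[0] == counts[1]).all()

    def test_single_stratum_reduces_to_balanced_sampling(self, world):
        rg, layers = world
        out = tr.stratified_sample_range(rg, layers, n_bins=1, seed=3)
        assert out["stratum"].nunique() == 1
        assert (out["presence"] == 1).sum() == (out["presence"] == 0).sum()
        m = min(rg.n_presences, rg.n_absences)
        assert (out["presence"] == 1).sum() == m

    def test_same_seed_identical_sample(self, world):
        rg, layers = world
        a = tr.stratified_sample_range(rg, layers, seed=4)
        b = tr.stratified_sample_range(rg, layers, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_grid_rejected(self):
        rg = RangeGrid(status=np.ones((5, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            tr.stratified_sample_range(rg, coarse_world(), seed=0)


class TestHistoricalModel:
    def test_prior_set_has_nine_entries(self):
        layers = coarse_world(5, shape=(25, 25))
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 400)
        sample = pd.DataFrame({v: rng.normal(size=400) for v in tr.CLIMATE_VARS})
        sample["presence"] = y
        fit = fit_historical_model(sample, settings=FAST)
        assert len(fit.prior_set.table) == 9  # intercept + 4 linear + 4 quadratic
        assert list(fit.prior_set.table.index) == ["intercept"] + climate_terms()

    def test_parameter_recovery_within_two_posterior_sds(self):
        rng = np.random.default_rng(6)
        n = 2000
        cols = {v: rng.normal(size=n) for v in tr.CLIMATE_VARS}
        beta = {"intercept": -0.3}
        for k, v in enumerate(tr.CLIMATE_VARS):
            beta[v] = [0.6, -0.4, 0.5, -0.3][k]
            beta[f"{v}_sq"] = [-0.3, -0.2, -0.4, -0.1][k]
        eta = np.full(n, beta["intercept"])
        for v in tr.CLIMATE_VARS:
            eta += beta[v] * cols[v] + beta[f"{v}_sq"] * cols[v] ** 2
        y = (rng.random(n) < expit(eta)).astype(float)
        sample = pd.DataFrame(cols)
        sample["presence"] = y
        fit = fit_historical_model(
            sample,
            settings=SamplerSettings(seed=6),
            standardization={v: (0.0, 1.0) for v in tr.CLIMATE_VARS},
        )
        tab = fit.prior_set.table
        for term, true in beta.items():
            assert abs(tab.loc[term, "mean"] - true) <= 2 * tab.loc[term, "sd"], term

    def test_doubling_the_data_shrinks_every_posterior_sd(self):
        rng = np.random.default_rng(7)
        n = 500
        cols = {v: rng.normal(size=n) for v in tr.CLIMATE_VARS}
        eta = 0.8 * cols["Clim_8"] - 0.4 * cols["Clim_3"] ** 2
        y = (rng.random(n) < expit(eta)).astype(float)
        small = pd.DataFrame(cols)
        small["presence"] = y
        double = pd.concat([small, small], ignore_index=True)
        f1 = fit_historical_model(small, settings=FAST)
        f2 = fit_historical_model(
            double, settings=FAST, standardization=f1.prior_set.standardization
        )
        assert (f2.prior_set.table["sd"] < f1.prior_set.table["sd"]).all()


class TestPrepareOccurrences:
    @pytest.fixture(scope="class")
    def prepared(self):
        rng = np.random.default_rng(8)
        subpop_map = tr.make_subpop_partition((120, 120), 2)
        # subpopulation 0 gets 5000 presence cells, subpopulation 1 gets 300
        cells0 = np.argwhere(subpop_map == 0)
        cells1 = np.argwhere(subpop_map == 1)
        pres = np.vstack(
            [
                cells0[rng.choice(len(cells0), 5000, replace=False)],
                cells1[rng.choice(len(cells1), 300, replace=False)],
            ]
        )
        occ = pd.DataFrame({"row": pres[:, 0], "col": pres[:, 1]})
        sample = tr.prepare_occurrences(occ, subpop_map, seed=9)
        return sample, subpop_map

    def test_cap_limits_presences_per_subpopulation(self, prepared):
        sample, _ = prepared
        pres = sample.table[sample.table["presence"] == 1]
        assert pres.groupby("subpop").size().to_dict() == {0: 2000, 1: 300}

    def test_pseudo_absences_balanced_within_buffer_and_disjoint(self, prepared):
        sample, _ = prepared
        t = sample.table
        pres = t[t["presence"] == 1]
        absn = t[t["presence"] == 0]
        assert pres.groupby("subpop").size().equals(absn.groupby("subpop").size())
        pres_cells = pres[["row", "col"]].to_numpy(float)
        pres_set = {tuple(c) for c in pres[["row", "col"]].to_numpy()}
        rng = np.random.default_rng(10)
        for idx in rng.choice(len(absn), 100, replace=False):  # brute-force distances
            cell = absn.iloc[idx][["row", "col"]].to_numpy(float)
            assert tuple(cell.astype(int)) not in pres_set
            d = np.sqrt(((pres_cells - cell) ** 2).sum(axis=1)).min()
            assert 0 < d <= 5.0

    def test_split_is_exact_and_stratified(self, prepared):
        sample, _ = prepared
        assert sample.n_train_presences == round(0.8 * sample.n_presences)
        t = sample.table
        for subpop, grp in t[t["presence"] == 1].groupby("subpop"):
            frac = (grp["split"] == "train").mean()
            assert abs(frac - 0.8) < 0.01

    def test_water_mask_removes_cells(self):
        subpop_map = np.zeros((20, 20), int)
        occ = pd.DataFrame({"row": [1, 2, 3], "col": [1, 2, 3]})
        mask = np.zeros((20, 20), bool)
        mask[1, 1] = True
        sample = tr.prepare_occurrences(occ, subpop_map, water_mask=mask, seed=0)
        assert sample.n_presences == 2

    def test_largest_remainder_totals_are_exact(self):
        counts = {0: 471, 1: 437, 2: 2000, 3: 1999}
        out = _largest_remainder_split(counts, 0.8)
        assert sum(out.values()) == round(0.8 * sum(counts.values()))
        for g, n in counts.items():
            assert abs(out[g] - 0.8 * n) < 1


class TestSamplingIntensity:
    def test_rounding_contract(self):
        assert sampling_intensity(74, 10) == 7.4
        with pytest.raises(ValueError):
            sampling_intensity(10, 0)


class TestPriorTransfer:
    def simulate_1d(self, seed=11, n=900, beta=0.8):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = (rng.random(n) < expit(beta * x)).astype(float)
        return X, y

    def test_posterior_lies_between_prior_and_flat_posterior(self):
        X, y = self.simulate_1d()
        flat = fit_logistic_mcmc(X, y, [0, 0], [5.0, 2.5], settings=FAST)
        prior_mean = 0.2  # deliberately offset from the truth
        informed = fit_logistic_mcmc(X, y, [0, prior_mean], [5.0, 0.15], settings=FAST)
        flat_b = flat.beta.mean(0)[1]
        inf_b = informed.beta.mean(0)[1]
        lo, hi = sorted([prior_mean, flat_b])
        assert lo - 0.02 <= inf_b <= hi + 0.02

    def test_very_wide_priors_converge_to_flat_fit(self):
        X, y = self.simulate_1d(seed=12)
        flat = fit_logistic_mcmc(X, y, [0, 0], [5.0, 2.5], settings=FAST)
        wide = fit_logistic_mcmc(X, y, [0, 0.2], [5.0, 0.15 * 100], settings=FAST)
        diff = np.abs(flat.beta.mean(0) - wide.beta.mean(0))
        assert np.all(diff < 0.1 * flat.beta.std(0))


class TestFineScaleModels:
    def test_prior_predictive_returns_prior_means(self):
        # hierarchical variant with an empty current dataset: the posterior
        # for the climate coefficients is the transferred prior itself
        names = ["intercept"] + climate_terms(("Clim_8",))
        prior = tr.PriorSet(
            table=pd.DataFrame(
                {"mean": [0.5, 1.2, -0.7], "sd": [0.3, 0.2, 0.25]}, index=names
            ),
            standardization={"Clim_8": (0.0, 1.0)},
        )
        empty = tr.OccurrenceSample(
            table=pd.DataFrame(columns=["row", "col", "subpop", "presence", "split"]),
            cap=2000, train_frac=0.8, pa_buffer_km=5.0, seed=0,
        )
        layers = {"Clim_8": np.zeros((10, 10))}
        model = tr.fit_bayes_model(
            empty, layers, {"climate": ["Clim_8"], "landuse": [], "biotic": []},
            priors=prior, random_intercept=False, settings=FAST,
        )
        means = model.posterior.beta.mean(0)
        assert np.all(np.abs(means - prior.table["mean"].to_numpy()) < 0.05)

    def test_waic_stable_across_sampler_seeds(self, reduced_study):
        blocks = {"climate": ["Clim_8", "Clim_9"], "landuse": [], "biotic": []}
        m1 = tr.fit_bayes_model(
            reduced_study.sample, reduced_study.layers, blocks,
            hierarchical=False, settings=SamplerSettings(seed=21),
        )
        m2 = tr.fit_bayes_model(
            reduced_study.sample, reduced_study.layers, blocks,
            hierarchical=False, settings=SamplerSettings(seed=22),
        )
        assert abs(m1.waic - m2.waic) < 2 * max(m1.waic_se, m2.waic_se)

    def test_compare_waic_table_sorted_with_zero_self_delta(self, reduced_study):
        blocks = {"climate": ["Clim_8", "Clim_9"], "landuse": [], "biotic": []}
        m = tr.fit_bayes_model(
            reduced_study.sample, reduced_study.layers, blocks,
            hierarchical=False, settings=FAST,
        )
        null = tr.fit_bayes_model(
            reduced_study.sample, reduced_study.layers,
            {"climate": [], "landuse": [], "biotic": []}, settings=FAST,
        )
        table = tr.compare_waic([null, m])
        assert table.iloc[0]["delta_waic"] == 0.0
        assert table["waic"].is_monotonic_increasing
        assert table.iloc[0]["variant"] == "abiotic"


class TestThreshold:
    def test_perfect_model_has_unit_tnr_and_ninety_pct_tpr(self):
        rng = np.random.default_rng(13)
        sep = np.zeros((40, 40))
        sep[:, 20:] = 4.0  # presences live on the right half
        rows = rng.integers(0, 40, 400)
        cols = np.r_[rng.integers(20, 40, 200), rng.integers(0, 20, 200)]
        table = pd.DataFrame(
            {
                "row": rows, "col": cols, "subpop": 0,
                "presence": np.r_[np.ones(200), np.zeros(200)],
                "split": np.where(rng.random(400) < 0.8, "train", "validation"),
            }
        )
        sample = tr.OccurrenceSample(table, cap=2000, train_frac=0.8, pa_buffer_km=5, seed=0)
        model = tr.fit_bayes_model(
            sample, {"sep": sep}, {"climate": [], "landuse": [], "biotic": ["sep"]},
            random_intercept=False, settings=FAST,
        )
        report = tr.threshold_and_evaluate(model, sample, {"sep": sep})
        assert report.tnr_train == pytest.approx(1.0)
        assert report.tnr_validation == pytest.approx(1.0)
        # tied (near-1) presence scores: the cutoff keeps at least 90%
        assert report.tpr_train >= 0.90

    def test_validation_rates_use_only_held_out_cells(self, reduced_study):
        model = tr.fit_bayes_model(
            reduced_study.sample, reduced_study.layers,
            {"climate": ["Clim_8", "Clim_9"], "landuse": [], "biotic": []},
            hierarchical=False, settings=FAST,
        )
        report = tr.threshold_and_evaluate(model, reduced_study.sample, reduced_study.layers)
        t = reduced_study.sample.table
        train_cells = set(map(tuple, t[t["split"] == "train"][["row", "col"]].to_numpy()))
        val_cells = set(map(tuple, t[t["split"] == "validation"][["row", "col"]].to_numpy()))
        assert not train_cells & val_cells
        assert np.isfinite(report.tpr_validation)
        n_tr_pres = ((t["presence"] == 1) & (t["split"] == "train")).sum()
        assert abs(report.tpr_train - 0.90) <= 1.5 / n_tr_pres + 1e-9
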