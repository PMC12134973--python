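"""Dietary energetics: imputation, rEDEC arithmetic and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trophicrange as tr
from trophicrange.diet import DietStudy, studies_to_frame


def make_study(rvals, study_id="s1", subpop=0, z=100, rv=None, species=None, categories=None,
               origins=None, cf=None):
    n = len(rvals)
    items = pd.DataFrame(
        {
            "item_id": [f"item{i}" for i in range(n)],
            "species_id": species if species is not None else [f"sp{i}" for i in range(n)],
            "category": categories if categories is not None else ["vertebrates"] * n,
            "origin": origins if origins is not None else ["wild"] * n,
            "f": np.asarray(rvals) * 100,
            "rF": rvals,
            "rV": rv if rv is not None else rvals,
            "cf_e": cf if cf is not None else 1.0,
        }
    )
    return DietStudy(study_id=study_id, subpop=subpop, row=0, col=0,
                     sample_type="scat", z=z, items=items)


class TestImputeRv:
    def test_complete_studies_returned_unchanged(self):
        studies = [make_study([0.6, 0.4]), make_study([0.3, 0.7], study_id="s2")]
        out, report = tr.impute_rv(studies, seed=0)
        assert report.n_imputed_items == 0
        for a, b in zip(studies, out):
            pd.testing.assert_frame_equal(a.items, b.items)

    def test_exact_linear_relation_imputes_rf(self):
        complete = [
            make_study([0.6, 0.4]),
            make_study([0.2, 0.3, 0.5], study_id="s2"),
        ]
        missing = make_study([0.7, 0.3], study_id="s3", rv=[np.nan, np.nan])
        out, report = tr.impute_rv(complete + [missing], seed=0)
        imputed = out[2].items
        assert report.r == pytest.approx(1.0)
        assert np.allclose(imputed["rV"], [0.7, 0.3], atol=1e-9)
        assert imputed["rv_imputed"].all()

    def test_observed_values_never_altered(self):
        rng = np.random.default_rng(3)
        studies = []
        for k in range(4):
            rf = rng.dirichlet(np.ones(5) * 2)
            rv = rng.dirichlet(np.ones(5) * 2)
            studies.append(make_study(rf, study_id=f"c{k}", rv=rv))
        studies.append(make_study(rng.dirichlet(np.ones(4)), study_id="m", rv=[np.nan] * 4))
        out, _ = tr.impute_rv(studies, seed=1)
        for orig, new in zip(studies[:4], out[:4]):
            assert np.array_equal(orig.items["rV"], new.items["rV"])
            assert not new.items["rv_imputed"].any()

    def test_bootstrap_ci_covers_generator_target_in_most_replicates(self):
        subpop_map = tr.make_subpop_partition((40, 40), 2)
        hits = 0
        for rep in range(50):
            cfg = tr.default_diet_config([0, 1], seed=rep, studies_per_subpop=6,
                                         missing_rv_fraction=0.25)
            studies = tr.generate_diet_studies(cfg, subpop_map, seed=rep + 500)
            _, report = tr.impute_rv(studies, n_bootstrap=400, seed=rep)
            hits += report.ci_low <= cfg.target_corr <= report.ci_high
        assert hits >= 45  # >= 90% coverage of the generating correlation

    def test_errors_without_complete_studies_or_variance(self):
        with pytest.raises(ValueError):
            tr.impute_rv([make_study([0.6, 0.4], rv=[np.nan, np.nan])], seed=0)
        constant = [make_study([0.5, 0.5]), make_study([0.5, 0.5], study_id="s2")]
        with pytest.raises(ValueError):
            tr.impute_rv(constant, seed=0)


class TestComputeRedec:
    def test_worked_example_two_items(self):
        # rEDC (0.6, 0.4) with CF_E (2, 1) -> (0.75, 0.25)
        study = make_study([0.6, 0.4], cf=[2.0, 1.0])
        out = tr.compute_redec(study)
        assert np.allclose(out.items["rEDEC"], [0.75, 0.25])
        assert np.allclose(out.items["rEDC"], [0.6, 0.4])

    def test_equal_cf_leaves_shares_unchanged(self):
        study = make_study([0.2, 0.5, 0.3], cf=[3.0, 3.0, 3.0])
        out = tr.compute_redec(study)
        assert np.allclose(out.items["rEDEC"], out.items["rEDC"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.lists(st.floats(0.1, 5.0), min_size=6, max_size=6),
        st.floats(0.1, 10.0),
    )
    def test_invariant_to_common_cf_scaling_and_sums_to_one(self, raw, cfs, scale):
        rv = np.asarray(raw) / np.sum(raw)
        cf = np.asarray(cfs[: len(rv)])
        a = tr.compute_redec(make_study(rv, cf=cf))
        b = tr.compute_redec(make_study(rv, cf=cf * scale))
        assert np.allclose(a.items["rEDEC"], b.items["rEDEC"], atol=1e-9)
        assert a.items["rEDEC"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_cf_table_lookup_item_then_category_then_error(self):
        study = make_study([0.5, 0.5], categories=["vertebrates", "invertebrates"])
        cf_table = pd.DataFrame(
            {
                "item_id": ["item0", None],
                "category": [None, "invertebrates"],
                "cf_e": [2.0, 4.0],
            }
        )
        out = tr.compute_redec(study, cf_table)
        assert np.allclose(out.items["cf_e"], [2.0, 4.0])
        with pytest.raises(KeyError):
            tr.compute_redec(study, cf_table[cf_table["item_id"] == "item0"])

    def test_incomplete_rv_rejected(self):
        with pytest.raises(ValueError):
            tr.compute_redec(make_study([0.6, 0.4], rv=[np.nan, 0.4]))


class TestAggregateSubpopulation:
    def test_single_study_identity(self):
        s = tr.compute_redec(make_study([0.6, 0.4]))
        diet = tr.aggregate_subpopulation_diet([s], 0)
        assert diet.species_redec("sp0") == pytest.approx(0.6)
        assert diet.species_redec("sp1") == pytest.approx(0.4)

    def test_z_weighted_worked_example(self):
        # Z = (100, 50), species rEDEC (0.3, 0.0) -> 0.2
        s1 = tr.compute_redec(make_study([0.3, 0.7], species=["A", "B"], z=100))
        s2 = tr.compute_redec(make_study([0.5, 0.5], species=["C", "B"], study_id="s2", z=50))
        diet = tr.aggregate_subpopulation_diet([s1, s2], 0)
        assert diet.species_redec("A") == pytest.approx(0.2)

    def test_species_absent_everywhere_is_zero(self):
        s = tr.compute_redec(make_study([1.0], species=["A"]))
        diet = tr.aggregate_subpopulation_diet([s], 0)
        assert diet.species_redec("Unseen species") == 0.0

    def test_equal_z_equals_unweighted_mean_and_dominant_z_converges(self):
        s1 = tr.compute_redec(make_study([0.8, 0.2], species=["A", "B"], z=70))
        s2 = tr.compute_redec(make_study([0.4, 0.6], species=["A", "B"], study_id="s2", z=70))
        diet = tr.aggregate_subpopulation_diet([s1, s2], 0)
        assert diet.species_redec("A") == pytest.approx(0.6)
        s2_dom = tr.compute_redec(
            make_study([0.4, 0.6], species=["A", "B"], study_id="s2", z=70000)
        )
        dom = tr.aggregate_subpopulation_diet([s1, s2_dom], 0)
        assert dom.species_redec("A") == pytest.approx(0.4, abs=1e-3)

    def test_unresolved_items_account_for_remainder(self):
        s = tr.compute_redec(
            make_study([0.5, 0.3, 0.2], species=["A", "B", np.nan])
        )
        diet = tr.aggregate_subpopulation_diet([s], 0)
        assert diet.species["redec"].sum() + diet.unresolved == pytest.approx(1.0, abs=1e-9)
        assert diet.unresolved == pytest.approx(0.2)

    def test_empty_subpopulation_rejected(self):
        s = tr.compute_redec(make_study([1.0]))
        with pytest.raises(ValueError):
            tr.aggregate_subpopulation_diet([s], 42)


class TestClassifyItems:
    def test_single_category_share_is_one(self):
        s = tr.compute_redec(make_study([0.6, 0.4]))
        cat, orig = tr.classify_items(s)
        assert cat["vertebrates"] == pytest.approx(1.0)
        assert cat.sum() == pytest.approx(1.0)
        assert orig["wild"] == pytest.approx(1.0)

    def test_shares_match_hand_summed_labels_and_are_order_invariant(self):
        rv = [0.1, 0.2, 0.3, 0.4]
        cats = ["vertebrates", "invertebrates", "vertebrates", "reproductive plants"]
        origs = ["wild", "wild", "human-derived", "wild"]
        s = tr.compute_redec(make_study(rv, categories=cats, origins=origs))
        cat, orig = tr.classify_items(s)
        assert cat["vertebrates"] == pytest.approx(0.4)
        assert cat["reproductive plants"] == pytest.approx(0.4)
        assert orig["human-derived"] == pytest.approx(0.3)
        perm = [3, 1, 0, 2]
        s2 = tr.compute_redec(
            make_study(
                [rv[i] for i in perm],
                categories=[cats[i] for i in perm],
                origins=[origs[i] for i in perm],
            )
        )
        cat2, orig2 = tr.classify_items(s2)
        pd.testing.assert_series_equal(cat, cat2)
        pd.testing.assert_series_equal(orig, orig2)

    def test_unknown_category_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_study([1.0], categories=["unicorns"])


class TestStudyValidationAndIO:
    def test_invalid_study_metadata_rejected(self):
        with pytest.raises(ValueError):
            make_study([1.0], z=0)
        with pytest.raises(ValueError):
            DietStudy("s", 0, 0, 0, "scat", 10, pd.DataFrame(columns=["rF"]))

    def test_csv_roundtrip(self, tmp_path):
        studies = [tr.compute_redec(make_study([0.6, 0.4])),
                   tr.compute_redec(make_study([0.2, 0.8], study_id="s2", subpop=1))]
        path = tmp_path / "diet.csv"
        tr.write_studies_csv(path, studies)
        back = tr.read_studies_csv(path)
        assert len(back) == 2
        assert np.allclose(back[0].items["rEDEC"], studies[0].items["rEDEC"])
        assert back[1].subpop == 1 and back[1].z == 100
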