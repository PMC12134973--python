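"""Shared fixtures: small landscapes, a full pipeline run, and the reduced
replicate study used by the model-comparison and parameter-recovery checks."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import trophicrange as tr
from trophicrange.diet import SubpopulationDiet

logging.disable(logging.WARNING)

REDUCED_CLIMATE = ("Clim_8", "Clim_9")
REDUCED_LANDUSE = ["Urban", "Broadleaved Forest"]


@pytest.fixture(scope="session")
def small_landscape() -> tr.GridStack:
    return tr.generate_landscape(tr.LandscapeConfig(rows=80, cols=80, seed=11))


@pytest.fixture(scope="session")
def pipeline_result():
    """One full synthetic study (landscape -> diets -> food SDMs -> biotic
    layers -> hierarchical model -> threshold), shared across tests."""
    from trophicrange.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(seed=1))


@dataclass
class ReducedStudy:
    """A compact abiotic + biotic world with known truth (2 climate, 2
    land-use, 2 biotic predictors, 4 subpopulations on a 100x100 grid)."""

    landscape: tr.GridStack
    subpop_map: np.ndarray
    biotic_set: Dict[str, np.ndarray]
    biotic_names: Tuple[str, str]
    truth: tr.FocalTruth
    truth_model: tr.TrueOccurrenceModel
    sample: tr.OccurrenceSample
    layers: Dict[str, np.ndarray]

    def true_coefficients(self) -> Dict[str, float]:
        tm = self.truth_model
        out = {"intercept": tm.intercept}
        for v, (b1, b2) in tm.climate.items():
            out[v] = b1
            out[f"{v}_sq"] = b2
        for v, b in tm.landuse.items():
            out[v] = b
        for v, b in tm.biotic.items():
            out[v] = b
        return out


def make_reduced_study(seed: int) -> ReducedStudy:
    cfg = tr.LandscapeConfig(
        rows=100,
        cols=100,
        climate_layers=REDUCED_CLIMATE,
        landuse_layers=tuple(REDUCED_LANDUSE),
        scenarios={"none": {}},
        coarse_factor=10,
        seed=seed,
    )
    landscape = tr.generate_landscape(cfg)
    subpop_map = tr.make_subpop_partition(landscape.shape, 4)
    niches = [
        tr.TrueNiche(
            "sp_fruit", {"Clim_8": (0.8, -0.7)}, intercept=-0.5, category="reproductive plants"
        ),
        tr.TrueNiche(
            "sp_deer",
            {"Clim_9": (-0.6, -0.5), "Broadleaved Forest": (0.8, 0.0)},
            intercept=-0.4,
            category="vertebrates",
        ),
    ]
    stand = landscape.standardization()
    suitability = {
        n.species_id: expit(n.linear_predictor(landscape.layers, stand)) for n in niches
    }
    redecs = {0: [0.5, 0.3], 1: [0.6, 0.2], 2: [0.4, 0.45], 3: [0.3, 0.5]}
    diets = {}
    for sp in range(4):
        species = pd.DataFrame(
            {
                "category": ["reproductive plants", "vertebrates"],
                "origin": ["wild", "wild"],
                "redec": redecs[sp],
            },
            index=pd.Index(["sp_fruit", "sp_deer"], name="species_id"),
        )
        diets[sp] = SubpopulationDiet(
            sp, species, category_redec=pd.Series(dtype=float),
            origin_redec=pd.Series(dtype=float), n_studies=1, total_z=100,
        )
    biotic_set = tr.build_layer_set(diets, suitability, subpop_map)
    b_repro = tr.layer_name("reproductive plants")
    b_vert = tr.layer_name("vertebrates")
    truth_model = tr.TrueOccurrenceModel(
        intercept=-1.0,
        climate={"Clim_8": (0.5, -0.45), "Clim_9": (-0.4, -0.35)},
        landuse={"Urban": -0.5, "Broadleaved Forest": 0.5},
        biotic={b_repro: 0.6, b_vert: 0.5},
    )
    truth = tr.generate_focal_occurrences(
        truth_model, landscape, biotic_set, seed=seed + 1, n_subpops=4, coarse_factor=10
    )
    sample = tr.prepare_occurrences(truth.presences, truth.subpop_map, seed=seed + 2)
    layers = dict(landscape.layers)
    layers.update(biotic_set)
    return ReducedStudy(
        landscape=landscape,
        subpop_map=subpop_map,
        biotic_set=biotic_set,
        biotic_names=(b_repro, b_vert),
        truth=truth,
        truth_model=truth_model,
        sample=sample,
        layers=layers,
    )


def fit_reduced_variants(study: ReducedStudy, seed: int, variants=("abiotic+biotic", "abiotic", "null")):
    """Historical priors plus the requested fine-scale variants, sharing the
    generator's standardization so coefficients are comparable with truth."""
    settings = tr.SamplerSettings(seed=seed)
    coarse = study.landscape.block_reduce(10)
    coarse_sample = tr.stratified_sample_range(
        study.truth.range_grid, coarse.layers, n_bins=2, seed=seed + 3,
        variables=REDUCED_CLIMATE,
    )
    hist = tr.fit_historical_model(
        coarse_sample,
        variables=REDUCED_CLIMATE,
        settings=settings.scaled(0.5),
        standardization={v: study.truth.standardization[v] for v in REDUCED_CLIMATE},
    )
    models = {}
    for variant in variants:
        blocks = tr.variant_blocks(
            variant, REDUCED_CLIMATE, REDUCED_LANDUSE, list(study.biotic_names)
        )
        st = settings if variant != "null" else settings.scaled(0.5)
        models[variant] = tr.fit_bayes_model(
            study.sample,
            study.layers,
            blocks,
            priors=hist.prior_set if blocks["climate"] else None,
            variant=variant,
            settings=st,
            standardization=study.truth.standardization,
        )
    return hist, models


@pytest.fixture(scope="session")
def reduced_study() -> ReducedStudy:
    return make_reduced_study(2024)


@pytest.fixture(scope="session")
def replicate_study():
    """20 seeded replicates of the reduced study: per replicate, the WAIC of
    the abiotic+biotic / abiotic / null variants and the 90% credible-interval
    coverage of the generating coefficients under the hierarchical model."""
    results: List[dict] = []
    for rep in range(20):
        seed = 1000 + 37 * rep
        study = make_reduced_study(seed)
        _, models = fit_reduced_variants(study, seed)
        truth_map = study.true_coefficients()
        ci = models["abiotic+biotic"].posterior.credible_interval(0.90)
        covered = [
            float(ci.loc[t, "low"] <= truth_map[t] <= ci.loc[t, "high"]) for t in ci.index
        ]
        results.append(
            {
                "seed": seed,
                "waic": {v: m.waic for v, m in models.items()},
                "coverage": covered,
            }
        )
    return results
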