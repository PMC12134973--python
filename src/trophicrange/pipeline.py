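"""End-to-end synthetic study: generate, fit, compare, threshold, project.

Glue that strings the modules together on a fully synthetic landscape:
landscape -> food-species occurrences -> food SDM ensembles -> suitability
(current + scenarios) -> diet studies -> imputation -> rEDEC ->
subpopulation diets -> biotic layers -> focal occurrences (from a known
abiotic + biotic truth) -> occurrence preparation -> historical priors ->
fine-scale model variants -> WAIC comparison -> threshold/evaluation.
Used by the examples and the acceptance script; every knob defaults to the
study conditions described in docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import biotic as bt
from . import diet as dt
from . import foodsdm as fs
from .bayes import SamplerSettings
from .bearsdm import (
    CLIMATE_VARS,
    EvaluationReport,
    FittedBayesModel,
    HistoricalFit,
    OccurrenceSample,
    compare_waic,
    fit_bayes_model,
    fit_historical_model,
    prepare_occurrences,
    select_block_variables,
    stratified_sample_range,
    variant_blocks,
)
from .grids import GridStack
from .synth import (
    LANDUSE_LAYERS,
    FocalTruth,
    LandscapeConfig,
    TrueOccurrenceModel,
    default_diet_config,
    default_niches,
    generate_diet_studies,
    generate_focal_occurrences,
    generate_food_species,
    generate_landscape,
)

logger = logging.getLogger(__name__)


def default_focal_model() -> TrueOccurrenceModel:
    """The known focal-species truth: bell-shaped climate responses, a
    negative urban and positive forest/natural association, and positive
    energy (biotic) effects from the plant and vertebrate categories."""
    return TrueOccurrenceModel(
        intercept=-0.8,
        climate={
            "Clim_3": (0.5, -0.45),
            "Clim_4": (-0.4, -0.35),
            "Clim_8": (0.45, -0.4),
            "Clim_9": (-0.3, -0.3),
        },
        landuse={
            "Urban": -0.6,
            "Broadleaved Forest": 0.5,
            "Coniferous Forest": 0.35,
            "Natural Landscape": 0.45,
        },
        biotic={
            bt.layer_name("reproductive plants"): 0.6,
            bt.layer_name("vertebrates"): 0.5,
            bt.layer_name("unknown plants"): 0.3,
            bt.layer_name("invertebrates"): -0.25,
        },
    )


@dataclass
class PipelineConfig:
    """Study conditions of the synthetic end-to-end run."""

    rows: int = 100
    cols: int = 100
    coarse_factor: int = 10
    n_subpops: int = 4
    seed: int = 0
    cap: int = 2000
    train_frac: float = 0.8
    pa_buffer_km: float = 5.0
    n_bins_strata: int = 2
    annulus_inner_km: float = 3.0
    annulus_outer_km: float = 10.0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    focal_model: Optional[TrueOccurrenceModel] = None
    fit_variants: Tuple[str, ...] = ("abiotic+biotic", "abiotic", "null")
    studies_per_subpop: int = 3
    missing_rv_fraction: float = 0.3


@dataclass
class PipelineResult:
    landscape: GridStack
    food_models: Dict[str, fs.EnsembleModel]
    suitability: Dict[str, Dict[str, np.ndarray]]  # scenario -> species -> map
    diet_studies: List[dt.DietStudy]
    diets: Dict[int, dt.SubpopulationDiet]
    biotic_sets: Dict[str, Dict[str, np.ndarray]]  # scenario -> layer -> map
    truth: FocalTruth
    sample: OccurrenceSample
    historical: HistoricalFit
    models: Dict[str, FittedBayesModel]
    waic_table: pd.DataFrame
    evaluation: EvaluationReport
    layers_all: Dict[str, np.ndarray]  # abiotic + current biotic layers


def build_biotic_sets(
    diets: Mapping[int, dt.SubpopulationDiet],
    suitability: Mapping[str, Mapping[str, np.ndarray]],
    subpop_map: np.ndarray,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Biotic layer sets for every scenario (current diets throughout)."""
    return {
        scen: bt.build_layer_set(diets, suit, subpop_map)
        for scen, suit in suitability.items()
    }


def run_pipeline(config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full synthetic study and fit the requested model variants."""
    config = config or PipelineConfig()
    seed = config.seed
    rng = np.random.default_rng(seed)

    # --- landscape and food species -------------------------------------
    lcfg = LandscapeConfig(
        rows=config.rows, cols=config.cols, coarse_factor=config.coarse_factor, seed=seed
    )
    landscape = generate_landscape(lcfg)
    niches = default_niches()
    occ, food_truth = generate_food_species(niches, landscape, seed=seed + 1)

    # --- food SDMs and suitability under every scenario ------------------
    food_models: Dict[str, fs.EnsembleModel] = {}
    candidates = list(landscape.layer_names)
    for niche in niches:
        pg = fs.grid_presences(occ, niche.species_id, landscape.shape)
        if pg.excluded:
            logger.info("species %s below presence threshold; skipped", niche.species_id)
            continue
        try:
            absences = fs.sample_pseudoabsences_annulus(
                pg,
                inner_km=config.annulus_inner_km,
                outer_km=config.annulus_outer_km,
                seed=int(rng.integers(2**31 - 1)),
            )
        except ValueError as exc:
            logger.warning("species %s: %s", niche.species_id, exc)
            continue
        pa = fs.make_pa_table(pg.cells, absences, landscape.layers)
        variables = fs.select_species_variables(pa, candidates)
        food_models[niche.species_id] = fs.fit_ensemble(
            pa, variables, seed=int(rng.integers(2**31 - 1)), species_id=niche.species_id
        )
    scen_ids = ["current", *landscape.scenario_names]
    suitability = {
        scen: {
            sid: fs.predict_suitability(m, landscape, None if scen == "current" else scen)
            for sid, m in food_models.items()
        }
        for scen in scen_ids
    }

    # --- diets ------------------------------------------------------------
    subpop_map = None  # defined with the focal truth below; diets need it first
    from .grids import make_subpop_partition

    subpop_map = make_subpop_partition(landscape.shape, config.n_subpops)
    diet_cfg = default_diet_config(
        sorted(np.unique(subpop_map).tolist()),
        seed=seed + 2,
        studies_per_subpop=config.studies_per_subpop,
        missing_rv_fraction=config.missing_rv_fraction,
    )
    studies = generate_diet_studies(diet_cfg, subpop_map, seed=seed + 3)
    studies, _ = dt.impute_rv(studies, seed=seed + 4)
    studies = [dt.compute_redec(s) for s in studies]
    diets = {
        sp: dt.aggregate_subpopulation_diet(studies, sp)
        for sp in sorted(np.unique(subpop_map).tolist())
    }

    # --- biotic layers and focal truth ------------------------------------
    biotic_sets = build_biotic_sets(diets, suitability, subpop_map)
    focal_model = config.focal_model or default_focal_model()
    truth = generate_focal_occurrences(
        focal_model,
        landscape,
        biotic_sets["current"],
        seed=seed + 5,
        n_subpops=config.n_subpops,
        coarse_factor=config.coarse_factor,
    )

    # --- occurrence sample and historical priors ---------------------------
    sample = prepare_occurrences(
        truth.presences,
        truth.subpop_map,
        cap=config.cap,
        train_frac=config.train_frac,
        pa_buffer_km=config.pa_buffer_km,
        seed=seed + 6,
    )
    coarse = landscape.block_reduce(config.coarse_factor)
    coarse_sample = stratified_sample_range(
        truth.range_grid, coarse.layers, n_bins=config.n_bins_strata, seed=seed + 7
    )
    hist_settings = config.sampler.scaled(0.7)
    hist_settings.seed = seed + 8
    historical = fit_historical_model(coarse_sample, settings=hist_settings)

    # --- fine-scale models --------------------------------------------------
    layers_all = dict(landscape.layers)
    layers_all.update(biotic_sets["current"])
    landuse_sel = select_block_variables(
        sample.table, layers_all, list(LANDUSE_LAYERS), k=4
    )
    biotic_candidates = [bt.layer_name(c) for c in dt.CATEGORIES]
    biotic_sel = select_block_variables(sample.table, layers_all, biotic_candidates, k=4)

    models: Dict[str, FittedBayesModel] = {}
    for k, variant in enumerate(config.fit_variants):
        blocks = variant_blocks(variant, CLIMATE_VARS, landuse_sel, biotic_sel)
        st = config.sampler.scaled(1.0)
        st.seed = seed + 10 + k
        models[variant] = fit_bayes_model(
            sample,
            layers_all,
            blocks,
            priors=historical.prior_set if blocks["climate"] else None,
            variant=variant,
            settings=st,
        )
    waic_table = compare_waic(list(models.values()))

    best_variant = waic_table.iloc[0]["variant"]
    evaluation = threshold_and_evaluate_best(
        models[best_variant], sample, layers_all, truth.subpop_map
    )
    return PipelineResult(
        landscape=landscape,
        food_models=food_models,
        suitability=suitability,
        diet_studies=studies,
        diets=diets,
        biotic_sets=biotic_sets,
        truth=truth,
        sample=sample,
        historical=historical,
        models=models,
        waic_table=waic_table,
        evaluation=evaluation,
        layers_all=layers_all,
    )


def threshold_and_evaluate_best(model, sample, layers, subpop_map):
    from .bearsdm import threshold_and_evaluate

    return threshold_and_evaluate(model, sample, layers, subpop_map=subpop_map)
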