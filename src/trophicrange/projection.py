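"""Scenario projection, range-change descriptors and biotic sensitivity.

The fitted fine-scale model is projected under each coupled climate/land-use
scenario in three change modes — abiotic + biotic, abiotic-only (biotic
layers pinned to current), biotic-only (abiotic pinned to current) — using
the single current-conditions threshold throughout.  Predictions are masked
to a 200-km buffer around the current predicted distribution to avoid
extrapolating trophic information into space with no diet data.  Range
descriptors (area, % change, % protected, % occupied) are reported overall
and per subpopulation.  The biotic sensitivity analysis refits the
abiotic + biotic model with the biotic inputs replaced by their lower and
upper uncertainty bounds and correlates the resulting prediction maps with
the original.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bayes import SamplerSettings
from .bearsdm import FittedBayesModel, OccurrenceSample, fit_bayes_model
from .grids import GridStack, distance_to_cells

logger = logging.getLogger(__name__)

MODES = ("abiotic+biotic", "abiotic", "biotic")


@dataclass
class ScenarioRun:
    """One projected scenario x change-mode prediction."""

    scenario: str
    mode: str
    probability: np.ndarray
    binary: np.ndarray  # bool, already masked
    mask: np.ndarray  # bool: cells within buffer_km of the current range


def _merge_layers(
    abiotic: Mapping[str, np.ndarray], biotic: Mapping[str, np.ndarray]
) -> Dict[str, np.ndarray]:
    out = dict(abiotic)
    out.update(biotic)
    return out


def project_scenarios(
    model: FittedBayesModel,
    landscape: GridStack,
    biotic_sets: Mapping[str, Mapping[str, np.ndarray]],
    threshold: Optional[float] = None,
    subpop_map: Optional[np.ndarray] = None,
    buffer_km: float = 200.0,
    scenarios: Optional[Sequence[str]] = None,
    modes: Sequence[str] = MODES,
) -> Tuple[ScenarioRun, List[ScenarioRun]]:
    """Project the model for the current state and all scenario x mode runs.

    ``biotic_sets`` maps scenario ids (plus ``"current"``) to their biotic
    layer dictionaries.  Per mode, the non-changing block is pinned to its
    current layers.  Returns the current run and the scenario runs.
    """
    threshold = model.threshold if threshold is None else threshold
    if threshold is None:
        raise ValueError("no threshold: evaluate the model first or pass one")
    if "current" not in biotic_sets:
        raise KeyError("biotic_sets must include 'current'")
    scenarios = list(landscape.scenario_names) if scenarios is None else list(scenarios)
    for s in scenarios:
        if s not in biotic_sets:
            raise KeyError(f"biotic layer set missing for scenario {s!r}")

    cur_layers = _merge_layers(landscape.layers_for(None), biotic_sets["current"])
    cur_prob = model.predict_map(cur_layers, subpop_map=subpop_map)
    cur_binary = np.where(np.isnan(cur_prob), False, cur_prob >= threshold)
    mask = distance_to_cells(cur_binary, landscape.cell_km) <= buffer_km
    current = ScenarioRun(
        scenario="current",
        mode="current",
        probability=cur_prob,
        binary=cur_binary & mask,
        mask=mask,
    )

    runs: List[ScenarioRun] = []
    for scen in scenarios:
        for mode in modes:
            if mode not in MODES:
                raise ValueError(f"unknown change mode {mode!r}")
            abi = landscape.layers_for(scen if mode in ("abiotic+biotic", "abiotic") else None)
            bio = biotic_sets[scen if mode in ("abiotic+biotic", "biotic") else "current"]
            prob = model.predict_map(_merge_layers(abi, bio), subpop_map=subpop_map)
            prob = np.where(mask, prob, np.nan)
            binary = np.where(np.isnan(prob), False, prob >= threshold)
            runs.append(
                ScenarioRun(scenario=scen, mode=mode, probability=prob, binary=binary, mask=mask)
            )
    return current, runs


def range_descriptors(
    runs: Sequence[ScenarioRun],
    current: ScenarioRun,
    subpop_map: np.ndarray,
    protected_mask: Optional[np.ndarray] = None,
    observed_presences: Optional[pd.DataFrame] = None,
    cell_area_km2: float = 1.0,
) -> pd.DataFrame:
    """Range areas, % change vs current, % protected and % occupied.

    One row per run x (overall + each subpopulation).  % change is
    100 * (future - current) / current; % protected the share of predicted
    presence cells on the protected mask; % occupied the share of predicted
    presence cells holding an observed presence.
    """
    obs_mask = None
    if observed_presences is not None:
        obs_mask = np.zeros(subpop_map.shape, dtype=bool)
        obs_mask[
            observed_presences["row"].to_numpy(int), observed_presences["col"].to_numpy(int)
        ] = True
    if (subpop_map[current.mask] < 0).any():
        raise ValueError("subpop_map does not cover the prediction mask")

    subpops = [s for s in np.unique(subpop_map) if s >= 0]
    rows = []
    for run in [current, *runs]:
        for scope in ["all", *subpops]:
            sel = np.ones(subpop_map.shape, bool) if scope == "all" else subpop_map == scope
            pred = run.binary & sel
            cur = current.binary & sel
            area = pred.sum() * cell_area_km2
            cur_area = cur.sum() * cell_area_km2
            rows.append(
                {
                    "scenario": run.scenario,
                    "mode": run.mode,
                    "subpop": scope,
                    "area_km2": float(area),
                    "pct_change": float(100.0 * (area - cur_area) / cur_area)
                    if cur_area > 0
                    else np.nan,
                    "pct_protected": float(100.0 * (pred & protected_mask).sum() / pred.sum())
                    if protected_mask is not None and pred.sum() > 0
                    else np.nan,
                    "pct_occupied": float(100.0 * (pred & obs_mask).sum() / pred.sum())
                    if obs_mask is not None and pred.sum() > 0
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Refits of the model at the biotic-layer uncertainty extremes."""

    fit_lower: FittedBayesModel
    fit_upper: FittedBayesModel
    coefficient_shift: pd.DataFrame  # original, lower, upper posterior means
    corr_lower: float
    corr_upper: float
    prob_original: np.ndarray
    prob_lower: np.ndarray
    prob_upper: np.ndarray


def sensitivity_biotic(
    model: FittedBayesModel,
    sample: OccurrenceSample,
    layers: Mapping[str, np.ndarray],
    lower: Mapping[str, np.ndarray],
    upper: Mapping[str, np.ndarray],
    subpop_map: np.ndarray,
    priors=None,
    settings: Optional[SamplerSettings] = None,
) -> SensitivityReport:
    """Propagate biotic-layer uncertainty through the model.

    The abiotic + biotic model is refitted twice with every biotic predictor
    replaced by its lower, then upper, bound raster (e.g. the envelope of
    the food-SDM ensemble members); the report gives the coefficient shifts
    and the Pearson correlation of each bound run's current prediction map
    with the original.  Bound layers must satisfy lower <= upper cellwise.
    """
    biotic_vars = model.blocks.get("biotic", [])
    if not biotic_vars:
        raise ValueError("model has no biotic block to perturb")
    for v in biotic_vars:
        lo, up = np.asarray(lower[v]), np.asarray(upper[v])
        both = np.isfinite(lo) & np.isfinite(up)
        if (lo[both] > up[both] + 1e-12).any():
            raise ValueError(f"bounds inverted for layer {v!r}")

    fits = {}
    probs = {}
    for tag, bounds in (("lower", lower), ("upper", upper)):
        lay = dict(layers)
        for v in biotic_vars:
            lay[v] = np.asarray(bounds[v], dtype=float)
        fit = fit_bayes_model(
            sample,
            lay,
            model.blocks,
            priors=priors,
            variant=model.variant,
            hierarchical=model.hierarchical,
            random_intercept=model.random_intercept,
            settings=settings,
            standardization=model.design.standardization,
        )
        fits[tag] = fit
        probs[tag] = fit.predict_map(lay, subpop_map=subpop_map)

    prob0 = model.predict_map(layers, subpop_map=subpop_map)

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        ok = np.isfinite(a) & np.isfinite(b)
        return float(np.corrcoef(a[ok], b[ok])[0, 1])

    shift = pd.DataFrame(
        {
            "original": model.posterior.coef_summary()["mean"],
            "lower": fits["lower"].posterior.coef_summary()["mean"],
            "upper": fits["upper"].posterior.coef_summary()["mean"],
        }
    )
    return SensitivityReport(
        fit_lower=fits["lower"],
        fit_upper=fits["upper"],
        coefficient_shift=shift,
        corr_lower=_corr(probs["lower"], prob0),
        corr_upper=_corr(probs["upper"], prob0),
        prob_original=prob0,
        prob_lower=probs["lower"],
        prob_upper=probs["upper"],
    )
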