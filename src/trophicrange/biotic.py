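"""Spatial biotic-interaction variables from diets and habitat suitability.

The quantitative biotic layer for a food category is, in every cell x of
subpopulation Subp,

    Biotic_cat(x) = sum_{S in cat} rEDEC_SubpS * HS_S(x),

the diet-weighted sum of the food species' habitat suitabilities; the binary
variant replaces rEDEC_SubpS with an observed/not-observed indicator per
subpopulation.  "Combining the values for each food category" is summation,
which preserves the energy-flow semantics (Bio_All_species is then the total
potential energy across categories); a mean can be requested instead.
Scenario layer sets use scenario suitabilities with *current* diets — diets
are not re-estimated under scenarios.
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diet import CATEGORIES, SubpopulationDiet

logger = logging.getLogger(__name__)

ALL_SPECIES_LAYER = "Bio_All_species"


def layer_name(category: str, binary: bool = False) -> str:
    stem = category.replace(" ", "_")
    return f"Biotic_binary_{stem}" if binary else f"Biotic_{stem}"


def _accumulate(
    weights_by_subpop: Mapping[int, Mapping[str, float]],
    suitability: Mapping[str, np.ndarray],
    subpop_map: np.ndarray,
) -> np.ndarray:
    shape = subpop_map.shape
    out = np.zeros(shape, dtype=float)
    skipped = set()
    for subpop, weights in weights_by_subpop.items():
        inside = subpop_map == subpop
        for species, w in weights.items():
            if w == 0:
                continue
            hs = suitability.get(species)
            if hs is None:
                skipped.add(species)
                continue
            out[inside] += w * np.nan_to_num(hs[inside])
    if skipped:
        logger.info("species without suitability model skipped: %s", sorted(skipped))
    out[subpop_map < 0] = np.nan
    return out


def build_quantitative_layer(
    diets: Mapping[int, SubpopulationDiet],
    suitability: Mapping[str, np.ndarray],
    category: str,
    subpop_map: np.ndarray,
) -> np.ndarray:
    """Diet-energy-weighted suitability sum for one food category.

    Species with rEDEC_SubpS > 0 but no suitability raster are skipped and
    logged (they correspond to food species without a usable distribution
    model).  Cells outside every subpopulation are nodata.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    weights = {
        sp: {
            s: float(r)
            for s, r in d.species.loc[d.species["category"] == category, "redec"].items()
        }
        for sp, d in diets.items()
    }
    return _accumulate(weights, suitability, subpop_map)


def build_binary_layer(
    diets: Mapping[int, SubpopulationDiet],
    suitability: Mapping[str, np.ndarray],
    category: str,
    subpop_map: np.ndarray,
) -> np.ndarray:
    """Observed-interaction-indicator-weighted suitability sum per category."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    weights = {
        sp: {
            s: 1.0
            for s in d.species.index[(d.species["category"] == category) & (d.species["redec"] > 0)]
        }
        for sp, d in diets.items()
    }
    return _accumulate(weights, suitability, subpop_map)


def build_layer_set(
    diets: Mapping[int, SubpopulationDiet],
    suitability: Mapping[str, np.ndarray],
    subpop_map: np.ndarray,
    categories: Sequence[str] = CATEGORIES,
    include_binary: bool = True,
) -> Dict[str, np.ndarray]:
    """All biotic layers for one scenario's suitability set.

    Returns quantitative layers per category, optional binary variants, and
    the all-species total (the sum of the quantitative layers).
    """
    out: Dict[str, np.ndarray] = {}
    total = np.zeros(subpop_map.shape)
    for cat in categories:
        q = build_quantitative_layer(diets, suitability, cat, subpop_map)
        out[layer_name(cat)] = q
        total = total + np.nan_to_num(q)
        if include_binary:
            out[layer_name(cat, binary=True)] = build_binary_layer(
                diets, suitability, cat, subpop_map
            )
    total[subpop_map < 0] = np.nan
    out[ALL_SPECIES_LAYER] = total
    return out


def compare_proxies(
    pa_table: pd.DataFrame,
    quantitative: Mapping[str, np.ndarray],
    binary: Mapping[str, np.ndarray],
    categories: Sequence[str] = CATEGORIES,
    quadratic: bool = True,
) -> pd.DataFrame:
    """AIC of univariable presence models on quantitative vs binary layers.

    For each food category two binomial GLMs (logit link, linear + quadratic
    terms on the standardized layer) explain the focal species'
    presence/absence; the lower-AIC proxy is flagged best.  A layer constant
    over the sample makes that model degenerate, flagged with NaN AIC.
    """
    y = pa_table["presence"].to_numpy(float)
    rows_idx = pa_table["row"].to_numpy(int)
    cols_idx = pa_table["col"].to_numpy(int)

    def _aic(arr: np.ndarray) -> float:
        vals = arr[rows_idx, cols_idx]
        if not np.isfinite(vals).all():
            vals = np.nan_to_num(vals)
        s = vals.std()
        if s == 0:
            return np.nan
        z = (vals - vals.mean()) / s
        X = np.column_stack([z, z**2]) if quadratic else z[:, None]
        try:
            return float(sm.Logit(y, sm.add_constant(X)).fit(disp=0).aic)
        except Exception as exc:
            logger.warning("proxy model degenerate: %s", exc)
            return np.nan

    out = []
    for cat in categories:
        qa = _aic(quantitative[layer_name(cat)])
        ba = _aic(binary[layer_name(cat, binary=True)])
        if np.isnan(qa) and np.isnan(ba):
            best = "degenerate"
        elif np.isnan(ba) or (not np.isnan(qa) and qa <= ba):
            best = "quantitative"
        else:
            best = "binary"
        out.append(
            {
                "category": cat,
                "aic_quantitative": qa,
                "aic_binary": ba,
                "delta_aic": ba - qa if np.isfinite(qa) and np.isfinite(ba) else np.nan,
                "best": best,
            }
        )
    return pd.DataFrame(out)
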