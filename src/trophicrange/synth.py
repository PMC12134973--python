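"""Synthetic data with the statistical structure the analysis assumes.

Every downstream stage of the pipeline — dietary energetics, diet-environment
regressions, food-species distribution models, biotic energy layers and the
hierarchical focal-species model — can be exercised against data generated
here with *known* ground truth: climate and land-use rasters with controlled
spatial autocorrelation, food-species occurrences drawn from known
environmental niches, diet studies with a controllable rF-rV correlation and
known energy-correction factors, and focal-species presences drawn from a
known logistic model combining abiotic and biotic terms, together with a
coarse historical range derived from a climate-only version of that truth.

Everything is reproducible bit-exactly from (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .diet import CATEGORIES, DietStudy
from .grids import GridStack, RangeGrid, block_mean, make_subpop_partition, moving_window_mean

logger = logging.getLogger(__name__)

#: Default climate layers.  Clim_3 = isothermality (mean diurnal range over
#: annual range, %), Clim_4 = temperature seasonality (sd * 100), Clim_8 /
#: Clim_9 = mean temperature of the wettest / driest quarter (degC).
CLIMATE_LAYERS = ("Clim_3", "Clim_4", "Clim_8", "Clim_9")

#: Default land-use fraction layers.
LANDUSE_LAYERS = ("Urban", "Broadleaved Forest", "Coniferous Forest", "Natural Landscape")

#: Plausible (offset, scale) per climate layer, in the layer's units.
_CLIMATE_AFFINE = {
    "Clim_3": (33.0, 6.0),
    "Clim_4": (620.0, 160.0),
    "Clim_8": (11.0, 4.5),
    "Clim_9": (9.0, 6.0),
}

NATURAL_WINDOW = 11  # cells; the landscape-scale natural-area window


def default_scenarios() -> Dict[str, Dict[str, Dict[str, float]]]:
    """Three coupled climate/land-use change scenarios for 2050.

    Warming is applied to the quarterly temperature layers and to seasonality,
    urbanisation grows and forest fractions shrink multiplicatively; severity
    increases from SSP1-2.6 to SSP5-8.5.
    """
    out: Dict[str, Dict[str, Dict[str, float]]] = {}
    for name, warm, urb, forest in (
        ("SSP1-2.6", 1.0, 1.10, 0.97),
        ("SSP3-6.0", 2.0, 1.30, 0.88),
        ("SSP5-8.5", 3.2, 1.50, 0.78),
    ):
        out[name] = {
            "Clim_8": {"add": warm},
            "Clim_9": {"add": 1.1 * warm},
            "Clim_4": {"add": 25.0 * warm},
            "Clim_3": {"add": -0.8 * warm},
            "Urban": {"mul": urb},
            "Broadleaved Forest": {"mul": forest},
            "Coniferous Forest": {"mul": forest},
        }
    return out


@dataclass
class LandscapeConfig:
    """Dimensions, layer lists and scenario deltas of a synthetic landscape."""

    rows: int = 100
    cols: int = 100
    climate_layers: Tuple[str, ...] = CLIMATE_LAYERS
    landuse_layers: Tuple[str, ...] = LANDUSE_LAYERS
    length_scale_km: float = 8.0
    coarse_factor: int = 50
    scenarios: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=default_scenarios
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not self.scenarios:
            raise ValueError("scenario list must be non-empty")


def _smooth_field(rng: np.random.Generator, shape, scale_km: float) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to mean 0, sd 1."""
    z = ndimage.gaussian_filter(rng.normal(size=shape), sigma=scale_km, mode="reflect")
    return (z - z.mean()) / z.std()


def generate_landscape(config: LandscapeConfig) -> GridStack:
    """Generate co-registered current layers plus one layer set per scenario.

    Climate layers are spatially autocorrelated fields in plausible units;
    land-use layers are fractions in [0, 1]; "Natural Landscape" is the
    11 x 11-cell moving-window mean of a natural / non-natural indicator
    (a cell is natural when its urban fraction is below 0.5) and is
    recomputed for scenarios that change Urban.  Fraction layers pushed
    outside [0, 1] by scenario deltas are clipped (logged).
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.rows, config.cols)
    layers: Dict[str, np.ndarray] = {}
    for name in config.climate_layers:
        off, sc = _CLIMATE_AFFINE.get(name, (0.0, 1.0))
        layers[name] = off + sc * _smooth_field(rng, shape, config.length_scale_km)
    urban = None
    for name in config.landuse_layers:
        if name == "Natural Landscape":
            continue
        z = _smooth_field(rng, shape, config.length_scale_km)
        if name == "Urban":
            frac = expit(1.8 * z - 1.6)
            urban = frac
        elif name == "Broadleaved Forest":
            frac = expit(0.9 * z - 0.3)
        elif name == "Coniferous Forest":
            frac = expit(0.9 * z - 0.6)
        else:
            frac = expit(z)
        layers[name] = frac
    if urban is None:
        urban = np.zeros(shape)
    if "Natural Landscape" in config.landuse_layers:
        # uniform_filter can leave tiny negative round-off on a 0/1 field
        layers["Natural Landscape"] = np.clip(
            moving_window_mean((urban < 0.5).astype(float), NATURAL_WINDOW), 0.0, 1.0
        )

    fraction_layers = set(config.landuse_layers)
    scenarios: Dict[str, Dict[str, np.ndarray]] = {}
    for scen, deltas in config.scenarios.items():
        slay: Dict[str, np.ndarray] = {}
        for lname, spec in deltas.items():
            if lname not in layers:
                raise KeyError(f"scenario {scen!r} references unknown layer {lname!r}")
            arr = layers[lname] * spec.get("mul", 1.0) + spec.get("add", 0.0)
            if lname in fraction_layers:
                if arr.min() < 0 or arr.max() > 1:
                    logger.warning(
                        "scenario %s: layer %s clipped to [0, 1]", scen, lname
                    )
                    arr = np.clip(arr, 0.0, 1.0)
            slay[lname] = arr
        if (
            "Natural Landscape" in config.landuse_layers
            and "Urban" in slay
            and "Natural Landscape" not in slay
        ):
            slay["Natural Landscape"] = np.clip(
                moving_window_mean((slay["Urban"] < 0.5).astype(float), NATURAL_WINDOW),
                0.0,
                1.0,
            )
        scenarios[scen] = slay

    meta = {"seed": config.seed, "config": config, "coarse_factor": config.coarse_factor}
    return GridStack(layers=layers, cell_km=1.0, scenarios=scenarios, meta=meta)


# ---------------------------------------------------------------------------
# Food-species occurrences


@dataclass
class TrueNiche:
    """Ground-truth environmental niche of one (food) species.

    ``coefficients`` maps a layer name to (linear, quadratic) response
    coefficients on the standardized layer; the intercept controls prevalence.
    """

    species_id: str
    coefficients: Mapping[str, Tuple[float, float]]
    intercept: float = -1.0
    category: str = "reproductive plants"
    origin: str = "wild"
    mobility: Optional[str] = None  # placeholder, unused

    def linear_predictor(
        self, layers: Mapping[str, np.ndarray], standardization: Mapping[str, Tuple[float, float]]
    ) -> np.ndarray:
        eta = np.full(next(iter(layers.values())).shape, self.intercept, dtype=float)
        for name, (b1, b2) in self.coefficients.items():
            if name not in layers:
                raise KeyError(f"niche {self.species_id!r} references missing layer {name!r}")
            c, s = standardization[name]
            z = (layers[name] - c) / s
            eta += b1 * z + b2 * z**2
        return eta


@dataclass
class FoodTruth:
    """Truth record accompanying generated food-species occurrences."""

    niches: List[TrueNiche]
    standardization: Dict[str, Tuple[float, float]]
    presence_counts: Dict[str, int]
    excluded: List[str]
    probability: Dict[str, np.ndarray]
    seed: int = 0


def generate_food_species(
    niches: Sequence[TrueNiche],
    landscape: GridStack,
    seed: int = 0,
    min_presence_cells: int = 50,
    extra_point_rate: float = 0.5,
) -> Tuple[pd.DataFrame, FoodTruth]:
    """Sample per-species point occurrences from logistic niches.

    Each cell is a Bernoulli draw from the niche's presence probability on the
    current layers; occupied cells emit 1 + Poisson(``extra_point_rate``)
    points so that gridding has duplicates to collapse.  Species whose
    realized presence-cell count falls below ``min_presence_cells`` are
    flagged in the truth record.
    """
    if not niches:
        raise ValueError("niches must be non-empty")
    rng = np.random.default_rng(seed)
    layers = landscape.layers
    needed = sorted({n for niche in niches for n in niche.coefficients})
    stand = landscape.standardization(
        [n for n in needed if n in layers] + [n for n in layers if n not in needed]
    )
    rows_out: List[pd.DataFrame] = []
    counts: Dict[str, int] = {}
    probs: Dict[str, np.ndarray] = {}
    excluded: List[str] = []
    for niche in niches:
        p = expit(niche.linear_predictor(layers, stand))
        pres = rng.random(p.shape) < p
        rr, cc = np.nonzero(pres)
        counts[niche.species_id] = len(rr)
        probs[niche.species_id] = p
        if len(rr) < min_presence_cells:
            excluded.append(niche.species_id)
        reps = 1 + rng.poisson(extra_point_rate, size=len(rr))
        rows_out.append(
            pd.DataFrame(
                {
                    "species_id": niche.species_id,
                    "row": np.repeat(rr, reps),
                    "col": np.repeat(cc, reps),
                }
            )
        )
    occ = pd.concat(rows_out, ignore_index=True)
    truth = FoodTruth(
        niches=list(niches),
        standardization=stand,
        presence_counts=counts,
        excluded=excluded,
        probability=probs,
        seed=seed,
    )
    return occ, truth


# ---------------------------------------------------------------------------
# Diet studies


@dataclass
class TrueDietConfig:
    """Ground truth for diet-study generation.

    ``pools`` maps each subpopulation id to its species pool: a DataFrame
    with columns ``item_id``, ``species_id`` (NaN for items not resolved to
    species), ``category``, ``origin``, ``share`` (true energy share, summing
    to 1 within the subpopulation) and ``cf_e``.
    """

    pools: Mapping[int, pd.DataFrame]
    target_corr: float = 0.86
    studies_per_subpop: int = 3
    z_range: Tuple[int, int] = (40, 300)
    occurrences_per_study: int = 600
    concentration: float = 150.0
    missing_rv_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.target_corr <= 1:
            raise ValueError("target_corr must be in (0, 1]")
        for sp, pool in self.pools.items():
            tot = pool["share"].sum()
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"subpop {sp}: true shares sum to {tot}, not 1")


def generate_diet_studies(
    config: TrueDietConfig,
    subpop_map: np.ndarray,
    seed: int = 0,
) -> List[DietStudy]:
    """Generate diet studies whose pooled rF-rV correlation hits a target.

    Per study, item occurrence counts f are multinomial around the (slightly
    Dirichlet-jittered) true shares, rF = f / sum f, and rV is rF plus
    Gaussian noise scaled so that corr(rF, rV) approaches ``target_corr``,
    clipped at zero and renormalized.  A fixed fraction of studies
    (``missing_rv_fraction``, rounded to a count) has every rV masked.
    """
    rng = np.random.default_rng(seed)
    present = set(np.unique(subpop_map[subpop_map >= 0]).tolist())
    unknown = set(config.pools) - present
    if unknown:
        raise ValueError(f"subpopulations {sorted(unknown)} not in subpop_map")

    # First pass: draw every study's rF and its (unit-scale) rV noise.
    drafts = []
    for subpop, pool in config.pools.items():
        cells = np.argwhere(subpop_map == subpop)
        for k in range(config.studies_per_subpop):
            loc = cells[rng.integers(len(cells))]
            z = int(rng.integers(*config.z_range))
            p_study = rng.dirichlet(config.concentration * pool["share"].to_numpy() + 1e-9)
            f = rng.multinomial(config.occurrences_per_study, p_study)
            keep = f > 0
            if not keep.any():  # pragma: no cover - multinomial total > 0
                keep[np.argmax(p_study)] = True
            fk = f[keep].astype(float)
            rf = fk / fk.sum()
            drafts.append(
                {
                    "subpop": subpop,
                    "k": k,
                    "pool_rows": keep,
                    "loc": loc,
                    "z": z,
                    "fk": fk,
                    "rf": rf,
                    "eps": rng.normal(size=len(rf)),
                    "sample_type": "scat" if rng.random() < 0.8 else "stomach",
                }
            )

    # Calibrate one global noise scale so the *pooled* Pearson correlation of
    # (rF, rV) hits the target (clipping at zero and per-study renormalization
    # make the naive errors-in-variables scale biased, so solve for it).
    def _rv_all(scale: float) -> Tuple[np.ndarray, np.ndarray]:
        rfs, rvs = [], []
        for d in drafts:
            raw = np.clip(d["rf"] + scale * d["eps"], 0.0, None)
            tot = raw.sum()
            rvs.append(raw / tot if tot > 0 else d["rf"])
            rfs.append(d["rf"])
        return np.concatenate(rfs), np.concatenate(rvs)

    def _corr_gap(scale: float) -> float:
        rf, rv = _rv_all(scale)
        return float(np.corrcoef(rf, rv)[0, 1]) - config.target_corr

    if config.target_corr >= 1.0:
        scale = 0.0
    else:
        from scipy.optimize import brentq

        hi = 1.0
        while _corr_gap(hi) > 0 and hi < 64:
            hi *= 2
        scale = brentq(_corr_gap, 0.0, hi, xtol=1e-6) if _corr_gap(hi) <= 0 else hi

    studies: List[DietStudy] = []
    for d in drafts:
        pool = config.pools[d["subpop"]]
        items = pool.loc[
            d["pool_rows"], ["item_id", "species_id", "category", "origin", "cf_e"]
        ].copy()
        raw = np.clip(d["rf"] + scale * d["eps"], 0.0, None)
        tot = raw.sum()
        rv = raw / tot if tot > 0 else d["rf"]
        items["f"] = d["fk"]
        items["rF"] = d["rf"]
        items["v"] = 100.0 * rv
        items["rV"] = rv
        items["rv_imputed"] = False
        studies.append(
            DietStudy(
                study_id=f"S{d['subpop']}_{d['k']}",
                subpop=d["subpop"],
                row=int(d["loc"][0]),
                col=int(d["loc"][1]),
                sample_type=d["sample_type"],
                z=d["z"],
                items=items,
            )
        )

    n_missing = int(round(config.missing_rv_fraction * len(studies)))
    for idx in rng.choice(len(studies), size=n_missing, replace=False):
        studies[idx].items["rV"] = np.nan
        studies[idx].items["v"] = np.nan
    return studies


# ---------------------------------------------------------------------------
# Focal-species occurrences and historical range


@dataclass
class TrueOccurrenceModel:
    """Known logistic truth for the focal species.

    Coefficients act on standardized layers: ``climate`` maps layer ->
    (linear, quadratic); ``landuse`` and ``biotic`` map layer -> linear
    coefficient.  ``standardization`` (layer -> (center, scale)) defaults to
    landscape-wide moments and is recorded in the truth output so fitted
    coefficients are comparable with the generating ones.
    """

    intercept: float = 0.0
    climate: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    landuse: Mapping[str, float] = field(default_factory=dict)
    biotic: Mapping[str, float] = field(default_factory=dict)
    subpop_effects: Optional[Sequence[float]] = None
    standardization: Optional[Mapping[str, Tuple[float, float]]] = None


@dataclass
class FocalTruth:
    """Generated focal-species data plus the generating model."""

    presences: pd.DataFrame  # row, col, subpop
    probability: np.ndarray
    probability_climate: np.ndarray
    range_grid: RangeGrid
    subpop_map: np.ndarray
    model: TrueOccurrenceModel
    standardization: Dict[str, Tuple[float, float]]
    seed: int


def _standardize(arr: np.ndarray, cs: Tuple[float, float]) -> np.ndarray:
    return (arr - cs[0]) / cs[1]


def generate_focal_occurrences(
    model: TrueOccurrenceModel,
    landscape: GridStack,
    biotic_layers: Mapping[str, np.ndarray],
    seed: int = 0,
    n_subpops: int = 4,
    coarse_factor: Optional[int] = None,
) -> FocalTruth:
    """Draw fine-grid focal presences and a coarse historical range.

    Presences are Bernoulli draws from the full abiotic + biotic logistic
    truth.  The historical range is derived from a *climate-only* version of
    the truth: its presence probability is block-aggregated to the coarse
    grid and redrawn, so historical data are informative about the climate
    coefficients without duplicating the fine-scale data.  Subpopulation
    labels come from a rectangular spatial partition.
    """
    rng = np.random.default_rng(seed)
    layers = landscape.layers
    shape = landscape.shape
    for name, arr in biotic_layers.items():
        if arr.shape != shape:
            raise ValueError(f"biotic layer {name!r} not co-registered with landscape")
    coarse_factor = coarse_factor or landscape.meta.get("coarse_factor", 50)

    stand: Dict[str, Tuple[float, float]] = dict(model.standardization or {})
    for name in list(model.climate) + list(model.landuse):
        if name not in layers:
            raise KeyError(f"true model references missing abiotic layer {name!r}")
        if name not in stand:
            a = layers[name]
            stand[name] = (float(a.mean()), float(a.std()) or 1.0)
    for name in model.biotic:
        if name not in biotic_layers:
            raise KeyError(f"true model references missing biotic layer {name!r}")
        if name not in stand:
            a = biotic_layers[name]
            stand[name] = (float(np.nanmean(a)), float(np.nanstd(a)) or 1.0)

    eta_clim = np.full(shape, model.intercept, dtype=float)
    for name, (b1, b2) in model.climate.items():
        z = _standardize(layers[name], stand[name])
        eta_clim += b1 * z + b2 * z**2
    eta = eta_clim.copy()
    for name, b in model.landuse.items():
        eta += b * _standardize(layers[name], stand[name])
    for name, b in model.biotic.items():
        eta += b * _standardize(np.nan_to_num(biotic_layers[name]), stand[name])

    subpop_map = make_subpop_partition(shape, n_subpops)
    if model.subpop_effects is not None:
        eta = eta + np.asarray(model.subpop_effects)[subpop_map]

    prob = expit(eta)
    pres = rng.random(shape) < prob
    rr, cc = np.nonzero(pres)
    presences = pd.DataFrame({"row": rr, "col": cc, "subpop": subpop_map[rr, cc]})

    prob_clim = expit(eta_clim)
    coarse_p = block_mean(prob_clim, coarse_factor)
    status = (rng.random(coarse_p.shape) < coarse_p).astype(np.int8)
    if status.min() == status.max():  # degenerate draw: fall back to thresholding
        status = (coarse_p >= np.median(coarse_p)).astype(np.int8)
    range_grid = RangeGrid(status=status, coarse_factor=coarse_factor)

    return FocalTruth(
        presences=presences,
        probability=prob,
        probability_climate=prob_clim,
        range_grid=range_grid,
        subpop_map=subpop_map,
        model=model,
        standardization=stand,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Default study system

#: A compact food-species pool spanning all five categories.  Wild species
#: get niches (and hence distribution models); human-derived items appear in
#: diets only.
DEFAULT_SPECIES = (
    # species_id, category, origin, has_niche
    ("Vaccinium myrtillus", "reproductive plants", "wild", True),
    ("Fagus sylvatica", "reproductive plants", "wild", True),
    ("Festuca rubra", "vegetative plants", "wild", True),
    ("Heracleum sphondylium", "unknown plants", "wild", True),
    ("Formica rufa", "invertebrates", "wild", True),
    ("Vespula vulgaris", "invertebrates", "wild", True),
    ("Cervus elaphus", "vertebrates", "wild", True),
    ("Capreolus capreolus", "vertebrates", "wild", True),
    ("Malus domestica", "reproductive plants", "human-derived", False),
    ("Zea mays", "reproductive plants", "human-derived", False),
)

#: Energy correction factors by category (synthetic stand-ins: fruits and
#: crops digest well, vegetative matter poorly, animal matter best).
DEFAULT_CF_E = {
    "reproductive plants": 2.0,
    "vegetative plants": 0.6,
    "unknown plants": 1.0,
    "invertebrates": 2.5,
    "vertebrates": 3.5,
}


def default_niches() -> List[TrueNiche]:
    """Known niches for the wild default species (bell-shaped in climate)."""
    spec = {
        "Vaccinium myrtillus": ({"Clim_8": (-1.2, -1.0), "Coniferous Forest": (1.2, 0.0)}, -2.2),
        "Fagus sylvatica": ({"Clim_3": (1.0, -1.2), "Broadleaved Forest": (1.5, 0.0)}, -2.3),
        "Festuca rubra": ({"Clim_4": (0.8, -0.8), "Natural Landscape": (1.0, 0.0)}, -2.0),
        "Heracleum sphondylium": ({"Clim_9": (-0.9, -0.8), "Natural Landscape": (0.8, 0.0)}, -2.3),
        "Formica rufa": ({"Clim_9": (1.0, -0.9), "Coniferous Forest": (1.0, 0.0)}, -2.4),
        "Vespula vulgaris": ({"Clim_8": (1.2, -0.9), "Urban": (0.3, 0.0)}, -2.5),
        "Cervus elaphus": ({"Clim_4": (1.0, -1.0), "Broadleaved Forest": (0.9, 0.0)}, -2.3),
        "Capreolus capreolus": ({"Clim_8": (0.8, -0.9), "Broadleaved Forest": (1.1, 0.0)}, -2.1),
    }
    out = []
    for sid, cat, orig, has in DEFAULT_SPECIES:
        if not has:
            continue
        coefs, icpt = spec[sid]
        out.append(
            TrueNiche(species_id=sid, coefficients=coefs, intercept=icpt, category=cat, origin=orig)
        )
    return out


def default_diet_config(
    subpop_ids: Sequence[int],
    seed: int = 0,
    studies_per_subpop: int = 3,
    missing_rv_fraction: float = 0.3,
) -> TrueDietConfig:
    """Subpopulation diet pools over the default species with varied shares.

    Shares differ among subpopulations (Dirichlet draws around a common
    base), and each pool carries one genus-level item not resolved to species
    so per-species shares sum to less than 1.
    """
    rng = np.random.default_rng(seed)
    base = np.array([0.22, 0.12, 0.08, 0.05, 0.03, 0.02, 0.16, 0.10, 0.06, 0.06])
    pools = {}
    for sp in subpop_ids:
        rows = []
        shares = rng.dirichlet(base * 60.0)
        for (sid, cat, orig, _), w in zip(DEFAULT_SPECIES, shares):
            rows.append(
                {
                    "item_id": sid,
                    "species_id": sid,
                    "category": cat,
                    "origin": orig,
                    "share": w,
                    "cf_e": DEFAULT_CF_E[cat],
                }
            )
        # one unresolved (genus-level) item takes 10% of the energy
        rows.append(
            {
                "item_id": "Gramineae indet.",
                "species_id": np.nan,
                "category": "vegetative plants",
                "origin": "wild",
                "share": 0.10,
                "cf_e": DEFAULT_CF_E["vegetative plants"],
            }
        )
        pool = pd.DataFrame(rows)
        pool["share"] = pool["share"] / pool["share"].sum()
        pools[int(sp)] = pool
    return TrueDietConfig(
        pools=pools,
        studies_per_subpop=studies_per_subpop,
        missing_rv_fraction=missing_rv_fraction,
    )
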