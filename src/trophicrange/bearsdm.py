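"""Hierarchical Bayesian distribution model for the focal species.

The workflow mirrors a two-scale design.  A coarse (50-km) *historical* model
— a Bayesian logistic regression of historical range status on four climate
variables (isothermality Clim_3, temperature seasonality Clim_4, and mean
temperature of the wettest/driest quarters Clim_8/Clim_9, linear + quadratic
on standardized values) — is fitted to an environmentally stratified,
class-balanced sample of the range grid.  Its posterior means and standard
deviations become the *informative priors* of the fine-scale (1-km) model,
transferred unmodified, together with the standardization constants so both
scales share one coordinate system.

The fine-scale models are Bayesian binomial GLMMs (logit link, subpopulation
random intercept) on gridded presences and 5-km-buffer pseudo-absences,
balanced per subpopulation, capped at 2000 presences per subpopulation and
split 80/20 into training and validation.  Variants: abiotic + biotic,
abiotic-only, biotic-only and intercept-only (null), each hierarchical
(historical priors on climate terms) or not.  Models are compared by WAIC;
the presence/absence cutoff is the 90th-percentile training-presence
threshold, leaving out 10% of training presences (training TPR = 0.90 by
construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from .bayes import LogisticPosterior, SamplerSettings, fit_logistic_mcmc, waic_difference
from .grids import RangeGrid

logger = logging.getLogger(__name__)

CLIMATE_VARS = ("Clim_3", "Clim_4", "Clim_8", "Clim_9")
VARIANTS = ("abiotic+biotic", "abiotic", "biotic", "null")

DEFAULT_COEF_SD = 2.5
DEFAULT_INTERCEPT_SD = 5.0


# ---------------------------------------------------------------------------
# Historical (coarse) stage


def stratified_sample_range(
    range_grid: RangeGrid,
    coarse_layers: Mapping[str, np.ndarray],
    n_bins: int = 3,
    seed: int = 0,
    variables: Sequence[str] = CLIMATE_VARS,
) -> pd.DataFrame:
    """Environmentally stratified, class-balanced sample of the range grid.

    Strata are the intersections of per-variable quantile bins; within every
    stratum holding both presences and absences, an equal number of each
    (the smaller class count) is drawn.  Strata lacking a class are skipped
    and logged.
    """
    status = range_grid.status
    valid = status >= 0
    if not ((status == 1) & valid).any() or not ((status == 0) & valid).any():
        raise ValueError("range grid needs both presence and absence cells")
    rr, cc = np.nonzero(valid)
    y = status[rr, cc]

    stratum = np.zeros(len(rr), dtype=int)
    for v in variables:
        vals = coarse_layers[v][rr, cc]
        edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1)[1:-1])
        stratum = stratum * n_bins + np.digitize(vals, edges)

    rng = np.random.default_rng(seed)
    keep_idx: List[np.ndarray] = []
    n_skipped = 0
    for s in np.unique(stratum):
        members = np.nonzero(stratum == s)[0]
        pres = members[y[members] == 1]
        abs_ = members[y[members] == 0]
        if len(pres) == 0 or len(abs_) == 0:
            n_skipped += 1
            continue
        m = min(len(pres), len(abs_))
        keep_idx.append(rng.choice(pres, m, replace=False))
        keep_idx.append(rng.choice(abs_, m, replace=False))
    if not keep_idx:
        raise ValueError("no stratum contains both classes")
    if n_skipped:
        logger.info("stratified sampling: %d strata lacked a class and were skipped", n_skipped)
    sel = np.sort(np.concatenate(keep_idx))
    out = pd.DataFrame(
        {"row": rr[sel], "col": cc[sel], "presence": y[sel], "stratum": stratum[sel]}
    )
    for v in variables:
        out[v] = coarse_layers[v][out["row"], out["col"]]
    return out


@dataclass
class PriorSet:
    """Coefficient priors transferred from the historical model.

    ``table`` holds one row per coefficient (index: term name; columns
    ``mean``, ``sd``); ``standardization`` the per-variable (center, scale)
    used when fitting the historical model, to be reused verbatim at fine
    scale so the priors refer to the same coordinate system.
    """

    table: pd.DataFrame
    standardization: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        if (self.table["sd"] <= 0).any():
            raise ValueError("prior sds must be > 0")

    @property
    def terms(self) -> List[str]:
        return list(self.table.index)

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["center"] = [
            self.standardization.get(_term_var(t), (np.nan, np.nan))[0] for t in df.index
        ]
        df["scale"] = [
            self.standardization.get(_term_var(t), (np.nan, np.nan))[1] for t in df.index
        ]
        return df


def _term_var(term: str) -> str:
    return term[:-3] if term.endswith("_sq") else term


def climate_terms(variables: Sequence[str] = CLIMATE_VARS) -> List[str]:
    return [v for v in variables] + [f"{v}_sq" for v in variables]


@dataclass
class HistoricalFit:
    prior_set: PriorSet
    posterior: LogisticPosterior


def fit_historical_model(
    sample: pd.DataFrame,
    coarse_layers: Optional[Mapping[str, np.ndarray]] = None,
    variables: Sequence[str] = CLIMATE_VARS,
    settings: Optional[SamplerSettings] = None,
    standardization: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> HistoricalFit:
    """Bayesian logistic regression of range status on climate (lin + quad).

    Weakly informative defaults (Normal(0, 2.5) on standardized terms,
    Normal(0, 5) intercept).  Returns the posterior and a :class:`PriorSet`
    of per-coefficient posterior means/sds plus the standardization
    constants (computed from the sample unless supplied).
    """
    y = sample["presence"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("historical sample needs both classes")
    cols = {}
    for v in variables:
        if v in sample.columns:
            cols[v] = sample[v].to_numpy(float)
        elif coarse_layers is not None:
            cols[v] = coarse_layers[v][sample["row"].to_numpy(int), sample["col"].to_numpy(int)]
        else:
            raise KeyError(f"variable {v!r} not in sample and no coarse_layers given")
    stand = dict(standardization or {})
    for v in variables:
        if v not in stand:
            stand[v] = (float(cols[v].mean()), float(cols[v].std()) or 1.0)

    names = ["intercept"] + climate_terms(variables)
    X = np.ones((len(y), len(names)))
    for k, v in enumerate(variables):
        z = (cols[v] - stand[v][0]) / stand[v][1]
        X[:, 1 + k] = z
        X[:, 1 + len(variables) + k] = z**2
    prior_mean = np.zeros(len(names))
    prior_sd = np.r_[DEFAULT_INTERCEPT_SD, np.full(len(names) - 1, DEFAULT_COEF_SD)]
    post = fit_logistic_mcmc(
        X, y, prior_mean, prior_sd, coef_names=names, settings=settings
    )
    summ = post.coef_summary()
    prior = PriorSet(
        table=pd.DataFrame({"mean": summ["mean"], "sd": summ["sd"]}),
        standardization=stand,
    )
    return HistoricalFit(prior_set=prior, posterior=post)


# ---------------------------------------------------------------------------
# Occurrence preparation


@dataclass
class OccurrenceSample:
    """Balanced, capped, split presence/pseudo-absence sample.

    ``table`` columns: row, col, subpop, presence (1/0), split
    ("train"/"validation").  Per subpopulation, pseudo-absences equal
    presences; the train fraction holds exactly over presences and over
    pseudo-absences (largest-remainder allocation across subpopulations).
    """

    table: pd.DataFrame
    cap: int
    train_frac: float
    pa_buffer_km: float
    seed: int

    def subset(self, split: str) -> pd.DataFrame:
        return self.table[self.table["split"] == split]

    @property
    def n_presences(self) -> int:
        return int((self.table["presence"] == 1).sum())

    @property
    def n_train_presences(self) -> int:
        t = self.table
        return int(((t["presence"] == 1) & (t["split"] == "train")).sum())

    @property
    def n_validation_presences(self) -> int:
        t = self.table
        return int(((t["presence"] == 1) & (t["split"] == "validation")).sum())


def _largest_remainder_split(
    counts: Mapping[int, int], frac: float
) -> Dict[int, int]:
    """Per-group train counts whose total is exactly round(frac * total)."""
    total_train = int(round(frac * sum(counts.values())))
    base = {g: int(np.floor(frac * n)) for g, n in counts.items()}
    rem = total_train - sum(base.values())
    order = sorted(
        counts, key=lambda g: (frac * counts[g] - base[g], -counts[g], g), reverse=True
    )
    for g in order[:rem]:
        base[g] += 1
    return base


def prepare_occurrences(
    occurrences: pd.DataFrame,
    subpop_map: np.ndarray,
    water_mask: Optional[np.ndarray] = None,
    cap: int = 2000,
    train_frac: float = 0.8,
    pa_buffer_km: float = 5.0,
    seed: int = 0,
    cell_km: float = 1.0,
) -> OccurrenceSample:
    """Grid, filter, cap, balance and split focal-species occurrences.

    Occurrence points are deduplicated to 1-km presence cells; cells on the
    water mask are removed; each subpopulation keeps at most ``cap``
    presences (uniform subsample); pseudo-absences are drawn per
    subpopulation, one per presence, uniformly from non-presence terrestrial
    cells within ``pa_buffer_km`` of any presence cell; the 80/20 split is
    stratified by subpopulation separately for presences and pseudo-absences.
    """
    rng = np.random.default_rng(seed)
    shape = subpop_map.shape
    cells = np.unique(occurrences[["row", "col"]].to_numpy(int), axis=0)
    if water_mask is not None:
        keep = ~water_mask[cells[:, 0], cells[:, 1]]
        cells = cells[keep]
    sp = subpop_map[cells[:, 0], cells[:, 1]]
    cells = cells[sp >= 0]
    sp = sp[sp >= 0]
    if len(cells) == 0:
        raise ValueError("no presence cells after masking")

    pres_mask = np.zeros(shape, dtype=bool)
    pres_mask[cells[:, 0], cells[:, 1]] = True
    dist = ndimage.distance_transform_edt(~pres_mask) * cell_km
    cand_mask = (dist > 0) & (dist <= pa_buffer_km)
    if water_mask is not None:
        cand_mask &= ~water_mask

    rows = []
    for subpop in np.unique(sp):
        pc = cells[sp == subpop]
        if len(pc) > cap:
            pc = pc[rng.choice(len(pc), size=cap, replace=False)]
        cand = np.argwhere(cand_mask & (subpop_map == subpop))
        if len(cand) < len(pc):
            raise ValueError(
                f"subpopulation {subpop}: {len(cand)} pseudo-absence candidates "
                f"for {len(pc)} presences"
            )
        ac = cand[rng.choice(len(cand), size=len(pc), replace=False)]
        for arr, label in ((pc, 1), (ac, 0)):
            rows.append(
                pd.DataFrame(
                    {"row": arr[:, 0], "col": arr[:, 1], "subpop": subpop, "presence": label}
                )
            )
    table = pd.concat(rows, ignore_index=True)

    table["split"] = "validation"
    for label in (1, 0):
        cls = table[table["presence"] == label]
        counts = cls.groupby("subpop").size().to_dict()
        train_n = _largest_remainder_split(counts, train_frac)
        for subpop, k in train_n.items():
            idx = cls.index[cls["subpop"] == subpop].to_numpy()
            chosen = rng.choice(idx, size=k, replace=False)
            table.loc[chosen, "split"] = "train"
    return OccurrenceSample(
        table=table, cap=cap, train_frac=train_frac, pa_buffer_km=pa_buffer_km, seed=seed
    )


def sampling_intensity(n_presences: int, n_individuals: int, ndigits: int = 1) -> float:
    """Average number of grid presences per known individual."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return round(n_presences / n_individuals, ndigits)


# ---------------------------------------------------------------------------
# Variable screening for land-use / biotic blocks


def select_block_variables(
    sample: pd.DataFrame,
    layers: Mapping[str, np.ndarray],
    candidates: Sequence[str],
    k: int = 4,
    r_threshold: float = 0.7,
) -> List[str]:
    """Best (AIC-based) uncorrelated variables by univariable screening.

    Candidates are first reduced by a pairwise |r| filter, then ranked by
    the AIC of a univariable logistic regression with subpopulation
    intercepts (a fixed-effects stand-in for the mixed model, adequate for
    ranking).  The best ``k`` are returned, ties broken by name.
    """
    train = sample[sample["split"] == "train"] if "split" in sample.columns else sample
    y = train["presence"].to_numpy(float)
    r_idx, c_idx = train["row"].to_numpy(int), train["col"].to_numpy(int)
    vals = pd.DataFrame(
        {name: np.nan_to_num(layers[name][r_idx, c_idx]) for name in candidates}
    )
    keep = list(candidates)
    while len(keep) > 1:
        corr = vals[keep].corr().abs()
        np.fill_diagonal(corr.values, 0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        if corr.values[i, j] <= r_threshold:
            break
        a, b = corr.index[i], corr.columns[j]
        drop = a if (corr.loc[a].mean(), str(a)) > (corr.loc[b].mean(), str(b)) else b
        keep.remove(drop)

    subpop_dummies = pd.get_dummies(train["subpop"].to_numpy(), drop_first=True, dtype=float)
    scored = []
    for name in keep:
        z = vals[name].to_numpy()
        s = z.std()
        z = (z - z.mean()) / (s if s > 0 else 1.0)
        X = sm.add_constant(np.column_stack([z, subpop_dummies.to_numpy()]))
        try:
            aic = sm.Logit(y, X).fit(disp=0).aic
        except Exception:
            aic = np.inf
        scored.append((aic, name))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [name for _, name in scored[:k]]


# ---------------------------------------------------------------------------
# Fine-scale Bayesian models


@dataclass
class DesignSpec:
    """Term list and standardization for building design matrices."""

    terms: List[str]  # excluding intercept; climate vars contribute v and v_sq
    standardization: Dict[str, Tuple[float, float]]

    @property
    def coef_names(self) -> List[str]:
        return ["intercept"] + self.terms

    def matrix(self, values: Mapping[str, np.ndarray], n: int) -> np.ndarray:
        X = np.ones((n, 1 + len(self.terms)))
        for k, t in enumerate(self.terms):
            v = _term_var(t)
            c, s = self.standardization[v]
            z = (np.nan_to_num(np.asarray(values[v], dtype=float)) - c) / s
            X[:, 1 + k] = z**2 if t.endswith("_sq") else z
        return X


@dataclass
class FittedBayesModel:
    """One fitted fine-scale model variant with its design and provenance."""

    variant: str
    hierarchical: bool
    blocks: Dict[str, List[str]]
    design: DesignSpec
    posterior: LogisticPosterior
    priors: pd.DataFrame  # term, mean, sd actually used
    prior_provenance: str
    random_intercept: bool
    threshold: Optional[float] = None

    @property
    def waic(self) -> float:
        return self.posterior.waic

    @property
    def waic_se(self) -> float:
        return self.posterior.waic_se

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    def _group_index(self, subpops: np.ndarray) -> Optional[np.ndarray]:
        if self.posterior.group_labels is None:
            return None
        lookup = {g: i for i, g in enumerate(self.posterior.group_labels)}
        return np.array([lookup.get(s, -1) for s in subpops])

    def predict_table(self, table: pd.DataFrame, layers: Mapping[str, np.ndarray]) -> np.ndarray:
        """Posterior-mean presence probability at table cells."""
        r, c = table["row"].to_numpy(int), table["col"].to_numpy(int)
        values = {
            _term_var(t): layers[_term_var(t)][r, c] for t in self.design.terms
        }
        X = self.design.matrix(values, len(table))
        groups = self._group_index(table["subpop"].to_numpy()) if "subpop" in table else None
        return self.posterior.predict_prob(X, groups=groups)

    def predict_map(
        self,
        layers: Mapping[str, np.ndarray],
        subpop_map: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Posterior-mean probability raster (NaN where any layer is nodata)."""
        needed = {_term_var(t) for t in self.design.terms}
        if needed:
            shape = next(iter(layers.values())).shape
            stack = np.stack([np.asarray(layers[v], dtype=float) for v in needed])
            valid = np.isfinite(stack).all(axis=0)
        else:
            shape = subpop_map.shape if subpop_map is not None else None
            if shape is None:
                raise ValueError("null model needs subpop_map for the output shape")
            valid = np.ones(shape, dtype=bool)
        rr, cc = np.nonzero(valid)
        values = {v: layers[v][rr, cc] for v in needed}
        X = self.design.matrix(values, len(rr))
        groups = (
            self._group_index(subpop_map[rr, cc]) if subpop_map is not None else None
        )
        out = np.full(shape, np.nan)
        out[rr, cc] = self.posterior.predict_prob(X, groups=groups)
        return out


def variant_blocks(
    variant: str,
    climate: Sequence[str] = CLIMATE_VARS,
    landuse: Sequence[str] = (),
    biotic: Sequence[str] = (),
) -> Dict[str, List[str]]:
    """Predictor blocks for a named model variant."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if variant == "abiotic+biotic":
        return {"climate": list(climate), "landuse": list(landuse), "biotic": list(biotic)}
    if variant == "abiotic":
        return {"climate": list(climate), "landuse": list(landuse), "biotic": []}
    if variant == "biotic":
        return {"climate": [], "landuse": [], "biotic": list(biotic)}
    return {"climate": [], "landuse": [], "biotic": []}


def fit_bayes_model(
    sample: OccurrenceSample,
    layers: Mapping[str, np.ndarray],
    blocks: Mapping[str, Sequence[str]],
    priors: Optional[PriorSet] = None,
    variant: Optional[str] = None,
    hierarchical: Optional[bool] = None,
    random_intercept: bool = True,
    settings: Optional[SamplerSettings] = None,
    standardization: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FittedBayesModel:
    """Fit one fine-scale Bayesian binomial GLMM variant on the training split.

    Climate variables enter with linear + quadratic terms, land-use and
    biotic variables linearly.  When ``priors`` is given (hierarchical
    variant) the climate coefficients receive the historical posterior
    means/sds unmodified and the historical standardization constants are
    reused; all other coefficients get weakly informative defaults.
    """
    blocks = {k: list(v) for k, v in blocks.items()}
    climate = blocks.get("climate", [])
    others = blocks.get("landuse", []) + blocks.get("biotic", [])
    hierarchical = (priors is not None) if hierarchical is None else hierarchical
    if hierarchical and priors is None and climate:
        raise ValueError("hierarchical variant with climate block requires priors")
    if variant is None:
        if climate and blocks.get("biotic"):
            variant = "abiotic+biotic"
        elif climate:
            variant = "abiotic"
        elif blocks.get("biotic"):
            variant = "biotic"
        else:
            variant = "null"

    train = sample.subset("train")
    y = train["presence"].to_numpy(float)
    r_idx, c_idx = train["row"].to_numpy(int), train["col"].to_numpy(int)

    stand: Dict[str, Tuple[float, float]] = dict(standardization or {})
    if priors is not None:
        for v in climate:
            stand.setdefault(v, priors.standardization[v])
    for v in climate + others:
        if v not in stand:
            vals = np.nan_to_num(layers[v][r_idx, c_idx])
            stand[v] = (float(vals.mean()), float(vals.std()) or 1.0)

    terms = climate_terms(climate) if climate else []
    terms = terms + others
    design = DesignSpec(terms=terms, standardization=stand)
    values = {v: np.nan_to_num(layers[v][r_idx, c_idx]) for v in set(map(_term_var, terms))}
    X = design.matrix(values, len(train))

    names = design.coef_names
    prior_mean = np.zeros(len(names))
    prior_sd = np.r_[DEFAULT_INTERCEPT_SD, np.full(len(names) - 1, DEFAULT_COEF_SD)]
    provenance = "weakly-informative defaults"
    if hierarchical and priors is not None and climate:
        for k, t in enumerate(names):
            if t in priors.table.index and (t == "intercept" or _term_var(t) in climate):
                prior_mean[k] = priors.table.loc[t, "mean"]
                prior_sd[k] = priors.table.loc[t, "sd"]
        provenance = "historical-model posterior (climate terms), defaults elsewhere"

    groups = None
    group_labels = None
    if random_intercept:
        group_labels = sorted(train["subpop"].unique().tolist())
        lut = {g: i for i, g in enumerate(group_labels)}
        groups = train["subpop"].map(lut).to_numpy()

    post = fit_logistic_mcmc(
        X,
        y,
        prior_mean,
        prior_sd,
        coef_names=names,
        groups=groups,
        group_labels=group_labels,
        settings=settings,
    )
    return FittedBayesModel(
        variant=variant,
        hierarchical=bool(hierarchical),
        blocks=blocks,
        design=design,
        posterior=post,
        priors=pd.DataFrame({"mean": prior_mean, "sd": prior_sd}, index=names),
        prior_provenance=provenance,
        random_intercept=random_intercept,
    )


def compare_waic(models: Sequence[FittedBayesModel]) -> pd.DataFrame:
    """WAIC ranking with pairwise differences from the best model.

    All models must share the identical response vector; delta-WAIC standard
    errors come from the pointwise WAIC contributions.
    """
    if not models:
        raise ValueError("no models to compare")
    ordered = sorted(models, key=lambda m: m.waic)
    best = ordered[0]
    rows = []
    for m in ordered:
        if m is best:
            delta, dse = 0.0, 0.0
        else:
            delta, dse = waic_difference(m.posterior, best.posterior)
        rows.append(
            {
                "variant": m.variant,
                "hierarchical": m.hierarchical,
                "waic": m.waic,
                "waic_se": m.waic_se,
                "p_waic": m.posterior.p_waic,
                "delta_waic": delta,
                "delta_se": dse,
                "converged": m.converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Threshold and classification rates of one model."""

    threshold: float
    percentile: float
    tpr_train: float
    tnr_train: float
    tpr_validation: float
    tnr_validation: float
    binary_map: Optional[np.ndarray] = None
    probability_map: Optional[np.ndarray] = None


def threshold_and_evaluate(
    model: FittedBayesModel,
    sample: OccurrenceSample,
    layers: Mapping[str, np.ndarray],
    subpop_map: Optional[np.ndarray] = None,
    percentile: float = 90.0,
) -> EvaluationReport:
    """Set the 90th-percentile training-presence cutoff and evaluate.

    The threshold is the (100 - percentile)th percentile of predicted
    probability at training presences, so ``percentile`` percent of training
    presences score at or above it.  True-positive and true-negative rates
    are reported on the training and validation splits; the binary map
    applies the cutoff to the probability raster.
    """
    train = sample.subset("train")
    val = sample.subset("validation")
    p_train = model.predict_table(train, layers)
    pres_scores = p_train[train["presence"].to_numpy() == 1]
    if len(pres_scores) < 10:
        raise ValueError("need at least 10 training presences to set the threshold")
    threshold = float(np.quantile(pres_scores, 1 - percentile / 100, method="lower"))
    if np.ptp(p_train) == 0:
        logger.warning("degenerate threshold: all training predictions identical")

    def rates(tab: pd.DataFrame, p: np.ndarray) -> Tuple[float, float]:
        yy = tab["presence"].to_numpy()
        pred = p >= threshold
        tpr = float(pred[yy == 1].mean()) if (yy == 1).any() else np.nan
        tnr = float((~pred[yy == 0]).mean()) if (yy == 0).any() else np.nan
        return tpr, tnr

    tpr_t, tnr_t = rates(train, p_train)
    p_val = model.predict_table(val, layers) if len(val) else np.array([])
    tpr_v, tnr_v = rates(val, p_val) if len(val) else (np.nan, np.nan)

    prob_map = None
    binary_map = None
    if subpop_map is not None:
        prob_map = model.predict_map(layers, subpop_map=subpop_map)
        binary_map = prob_map >= threshold
    model.threshold = threshold
    return EvaluationReport(
        threshold=threshold,
        percentile=percentile,
        tpr_train=tpr_t,
        tnr_train=tnr_t,
        tpr_validation=tpr_v,
        tnr_validation=tnr_v,
        binary_map=binary_map,
        probability_map=prob_map,
    )
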