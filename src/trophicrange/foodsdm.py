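"""Ensemble habitat models for food species.

Occurrence points are aggregated to 1-km presence cells (a cell with one or
more points counts once); species with fewer than 50 presence cells are
excluded.  Pseudo-absences are drawn uniformly, one per presence, from the
annulus more than 3 km but at most 10 km from the nearest presence cell,
which keeps background sampling under the same spatial bias as the
presences.  Habitat suitability is a small, documented ensemble: a
regularized logistic regression with quadratic terms and gradient-boosted
trees, each evaluated on a held-out stratified split and weighted by its
true skill statistic (TSS = sensitivity + specificity - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

logger = logging.getLogger(__name__)

MIN_PRESENCE_CELLS = 50


@dataclass
class PresenceGrid:
    """Deduplicated presence cells of one species on the 1-km grid."""

    species_id: str
    cells: np.ndarray  # (k, 2) int array of (row, col), lexicographically sorted
    shape: Tuple[int, int]
    min_presences: int = MIN_PRESENCE_CELLS

    @property
    def count(self) -> int:
        return len(self.cells)

    @property
    def excluded(self) -> bool:
        """True when the species falls below the presence-cell threshold."""
        return self.count < self.min_presences

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.cells[:, 0], self.cells[:, 1]] = True
        return m


def grid_presences(
    occurrences: pd.DataFrame,
    species_id: str,
    shape: Tuple[int, int],
    min_presences: int = MIN_PRESENCE_CELLS,
) -> PresenceGrid:
    """Collapse a species' occurrence points to unique presence cells."""
    sub = occurrences[occurrences["species_id"] == species_id]
    if sub.empty:
        raise ValueError(f"no occurrences for species {species_id!r}")
    cells = np.unique(sub[["row", "col"]].to_numpy(int), axis=0)
    if (cells < 0).any() or (cells[:, 0] >= shape[0]).any() or (cells[:, 1] >= shape[1]).any():
        raise ValueError("occurrence outside grid bounds")
    return PresenceGrid(species_id=species_id, cells=cells, shape=shape, min_presences=min_presences)


def sample_pseudoabsences_annulus(
    presences: PresenceGrid,
    inner_km: float = 3.0,
    outer_km: float = 10.0,
    seed: int = 0,
    n: Optional[int] = None,
    cell_km: float = 1.0,
) -> np.ndarray:
    """Sample pseudo-absence cells from a distance annulus around presences.

    Candidate cells have nearest-presence distance in (``inner_km``,
    ``outer_km``]; by default as many cells as there are presences are drawn
    uniformly without replacement.
    """
    n = presences.count if n is None else n
    dist = ndimage.distance_transform_edt(~presences.mask()) * cell_km
    cand = np.argwhere((dist > inner_km) & (dist <= outer_km))
    if len(cand) < n:
        raise ValueError(
            f"annulus ({inner_km}, {outer_km}] km holds {len(cand)} candidate cells, "
            f"but {n} pseudo-absences are required"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cand), size=n, replace=False)
    return cand[idx]


def make_pa_table(
    presence_cells: np.ndarray,
    absence_cells: np.ndarray,
    layers: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Presence/absence table with layer values at each cell."""
    cells = np.vstack([presence_cells, absence_cells])
    y = np.r_[np.ones(len(presence_cells)), np.zeros(len(absence_cells))]
    out = pd.DataFrame({"row": cells[:, 0], "col": cells[:, 1], "presence": y})
    for name, arr in layers.items():
        out[name] = arr[cells[:, 0], cells[:, 1]]
    return out


def _correlation_filter(X: pd.DataFrame, r_threshold: float) -> List[str]:
    """Drop one of each |r| > threshold pair (the one more correlated overall)."""
    keep = list(X.columns)
    while len(keep) > 1:
        corr = X[keep].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        if corr.values[i, j] <= r_threshold:
            break
        a, b = corr.index[i], corr.columns[j]
        mean_a, mean_b = corr.loc[a].mean(), corr.loc[b].mean()
        drop = a if (mean_a, str(a)) > (mean_b, str(b)) else b
        keep.remove(drop)
    return keep


def select_species_variables(
    pa_table: pd.DataFrame,
    candidates: Sequence[str],
    max_vars: int = 6,
    r_threshold: float = 0.7,
) -> List[str]:
    """Correlation filter, then AIC ranking of univariable quadratic logits.

    After dropping pairwise-correlated candidates (|r| > ``r_threshold``),
    the remaining variables are ranked by the AIC of a univariable binomial
    GLM with linear + quadratic terms and the best ``max_vars`` kept.  Ties
    break deterministically by variable name.
    """
    y = pa_table["presence"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("presence/absence table needs both classes")
    X = pa_table[list(candidates)]
    keep = _correlation_filter(X, r_threshold)
    if not keep:
        raise ValueError("no candidate variables survive the correlation filter")
    scored = []
    for name in keep:
        z = X[name].to_numpy(float)
        s = z.std()
        z = (z - z.mean()) / (s if s > 0 else 1.0)
        design = sm.add_constant(np.column_stack([z, z**2]))
        try:
            aic = sm.Logit(y, design).fit(disp=0).aic
        except Exception:  # perfect separation etc.
            aic = np.inf
        scored.append((aic, name))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [name for _, name in scored[:max_vars]]


def _tss_threshold(y: np.ndarray, p: np.ndarray) -> Tuple[float, float]:
    """(threshold, TSS) maximizing sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(y, p)
    k = int(np.argmax(tpr - fpr))
    return float(thr[k]), float(tpr[k] - fpr[k])


def _evaluate(y: np.ndarray, p: np.ndarray, threshold: float) -> Tuple[float, float, float]:
    pred = p >= threshold
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float((~pred[neg]).mean()) if neg.any() else np.nan
    return sens, spec, sens + spec - 1.0


@dataclass
class EnsembleModel:
    """TSS-weighted ensemble of habitat-suitability members for one species."""

    species_id: str
    variables: List[str]
    members: List[Tuple[str, object]]
    weights: np.ndarray
    sensitivity: float
    specificity: float
    tss: float
    threshold: float
    n_train: int
    n_test: int

    def _features(self, layers: Mapping[str, np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
        missing = [v for v in self.variables if v not in layers]
        if missing:
            raise KeyError(f"missing layers {missing} for species {self.species_id!r}")
        stack = np.stack([np.asarray(layers[v], dtype=float) for v in self.variables])
        valid = np.isfinite(stack).all(axis=0)
        feats = stack[:, valid].T
        return feats, valid

    def predict_grid(self, layers: Mapping[str, np.ndarray]) -> np.ndarray:
        """Weighted-mean member probability per cell; nodata propagates as NaN."""
        feats, valid = self._features(layers)
        out = np.full(valid.shape, np.nan)
        out[valid] = self.predict(feats)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = np.stack([m.predict_proba(X)[:, 1] for _, m in self.members])
        return np.average(probs, axis=0, weights=self.weights)

    def member_grids(self, layers: Mapping[str, np.ndarray]) -> Dict[str, np.ndarray]:
        feats, valid = self._features(layers)
        out = {}
        for name, m in self.members:
            g = np.full(valid.shape, np.nan)
            g[valid] = m.predict_proba(feats)[:, 1]
            out[name] = g
        return out


def fit_ensemble(
    pa_table: pd.DataFrame,
    variables: Sequence[str],
    seed: int = 0,
    test_frac: float = 0.2,
    species_id: str = "species",
) -> EnsembleModel:
    """Fit the two-member ensemble on an 80/20 stratified split.

    Members: (a) standardized quadratic logistic regression, (b) shallow
    gradient-boosted trees.  Member weights are their TSS on the held-out
    split (clipped at zero; equal weights if no member has skill).  The
    ensemble threshold maximizes TSS on the training predictions and the
    reported sensitivity/specificity/TSS come from the held-out split.
    """
    y = pa_table["presence"].to_numpy(float)
    X = pa_table[list(variables)].to_numpy(float)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_frac, stratify=y, random_state=seed
    )
    if ytr.min() == ytr.max() or yte.min() == yte.max():
        raise ValueError("both classes required in train and test splits")

    candidates: List[Tuple[str, object]] = [
        (
            "logistic_quadratic",
            make_pipeline(
                StandardScaler(),
                PolynomialFeatures(degree=2, include_bias=False),
                LogisticRegression(max_iter=2000, C=1.0),
            ),
        ),
        (
            "gradient_boosting",
            HistGradientBoostingClassifier(
                max_depth=3, max_iter=150, learning_rate=0.1, random_state=seed
            ),
        ),
    ]
    members: List[Tuple[str, object]] = []
    weights: List[float] = []
    for name, est in candidates:
        try:
            est.fit(Xtr, ytr)
        except Exception as exc:
            logger.warning("member %s failed to fit and was dropped: %s", name, exc)
            continue
        thr_m, _ = _tss_threshold(ytr, est.predict_proba(Xtr)[:, 1])
        _, _, tss_m = _evaluate(yte, est.predict_proba(Xte)[:, 1], thr_m)
        members.append((name, est))
        weights.append(max(tss_m, 0.0))
    if not members:
        raise RuntimeError("all ensemble members failed to fit")
    w = np.asarray(weights)
    if w.sum() == 0:
        w = np.ones(len(members))
    w = w / w.sum()

    model = EnsembleModel(
        species_id=species_id,
        variables=list(variables),
        members=members,
        weights=w,
        sensitivity=np.nan,
        specificity=np.nan,
        tss=np.nan,
        threshold=np.nan,
        n_train=len(ytr),
        n_test=len(yte),
    )
    p_tr = model.predict(Xtr)
    thr, _ = _tss_threshold(ytr, p_tr)
    sens, spec, tss = _evaluate(yte, model.predict(Xte), thr)
    model.threshold = thr
    model.sensitivity = sens
    model.specificity = spec
    model.tss = tss
    return model


def predict_suitability(
    model: EnsembleModel,
    landscape,
    scenario: Optional[str] = None,
    extra_layers: Optional[Mapping[str, np.ndarray]] = None,
) -> np.ndarray:
    """Suitability raster in [0, 1] under current or scenario layers."""
    layers = dict(landscape.layers_for(scenario))
    if extra_layers:
        layers.update(extra_layers)
    return model.predict_grid(layers)


def member_prediction_bounds(
    model: EnsembleModel,
    layers: Mapping[str, np.ndarray],
    lower_q: float = 2.5,
    upper_q: float = 97.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Percentile envelope of the member predictions (suitability uncertainty)."""
    grids = np.stack(list(model.member_grids(layers).values()))
    return (
        np.percentile(grids, lower_q, axis=0),
        np.percentile(grids, upper_q, axis=0),
    )
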