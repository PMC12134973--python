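"""Diet-environment associations: buffer covariates and averaged linear models.

Environmental covariates are summarized as layer means within an 18-km
buffer around each diet-study site (about 1018 km^2 of 1-km cells), highly
collinear covariates are dropped by iterative VIF filtering, and each
response (a food category's energy share, or a diet diversity index) is
regressed on every subset of the retained covariates.  The candidate models
within delta-AICc < 3 of the best one are combined by conditional ("subset")
model averaging with renormalized Akaike weights.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .grids import GridStack

logger = logging.getLogger(__name__)

DELTA_AICC_CUTOFF = 3.0


def buffer_offsets(radius_km: float, cell_km: float = 1.0) -> np.ndarray:
    """(dy, dx) cell offsets whose centers lie within ``radius_km`` (inclusive)."""
    r = int(np.floor(radius_km / cell_km))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = (dy**2 + dx**2) * cell_km**2 <= radius_km**2
    return np.column_stack([dy[keep], dx[keep]])


def extract_buffer_covariates(
    landscape: GridStack,
    sites: pd.DataFrame,
    radius_km: float = 18.0,
) -> pd.DataFrame:
    """Mean of every layer within a circular buffer around each site.

    ``sites`` needs ``row`` and ``col`` columns (and optionally ``study_id``).
    A cell belongs to the buffer when its center is within ``radius_km`` of
    the site's cell center; buffers are truncated at the grid edge and the
    used cell count is reported as ``n_cells``.
    """
    nrow, ncol = landscape.shape
    offs = buffer_offsets(radius_km, landscape.cell_km)
    records = []
    for _, site in sites.iterrows():
        r, c = int(site["row"]), int(site["col"])
        if not (0 <= r < nrow and 0 <= c < ncol):
            raise ValueError(f"site ({r}, {c}) outside grid {landscape.shape}")
        rr = offs[:, 0] + r
        cc = offs[:, 1] + c
        ok = (rr >= 0) & (rr < nrow) & (cc >= 0) & (cc < ncol)
        rr, cc = rr[ok], cc[ok]
        rec = {"n_cells": int(ok.sum())}
        if "study_id" in site.index:
            rec["study_id"] = site["study_id"]
        n_valid = None
        for name, arr in landscape.layers.items():
            vals = arr[rr, cc]
            finite = np.isfinite(vals)
            if not finite.any():
                raise ValueError(f"buffer at ({r}, {c}) entirely nodata for layer {name!r}")
            rec[name] = float(vals[finite].mean())
        records.append(rec)
    out = pd.DataFrame(records)
    lead = [c for c in ("study_id", "n_cells") if c in out.columns]
    return out[lead + [c for c in out.columns if c not in lead]]


@dataclass
class VifResult:
    retained: List[str]
    dropped: List[Tuple[str, float]]  # (name, VIF at the time it was dropped)

    @property
    def drop_order(self) -> List[str]:
        return [n for n, _ in self.dropped]


def _vifs(X: pd.DataFrame) -> pd.Series:
    """VIF_k = 1 / (1 - R^2) of each column regressed on the others."""
    out = {}
    for name in X.columns:
        others = sm.add_constant(X.drop(columns=[name]).to_numpy())
        r2 = sm.OLS(X[name].to_numpy(), others).fit().rsquared
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_filter(covariates: pd.DataFrame, threshold: float = 10.0) -> VifResult:
    """Iteratively drop the highest-VIF covariate until all VIF <= threshold."""
    X = covariates.copy()
    if X.shape[1] < 2:
        raise ValueError("need at least two covariates")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than covariates")
    dropped: List[Tuple[str, float]] = []
    while X.shape[1] >= 2:
        vifs = _vifs(X)
        worst = vifs.idxmax()
        if vifs[worst] <= threshold:
            break
        logger.info("VIF filter: dropping %s (VIF = %.2f)", worst, vifs[worst])
        dropped.append((worst, float(vifs[worst])))
        X = X.drop(columns=[worst])
    return VifResult(retained=list(X.columns), dropped=dropped)


@dataclass
class AveragedModelResult:
    """All-subsets AICc table and conditionally averaged coefficients."""

    response: str
    model_table: pd.DataFrame  # terms, k, aicc, delta, weight, in_subset
    coefficients: pd.DataFrame  # estimate, se, z, p, weight (per term)
    best_terms: Tuple[str, ...]
    best_coefficients: pd.DataFrame  # estimate, se, p from the single best model
    retained: List[str]


def _aicc(llf: float, k: int, n: int) -> float:
    return -2 * llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_averaged_models(
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    response_name: str = "response",
    max_terms: Optional[int] = None,
) -> AveragedModelResult:
    """All-subsets OLS with AICc ranking and conditional model averaging.

    Every subset of the covariates (up to ``max_terms``, default all columns
    capped at 8 to bound the 2^k enumeration) is fitted by OLS.  Candidate
    models within delta AICc < 3 of the best receive renormalized Akaike
    weights; each term's averaged coefficient is the weighted mean over the
    subset models *containing* it (conditional averaging), with an
    unconditional-variance standard error.  Significance is reported both as
    the averaged-model z-test and the best model's t-test, asserting neither.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    names = list(covariates.columns)
    n = len(y)
    max_terms = min(len(names), 8) if max_terms is None else min(max_terms, len(names))

    rows = []
    fits = {}
    for size in range(0, max_terms + 1):
        for combo in itertools.combinations(names, size):
            k = len(combo) + 2  # intercept + residual variance
            if n - k - 1 <= 0:
                logger.info("skipping %s: n too small for AICc", combo)
                continue
            X = sm.add_constant(covariates[list(combo)].to_numpy()) if combo else np.ones((n, 1))
            fit = sm.OLS(y, X).fit()
            fits[combo] = fit
            rows.append({"terms": combo, "k": k, "aicc": _aicc(fit.llf, k, n)})
    if not rows:
        raise ValueError("no candidate model could be fitted (n too small)")
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta"] = table["aicc"] - table["aicc"].iloc[0]
    table["in_subset"] = table["delta"] < DELTA_AICC_CUTOFF
    w = np.exp(-table.loc[table["in_subset"], "delta"] / 2)
    table["weight"] = np.nan
    table.loc[table["in_subset"], "weight"] = w / w.sum()

    subset = table[table["in_subset"]]
    coef_rows = []
    for term in names:
        members = subset[[term in t for t in subset["terms"]]]
        if members.empty:
            continue
        ws = members["weight"].to_numpy()
        ws = ws / ws.sum()
        est = np.array([fits[t].params[list(t).index(term) + 1] for t in members["terms"]])
        ses = np.array([fits[t].bse[list(t).index(term) + 1] for t in members["terms"]])
        avg = float(ws @ est)
        se = float(np.sqrt(ws @ (ses**2 + (est - avg) ** 2)))
        z = avg / se if se > 0 else np.inf
        coef_rows.append(
            {
                "term": term,
                "estimate": avg,
                "se": se,
                "z": z,
                "p": 2 * norm.sf(abs(z)),
                "weight": float(members["weight"].sum()),
            }
        )
    coefficients = pd.DataFrame(coef_rows).set_index("term") if coef_rows else pd.DataFrame(
        columns=["estimate", "se", "z", "p", "weight"]
    )

    best_terms = table["terms"].iloc[0]
    bf = fits[best_terms]
    best = pd.DataFrame(
        {
            "estimate": bf.params[1:] if best_terms else [],
            "se": bf.bse[1:] if best_terms else [],
            "p": bf.pvalues[1:] if best_terms else [],
        },
        index=list(best_terms),
    )
    return AveragedModelResult(
        response=response_name,
        model_table=table,
        coefficients=coefficients,
        best_terms=tuple(best_terms),
        best_coefficients=best,
        retained=names,
    )


def diet_diversity(shares: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Shannon, Simpson and inverse-Simpson diversity of category shares.

    One row per study; shares must be simplex-valued.  H = -sum p ln p,
    Simpson D = 1 - sum p^2, inverse Simpson = 1 / sum p^2.
    """
    P = shares.to_numpy(dtype=float)
    if (P < -tol).any():
        raise ValueError("negative share")
    if np.abs(P.sum(axis=1) - 1).max() > 1e-6:
        raise ValueError("shares must sum to 1 per row")
    P = np.clip(P, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    ss = (P**2).sum(axis=1)
    return pd.DataFrame(
        {
            "shannon": -plogp.sum(axis=1),
            "simpson": 1.0 - ss,
            "inv_simpson": 1.0 / ss,
        },
        index=shares.index,
    )
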