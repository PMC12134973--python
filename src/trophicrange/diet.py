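"""Dietary energetics: from diet-study tables to per-subpopulation diets.

A diet study reports, for each food item i, the relative frequency of
occurrence rF_i = f_i / sum f_i and (when volumes were recorded) the relative
volume rV_i = v_i / sum v_i.  Volumes missing from a study are imputed from
the pooled rF-rV relationship across complete studies.  The relative
estimated dietary energy content is then

    rEDEC_i = CF_Ei * rEDC_i / sum_j (CF_Ej * rEDC_j)

where CF_E is an item-specific energy correction factor and rEDC the
(volume-)corrected relative content, rEDC_i = rV_i by default.  A
subpopulation's representative diet weights each study by its number of
sampling units Z (scats or stomachs):

    rEDEC_SubpS = sum_i Z_i * rEDEC_Si / sum_i Z_i

with rEDEC_Si = 0 for studies not recording species S.  Items resolved only
above species level stay out of the per-species representative diet but are
kept in food-category and wild/human-origin energy summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical food categories.
CATEGORIES = (
    "reproductive plants",
    "vegetative plants",
    "unknown plants",
    "invertebrates",
    "vertebrates",
)

#: Item origins.
ORIGINS = ("wild", "human-derived")

#: Columns of the per-item table inside a :class:`DietStudy` (one row per
#: food item record): ``item_id``, ``species_id`` (NaN when the item is not
#: resolved to species), ``category``, ``origin``, ``f`` (occurrence count),
#: ``rF``, ``v`` (volume, optional), ``rV`` (optional until imputed),
#: ``rv_imputed`` (bool), ``cf_e`` (energy correction factor), ``rEDC``,
#: ``rEDEC``.
ITEM_COLUMNS = (
    "item_id",
    "species_id",
    "category",
    "origin",
    "f",
    "rF",
    "v",
    "rV",
    "rv_imputed",
    "cf_e",
    "rEDC",
    "rEDEC",
)

_SIMPLEX_TOL = 1e-9


@dataclass
class DietStudy:
    """One diet study: metadata plus its per-item record table."""

    study_id: str
    subpop: int | str
    row: int
    col: int
    sample_type: str  # "scat" or "stomach"
    z: int  # number of sampling units
    items: pd.DataFrame
    year_range: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError(f"study {self.study_id}: Z must be >= 1, got {self.z}")
        if len(self.items) == 0:
            raise ValueError(f"study {self.study_id}: empty item list")
        items = self.items.copy()
        for col in ITEM_COLUMNS:
            if col not in items.columns:
                items[col] = (
                    False if col == "rv_imputed" else np.nan
                )
        self.items = items[list(ITEM_COLUMNS)].reset_index(drop=True)
        bad = set(items["category"].dropna()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"study {self.study_id}: unknown categories {sorted(bad)}")

    @property
    def has_rv(self) -> bool:
        return bool(self.items["rV"].notna().all())

    def copy(self) -> "DietStudy":
        return replace(self, items=self.items.copy())


@dataclass
class SubpopulationDiet:
    """Representative diet of one subpopulation.

    ``species`` has one row per food species recorded in the subpopulation
    (index: species id; columns ``category``, ``origin``, ``redec``).  The
    per-species shares need not sum to 1: items unresolved to species account
    for the remainder, reported as ``unresolved``.
    """

    subpop: int | str
    species: pd.DataFrame
    category_redec: pd.Series
    origin_redec: pd.Series
    n_studies: int
    total_z: int

    @property
    def unresolved(self) -> float:
        return float(1.0 - self.species["redec"].sum())

    def species_redec(self, species_id: str) -> float:
        """rEDEC_SubpS; 0 for species recorded in no study of the subpopulation."""
        if species_id in self.species.index:
            return float(self.species.loc[species_id, "redec"])
        return 0.0

    @property
    def observed_species(self) -> frozenset:
        return frozenset(self.species.index)


@dataclass
class RvImputationReport:
    """Fit and bootstrap summary of the pooled rF-rV relationship."""

    r: float
    ci_low: float
    ci_high: float
    slope: float
    intercept: float
    n_pooled: int
    n_bootstrap: int
    n_imputed_items: int
    n_imputed_studies: int


def impute_rv(
    studies: Sequence[DietStudy],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> Tuple[List[DietStudy], RvImputationReport]:
    """Impute missing relative volumes from the pooled rF-rV relationship.

    An ordinary least-squares line rV ~ rF is fitted on items pooled over all
    studies reporting both quantities; items in incomplete studies get the
    predicted value, clipped at zero and renormalized within each study.
    The report carries the pooled Pearson r with a percentile bootstrap 95%
    confidence interval (resampling items).  Observed rV values are never
    altered.
    """
    complete = [s for s in studies if s.has_rv]
    if len(complete) < 2:
        raise ValueError("need >= 2 studies reporting rV to fit the rF-rV relationship")
    rf = np.concatenate([s.items["rF"].to_numpy(float) for s in complete])
    rv = np.concatenate([s.items["rV"].to_numpy(float) for s in complete])
    if np.ptp(rf) == 0:
        raise ValueError("degenerate fit: pooled rF has zero variance")

    slope, intercept = np.polyfit(rf, rv, 1)
    r = float(np.corrcoef(rf, rv)[0, 1])

    rng = np.random.default_rng(seed)
    n = len(rf)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    bx, by = rf[idx], rv[idx]
    bx = bx - bx.mean(axis=1, keepdims=True)
    by = by - by.mean(axis=1, keepdims=True)
    denom = np.sqrt((bx**2).sum(1) * (by**2).sum(1))
    rs = np.divide((bx * by).sum(1), denom, out=np.zeros(n_bootstrap), where=denom > 0)
    ci_low, ci_high = np.percentile(rs, [2.5, 97.5])

    out: List[DietStudy] = []
    n_items = 0
    n_stud = 0
    for s in studies:
        s = s.copy()
        missing = s.items["rV"].isna()
        if missing.any():
            pred = np.clip(intercept + slope * s.items.loc[missing, "rF"], 0.0, None)
            s.items.loc[missing, "rV"] = pred
            tot = s.items["rV"].sum()
            if tot <= 0:
                raise ValueError(f"study {s.study_id}: imputed rV sums to zero")
            s.items["rV"] = s.items["rV"] / tot
            s.items.loc[missing, "rv_imputed"] = True
            n_items += int(missing.sum())
            n_stud += 1
        out.append(s)
    report = RvImputationReport(
        r=r,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        slope=float(slope),
        intercept=float(intercept),
        n_pooled=n,
        n_bootstrap=n_bootstrap,
        n_imputed_items=n_items,
        n_imputed_studies=n_stud,
    )
    return out, report


def _lookup_cf(
    items: pd.DataFrame, cf_table: Optional[pd.DataFrame], column: str, default: float
) -> np.ndarray:
    """Correction-factor lookup: item-specific row, else category default."""
    if cf_table is None:
        if column == "cf_e":
            vals = items["cf_e"].to_numpy(float)
            if np.isnan(vals).any():
                missing = items.loc[items["cf_e"].isna(), "item_id"].tolist()
                raise KeyError(f"no CF_E for items {missing} and no cf_table given")
            return vals
        return np.full(len(items), default)
    if column not in cf_table.columns:
        return np.full(len(items), default)
    by_item = cf_table.dropna(subset=["item_id"]).set_index("item_id")[column]
    by_cat = (
        cf_table[cf_table["item_id"].isna()].set_index("category")[column]
        if "category" in cf_table.columns
        else pd.Series(dtype=float)
    )
    vals = np.empty(len(items))
    for k, (iid, cat) in enumerate(zip(items["item_id"], items["category"])):
        if iid in by_item.index and pd.notna(by_item.get(iid)):
            vals[k] = by_item[iid]
        elif cat in by_cat.index and pd.notna(by_cat.get(cat)):
            vals[k] = by_cat[cat]
        else:
            raise KeyError(f"no {column} for item {iid!r} (category {cat!r})")
    return vals


def compute_redec(
    study: DietStudy,
    cf_table: Optional[pd.DataFrame] = None,
    volume_correction: bool = False,
) -> DietStudy:
    """Fill rEDC and rEDEC for one study.

    ``cf_table`` (columns ``item_id`` — NaN for category-default rows,
    ``category``, ``cf_e``, optional ``cf_v``) supplies correction factors;
    without it the study's own ``cf_e`` column is used.  rEDC_i defaults to
    rV_i; with ``volume_correction`` it is rV_i * CF_Vi renormalized.
    """
    s = study.copy()
    rv = s.items["rV"].to_numpy(float)
    if np.isnan(rv).any():
        raise ValueError(f"study {s.study_id}: rV incomplete; impute first")
    cf_e = _lookup_cf(s.items, cf_table, "cf_e", 1.0)
    redc = rv * (_lookup_cf(s.items, cf_table, "cf_v", 1.0) if volume_correction else 1.0)
    tot = redc.sum()
    if tot <= 0:
        raise ValueError(f"study {s.study_id}: rEDC sums to zero")
    redc = redc / tot
    num = cf_e * redc
    den = num.sum()
    if den <= 0:
        raise ValueError(f"study {s.study_id}: all CF_E * rEDC are zero")
    s.items["cf_e"] = cf_e
    s.items["rEDC"] = redc
    s.items["rEDEC"] = num / den
    return s


def aggregate_subpopulation_diet(
    studies: Sequence[DietStudy], subpop: int | str
) -> SubpopulationDiet:
    """Z-weighted representative diet of one subpopulation.

    Species absent from a study contribute rEDEC = 0 there, so each species'
    representative share is sum_i Z_i * rEDEC_Si / sum_i Z_i over *all*
    studies of the subpopulation.
    """
    members = [s for s in studies if s.subpop == subpop]
    if not members:
        raise ValueError(f"no studies in subpopulation {subpop!r}")
    for s in members:
        if s.items["rEDEC"].isna().any():
            raise ValueError(f"study {s.study_id}: rEDEC not computed")
    total_z = sum(s.z for s in members)

    species_acc: Dict[str, Dict[str, object]] = {}
    cat_acc = pd.Series(0.0, index=list(CATEGORIES))
    orig_acc = pd.Series(0.0, index=list(ORIGINS))
    for s in members:
        it = s.items
        sp = it.dropna(subset=["species_id"])
        for spid, grp in sp.groupby("species_id"):
            rec = species_acc.setdefault(
                spid,
                {"category": grp["category"].iloc[0], "origin": grp["origin"].iloc[0], "wsum": 0.0},
            )
            rec["wsum"] += s.z * float(grp["rEDEC"].sum())
        cat_acc = cat_acc.add(s.z * it.groupby("category")["rEDEC"].sum(), fill_value=0.0)
        orig_acc = orig_acc.add(s.z * it.groupby("origin")["rEDEC"].sum(), fill_value=0.0)

    species = pd.DataFrame(
        {
            "category": {k: v["category"] for k, v in species_acc.items()},
            "origin": {k: v["origin"] for k, v in species_acc.items()},
            "redec": {k: v["wsum"] / total_z for k, v in species_acc.items()},
        }
    )
    species.index.name = "species_id"
    species = species.sort_index()
    return SubpopulationDiet(
        subpop=subpop,
        species=species,
        category_redec=(cat_acc / total_z).reindex(list(CATEGORIES)).fillna(0.0),
        origin_redec=(orig_acc / total_z).reindex(list(ORIGINS)).fillna(0.0),
        n_studies=len(members),
        total_z=total_z,
    )


def classify_items(study: DietStudy) -> Tuple[pd.Series, pd.Series]:
    """Per-category and per-origin rEDEC shares of one study (each sums to 1)."""
    it = study.items
    if it["rEDEC"].isna().any():
        raise ValueError(f"study {study.study_id}: rEDEC not computed")
    if it["category"].isna().any() or it["origin"].isna().any():
        raise ValueError(f"study {study.study_id}: unlabeled items")
    bad = set(it["origin"]) - set(ORIGINS)
    if bad:
        raise ValueError(f"unknown origin labels {sorted(bad)}")
    cat = it.groupby("category")["rEDEC"].sum().reindex(list(CATEGORIES)).fillna(0.0)
    orig = it.groupby("origin")["rEDEC"].sum().reindex(list(ORIGINS)).fillna(0.0)
    return cat, orig


# ---------------------------------------------------------------------------
# CSV interchange

_STUDY_COLS = ("study_id", "subpop", "row", "col", "sample_type", "Z")


def studies_to_frame(studies: Sequence[DietStudy]) -> pd.DataFrame:
    """Flatten studies to one row per item (documented interchange format)."""
    frames = []
    for s in studies:
        it = s.items.copy()
        it.insert(0, "study_id", s.study_id)
        it.insert(1, "subpop", s.subpop)
        it.insert(2, "row", s.row)
        it.insert(3, "col", s.col)
        it.insert(4, "sample_type", s.sample_type)
        it.insert(5, "Z", s.z)
        frames.append(it)
    return pd.concat(frames, ignore_index=True)


def studies_from_frame(df: pd.DataFrame) -> List[DietStudy]:
    """Inverse of :func:`studies_to_frame`."""
    out = []
    for sid, grp in df.groupby("study_id", sort=False):
        head = grp.iloc[0]
        out.append(
            DietStudy(
                study_id=str(sid),
                subpop=head["subpop"],
                row=int(head["row"]),
                col=int(head["col"]),
                sample_type=str(head["sample_type"]),
                z=int(head["Z"]),
                items=grp.drop(columns=list(_STUDY_COLS)).reset_index(drop=True),
            )
        )
    return out


def write_studies_csv(path: str | Path, studies: Sequence[DietStudy]) -> None:
    studies_to_frame(studies).to_csv(path, index=False)


def read_studies_csv(path: str | Path) -> List[DietStudy]:
    return studies_from_frame(pd.read_csv(path))
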