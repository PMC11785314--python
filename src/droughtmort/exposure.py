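"""Analysis-dataset construction.

Turns survey tables plus a SPEI grid into the counting-process
person-month table the hazard models consume:

* household wealth quintiles from the first principal component of the
  standardized asset indicators;
* cluster-to-grid-cell linkage by nearest cell centre;
* per-child exposure windows spanning the 9 gestation months through
  death or the 12th month after birth (10-21 months);
* the person-month expansion with time-varying drought indicators.

Time convention: the survival clock starts at conception (entry 0),
deaths become possible from month 9; an option restarts the clock at
birth for the corresponding sensitivity analysis.  The day-based record
of death maps to a 0-based postnatal month as ``floor(days / 30.44)``
capped at 11; neonatal means ``days <= 27``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.decomposition import PCA

from .errors import CoverageError, DegenerateSampleError, LinkageError
from .spei import CLASS_MILD, CLASS_MISSING, CLASS_SEVERE
from .synth import DAYS_PER_MONTH, GESTATION_MONTHS

__all__ = [
    "wealth_index",
    "link_cluster_to_cell",
    "exposure_window",
    "build_person_months",
    "count_drought_months",
    "death_month_from_days",
    "ExposureWindow",
]


def death_month_from_days(age_days):
    """0-based postnatal month of death: floor(days/30.44), capped at 11."""
    days = np.asarray(age_days, dtype=float)
    return np.minimum(np.floor(days / DAYS_PER_MONTH), 11).astype(int)


# ---------------------------------------------------------------------------
# wealth index


def wealth_index(assets: pd.DataFrame, household_col: str = "household_id"):
    """Household wealth quintiles from the first principal component.

    Asset indicator columns are standardized (constant columns dropped);
    PC1 is oriented so that owning more assets scores higher, and
    quintiles are cut at the 20/40/60/80 percentiles of the score
    (scores tied with a cut go to the lower quintile).

    Returns a DataFrame with ``household_id``, ``wealth_score`` and
    ``wealth_quintile`` (1-5).

    Raises :class:`DegenerateSampleError` when fewer than two distinct
    asset patterns exist (e.g. all households identical).
    """
    cols = [c for c in assets.columns if c != household_col]
    mat = assets[cols].to_numpy(dtype=float)
    if np.unique(mat, axis=0).shape[0] < 2:
        raise DegenerateSampleError("fewer than 2 distinct asset patterns")
    sd = mat.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise DegenerateSampleError("zero-variance asset matrix")
    z = (mat[:, keep] - mat[:, keep].mean(axis=0)) / sd[keep]
    score = PCA(n_components=1, svd_solver="full").fit_transform(z)[:, 0]
    if np.corrcoef(score, z.sum(axis=1))[0, 1] < 0:
        score = -score
    cuts = np.percentile(score, [20, 40, 60, 80])
    quintile = np.searchsorted(cuts, score, side="left") + 1
    return pd.DataFrame({
        household_col: assets[household_col].to_numpy(),
        "wealth_score": score,
        "wealth_quintile": quintile,
    })


# ---------------------------------------------------------------------------
# linkage


def link_cluster_to_cell(lat, lon, grid: xr.Dataset, cluster_ids=None):
    """Nearest-cell-centre linkage of cluster coordinates to grid cells.

    Cells are ``resolution``-degree squares around the centres in
    ``grid.lat``/``grid.lon``; a coordinate equidistant from two centres
    (on a shared edge) goes to the lower index.  Clusters outside the
    grid bounding box (centres +- half a cell) raise
    :class:`LinkageError` listing the offending clusters.

    Returns integer arrays ``(lat_idx, lon_idx)``.
    """
    lats = grid["lat"].values
    lons = grid["lon"].values
    res = float(grid.attrs.get("resolution_deg", np.diff(lats).mean() if lats.size > 1 else 0.1))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    half = res / 2
    out = (
        (lat < lats.min() - half) | (lat > lats.max() + half)
        | (lon < lons.min() - half) | (lon > lons.max() + half)
    )
    if np.any(out):
        ids = (np.asarray(cluster_ids)[out] if cluster_ids is not None
               else np.flatnonzero(out))
        raise LinkageError(f"clusters outside grid bounding box: {list(ids[:10])}")
    fi = (lat - lats[0]) / res
    fj = (lon - lons[0]) / res
    i = np.clip(np.ceil(fi - 0.5).astype(int), 0, lats.size - 1)
    j = np.clip(np.ceil(fj - 0.5).astype(int), 0, lons.size - 1)
    return i, j


# ---------------------------------------------------------------------------
# exposure windows


@dataclass(frozen=True)
class ExposureWindow:
    """Per-child monthly drought classes from conception onward.

    ``start_month_index = birth - 9``; the window ends at the month of
    death (0-based postnatal month from the day record) or at
    ``birth + 11`` for children recorded alive.  The prenatal portion is
    always exactly 9 months; total length is 10-21 months.
    """

    child_id: int
    start_month_index: int
    birth_month_index: int
    classes: np.ndarray  # int8 drought classes, one per month

    def __len__(self):
        return self.classes.size

    @property
    def prenatal_classes(self):
        return self.classes[:GESTATION_MONTHS]

    @property
    def postnatal_classes(self):
        return self.classes[GESTATION_MONTHS:]


def exposure_window(child, spei_series: np.ndarray, series_start: int = 0) -> ExposureWindow:
    """Build one child's exposure window from a per-cell class series.

    ``child`` is a mapping with ``child_id``, ``birth_month_index`` and
    ``age_at_death_days`` (NaN for alive); ``spei_series`` holds integer
    drought classes indexed from month ``series_start``.

    Raises :class:`CoverageError` if any month in the window is missing.
    """
    birth = int(child["birth_month_index"])
    days = child.get("age_at_death_days", np.nan)
    if days is not None and np.isfinite(days):
        end = birth + int(death_month_from_days(days))
    else:
        end = birth + 11
    start = birth - GESTATION_MONTHS
    lo, hi = start - series_start, end - series_start + 1
    if lo < 0 or hi > len(spei_series):
        raise CoverageError(
            f"child {child['child_id']}: window [{start}, {end}] outside the "
            "drought-class series"
        )
    classes = np.asarray(spei_series[lo:hi], dtype=np.int8)
    if np.any(classes == CLASS_MISSING):
        raise CoverageError(
            f"child {child['child_id']}: missing drought class inside window "
            f"[{start}, {end}]"
        )
    return ExposureWindow(int(child["child_id"]), start, birth, classes)


def count_drought_months(window: ExposureWindow, segment: str, severity: str = "any") -> int:
    """Count drought months in the pregnancy or survival segment.

    ``segment`` is ``"pregnancy"`` (exactly the 9 prenatal months) or
    ``"survival"`` (birth month through the end of the window);
    ``severity`` one of ``"any"``, ``"mild"``, ``"severe"``.
    """
    seg = (window.prenatal_classes if segment == "pregnancy"
           else window.postnatal_classes)
    if severity == "any":
        return int(np.sum(seg >= CLASS_MILD))
    if severity == "mild":
        return int(np.sum(seg == CLASS_MILD))
    if severity == "severe":
        return int(np.sum(seg == CLASS_SEVERE))
    raise ValueError(f"unknown severity {severity!r}")


# ---------------------------------------------------------------------------
# person-month expansion


def build_person_months(
    children: pd.DataFrame,
    clusters: pd.DataFrame,
    spei: xr.Dataset,
    severity_mode: str = "any",
    climate: Optional[xr.Dataset] = None,
) -> pd.DataFrame:
    """Counting-process expansion: one row per child-month at risk.

    Each child contributes one row per month of their exposure window on
    the months-since-conception axis (``t`` = 0..len-1); the event flag
    sits on the final row of cases.  Drought indicators follow
    ``severity_mode``: ``"any"`` gives a single binary column
    ``drought_any``; ``"stratified"`` gives ``drought_mild`` and
    ``drought_severe`` dummies against the no-drought reference.

    Time-invariant covariates, the sampling weight, the calendar month of
    the row and the composite country-cluster id are carried along; when
    ``climate`` is given the row's monthly precipitation at the linked
    cell is attached (for the precipitation-spline sensitivity model).
    """
    cl = clusters.set_index("cluster_id")
    lat_idx, lon_idx = link_cluster_to_cell(
        cl["lat"].values, cl["lon"].values, spei, cluster_ids=cl.index.values
    )
    cl_row = children["cluster_id"].map(pd.Series(np.arange(len(cl)), index=cl.index))
    ci = lat_idx[cl_row.values]
    cj = lon_idx[cl_row.values]

    classes = spei["drought_class"].values
    n = len(children)
    birth = children["birth_month_index"].to_numpy()
    days = children["age_at_death_days"].to_numpy(dtype=float)
    died = np.isfinite(days)
    death_m = np.where(died, death_month_from_days(np.where(died, days, 0)), -1)
    length = np.where(died, GESTATION_MONTHS + death_m + 1, 21).astype(int)

    start = birth - GESTATION_MONTHS
    rep = np.repeat(np.arange(n), length)
    # vectorised ragged arange
    offsets = np.cumsum(length) - length
    t = np.arange(rep.size) - offsets[rep]
    cal = start[rep] + t
    cls = classes[cal, ci[rep], cj[rep]]
    if np.any(cls == CLASS_MISSING):
        bad = int(children["child_id"].to_numpy()[rep[np.argmax(cls == CLASS_MISSING)]])
        raise CoverageError(f"child {bad}: missing drought class inside window")
    event = np.zeros(rep.size, dtype=np.int8)
    last = offsets + length - 1
    event[last[died]] = 1

    table = pd.DataFrame({
        "child_id": children["child_id"].to_numpy()[rep],
        "t": t,
        "event": event,
        "calendar_month": cal,
        "age_month": t - GESTATION_MONTHS,
        "sex": children["sex"].to_numpy()[rep],
        "residence": children["residence"].to_numpy()[rep],
        "mother_education": children["mother_education"].to_numpy()[rep],
        "birth_month_index": birth[rep],
        "weight": children["sampling_weight"].to_numpy()[rep],
        "climate_zone": children["climate_zone"].to_numpy()[rep],
        "age_at_death_days": days[rep],
    })
    if "wealth_quintile" in children:
        wq = children["wealth_quintile"].to_numpy(dtype=float)[rep]
        table["wealth_quintile"] = wq
    origin = spei.attrs.get("origin") or (climate.attrs.get("origin") if climate is not None else None)
    start_month = 1
    if origin:
        start_month = int(str(origin).split("-")[1])
    table["birth_month"] = (birth[rep] + (start_month - 1)) % 12 + 1
    table["birth_year"] = (birth[rep] + (start_month - 1)) // 12.0
    composite = (
        children["cluster_id"].astype(str).to_numpy()
        if "country" not in clusters
        else (cl["country"].to_numpy()[cl_row.values].astype(object) + ":"
              + children["cluster_id"].astype(str).to_numpy())
    )
    table["cluster_cid"] = composite[rep] if isinstance(composite, np.ndarray) else composite

    if severity_mode == "any":
        table["drought_any"] = (cls >= CLASS_MILD).astype(np.int8)
    elif severity_mode == "stratified":
        table["drought_mild"] = (cls == CLASS_MILD).astype(np.int8)
        table["drought_severe"] = (cls == CLASS_SEVERE).astype(np.int8)
    else:
        raise ValueError(f"unknown severity_mode {severity_mode!r}")

    if climate is not None:
        precip = climate["precip"].values
        table["precip"] = precip[cal, ci[rep], cj[rep]]
    return table
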