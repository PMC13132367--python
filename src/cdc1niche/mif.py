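"""Multiplex-immunofluorescence spatial statistics.

Phenotypes per-cell marker-intensity tables via triclass Otsu thresholds,
computes per-phenotype densities on an occupancy-grid tissue-area estimate,
measures cDC1-to-T-cell nearest-neighbour distances and triad radii, and
runs the group / survival associations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .types import EXCLUDED, validate_cell_table

__all__ = [
    "otsu_threshold",
    "triclass_otsu",
    "marker_thresholds",
    "assign_phenotypes",
    "trim_border",
    "estimate_tissue_area",
    "densities",
    "mean_min_distance",
    "triad_radius",
    "distance_summary",
    "group_distance_compare",
    "survival_median_split",
    "cox_decile",
]

MARKERS = ("BATF3", "CD3", "CD8")


# ---------------------------------------------------------------------------
# thresholding and phenotyping
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Classic Otsu threshold on an nbins histogram of ``values``.

    Returns the upper edge of the bin maximizing between-class variance;
    positivity is value > threshold.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("constant input: Otsu threshold undefined")
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    w = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(w)
    w1 = 1.0 - w0
    mu_cum = np.cumsum(w * centers)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between[:-1]))  # last split leaves empty upper class
    return float(edges[k + 1])


def triclass_otsu(values: np.ndarray, nbins: int = 256, min_frac: float = 0.01,
                  max_iter: int = 100) -> float:
    """Iterative triclass Otsu threshold.

    Each pass applies Otsu to the current to-be-determined (TBD) region and
    splits it at the two class means: values above the upper-class mean are
    committed foreground, values at or below the lower-class mean committed
    background, and the band in between becomes the next TBD region.
    Iteration stops when the TBD region is stable or holds fewer than
    ``min_frac`` of all values; the final Otsu threshold is returned.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("constant input: triclass Otsu undefined")
    n_total = values.size
    region = values
    thr = otsu_threshold(region, nbins)
    for _ in range(max_iter):
        upper = region[region > thr]
        lower = region[region <= thr]
        if upper.size == 0 or lower.size == 0:
            break
        mu0, mu1 = lower.mean(), upper.mean()
        tbd = region[(region > mu0) & (region <= mu1)]
        if (tbd.size < max(2, min_frac * n_total)
                or tbd.size == region.size
                or np.unique(tbd).size < 2):
            break
        region = tbd
        thr = otsu_threshold(region, nbins)
    return float(thr)


def marker_thresholds(table: pd.DataFrame,
                      markers: tuple[str, ...] = MARKERS) -> dict[str, float]:
    """Triclass-Otsu positivity threshold per marker intensity column."""
    validate_cell_table(table)
    return {m: triclass_otsu(table[m].to_numpy(dtype=float)) for m in markers}


def assign_phenotypes(table: pd.DataFrame, thresholds: dict[str, float]) -> pd.DataFrame:
    """Assign one phenotype per cell by the priority rule
    BATF3+ -> cDC1; else CD8+ -> CD8T; else CD3+ -> CD4T; else other."""
    for m in MARKERS:
        if m not in table.columns:
            raise ValueError(f"missing marker column: {m}")
        if m not in thresholds:
            raise ValueError(f"missing threshold for marker: {m}")
    out = table.copy()
    batf3 = out["BATF3"].to_numpy(dtype=float) > thresholds["BATF3"]
    cd8 = out["CD8"].to_numpy(dtype=float) > thresholds["CD8"]
    cd3 = out["CD3"].to_numpy(dtype=float) > thresholds["CD3"]
    pheno = np.where(batf3, "cDC1",
                     np.where(cd8, "CD8T", np.where(cd3, "CD4T", "other")))
    out["phenotype"] = pheno
    return out


def trim_border(table: pd.DataFrame, bounds: tuple[float, float, float, float],
                margin_um: float = 20.0) -> pd.DataFrame:
    """Drop cells within ``margin_um`` of any field edge.

    ``bounds`` = (xmin, ymin, xmax, ymax) of the imaged field.
    """
    if margin_um < 0:
        raise ValueError("margin must be >= 0")
    xmin, ymin, xmax, ymax = bounds
    if 2 * margin_um >= min(xmax - xmin, ymax - ymin):
        raise ValueError("margin is at least half the field extent")
    x = table["x_um"].to_numpy(dtype=float)
    y = table["y_um"].to_numpy(dtype=float)
    keep = ((x >= xmin + margin_um) & (x <= xmax - margin_um)
            & (y >= ymin + margin_um) & (y <= ymax - margin_um))
    return table.loc[keep].reset_index(drop=True)


def estimate_tissue_area(table: pd.DataFrame, bin_um: float = 50.0) -> float:
    """Occupancy-grid tissue area in mm^2: tile the coordinate bounding box
    into ``bin_um`` squares and count bins containing at least one cell."""
    if len(table) == 0:
        raise ValueError("empty cell table")
    if bin_um <= 0:
        raise ValueError("bin size must be > 0")
    x = table["x_um"].to_numpy(dtype=float)
    y = table["y_um"].to_numpy(dtype=float)
    ix = np.floor((x - x.min()) / bin_um).astype(int)
    iy = np.floor((y - y.min()) / bin_um).astype(int)
    n_occupied = len(set(zip(ix.tolist(), iy.tolist())))
    return n_occupied * (bin_um ** 2) / 1e6


def densities(table: pd.DataFrame, area_mm2: float) -> dict[str, float]:
    """Per-phenotype cell density (cells/mm^2) over the whole tissue area."""
    if area_mm2 <= 0:
        raise ValueError("area must be > 0")
    counts = table["phenotype"].value_counts()
    return {ph: float(counts.get(ph, 0)) / area_mm2
            for ph in ("cDC1", "CD8T", "CD4T", "other")}


# ---------------------------------------------------------------------------
# distance statistics
# ---------------------------------------------------------------------------

def _coords(table: pd.DataFrame, phenotype: str) -> np.ndarray:
    sub = table.loc[table["phenotype"] == phenotype, ["x_um", "y_um"]]
    return sub.to_numpy(dtype=float)


def mean_min_distance(table: pd.DataFrame, from_type: str, to_type: str):
    """Mean over from-type cells of the Euclidean distance to the nearest
    to-type cell (microns). Returns the EXCLUDED sentinel when either
    phenotype is absent, mirroring the sample-exclusion rule."""
    src = _coords(table, from_type)
    dst = _coords(table, to_type)
    if len(src) == 0 or len(dst) == 0:
        return EXCLUDED
    d, _ = cKDTree(dst).query(src, k=1)
    return float(np.mean(d))


def triad_radius(table: pd.DataFrame):
    """Per-cDC1 triad radius = max(nearest CD8T distance, nearest CD4T
    distance): the smallest circle around the cDC1 containing one of each.
    Returns (per-cell radii, mean) or the EXCLUDED sentinel."""
    cdc1 = _coords(table, "cDC1")
    cd8 = _coords(table, "CD8T")
    cd4 = _coords(table, "CD4T")
    if len(cdc1) == 0 or len(cd8) == 0 or len(cd4) == 0:
        return EXCLUDED
    d8, _ = cKDTree(cd8).query(cdc1, k=1)
    d4, _ = cKDTree(cd4).query(cdc1, k=1)
    radii = np.maximum(d8, d4)
    return radii, float(np.mean(radii))


def distance_summary(table: pd.DataFrame, sample_id: str = "") -> dict:
    """Per-sample distance summary: mean min cDC1->CD8, cDC1->CD4, mean triad
    radius, and per-phenotype counts. Missing phenotypes yield EXCLUDED."""
    counts = table["phenotype"].value_counts().to_dict()
    tri = triad_radius(table)
    return {
        "sample_id": sample_id,
        "mean_min_cdc1_cd8": mean_min_distance(table, "cDC1", "CD8T"),
        "mean_min_cdc1_cd4": mean_min_distance(table, "cDC1", "CD4T"),
        "mean_triad_radius": tri if tri == EXCLUDED else tri[1],
        "n_cdc1": int(counts.get("cDC1", 0)),
        "n_cd8t": int(counts.get("CD8T", 0)),
        "n_cd4t": int(counts.get("CD4T", 0)),
        "n_other": int(counts.get("other", 0)),
    }


def group_distance_compare(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum comparison of per-sample distance statistics
    between two benefit groups; EXCLUDED samples must be removed upstream."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def survival_median_split(values: np.ndarray, time: np.ndarray,
                          event: np.ndarray) -> dict:
    """Median-cutoff log-rank analysis: high arm = value > median (ties go
    low). Returns the chi-square statistic, p, and per-arm KM curves."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.all(values == values[0]):
        raise ValueError("all stratifier values equal: median split undefined")
    high = values > np.median(values)
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("fewer than 2 samples in a median-split arm")
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    curves = {}
    for arm, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        ev = kmf.event_table
        curves[arm] = pd.DataFrame({
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=float),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        })
    return {"chi2": float(res.test_statistic), "p": float(res.p_value),
            "curves": curves, "n_high": int(high.sum()), "n_low": int((~high).sum())}


def decile_index(values: np.ndarray) -> np.ndarray:
    """Decile index 1-10 by empirical quantiles; tied quantile edges collapse."""
    values = np.asarray(values, dtype=float)
    inner_edges = np.quantile(values, np.linspace(0.1, 0.9, 9))
    return (np.searchsorted(inner_edges, values, side="left") + 1).astype(int)


def cox_decile(values: np.ndarray, time: np.ndarray, event: np.ndarray) -> dict:
    """Cox proportional-hazards model with the decile index (1-10) of
    ``values`` as a numeric covariate; Efron tie handling. Returns the
    per-decile hazard ratio, its CI and p."""
    from lifelines import CoxPHFitter

    values = np.asarray(values, dtype=float)
    if np.all(values == values[0]):
        raise ValueError("constant covariate")
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("no events")
    df = pd.DataFrame({
        "decile": decile_index(values).astype(float),
        "time": np.asarray(time, dtype=float),
        "event": event,
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["decile"])
    return {
        "hr_per_decile": math.exp(coef),
        "coef": coef,
        "p": float(cph.summary.loc["decile", "p"]),
        "ci_lower": math.exp(float(cph.confidence_intervals_.iloc[0, 0])),
        "ci_upper": math.exp(float(cph.confidence_intervals_.iloc[0, 1])),
    }
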