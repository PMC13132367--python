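"""Spatial-transcriptomic immune niche/hub analysis.

QC-filters a cell x gene matrix, detects candidate cDC1/CD8 cells by the
consensus of a bimodal-threshold call and a Leiden-cluster call, builds
10-um-radius hubs around each candidate by aggregating the transcripts of
all neighbouring cells, classifies hubs as cDC1-rich or cDC1-devoid, and
runs hub differential expression plus preranked gene-set enrichment.
A median-ratio-normalized Spearman correlation stage covers the
tumor-compartment validation analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .synthetic import CANONICAL_GENES
from .types import CellTranscriptMatrix, Hub, HubSet

__all__ = [
    "qc_filter",
    "detect_threshold",
    "detect_cluster",
    "consensus",
    "build_hubs",
    "classify_hubs",
    "hub_density_by_group",
    "hub_de",
    "preranked_gsea",
    "tumor_compartment_correlations",
]

CDC1_GENES = tuple(CANONICAL_GENES["cDC1"])


# ---------------------------------------------------------------------------
# QC and candidate detection
# ---------------------------------------------------------------------------

def qc_filter(matrix: CellTranscriptMatrix, min_molecules: int = 50) -> CellTranscriptMatrix:
    """Drop cells with total molecule count strictly below ``min_molecules``."""
    return matrix.subset_cells(matrix.totals >= min_molecules)


def _canonical_sums(matrix: CellTranscriptMatrix,
                    canonical: dict[str, list[str]]) -> dict[str, np.ndarray]:
    sums = {}
    for t, genes in canonical.items():
        idx = [matrix.gene_index(g) for g in genes]
        sums[t] = np.asarray(matrix.counts[idx, :].sum(axis=0), dtype=float)
    return sums


def _kde_valley(s: np.ndarray, grid_size: int = 512) -> float | None:
    """Valley (density minimum) between the two highest modes of a Gaussian
    KDE with Silverman bandwidth; None when fewer than two modes exist."""
    if np.std(s) == 0:
        return None
    kde = stats.gaussian_kde(s, bw_method="silverman")
    grid = np.linspace(s.min(), s.max(), grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if dens[0] > dens[1]:
        peaks = np.r_[0, peaks]
    if dens[-1] > dens[-2]:
        peaks = np.r_[peaks, grid_size - 1]
    if len(peaks) < 2:
        return None
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    a, b = sorted(top2)
    if b - a < 2:
        return None
    valley_idx = a + 1 + int(np.argmin(dens[a + 1:b]))
    return float(grid[valley_idx])


def detect_threshold(matrix: CellTranscriptMatrix,
                     canonical: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Per-cell threshold-based candidate calls.

    For each cell type, s = log1p(sum of canonical counts); a cell is
    positive when s exceeds the KDE valley between the two highest modes of
    the distribution of s. Unimodal distributions fall back to an Otsu
    threshold with a warning. Returns a frame with per-type booleans and a
    combined call in {cDC1, CD8, both, none}.
    """
    from .mif import otsu_threshold

    canonical = canonical or CANONICAL_GENES
    sums = _canonical_sums(matrix, canonical)
    out = pd.DataFrame(index=range(matrix.n_cells))
    for t, raw in sums.items():
        s = np.log1p(raw)
        if np.all(raw == 0):
            warnings.warn(f"all-zero canonical sums for {t}: no positives")
            out[t] = False
            continue
        valley = _kde_valley(s)
        if valley is None:
            warnings.warn(f"no bimodal structure for {t}: falling back to Otsu")
            valley = otsu_threshold(s)
        out[t] = s > valley
        out[f"{t}_sum"] = raw
    types = list(canonical)
    pos = out[types].to_numpy()
    call = np.where(pos.all(axis=1), "both",
                    np.where(pos[:, 0], types[0],
                             np.where(pos[:, 1], types[1], "none")))
    out["call"] = call
    return out


def detect_cluster(matrix: CellTranscriptMatrix, resolution: float = 2.0,
                   k: int = 15, seed: int = 0, n_pcs: int = 30,
                   canonical: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Per-cell cluster-based candidate calls.

    Leiden community detection on a kNN graph over a PCA embedding of log1p
    depth-normalized counts. A cluster is positive for a cell type when its
    mean canonical log1p-sum exceeds the global mean by one global SD;
    labels are cDC1/CD8/mixture/none and cells inherit their cluster's label.
    """
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    canonical = canonical or CANONICAL_GENES
    n = matrix.n_cells
    if n < 2:
        raise ValueError("need >= 2 cells for clustering")
    if n <= k:
        warnings.warn(f"fewer cells than k={k}: reducing to {n - 1}")
        k = n - 1

    totals = matrix.totals.astype(float)
    totals[totals == 0] = 1.0
    target = np.median(totals[totals > 0])
    x = np.log1p(matrix.counts / totals * target).T  # cells x genes
    n_pcs = min(n_pcs, n - 1, x.shape[1])
    if x.shape[1] > n_pcs:
        x = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    graph = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    membership = np.asarray(part.membership)

    sums = {t: np.log1p(v) for t, v in _canonical_sums(matrix, canonical).items()}
    types = list(canonical)
    cluster_pos = {}
    for t in types:
        s = sums[t]
        cut = s.mean() + s.std()
        cluster_pos[t] = {
            c: float(s[membership == c].mean()) > cut
            for c in np.unique(membership)
        }
    labels = []
    for c in membership:
        p = [cluster_pos[t][c] for t in types]
        if all(p):
            labels.append("mixture")
        elif p[0]:
            labels.append(types[0])
        elif p[1]:
            labels.append(types[1])
        else:
            labels.append("none")
    return pd.DataFrame({"cluster": membership, "call": labels})


def consensus(threshold_calls: pd.DataFrame,
              cluster_calls: pd.DataFrame,
              canonical: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Cross the two annotations: consensus type t requires the threshold
    call to include t and the cluster call to be t or 'mixture'. Cells
    thresholded 'both' resolve to the type with the larger canonical sum."""
    canonical = canonical or CANONICAL_GENES
    types = list(canonical)
    if len(threshold_calls) != len(cluster_calls):
        raise ValueError("call vectors are not aligned")
    thr = threshold_calls["call"].to_numpy()
    clu = cluster_calls["call"].to_numpy()
    out = np.full(len(thr), "none", dtype=object)
    for i in range(len(thr)):
        t_call = thr[i]
        if t_call == "none":
            continue
        if t_call == "both":
            sums = [threshold_calls.at[i, f"{t}_sum"] for t in types]
            t_call = types[int(np.argmax(sums))]
        if clu[i] in (t_call, "mixture"):
            out[i] = t_call
    return pd.DataFrame({"consensus": out})


# ---------------------------------------------------------------------------
# hub construction
# ---------------------------------------------------------------------------

def build_hubs(matrix: CellTranscriptMatrix, candidate_mask: np.ndarray,
               radius_um: float = 10.0) -> HubSet:
    """One hub per candidate cell: members are ALL cells (candidate or not)
    whose centroid lies within ``radius_um`` of the candidate centroid,
    center included; aggregated counts are the member sum. Hubs may overlap."""
    candidate_idx = np.flatnonzero(np.asarray(candidate_mask))
    if candidate_idx.size == 0:
        raise ValueError("no candidate cells to seed hubs")
    xy = np.column_stack([matrix.x_um, matrix.y_um])
    tree = cKDTree(xy)
    hubs = []
    for ci in candidate_idx:
        members = np.array(sorted(tree.query_ball_point(xy[ci], radius_um)))
        agg = np.asarray(matrix.counts[:, members].sum(axis=1))
        hubs.append(Hub(
            center_cell=matrix.cell_ids[ci], center_index=int(ci),
            member_indices=members, agg_counts=agg, n_cells=len(members),
            x_um=float(matrix.x_um[ci]), y_um=float(matrix.y_um[ci])))
    return HubSet(list(matrix.genes), hubs, radius_um)


def classify_hubs(hub_set: HubSet, cdc1_genes: tuple[str, ...] = CDC1_GENES) -> HubSet:
    """cDC1-rich iff the aggregated BATF3+XCR1+CLEC9A count is >= 1 molecule."""
    idx = [hub_set.genes.index(g) for g in cdc1_genes if g in hub_set.genes]
    if not idx:
        raise ValueError("no cDC1 canonical genes in hub gene axis")
    for h in hub_set.hubs:
        h.hub_class = ("cDC1-rich" if h.agg_counts[idx].sum() >= 1
                       else "cDC1-devoid")
    return hub_set


def hub_density_by_group(hub_sets: dict[str, HubSet], areas_mm2: dict[str, float],
                         labels: dict[str, str]) -> pd.DataFrame:
    """Per-sample rich/devoid hub densities (hubs/mm^2 and hubs per 1,000
    cells of the sample's hub census), grouped by benefit label."""
    rows = []
    for sample, hs in hub_sets.items():
        area = areas_mm2[sample]
        if area <= 0:
            raise ValueError(f"non-positive area for sample {sample}")
        classes = np.array([h.hub_class for h in hs.hubs])
        n_rich = int((classes == "cDC1-rich").sum())
        n_devoid = int((classes == "cDC1-devoid").sum())
        n = len(hs.hubs)
        rows.append({
            "sample_id": sample, "label": labels[sample],
            "n_hubs": n, "n_rich": n_rich, "n_devoid": n_devoid,
            "rich_per_mm2": n_rich / area, "devoid_per_mm2": n_devoid / area,
            "total_per_mm2": n / area,
            "rich_frac": n_rich / n if n else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential expression and enrichment
# ---------------------------------------------------------------------------

def hub_de(hub_set: HubSet, test: str = "ranksum") -> pd.DataFrame:
    """Per-gene differential expression, cDC1-rich vs cDC1-devoid hubs.

    Default backend: two-sided rank-sum on log1p aggregated counts with
    Benjamini-Hochberg correction; log2FC = log2((mean_rich+1)/(mean_devoid+1)).
    The backend is pluggable so a zero-inflated NB test can be slotted in.
    """
    if test != "ranksum":
        raise ValueError(f"unknown DE backend: {test}")
    classes = np.array([h.hub_class for h in hub_set.hubs])
    rich = classes == "cDC1-rich"
    devoid = classes == "cDC1-devoid"
    if rich.sum() < 2 or devoid.sum() < 2:
        raise ValueError("need >= 2 hubs in each class")
    mat = np.column_stack([h.agg_counts for h in hub_set.hubs]).astype(float)
    log_mat = np.log1p(mat)
    pvals = np.empty(mat.shape[0])
    stats_ = np.empty(mat.shape[0])
    for i in range(mat.shape[0]):
        a, b = log_mat[i, rich], log_mat[i, devoid]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stats_[i], pvals[i] = len(a) * len(b) / 2.0, 1.0
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        stats_[i], pvals[i] = res.statistic, res.pvalue
    qvals = stats.false_discovery_control(pvals, method="bh")
    log2fc = np.log2((mat[:, rich].mean(axis=1) + 1.0)
                     / (mat[:, devoid].mean(axis=1) + 1.0))
    return pd.DataFrame({
        "gene": hub_set.genes, "log2fc": log2fc,
        "statistic": stats_, "p": pvals, "q": qvals,
    })


def _es_walk(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Weighted KS enrichment score over a ranked list (max |deviation|)."""
    w = np.where(in_set, weights, 0.0)
    denom = w.sum()
    if denom == 0:
        return 0.0
    step_in = np.cumsum(w) / denom
    n_out = len(in_set) - int(in_set.sum())
    step_out = np.cumsum(~in_set) / n_out
    walk = step_in - step_out
    return float(walk[np.argmax(np.abs(walk))])


def preranked_gsea(ranked: pd.Series, gene_sets: dict[str, list[str]],
                   n_perm: int = 1000, seed: int = 0,
                   min_size: int = 3, max_size: int | None = None) -> pd.DataFrame:
    """Preranked gene-set enrichment with weight |stat| (exponent 1).

    ``ranked``: index = gene, value = ranking statistic. ES is the maximum
    deviation of the weighted KS walk over genes sorted by decreasing
    statistic. NES = ES / mean(|ES|) of same-sign gene-label permutations;
    p is the permutation tail probability among same-sign permutations.
    Sets smaller than ``min_size`` or larger than ``max_size`` (default:
    half the ranked list) or disjoint from the ranking are skipped.
    """
    rng = np.random.default_rng(seed)
    ranked = ranked.sort_values(ascending=False)
    genes = np.array(ranked.index)
    statv = ranked.to_numpy(dtype=float)
    weights = np.abs(statv)
    p_total = len(genes)
    if max_size is None:
        max_size = p_total // 2
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    for name, members in gene_sets.items():
        pos = sorted(gene_pos[g] for g in set(members) if g in gene_pos)
        m = len(pos)
        if m == 0:
            rows.append((name, np.nan, np.nan, np.nan, m, "", "skipped: disjoint"))
            continue
        if m < min_size or m > max_size:
            rows.append((name, np.nan, np.nan, np.nan, m, "", "skipped: size"))
            continue
        in_set = np.zeros(p_total, dtype=bool)
        in_set[pos] = True
        es = _es_walk(in_set, weights)
        # leading edge: genes before/at the extreme walk point, in the set
        w = np.where(in_set, weights, 0.0)
        walk = np.cumsum(w) / w.sum() - np.cumsum(~in_set) / (p_total - m)
        peak = int(np.argmax(np.abs(walk)))
        if es >= 0:
            lead = [g for g in genes[:peak + 1] if g in set(members)]
        else:
            lead = [g for g in genes[peak:] if g in set(members)]

        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(p_total, dtype=bool)
            perm[rng.choice(p_total, size=m, replace=False)] = True
            perm_es[b] = _es_walk(perm, weights)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if len(same_sign) == 0:
            nes, pval = np.nan, 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same_sign))
            pval = ((np.sum(np.abs(same_sign) >= abs(es)) + 1)
                    / (len(same_sign) + 1))
        rows.append((name, es, nes, pval, m, ",".join(lead), ""))
    return pd.DataFrame(rows, columns=["gene_set", "es", "nes", "p",
                                       "size", "leading_edge", "note"])


# ---------------------------------------------------------------------------
# tumor-compartment (GeoMX-style) correlations
# ---------------------------------------------------------------------------

def median_ratio_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples), DESeq-style."""
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError("no gene is positive in all samples")
    log_geo = np.mean(np.log(counts[positive]), axis=1, keepdims=True)
    return np.exp(np.median(np.log(counts[positive]) - log_geo, axis=0))


def tumor_compartment_correlations(expr: pd.DataFrame, anchor_gene: str = "BATF3",
                                   partners: list[str] | None = None,
                                   min_total: float = 50_000) -> pd.DataFrame:
    """Spearman correlation of an anchor transcript with partner transcripts
    after a raw-count QC filter (samples with < ``min_total`` total counts
    removed) and median-ratio size-factor normalization.

    ``expr``: genes x samples raw counts.
    """
    totals = expr.sum(axis=0)
    kept = expr.loc[:, totals >= min_total]
    if kept.shape[1] < 3:
        raise ValueError("fewer than 3 samples pass the count filter")
    if anchor_gene not in kept.index:
        raise KeyError(f"anchor gene not in matrix: {anchor_gene}")
    if kept.loc[anchor_gene].nunique() == 1:
        raise ValueError("anchor gene is constant")
    sf = median_ratio_size_factors(kept.to_numpy())
    normed = kept / sf
    anchor = normed.loc[anchor_gene]
    partners = partners or [g for g in normed.index if g != anchor_gene]
    rows = []
    for g in partners:
        if g not in normed.index:
            rows.append((g, np.nan, np.nan, "missing"))
            continue
        rho, p = stats.spearmanr(anchor, normed.loc[g])
        rows.append((g, float(rho), float(p), ""))
    return pd.DataFrame(rows, columns=["partner", "rho", "p", "note"])
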