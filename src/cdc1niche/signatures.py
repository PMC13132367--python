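"""Bulk RNA-seq normalization, signature derivation and enrichment scoring.

The scoring stage is a from-scratch implementation of the kernel-CDF
rank-enrichment method of Hänzelmann et al. (gene set variation analysis,
'gsva' method) with its documented defaults for continuous log-normalized
input: Gaussian kernel with bandwidth sd/4, symmetric rank statistic,
weighted KS random walk with weight exponent tau=1 and max-deviation-
difference scoring.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import ClinicalTable, CountMatrix, GeneSignature, NormalizedMatrix

__all__ = [
    "compute_tmm_factors",
    "log2_cpm",
    "detectability_filter",
    "meta_signal",
    "gene_importance_filter",
    "cross_cohort_intersect",
    "enrichment_score",
    "minmax_rescale",
    "group_compare",
    "correlation_panel",
    "derive_signature",
    "score_table",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              log_ratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Trimmed mean of M-values between one sample and the reference.

    Doubly trimmed (30% on M, 5% on A), inverse-asymptotic-variance
    weighted; returns the factor on the linear scale.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = ((rank_r >= lo_l) & (rank_r <= hi_l)
            & (rank_e >= lo_s) & (rank_e <= hi_s))
    if not np.any(keep):
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def compute_tmm_factors(counts: CountMatrix) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile. Effective library size = library
    size x factor.
    """
    if len(counts.samples) < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.library_sizes
    zero = np.flatnonzero(lib <= 0)
    if zero.size:
        raise ValueError(f"all-zero sample: {counts.samples[zero[0]]}")
    mat = counts.counts.astype(float)
    f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75)
                    for j in range(mat.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx])
        for j in range(mat.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log2_cpm(counts: CountMatrix, factors: np.ndarray | None = None) -> NormalizedMatrix:
    """log2(CPM + 1) on effective library sizes (library size x TMM factor)."""
    if factors is None:
        factors = compute_tmm_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("normalization factors must be positive")
    eff = counts.library_sizes * factors
    values = np.log2(counts.counts / eff * 1e6 + 1.0)
    return NormalizedMatrix(list(counts.genes), list(counts.samples),
                            values, unit="log2-CPM", norm_factors=factors)


# ---------------------------------------------------------------------------
# signature derivation
# ---------------------------------------------------------------------------

def detectability_filter(counts: CountMatrix, min_count: float = 5,
                         min_frac: float = 0.5, tpm_mode: bool = False,
                         tpm: NormalizedMatrix | None = None) -> list[str]:
    """Genes detected (count >= min_count, or TPM >= 1 in tpm_mode) in at
    least ``min_frac`` of samples. Both comparisons are inclusive."""
    if min_count <= 0 or min_frac <= 0:
        raise ValueError("thresholds must be positive")
    if tpm_mode:
        if tpm is None:
            raise ValueError("tpm_mode requires a TPM matrix")
        frac = (2.0 ** tpm.values - 1.0 >= 1.0).mean(axis=1)
        genes = tpm.genes
    else:
        frac = (counts.counts >= min_count).mean(axis=1)
        genes = counts.genes
    return [g for g, f in zip(genes, frac) if f >= min_frac]


def meta_signal(norm: NormalizedMatrix, candidates: list[str]) -> np.ndarray:
    """Per-sample mean of gene-wise z-scored values over candidate genes.

    Zero-variance genes are excluded with a warning.
    """
    present = [g for g in candidates if g in norm.genes]
    if not present:
        raise ValueError("no candidate genes present in matrix")
    idx = [norm.genes.index(g) for g in present]
    sub = norm.values[idx, :]
    sd = sub.std(axis=1, ddof=1)
    ok = sd > 0
    if not np.all(ok):
        dropped = [g for g, o in zip(present, ok) if not o]
        warnings.warn(f"zero-variance genes excluded from meta-signal: {dropped}")
    if not np.any(ok):
        raise ValueError("all candidate genes have zero variance")
    z = (sub[ok] - sub[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    return z.mean(axis=0)


def gene_importance_filter(norm: NormalizedMatrix, candidates: list[str],
                           meta: np.ndarray, rho_min: float = 0.4,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Keep genes with Spearman rho > rho_min (strict) and two-sided p < alpha.

    Returns a frame (gene, rho, p, kept) ordered by rho descending.
    """
    if len(meta) < 3:
        raise ValueError("need >= 3 samples")
    if np.std(meta) == 0:
        raise ValueError("constant meta-signal")
    rows = []
    for g in candidates:
        if g not in norm.genes:
            continue
        x = norm.gene_values(g)
        if np.std(x) == 0:
            rows.append((g, np.nan, np.nan, False))
            continue
        rho, p = stats.spearmanr(x, meta)
        rows.append((g, rho, p, bool(rho > rho_min and p < alpha)))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p", "kept"])
    return out.sort_values("rho", ascending=False).reset_index(drop=True)


def cross_cohort_intersect(per_cohort: list[pd.DataFrame]) -> list[str]:
    """Intersection of kept genes across cohorts, ordered by mean rho
    descending. Empty intersection returns [] with a warning."""
    if not per_cohort:
        raise ValueError("need at least one cohort")
    kept_sets = [set(df.loc[df["kept"], "gene"]) for df in per_cohort]
    common = set.intersection(*kept_sets)
    if not common:
        warnings.warn("empty cross-cohort intersection")
        return []
    mean_rho = {
        g: float(np.mean([df.set_index("gene").loc[g, "rho"] for df in per_cohort]))
        for g in common
    }
    return sorted(common, key=lambda g: -mean_rho[g])


def derive_signature(cohorts: list[CountMatrix], candidate_pool: list[str],
                     name: str = "derived", min_count: float = 5,
                     min_frac: float = 0.5, rho_min: float = 0.4,
                     alpha: float = 0.05) -> GeneSignature:
    """Full derivation chain: per-cohort detectability filter -> meta-signal
    -> importance filter, then intersection across cohorts."""
    per_cohort = []
    for cm in cohorts:
        detectable = set(detectability_filter(cm, min_count, min_frac))
        cands = [g for g in candidate_pool if g in detectable]
        if not cands:
            per_cohort.append(pd.DataFrame(columns=["gene", "rho", "p", "kept"]))
            continue
        norm = log2_cpm(cm)
        meta = meta_signal(norm, cands)
        per_cohort.append(gene_importance_filter(norm, cands, meta, rho_min, alpha))
    genes = cross_cohort_intersect(per_cohort)
    if not genes:
        raise ValueError("derivation produced an empty signature")
    return GeneSignature(name, genes, {g: "importance-passed" for g in genes})


# ---------------------------------------------------------------------------
# enrichment scoring
# ---------------------------------------------------------------------------

def _gaussian_kcdf(values: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF estimate per gene across samples (bandwidth sd/4)."""
    p, n = values.shape
    sd = values.std(axis=1, ddof=1)
    out = np.empty_like(values, dtype=float)
    for i in range(p):
        h = sd[i] / 4.0
        if h == 0:
            # degenerate limit of the Gaussian kernel: step CDF with 0.5 at ties
            d = values[i, :, None] - values[i, None, :]
            out[i] = ((d > 0) + 0.5 * (d == 0)).mean(axis=1)
            continue
        diff = (values[i, :, None] - values[i, None, :]) / h
        out[i] = stats.norm.cdf(diff).mean(axis=1)
    return out


def _symmetric_rank_stats(kcdf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample gene ordering (by decreasing kernel-CDF score) and the
    symmetric rank statistic |position - p/2| mapped back to genes."""
    p, n = kcdf.shape
    order = np.argsort(-kcdf, axis=0, kind="stable")
    rank_stat = np.empty_like(kcdf)
    positions = np.arange(1, p + 1, dtype=float)
    weights = np.abs(positions - p / 2.0)
    for j in range(n):
        rank_stat[order[:, j], j] = weights
    return order, rank_stat


def _ks_walk_scores(order: np.ndarray, rank_stat: np.ndarray,
                    in_set: np.ndarray, tau: float = 1.0) -> np.ndarray:
    """Weighted KS random-walk enrichment score per sample.

    Score = max(walk) + min(walk) (difference of the largest positive and
    largest negative deviations).
    """
    p, n = order.shape
    m = int(in_set.sum())
    scores = np.empty(n)
    for j in range(n):
        ordered_in = in_set[order[:, j]]
        w = np.abs(rank_stat[order[:, j], j]) ** tau
        w[~ordered_in] = 0.0
        step_in = np.cumsum(w)
        denom = step_in[-1]
        step_in = step_in / denom if denom > 0 else step_in
        step_out = np.cumsum(~ordered_in) / float(p - m)
        walk = step_in - step_out
        scores[j] = walk.max() + walk.min()
    return scores


def enrichment_score(norm: NormalizedMatrix, sig: GeneSignature,
                     tau: float = 1.0) -> np.ndarray:
    """Per-sample raw enrichment scores for one signature; values in [-1, 1].

    Signature genes absent from the matrix are ignored; zero-variance genes
    are excluded from the ranking with a warning.
    """
    if len(norm.samples) < 2:
        raise ValueError("need >= 2 samples")
    sd = norm.values.std(axis=1, ddof=1)
    keep = sd > 0
    if not np.any(keep):
        # fully degenerate matrix: keep everything, kernel uses its h->0 limit
        keep = np.ones_like(keep)
    elif not np.all(keep):
        warnings.warn(f"{int((~keep).sum())} zero-variance genes excluded "
                      "from enrichment ranking")
    genes = [g for g, k in zip(norm.genes, keep) if k]
    values = norm.values[keep, :]
    gene_pos = {g: i for i, g in enumerate(genes)}
    set_idx = [gene_pos[g] for g in sig.genes if g in gene_pos]
    if len(set_idx) < 2:
        raise ValueError(
            f"signature {sig.name!r} has <2 genes present in the matrix")
    in_set = np.zeros(len(genes), dtype=bool)
    in_set[set_idx] = True
    kcdf = _gaussian_kcdf(values)
    order, rank_stat = _symmetric_rank_stats(kcdf)
    return _ks_walk_scores(order, rank_stat, in_set, tau=tau)


def minmax_rescale(raw: np.ndarray, lo: float = 1.0, hi: float = 10.0) -> np.ndarray:
    """Min-max rescale raw scores onto [lo, hi], intracohort.

    Degenerate (constant) input maps to (lo+hi)/2 with a warning. Statistics
    must always be run on the raw scores, never on these.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty score vector")
    mn, mx = raw.min(), raw.max()
    if mx == mn:
        warnings.warn("constant score vector: rescaled to midpoint")
        return np.full_like(raw, (lo + hi) / 2.0)
    return lo + (raw - mn) * (hi - lo) / (mx - mn)


def score_table(norm: NormalizedMatrix, signatures: list[GeneSignature],
                lo: float = 1.0, hi: float = 10.0) -> pd.DataFrame:
    """Long-format score table: sample_id, signature, raw_score, rescaled_score."""
    frames = []
    for sig in signatures:
        raw = enrichment_score(norm, sig)
        frames.append(pd.DataFrame({
            "sample_id": norm.samples,
            "signature": sig.name,
            "raw_score": raw,
            "rescaled_score": minmax_rescale(raw, lo, hi),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# group comparison and correlation
# ---------------------------------------------------------------------------

RESPONSE_PAIRS = (("CR/PR", "SD"), ("CR/PR", "PD"), ("SD", "PD"))


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact when combined n <= 20 and tie-free,
    normal approximation with tie correction otherwise."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_compare(raw_scores: np.ndarray, clinical: ClinicalTable,
                  sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests between grouped response classes
    (CR/PR vs SD, CR/PR vs PD, SD vs PD). Empty groups are skipped with a
    note in the output."""
    raw_scores = np.asarray(raw_scores, dtype=float)
    groups = clinical.grouped_response()
    if sample_ids is not None:
        aligned = clinical.table.set_index("sample_id").loc[sample_ids]
        groups = ClinicalTable(aligned.reset_index()).grouped_response()
    if len(groups) != len(raw_scores):
        raise ValueError("scores and clinical table are not aligned")
    by_group = {g: raw_scores[np.asarray(groups == g)] for g in groups.unique()}
    rows = []
    for a, b in RESPONSE_PAIRS:
        xa, xb = by_group.get(a, np.array([])), by_group.get(b, np.array([]))
        if len(xa) == 0 or len(xb) == 0:
            rows.append((a, b, len(xa), len(xb), np.nan, np.nan, "skipped: empty group"))
            continue
        u, p = _rank_sum(xa, xb)
        rows.append((a, b, len(xa), len(xb), u, p, ""))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                       "statistic", "p", "note"])


def correlation_panel(pairs: dict[str, tuple[np.ndarray, np.ndarray]],
                      method: str = "pearson") -> pd.DataFrame:
    """Correlation coefficient and two-sided p for each named pair of
    paired vectors. Zero-variance inputs are reported as missing."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method}")
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for name, (x, y) in pairs.items():
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise ValueError(f"pair {name!r}: vectors must be paired, length >= 3")
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((name, np.nan, np.nan, "zero variance"))
            continue
        r, p = fn(x, y)
        rows.append((name, float(r), float(p), ""))
    return pd.DataFrame(rows, columns=["pair", "r", "p", "note"])
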