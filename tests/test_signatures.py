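"""Normalization, derivation chain, enrichment scoring and group statistics.

The TMM and enrichment-score tests check the vectorized implementations
against independent, step-by-step oracle implementations written here.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from cdc1niche import signatures as S
from cdc1niche import synthetic
from cdc1niche.types import ClinicalTable, CountMatrix, GeneSignature, NormalizedMatrix


def make_cm(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(genes, samples, counts)


# ---------------------------------------------------------------------------
# TMM oracle: direct formula evaluation with plain loops
# ---------------------------------------------------------------------------

def tmm_oracle(counts: np.ndarray) -> np.ndarray:
    counts = counts.astype(float)
    lib = counts.sum(axis=0)
    # reference: upper-quartile count fraction closest to the mean
    f75 = [np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])]
    ref = min(range(len(f75)), key=lambda j: abs(f75[j] - np.mean(f75)))
    factors = []
    for j in range(counts.shape[1]):
        obs, refc = counts[:, j], counts[:, ref]
        rows = [i for i in range(len(obs)) if obs[i] > 0 and refc[i] > 0]
        m = [math.log2((obs[i] / lib[j]) / (refc[i] / lib[ref])) for i in rows]
        a = [(math.log2(obs[i] / lib[j]) + math.log2(refc[i] / lib[ref])) / 2
             for i in rows]
        w = [(lib[j] - obs[i]) / (lib[j] * obs[i])
             + (lib[ref] - refc[i]) / (lib[ref] * refc[i]) for i in rows]
        if not m or max(abs(v) for v in m) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m)
        lo_l, lo_s = math.floor(n * 0.3) + 1, math.floor(n * 0.05) + 1
        hi_l, hi_s = n + 1 - lo_l, n + 1 - lo_s
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        num = den = 0.0
        for i in range(n):
            if lo_l <= rank_m[i] <= hi_l and lo_s <= rank_a[i] <= hi_s:
                num += m[i] / w[i]
                den += 1.0 / w[i]
        factors.append(2.0 ** (num / den) if den else 1.0)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTmm:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.poisson(30, size=(60, 1))
        cm = make_cm(np.hstack([col, col]))
        np.testing.assert_allclose(S.compute_tmm_factors(cm), [1.0, 1.0])

    def test_pure_depth_change_unit_factors(self, rng):
        col = rng.poisson(30, size=(60, 1)) + 1
        cm = make_cm(np.hstack([col, 2 * col]))
        np.testing.assert_allclose(S.compute_tmm_factors(cm), [1.0, 1.0],
                                   atol=1e-12)

    def test_toy_matrix_matches_oracle(self):
        counts = np.array([
            [10, 20, 5],
            [100, 80, 110],
            [50, 500, 40],
            [200, 180, 260],
        ])
        cm = make_cm(counts)
        np.testing.assert_allclose(S.compute_tmm_factors(cm),
                                   tmm_oracle(counts), atol=1e-6)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(5):
            counts = rng.poisson(rng.uniform(1, 200, size=(80, 1)),
                                 size=(80, 4))
            np.testing.assert_allclose(
                S.compute_tmm_factors(make_cm(counts)), tmm_oracle(counts),
                atol=1e-9)

    def test_geometric_mean_one(self, rng):
        counts = rng.poisson(40, size=(100, 6))
        f = S.compute_tmm_factors(make_cm(counts))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_sample_permutation_permutes_factors(self, rng):
        counts = rng.poisson(rng.uniform(5, 100, size=(80, 1)), size=(80, 5))
        f = S.compute_tmm_factors(make_cm(counts))
        perm = [3, 1, 4, 0, 2]
        f2 = S.compute_tmm_factors(make_cm(counts[:, perm]))
        np.testing.assert_allclose(f2, f[perm], atol=1e-12)

    def test_all_zero_sample_names_sample(self):
        counts = np.array([[5, 0], [3, 0]])
        with pytest.raises(ValueError, match="s1"):
            S.compute_tmm_factors(make_cm(counts))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            S.compute_tmm_factors(make_cm([[5], [3]]))


class TestLog2Cpm:
    def test_known_value(self):
        # count 999 in an effective library of 10^6 -> log2(999 + 1)
        counts = np.zeros((2, 2), dtype=int)
        counts[0, 0] = 999
        counts[1, 0] = 10 ** 6 - 999
        counts[0, 1] = 999
        counts[1, 1] = 10 ** 6 - 999
        cm = make_cm(counts)
        norm = S.log2_cpm(cm, np.ones(2))
        assert norm.values[0, 0] == pytest.approx(math.log2(1000), abs=1e-9)

    def test_zero_count_is_zero(self, rng):
        counts = rng.poisson(20, size=(10, 3))
        counts[0, :] = 0
        norm = S.log2_cpm(make_cm(counts), np.ones(3))
        np.testing.assert_array_equal(norm.values[0], 0.0)

    def test_depth_invariance(self, rng):
        counts = rng.poisson(20, size=(30, 3)) + 1
        n1 = S.log2_cpm(make_cm(counts), np.ones(3))
        n2 = S.log2_cpm(make_cm(2 * counts), np.ones(3))
        np.testing.assert_allclose(n1.values, n2.values, atol=1e-12)

    def test_factor_validation(self, rng):
        cm = make_cm(rng.poisson(20, size=(10, 2)))
        with pytest.raises(ValueError):
            S.log2_cpm(cm, np.array([1.0, -1.0]))


class TestDetectabilityFilter:
    def test_boundary_inclusive(self):
        cm = make_cm(np.array([[5, 5, 0, 0]]))
        assert S.detectability_filter(cm) == ["g0"]

    def test_below_fraction_dropped(self):
        cm = make_cm(np.array([[5, 0, 0, 0]]))
        assert S.detectability_filter(cm) == []

    def test_below_count_dropped(self):
        cm = make_cm(np.array([[4, 4, 4, 4]]))
        assert S.detectability_filter(cm) == []

    def test_tpm_mode(self):
        # TPM >= 1 in >= 50% of samples
        tpm_values = np.log2(np.array([[1.0, 1.0, 0.0, 0.0],
                                       [0.5, 0.5, 0.5, 0.5]]) + 1)
        tpm = NormalizedMatrix(["a", "b"], list("wxyz"), tpm_values,
                               unit="log2-TPM")
        cm = make_cm(np.zeros((2, 4), dtype=int), genes=["a", "b"])
        kept = S.detectability_filter(cm, tpm_mode=True, tpm=tpm)
        assert kept == ["a"]


class TestMetaSignal:
    def test_single_candidate_equals_zscore(self, rng):
        values = rng.normal(size=(5, 20))
        norm = NormalizedMatrix([f"g{i}" for i in range(5)],
                                [f"s{j}" for j in range(20)], values)
        meta = S.meta_signal(norm, ["g2"])
        z = (values[2] - values[2].mean()) / values[2].std(ddof=1)
        np.testing.assert_allclose(meta, z, atol=1e-12)
        rho = stats.spearmanr(meta, values[2])[0]
        assert rho == pytest.approx(1.0)

    def test_duplicate_candidates_equal_single(self, rng):
        base = rng.normal(size=20)
        values = np.vstack([base, base])
        norm = NormalizedMatrix(["a", "b"], [f"s{j}" for j in range(20)], values)
        np.testing.assert_allclose(S.meta_signal(norm, ["a", "b"]),
                                   S.meta_signal(norm, ["a"]), atol=1e-12)

    def test_recovers_latent(self):
        cm, _, truth = synthetic.gen_bulk_cohort(
            synthetic.BulkSimParams(n_samples=200, seed=41))
        norm = S.log2_cpm(cm)
        meta = S.meta_signal(norm, truth.signature_genes["cDC1"])
        rho = stats.spearmanr(meta, truth.latents["cDC1"])[0]
        assert rho > 0.7

    def test_zero_variance_excluded_with_warning(self, rng):
        values = np.vstack([rng.normal(size=10), np.zeros(10)])
        norm = NormalizedMatrix(["a", "b"], [f"s{j}" for j in range(10)], values)
        with pytest.warns(UserWarning, match="zero-variance"):
            meta = S.meta_signal(norm, ["a", "b"])
        np.testing.assert_allclose(meta, S.meta_signal(norm, ["a"]))


class TestGeneImportanceFilter:
    def _norm(self, values):
        return NormalizedMatrix([f"g{i}" for i in range(values.shape[0])],
                                [f"s{j}" for j in range(values.shape[1])],
                                values)

    def test_identical_gene_kept(self, rng):
        meta = rng.normal(size=30)
        norm = self._norm(meta[None, :].copy())
        out = S.gene_importance_filter(norm, ["g0"], meta)
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert bool(out.loc[0, "kept"])

    def test_anticorrelated_gene_dropped(self, rng):
        meta = rng.normal(size=30)
        norm = self._norm(-meta[None, :])
        out = S.gene_importance_filter(norm, ["g0"], meta)
        assert out.loc[0, "rho"] == pytest.approx(-1.0)
        assert not bool(out.loc[0, "kept"])

    def test_noise_gene_dropped(self):
        # null distribution of Spearman rho at n=100: P(kept) well below 5%
        dropped = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            meta = r.normal(size=100)
            norm = self._norm(r.normal(size=(1, 100)))
            out = S.gene_importance_filter(norm, ["g0"], meta)
            dropped += not bool(out.loc[0, "kept"])
        assert dropped >= 19

    def test_constant_meta_raises(self, rng):
        norm = self._norm(rng.normal(size=(1, 10)))
        with pytest.raises(ValueError, match="constant"):
            S.gene_importance_filter(norm, ["g0"], np.ones(10))


class TestCrossCohortIntersect:
    @staticmethod
    def _frame(genes, rhos=None):
        rhos = rhos or [0.9] * len(genes)
        return pd.DataFrame({"gene": genes, "rho": rhos,
                             "p": [1e-4] * len(genes),
                             "kept": [True] * len(genes)})

    def test_simple_intersection(self):
        out = S.cross_cohort_intersect([self._frame(list("ABC")),
                                        self._frame(list("BCD"))])
        assert set(out) == {"B", "C"}

    def test_single_cohort_identity(self):
        out = S.cross_cohort_intersect([self._frame(list("AB"))])
        assert set(out) == {"A", "B"}

    def test_disjoint_empty_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            out = S.cross_cohort_intersect([self._frame(["A"]),
                                            self._frame(["B"])])
        assert out == []

    def test_ordered_by_mean_rho(self):
        a = self._frame(["X", "Y"], [0.5, 0.9])
        b = self._frame(["X", "Y"], [0.6, 0.8])
        assert S.cross_cohort_intersect([a, b]) == ["Y", "X"]


# ---------------------------------------------------------------------------
# enrichment score: clean-room oracle of the published algorithm
# ---------------------------------------------------------------------------

def gsva_oracle(values: np.ndarray, set_genes: set[int], tau: float = 1.0):
    """Step-by-step implementation with explicit loops: Gaussian kernel CDF
    (bandwidth sd/4), per-sample decreasing sort, symmetric rank statistic
    |position - p/2|, weighted KS walk, max(walk)+min(walk) score."""
    p, n = values.shape
    z = np.zeros((p, n))
    for i in range(p):
        h = np.std(values[i], ddof=1) / 4.0
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += stats.norm.cdf((values[i, j] - values[i, k]) / h)
            z[i, j] = acc / n
    m = len(set_genes)
    scores = []
    for j in range(n):
        order = sorted(range(p), key=lambda i: -z[i, j])
        rank_stat = {}
        for pos, gene in enumerate(order, start=1):
            rank_stat[gene] = abs(pos - p / 2.0)
        denom = sum(rank_stat[g] ** tau for g in set_genes)
        walk, cum_in, cum_out = [], 0.0, 0.0
        for gene in order:
            if gene in set_genes:
                cum_in += rank_stat[gene] ** tau / denom
            else:
                cum_out += 1.0 / (p - m)
            walk.append(cum_in - cum_out)
        scores.append(max(walk) + min(walk))
    return np.array(scores)


class TestEnrichmentScore:
    @staticmethod
    def _norm(values):
        return NormalizedMatrix([f"g{i}" for i in range(values.shape[0])],
                                [f"s{j}" for j in range(values.shape[1])],
                                values)

    def test_identical_columns_equal_scores(self, rng):
        col = rng.normal(size=(15, 1))
        values = np.tile(col, (1, 4))
        sig = GeneSignature("s", ["g0", "g1", "g2"])
        scores = S.enrichment_score(self._norm(values), sig)
        assert np.allclose(scores, scores[0])

    def test_forced_ordering(self, rng):
        # sample 0: signature genes at the top; sample 1: at the bottom
        values = rng.normal(0, 0.1, size=(20, 4))
        values[:3, 0] += 10.0
        values[:3, 1] -= 10.0
        sig = GeneSignature("s", ["g0", "g1", "g2"])
        scores = S.enrichment_score(self._norm(values), sig)
        assert scores[0] > scores[1]

    def test_matches_oracle_on_toy_matrix(self):
        rng = np.random.default_rng(777)
        values = rng.normal(size=(20, 6))
        sig = GeneSignature("s", ["g1", "g4", "g7", "g15"])
        got = S.enrichment_score(self._norm(values), sig)
        expected = gsva_oracle(values, {1, 4, 7, 15})
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_scores_bounded(self, rng):
        values = rng.normal(size=(30, 8))
        sig = GeneSignature("s", [f"g{i}" for i in range(5)])
        scores = S.enrichment_score(self._norm(values), sig)
        assert np.all(np.abs(scores) <= 1.0)

    def test_column_permutation_permutes_scores(self, rng):
        values = rng.normal(size=(25, 6))
        sig = GeneSignature("s", ["g0", "g3", "g5"])
        scores = S.enrichment_score(self._norm(values), sig)
        perm = [5, 0, 3, 1, 4, 2]
        scores2 = S.enrichment_score(self._norm(values[:, perm]), sig)
        np.testing.assert_allclose(scores2, scores[perm], atol=1e-12)

    def test_absent_genes_ignored(self, rng):
        values = rng.normal(size=(25, 5))
        sig1 = GeneSignature("s", ["g0", "g3", "g5"])
        sig2 = GeneSignature("s", ["g0", "g3", "g5", "NOT_THERE"])
        np.testing.assert_array_equal(
            S.enrichment_score(self._norm(values), sig1),
            S.enrichment_score(self._norm(values), sig2))

    def test_too_few_present_genes_raises(self, rng):
        values = rng.normal(size=(10, 4))
        sig = GeneSignature("s", ["g0", "ABSENT1", "ABSENT2"])
        with pytest.raises(ValueError, match="<2"):
            S.enrichment_score(self._norm(values), sig)


class TestMinmaxRescale:
    def test_linear_endpoints(self):
        np.testing.assert_allclose(S.minmax_rescale(np.array([-0.5, 0.0, 0.5])),
                                   [1.0, 5.5, 10.0])

    @given(hst.lists(hst.floats(-1, 1, allow_nan=False), min_size=2,
                     max_size=50).filter(lambda v: max(v) > min(v)))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_endpoints(self, vals):
        out = S.minmax_rescale(np.array(vals))
        assert out.min() == pytest.approx(1.0)
        assert out.max() == pytest.approx(10.0)
        assert np.all((out >= 1.0 - 1e-12) & (out <= 10.0 + 1e-12))

    def test_constant_vector_midpoint_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = S.minmax_rescale(np.array([0.2, 0.2, 0.2]))
        np.testing.assert_allclose(out, 5.5)


class TestGroupCompare:
    @staticmethod
    def _clin(responses):
        return ClinicalTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(responses))],
            "response": responses}))

    def test_exact_enumeration_p(self):
        # U=0 for [1,2,3] vs [4,5,6]; 2/20 orderings as extreme, p = 0.1
        clin = self._clin(["PR", "PR", "PR", "SD", "SD", "SD"])
        out = S.group_compare(np.array([1, 2, 3, 4, 5, 6.0]), clin)
        row = out[(out.group_a == "CR/PR") & (out.group_b == "SD")].iloc[0]
        assert row["statistic"] == 0.0
        assert row["p"] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        clin = self._clin(["PR"] * 3 + ["PD"] * 3)
        out = S.group_compare(np.array([1, 2, 3, 1, 2, 3.0]), clin)
        row = out[(out.group_a == "CR/PR") & (out.group_b == "PD")].iloc[0]
        assert row["p"] == pytest.approx(1.0)

    def test_empty_group_skipped(self):
        clin = self._clin(["PR", "PR", "PD", "PD"])
        out = S.group_compare(np.arange(4.0), clin)
        sd_rows = out[out.group_a == "CR/PR"]
        assert "skipped" in out[(out.group_a == "CR/PR")
                                & (out.group_b == "SD")].iloc[0]["note"]
        assert sd_rows.shape[0] == 2

    def test_power_on_synthetic_cohorts(self):
        # response_effect = 1 latent SD, n=100: cDC1 score separates CR/PR
        # from PD in most seeds
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cm, clin, truth = synthetic.gen_bulk_cohort(
                synthetic.BulkSimParams(n_samples=100, n_genes=200,
                                        response_effect=1.0, seed=100 + seed))
            norm = S.log2_cpm(cm)
            sig = GeneSignature("cDC1", truth.signature_genes["cDC1"])
            raw = S.enrichment_score(norm, sig)
            out = S.group_compare(raw, clin)
            row = out[(out.group_a == "CR/PR") & (out.group_b == "PD")].iloc[0]
            hits += row["p"] < 0.05
        assert hits >= 0.8 * n_seeds

    def test_monotone_invariance_raw_vs_rescaled(self, rng):
        # regression: U-test p identical on raw and min-max rescaled scores
        raw = rng.normal(size=30)
        clin = self._clin(["PR"] * 10 + ["SD"] * 10 + ["PD"] * 10)
        p_raw = S.group_compare(raw, clin)["p"].to_numpy()
        p_scaled = S.group_compare(S.minmax_rescale(raw), clin)["p"].to_numpy()
        np.testing.assert_allclose(p_raw, p_scaled, atol=1e-12)


class TestCorrelationPanel:
    def test_self_correlation(self, rng):
        x = rng.normal(size=20)
        out = S.correlation_panel({"xx": (x, x)})
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_negation(self, rng):
        x = rng.normal(size=20)
        out = S.correlation_panel({"xn": (x, -x)})
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_bivariate_normal_recovery(self):
        r = np.random.default_rng(55)
        z = r.standard_normal((500, 2))
        y = 0.6 * z[:, 0] + np.sqrt(1 - 0.36) * z[:, 1]
        out = S.correlation_panel({"xy": (z[:, 0], y)})
        assert out.loc[0, "r"] == pytest.approx(0.6, abs=0.08)

    def test_zero_variance_missing(self, rng):
        x = rng.normal(size=10)
        out = S.correlation_panel({"xc": (x, np.ones(10))})
        assert np.isnan(out.loc[0, "r"])
        assert out.loc[0, "note"] == "zero variance"

    def test_spearman_method(self, rng):
        x = rng.normal(size=30)
        out = S.correlation_panel({"xy": (x, np.exp(x))}, method="spearman")
        assert out.loc[0, "r"] == pytest.approx(1.0)


class TestDeriveSignature:
    def test_planted_signature_recovered(self):
        # full chain on three synthetic cohorts: detectability -> meta-signal
        # -> importance -> intersection recovers >= 80% of planted genes
        seed = 60
        cohorts, pool, planted = [], [], None
        for c in range(3):
            cm, _, truth = synthetic.gen_bulk_cohort(
                synthetic.BulkSimParams(n_samples=200, n_genes=300,
                                        seed=seed + c))
            cohorts.append(cm)
            planted = truth.signature_genes["cDC1"]
        noise = [g for g in cohorts[0].genes if g.startswith("BG_")][:30]
        pool = planted + noise
        sig = S.derive_signature(cohorts, pool, name="cDC1-derived")
        recovered = set(sig.genes) & set(planted)
        assert len(recovered) >= 0.8 * len(planted)
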