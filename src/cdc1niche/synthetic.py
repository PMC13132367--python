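"""Seeded synthetic-data generators.

Three generators emulate the statistical structure of the pipeline inputs:

* :func:`gen_bulk_cohort` — negative-binomial bulk RNA-seq counts with latent
  per-sample cell-type abundance factors and a response label tied to the
  cDC1 latent through a logistic link;
* :func:`gen_tissue` — planar marker-intensity point patterns in which a
  tunable fraction of T cells is displaced toward cDC1 positions;
* :func:`gen_spatial_transcriptome` — cell x gene Poisson counts with
  canonical-marker elevation in the owning cell type and activation-gene
  elevation near true cDC1 cells.

All generators are pure functions of their parameter object (which carries
the seed): calling them twice yields identical output. The single seed fans
out to independent per-stream substreams via ``numpy`` SeedSequence spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CellTranscriptMatrix, ClinicalTable, CountMatrix

__all__ = [
    "BulkSimParams",
    "TissueSimParams",
    "STSimParams",
    "BulkTruth",
    "gen_bulk_cohort",
    "gen_tissue",
    "gen_spatial_transcriptome",
]


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# bulk cohorts
# ---------------------------------------------------------------------------

@dataclass
class BulkSimParams:
    """Parameters for the bulk RNA-seq cohort generator."""

    n_samples: int = 200
    n_genes: int = 500
    signature_sizes: dict[str, int] = field(
        default_factory=lambda: {"cDC1": 20, "CD8": 20})
    latent_corr: float = 0.6
    response_effect: float = 1.0
    latent_sd: float = 0.5
    nb_dispersion: float = 0.2
    baseline_mean: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not -1.0 <= self.latent_corr <= 1.0:
            raise ValueError(
                f"latent_corr {self.latent_corr} gives a non-PSD factor covariance")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if sum(self.signature_sizes.values()) > self.n_genes:
            raise ValueError("signature genes exceed n_genes")


@dataclass
class BulkTruth:
    """Hidden truth retained for recovery tests."""

    latents: pd.DataFrame          # sample x cell type latent factors
    signature_genes: dict[str, list[str]]
    benefit: np.ndarray            # binary benefit indicator per sample


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB draw parameterized by mean and dispersion: var = mu + a*mu^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_bulk_cohort(params: BulkSimParams) -> tuple[CountMatrix, ClinicalTable, BulkTruth]:
    """Simulate one bulk RNA-seq cohort.

    Signature genes of cell type *t* have their NB mean multiplied by
    ``exp(latent_t)`` in each sample. The benefit label is drawn first
    (Bernoulli 1/2) and responders' cDC1 latent is shifted upward by
    ``response_effect`` latent SDs; by Gaussian discriminant analysis the
    implied P(benefit | latent) is a logistic link with slope
    ``response_effect`` per SD, i.e. response probability increases
    monotonically in the cDC1 latent.
    """
    params.validate()
    rng_latent, rng_counts, rng_resp = _substreams(params.seed, 3)

    types = list(params.signature_sizes)
    n, rho = params.n_samples, params.latent_corr

    # correlated standard-normal latents: cDC1<->CD8 pair gets rho, any
    # further types are independent
    z = rng_latent.standard_normal((n, len(types)))
    latents = z.copy()
    if len(types) >= 2:
        latents[:, 1] = rho * z[:, 0] + math.sqrt(max(0.0, 1 - rho * rho)) * z[:, 1]
    latents *= params.latent_sd

    benefit = (rng_resp.uniform(size=n) < 0.5).astype(int)
    latents[:, 0] += params.response_effect * params.latent_sd * benefit

    gene_names: list[str] = []
    sig_genes: dict[str, list[str]] = {}
    log_mult = np.zeros((0, n))
    for j, t in enumerate(types):
        k = params.signature_sizes[t]
        names = [f"{t}_SIG_{i:04d}" for i in range(k)]
        sig_genes[t] = names
        gene_names.extend(names)
        log_mult = np.vstack([log_mult, np.tile(latents[:, j], (k, 1))])
    n_bg = params.n_genes - len(gene_names)
    gene_names.extend(f"BG_{i:05d}" for i in range(n_bg))
    log_mult = np.vstack([log_mult, np.zeros((n_bg, n))])

    # spread baseline means over ~2 decades so ranks are informative
    base = params.baseline_mean * np.exp(
        rng_counts.normal(0.0, 1.0, size=params.n_genes))
    mean = base[:, None] * np.exp(log_mult)
    counts = _nb_sample(rng_counts, mean, params.nb_dispersion)

    # split benefit/no-benefit into RECIST-style categories
    u = rng_resp.uniform(size=n)
    response = np.where(benefit == 1,
                        np.where(u < 0.2, "CR", "PR"),
                        np.where(u < 0.4, "SD", "PD"))

    samples = [f"S{i:04d}" for i in range(n)]
    cm = CountMatrix(gene_names, samples, counts)
    clin = ClinicalTable(pd.DataFrame({"sample_id": samples, "response": response}))
    truth = BulkTruth(
        pd.DataFrame(latents, index=samples, columns=types), sig_genes, benefit)
    return cm, clin, truth


# ---------------------------------------------------------------------------
# mIF tissue point patterns
# ---------------------------------------------------------------------------

@dataclass
class TissueSimParams:
    """Parameters for the labelled planar point-pattern generator."""

    field_width: float = 1000.0
    field_height: float = 1000.0
    n_cdc1: int = 50
    n_cd8: int = 500
    n_cd4: int = 500
    n_other: int = 2000
    attraction_fraction: float = 0.0
    displacement_sd: float = 5.0
    intensity_gap: float = 40.0  # separation of positive/negative marker modes
    seed: int = 0

    def validate(self) -> None:
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("zero or negative field area")
        for name in ("n_cdc1", "n_cd8", "n_cd4", "n_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.attraction_fraction <= 1.0:
            raise ValueError("attraction_fraction must lie in [0, 1]")
        if self.displacement_sd <= 0:
            raise ValueError("displacement_sd must be > 0")


def _attracted_positions(rng: np.random.Generator, anchors: np.ndarray,
                         n: int, sd: float, w: float, h: float) -> np.ndarray:
    """Gaussian displacement from a random anchor; out-of-field draws are
    rejected and resampled to preserve the displacement distribution."""
    out = np.empty((n, 2))
    for i in range(n):
        while True:
            a = anchors[rng.integers(len(anchors))]
            p = a + rng.normal(0.0, sd, size=2)
            if 0 <= p[0] <= w and 0 <= p[1] <= h:
                out[i] = p
                break
    return out


def gen_tissue(params: TissueSimParams) -> pd.DataFrame:
    """Simulate a segmented-cell table (cell_id, x_um, y_um, marker
    intensities, hidden ``true_type``).

    Non-attracted cells are uniform on the field. A fraction
    ``attraction_fraction`` of CD8 and CD4 cells is instead placed by
    Gaussian displacement around a random cDC1. Marker intensities are drawn
    so that thresholding recovers the generating phenotype.
    """
    params.validate()
    rng_pos, rng_int = _substreams(params.seed, 2)
    w, h = params.field_width, params.field_height

    cdc1 = rng_pos.uniform([0, 0], [w, h], size=(params.n_cdc1, 2))

    def t_cells(n: int) -> np.ndarray:
        if n == 0:
            return np.empty((0, 2))
        n_attr = int(round(params.attraction_fraction * n)) if params.n_cdc1 > 0 else 0
        uni = rng_pos.uniform([0, 0], [w, h], size=(n - n_attr, 2))
        if n_attr == 0:
            return uni
        attr = _attracted_positions(rng_pos, cdc1, n_attr,
                                    params.displacement_sd, w, h)
        return np.vstack([uni, attr])

    cd8 = t_cells(params.n_cd8)
    cd4 = t_cells(params.n_cd4)
    other = rng_pos.uniform([0, 0], [w, h], size=(params.n_other, 2))

    xy = np.vstack([cdc1, cd8, cd4, other])
    true_type = (["cDC1"] * params.n_cdc1 + ["CD8T"] * params.n_cd8
                 + ["CD4T"] * params.n_cd4 + ["other"] * params.n_other)
    n_total = len(true_type)

    # marker intensities: positive cells sit intensity_gap above background
    gap = params.intensity_gap
    lo = rng_int.gamma(2.0, 1.5, size=(n_total, 3))   # background noise
    intens = pd.DataFrame(lo, columns=["BATF3", "CD3", "CD8"])
    tt = np.array(true_type)
    pos_high = lambda n: gap + rng_int.gamma(3.0, 3.0, size=n)  # noqa: E731
    intens.loc[tt == "cDC1", "BATF3"] = pos_high(int((tt == "cDC1").sum()))
    for marker, mask in (("CD3", (tt == "CD8T") | (tt == "CD4T")),
                         ("CD8", tt == "CD8T")):
        intens.loc[mask, marker] = pos_high(int(mask.sum()))

    table = pd.DataFrame({
        "cell_id": [f"c{i:06d}" for i in range(n_total)],
        "x_um": xy[:, 0], "y_um": xy[:, 1],
    })
    table = pd.concat([table, intens], axis=1)
    table["true_type"] = true_type
    return table


# ---------------------------------------------------------------------------
# imaging spatial transcriptomics
# ---------------------------------------------------------------------------

CANONICAL_GENES = {"cDC1": ["BATF3", "XCR1", "CLEC9A"], "CD8": ["CD8A", "CD8B"]}
DEFAULT_ACTIVATION_GENES = ["IDO1", "CXCL10", "CXCL9", "IL2RA", "TNFRSF9"]


@dataclass
class STSimParams:
    """Parameters for the cell x gene spatial-transcriptome generator."""

    n_cells: int = 3000
    field_width: float = 1000.0
    field_height: float = 1000.0
    activation_genes: list[str] = field(
        default_factory=lambda: list(DEFAULT_ACTIVATION_GENES))
    n_background_genes: int = 200
    type_proportions: dict[str, float] = field(
        default_factory=lambda: {"cDC1": 0.03, "CD8": 0.12, "other": 0.85})
    marker_fold: float = 300.0
    activation_fold: float = 5.0
    marker_baseline: float = 0.01   # per-gene mean in non-owning cells
    activation_baseline: float = 0.5
    count_depth: float = 300.0
    activation_radius_um: float = 10.0
    # each immune type also elevates a correlated program of ordinary genes,
    # the structure unsupervised clustering actually keys on
    program_size: int = 20
    program_fold: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if not self.panel():
            raise ValueError("empty gene panel")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type proportions sum to {total}, expected 1")
        if self.marker_fold < 1 or self.activation_fold < 1:
            raise ValueError("folds must be >= 1")
        if self.marker_baseline <= 0 or self.activation_baseline <= 0:
            raise ValueError("baselines must be > 0")
        if self.count_depth <= 0:
            raise ValueError("count_depth must be > 0")

    def panel(self) -> list[str]:
        markers = [g for gs in CANONICAL_GENES.values() for g in gs]
        programs = [f"PRG_{t}_{i:03d}" for t in CANONICAL_GENES
                    for i in range(self.program_size)]
        bg = [f"BG_{i:04d}" for i in range(self.n_background_genes)]
        return markers + list(self.activation_genes) + programs + bg


def gen_spatial_transcriptome(params: STSimParams) -> CellTranscriptMatrix:
    """Simulate an imaging-ST cell x gene matrix.

    Every gene has baseline Poisson mean ``count_depth / n_genes``. Canonical
    markers are elevated ``marker_fold``-fold in their owning type;
    activation genes are elevated ``activation_fold``-fold in cells whose
    centroid lies within ``activation_radius_um`` of any true cDC1 cell.
    Hidden truth (type label, near-cDC1 flag) is kept in ``meta``.
    """
    params.validate()
    rng_pos, rng_type, rng_counts = _substreams(params.seed, 3)

    panel = params.panel()
    n, p = params.n_cells, len(panel)
    xy = rng_pos.uniform([0, 0], [params.field_width, params.field_height],
                         size=(n, 2))
    type_names = list(params.type_proportions)
    probs = np.array([params.type_proportions[t] for t in type_names])
    cell_type = rng_type.choice(type_names, size=n, p=probs)

    # near-cDC1 flag from true cDC1 centroids
    from scipy.spatial import cKDTree
    cdc1_xy = xy[cell_type == "cDC1"]
    if len(cdc1_xy):
        tree = cKDTree(cdc1_xy)
        near = np.array([
            bool(tree.query_ball_point(q, params.activation_radius_um))
            for q in xy
        ])
    else:
        near = np.zeros(n, dtype=bool)

    # mean model: canonical markers and activation genes sit on low,
    # near-zero baselines (imaging-ST background) and are elevated
    # multiplicatively; background genes carry the sequencing depth
    n_bg = params.n_background_genes
    n_ordinary = n_bg + 2 * params.program_size
    mean = np.zeros((p, n))
    all_markers = [g for gs in CANONICAL_GENES.values() for g in gs]
    for g in all_markers:
        mean[panel.index(g), :] = params.marker_baseline
    for g in params.activation_genes:
        mean[panel.index(g), :] = params.activation_baseline
    ordinary = [g for g in panel
                if g.startswith(("BG_", "PRG_"))]
    if ordinary:
        idx = [panel.index(g) for g in ordinary]
        mean[idx, :] = params.count_depth / n_ordinary
    for t, markers in CANONICAL_GENES.items():
        owned = cell_type == t
        for g in markers:
            mean[panel.index(g), owned] *= params.marker_fold
        for i in range(params.program_size):
            mean[panel.index(f"PRG_{t}_{i:03d}"), owned] *= params.program_fold
    for g in params.activation_genes:
        mean[panel.index(g), near] *= params.activation_fold
    counts = rng_counts.poisson(mean)

    meta = pd.DataFrame({"true_type": cell_type, "near_cdc1": near})
    return CellTranscriptMatrix(
        [f"c{i:06d}" for i in range(n)], xy[:, 0], xy[:, 1], panel, counts, meta)
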