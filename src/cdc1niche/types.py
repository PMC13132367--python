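"""Core domain types shared across the analysis arms.

Conventions: coordinates are planar, in microns, origin top-left with y
increasing downward (imaging convention). Count matrices are genes x columns
(samples or cells) with non-negative integer entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneSignature",
    "ClinicalTable",
    "CellTranscriptMatrix",
    "Hub",
    "HubSet",
    "CELL_TABLE_COLUMNS",
    "PHENOTYPES",
    "EXCLUDED",
    "validate_cell_table",
]

#: required columns of a per-cell marker-intensity table
CELL_TABLE_COLUMNS = ("cell_id", "x_um", "y_um", "BATF3", "CD3", "CD8")

#: phenotype labels produced by the mIF arm
PHENOTYPES = ("cDC1", "CD8T", "CD4T", "other")

#: sentinel returned when a sample lacks a required phenotype and must be
#: excluded from a spatial statistic (distinct from an error)
EXCLUDED = "excluded"


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer counts."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate gene id: {dup}")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample library size (column sum)."""
        return np.asarray(self.counts.sum(axis=0), dtype=float)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene not in matrix: {gene}") from None

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        idx = [self.gene_index(g) for g in genes]
        return CountMatrix(list(genes), list(self.samples), self.counts[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)


@dataclass
class NormalizedMatrix:
    """Gene x sample matrix of normalized expression values.

    ``unit`` records provenance ('log2-CPM' or 'log2-TPM'); ``norm_factors``
    are the per-sample scaling factors used (geometric mean 1).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    unit: str = "log2-CPM"
    norm_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match gene/sample ids")
        if self.unit not in ("log2-CPM", "log2-TPM"):
            raise ValueError(f"unknown unit tag: {self.unit}")
        if self.norm_factors is None:
            self.norm_factors = np.ones(len(self.samples))

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene), :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class GeneSignature:
    """Named ordered set of gene symbols with per-gene provenance flags."""

    name: str
    genes: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    VALID_PROVENANCE = (
        "candidate",
        "detectability-passed",
        "importance-passed",
        "curated",
    )

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        # de-duplicate preserving first occurrence
        seen: set[str] = set()
        self.genes = [g for g in self.genes if not (g in seen or seen.add(g))]
        for g, p in self.provenance.items():
            if p not in self.VALID_PROVENANCE:
                raise ValueError(f"invalid provenance {p!r} for gene {g}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


#: default three-gene cDC1 signature
CDC1_DEFAULT = GeneSignature("cDC1", ["BATF3", "XCR1", "CLEC9A"],
                             {g: "curated" for g in ("BATF3", "XCR1", "CLEC9A")})

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations: response category and optional survival.

    ``table`` columns: sample_id, response, and optionally os_time, os_event.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "response"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        bad = set(self.table["response"]) - set(RESPONSE_CATEGORIES) - {"good", "bad"}
        if bad:
            raise ValueError(f"unknown response categories: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def grouped_response(self) -> pd.Series:
        """Merge CR and PR into a single benefit group; SD and PD stay apart."""
        mapping = {"CR": "CR/PR", "PR": "CR/PR", "SD": "SD", "PD": "PD",
                   "good": "good", "bad": "bad"}
        return self.table["response"].map(mapping)

    def benefit(self) -> pd.Series:
        """Binary clinical-benefit indicator (CR/PR or 'good' = 1)."""
        return self.table["response"].isin(["CR", "PR", "good"]).astype(int)


@dataclass
class CellTranscriptMatrix:
    """Cell x gene counts with cell centroids, stored genes x cells."""

    cell_ids: list[str]
    x_um: np.ndarray
    y_um: np.ndarray
    genes: list[str]
    counts: np.ndarray  # genes x cells
    meta: pd.DataFrame | None = None  # optional hidden truth / extra columns

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.cell_ids)
        if self.x_um.shape != (n,) or self.y_um.shape != (n,):
            raise ValueError("coordinate arrays do not match cell ids")
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise ValueError("non-finite cell coordinates")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), n):
            raise ValueError("counts shape does not match genes x cells")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def totals(self) -> np.ndarray:
        """Per-cell total molecule count (column sum)."""
        return np.asarray(self.counts.sum(axis=0))

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene not in panel: {gene}") from None

    def subset_cells(self, mask: np.ndarray) -> "CellTranscriptMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return CellTranscriptMatrix(
            [self.cell_ids[i] for i in idx],
            self.x_um[idx], self.y_um[idx],
            list(self.genes), self.counts[:, idx], meta,
        )


@dataclass
class Hub:
    """A 10-um-radius niche centered on a candidate immune cell."""

    center_cell: str
    center_index: int
    member_indices: np.ndarray
    agg_counts: np.ndarray  # summed over members, aligned to HubSet.genes
    n_cells: int
    x_um: float
    y_um: float
    hub_class: str | None = None  # 'cDC1-rich' | 'cDC1-devoid'


@dataclass
class HubSet:
    """All hubs built on one sample, sharing a gene axis."""

    genes: list[str]
    hubs: list[Hub]
    radius_um: float

    def __len__(self) -> int:
        return len(self.hubs)

    def __iter__(self):
        return iter(self.hubs)

    def classes(self) -> list[str | None]:
        return [h.hub_class for h in self.hubs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hub_id": [f"hub_{i}" for i in range(len(self.hubs))],
            "center_cell": [h.center_cell for h in self.hubs],
            "n_cells": [h.n_cells for h in self.hubs],
            "class": [h.hub_class for h in self.hubs],
            "x_um": [h.x_um for h in self.hubs],
            "y_um": [h.y_um for h in self.hubs],
        })


def validate_cell_table(table: pd.DataFrame, require_phenotype: bool = False) -> pd.DataFrame:
    """Check a per-cell table for required columns and finite coordinates."""
    required = list(CELL_TABLE_COLUMNS) + (["phenotype"] if require_phenotype else [])
    for col in required:
        if col not in table.columns:
            raise ValueError(f"cell table missing column: {col}")
    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("cell table has non-finite coordinates")
    return table
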