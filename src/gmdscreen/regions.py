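"""Gene-region-averaged methylation and epigenome-average methylation.

Probe betas are summarised over the six annotation-defined gene region
categories of the 450K manifest: TSS1500 (200-1500 b upstream of the TSS),
TSS200 (0-200 b upstream), 5'UTR, 1st exon, gene body, and 3'UTR. A probe
annotated to k distinct (gene, region) pairs contributes to k regions; a gene
is represented by at most six regions. Region values are unweighted
arithmetic means of the non-missing constituent probe betas per sample —
region identity is purely annotation-driven (no coordinate arithmetic), and a
single-probe region is valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import BetaMatrix

REGION_CATEGORIES: tuple[str, ...] = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "Body",
    "3'UTR",
)

REGION_SEP = "|"  # region ids are "GENE|CATEGORY"

__all__ = [
    "REGION_CATEGORIES",
    "REGION_SEP",
    "ProbeAnnotation",
    "RegionMethylation",
    "build_region_index",
    "average_regions",
    "epigenome_mean",
    "region_id",
    "split_region_id",
]


def region_id(gene: str, category: str) -> str:
    return f"{gene}{REGION_SEP}{category}"


def split_region_id(rid: str) -> tuple[str, str]:
    gene, _, category = rid.rpartition(REGION_SEP)
    return gene, category


@dataclass
class ProbeAnnotation:
    """Per-probe genomic metadata in the 450K manifest dialect.

    ``table`` columns: probe_id, chromosome, position, cytoband,
    gene_symbols and region_categories (semicolon-delimited, positionally
    paired). Duplicate (gene, region) pairs within a probe are collapsed.
    """

    table: pd.DataFrame

    REQUIRED = (
        "probe_id",
        "chromosome",
        "position",
        "cytoband",
        "gene_symbols",
        "region_categories",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in annotation")
        self._entries = {
            row.probe_id: _parse_entries(
                row.probe_id, row.gene_symbols, row.region_categories
            )
            for row in self.table.itertuples(index=False)
        }

    def gene_entries(self, probe_id: str) -> list[tuple[str, str]]:
        """Distinct (gene_symbol, region_category) pairs for one probe."""
        return self._entries[probe_id]

    def genes_of(self, probe_id: str) -> set[str]:
        return {g for g, _ in self._entries.get(probe_id, [])}

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])


def _parse_entries(
    probe_id: str, gene_symbols: str, region_categories: str
) -> list[tuple[str, str]]:
    gs = str(gene_symbols) if not pd.isna(gene_symbols) else ""
    rc = str(region_categories) if not pd.isna(region_categories) else ""
    genes = [g for g in gs.split(";")] if gs else []
    cats = [c for c in rc.split(";")] if rc else []
    if len(genes) != len(cats):
        raise ValueError(
            f"probe {probe_id}: gene list ({len(genes)}) and region list "
            f"({len(cats)}) are not positionally paired"
        )
    seen: list[tuple[str, str]] = []
    for g, c in zip(genes, cats):
        if not g:
            raise ValueError(f"probe {probe_id}: empty gene symbol")
        if c not in REGION_CATEGORIES:
            raise ValueError(
                f"probe {probe_id}: unknown region category {c!r}"
            )
        if (g, c) not in seen:
            seen.append((g, c))
    return seen


@dataclass
class RegionMethylation:
    """Gene-region x samples averaged betas.

    ``values`` rows are region ids ("GENE|CATEGORY"); ``n_probes`` records
    each region's constituent probe count in the source matrix.
    """

    values: pd.DataFrame
    n_probes: pd.Series

    @property
    def region_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def build_region_index(annotation: ProbeAnnotation) -> dict[str, list[str]]:
    """Map region id -> ordered probe id list.

    A probe with k distinct (gene, region) entries appears in k index lists;
    intergenic probes (empty gene_entries) appear in none.
    """
    index: dict[str, list[str]] = {}
    for probe in annotation.probe_ids:
        for gene, cat in annotation.gene_entries(probe):
            index.setdefault(region_id(gene, cat), []).append(probe)
    return index


def average_regions(
    bm: BetaMatrix, index: dict[str, list[str]]
) -> RegionMethylation:
    """Average probe betas over regions, per sample, ignoring missing values.

    Regions with no probes present in the matrix are omitted; a region value
    is missing for a sample only when all constituent betas are missing.
    """
    present = set(bm.probe_ids)
    rows: list[np.ndarray] = []
    rids: list[str] = []
    counts: list[int] = []
    beta = bm.beta
    for rid in sorted(index):
        probes = [p for p in index[rid] if p in present]
        if not probes:
            continue
        block = beta.loc[probes].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            rows.append(np.nanmean(block, axis=0))
        rids.append(rid)
        counts.append(len(probes))
    values = pd.DataFrame(
        np.asarray(rows) if rows else np.empty((0, beta.shape[1])),
        index=pd.Index(rids, name="region_id"),
        columns=beta.columns,
    )
    n_probes = pd.Series(counts, index=values.index, name="n_probes", dtype=int)
    return RegionMethylation(values, n_probes)


def epigenome_mean(bm: BetaMatrix) -> pd.Series:
    """Per-sample mean beta over all (QC-passing) probes, ignoring missing.

    Samples whose betas are all missing get NaN with a warning.
    """
    arr = bm.beta.to_numpy(dtype=float)
    all_missing = np.isnan(arr).all(axis=0)
    if all_missing.any():
        bad = list(bm.sample_ids[all_missing])
        warnings.warn(f"samples with no non-missing betas: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(arr, axis=0)
    return pd.Series(means, index=bm.sample_ids, name="epigenome_mean")
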