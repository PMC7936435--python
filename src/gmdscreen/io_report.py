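"""Readers, writers and reporting for panel files and screen results.

Canonical on-disk formats are TSV (matrices: features as rows, samples as
columns; drug response and mutations: long tables) plus the 450K-manifest
CSV dialect for probe annotation. Agent ids carry a dataset-of-origin suffix
(e.g. ``vorinostat@GDSC``) so dual-source agents stay separate response
variables. Duplicate (agent, sample) response measurements are averaged on
load with a logged count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import BetaMatrix
from .regions import ProbeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_beta",
    "read_drug",
    "read_mutations",
    "read_categories",
    "read_annotation",
    "read_snp_mask",
    "summarize_directions",
    "export_supplementary_style",
    "write_records",
    "write_run_manifest",
]


def _read_matrix(path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        raise ValueError(f"{path}: non-numeric columns {list(bad)}")
    return df


def read_expression(path) -> pd.DataFrame:
    """Gene x sample RPKM-like expression matrix; values must be >= 0."""
    df = _read_matrix(path, "gene_symbol")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene symbols")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def read_beta(path, detection_path=None) -> BetaMatrix:
    """Probe x sample beta matrix with optional aligned detection p-values.

    Out-of-range betas are rejected with the offending probe row named.
    """
    beta = _read_matrix(path, "probe_id")
    vals = beta.to_numpy(dtype=float)
    bad = np.where(np.nan_to_num(vals, nan=0.5) > 1.0)
    bad0 = np.where(np.nan_to_num(vals, nan=0.5) < 0.0)
    for rows in (bad, bad0):
        if rows[0].size:
            probe = beta.index[rows[0][0]]
            raise ValueError(f"{path}: beta out of [0, 1] at probe {probe!r}")
    detp = None
    if detection_path is not None:
        detp = _read_matrix(detection_path, "probe_id")
    return BetaMatrix(beta, detp)


def read_drug(path) -> pd.DataFrame:
    """Long (agent_id, sample_id, log_ic50) TSV -> wide agents x samples.

    Duplicate (agent, sample) measurements are collapsed to their mean; the
    number of collapsed duplicates is logged.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"agent_id", "sample_id", "log_ic50"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if not np.issubdtype(df["log_ic50"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric log_ic50 values")
    n_dup = int(df.duplicated(["agent_id", "sample_id"]).sum())
    if n_dup:
        logger.info("averaged %d duplicate (agent, sample) measurements", n_dup)
    wide = (
        df.groupby(["agent_id", "sample_id"])["log_ic50"]
        .mean()
        .unstack("sample_id")
    )
    wide.index.name = "agent_id"
    return wide


def read_mutations(path) -> pd.DataFrame:
    """Variant table, native dialect or minimal MAF-dialect columns."""
    df = pd.read_csv(path, sep="\t")
    native = {"sample_id", "gene_symbol", "protein_change", "variant_class"}
    maf = {"Tumor_Sample_Barcode", "Hugo_Symbol", "HGVSp_Short",
           "Variant_Classification"}
    if native.issubset(df.columns):
        return df[sorted(native)].reindex(
            columns=["sample_id", "gene_symbol", "protein_change", "variant_class"]
        )
    if maf.issubset(df.columns):
        nonsyn = {
            "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
            "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins", "Splice_Site",
            "Nonstop_Mutation", "Translation_Start_Site",
        }
        out = pd.DataFrame(
            {
                "sample_id": df["Tumor_Sample_Barcode"],
                "gene_symbol": df["Hugo_Symbol"],
                "protein_change": df["HGVSp_Short"].str.removeprefix("p."),
                "variant_class": np.where(
                    df["Variant_Classification"].isin(nonsyn),
                    "non_synonymous",
                    np.where(
                        df["Variant_Classification"] == "Silent",
                        "synonymous",
                        "other",
                    ),
                ),
            }
        )
        return out
    raise ValueError(f"{path}: unrecognized mutation table header")


def read_categories(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "category"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, category")
    return df.set_index("sample_id")["category"]


def read_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(
        path, dtype={"gene_symbols": str, "region_categories": str}
    )
    return ProbeAnnotation(df)


def read_snp_mask(path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


# ---------------------------------------------------------------------------
# reporting

def summarize_directions(
    records: pd.DataFrame, flag_column: str = "significant_strong"
) -> pd.DataFrame:
    """Directional counts of flagged records per (predictor, stratum, relation).

    The bar-chart analogue of the screen output: positive and negative
    correlation counts per GMD, split by stratum and cis/trans relation.
    n_positive + n_negative equals the flagged record count for each key.
    """
    flagged = records[records[flag_column].fillna(False).astype(bool)]
    if flagged.empty:
        return pd.DataFrame(
            columns=["predictor", "stratum", "relation", "n_positive", "n_negative"]
        )
    out = (
        flagged.assign(direction=np.where(flagged["rho"] > 0, "n_positive",
                                          "n_negative"))
        .groupby(["predictor", "stratum", "relation", "direction"])
        .size()
        .unstack("direction", fill_value=0)
        .reindex(columns=["n_positive", "n_negative"], fill_value=0)
        .reset_index()
    )
    out.columns.name = None
    return out


def _sorted_records(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["_abs_rho"] = out["rho"].abs()
    out = out.sort_values(
        by=["p_fdr", "_abs_rho", "predictor", "target", "stratum"],
        ascending=[True, False, True, True, True],
        kind="mergesort",
        na_position="last",
    ).drop(columns="_abs_rho")
    return out


def export_supplementary_style(
    records: pd.DataFrame, path, flag_column: str | None = "significant_strong"
) -> Path:
    """Write a result table sorted by p_FDR then |rho| descending.

    When ``flag_column`` is given, only flagged records are exported (the
    supplementary-table convention); pass None to export the full set. Ties
    are broken lexicographically for reproducible diffs.
    """
    path = Path(path)
    out = records
    if flag_column is not None:
        out = records[records[flag_column].fillna(False).astype(bool)]
    cols = [
        c
        for c in ["stratum", "predictor", "target", "rho", "p_raw", "p_fdr",
                  "n", "relation"]
        if c in records.columns
    ]
    _sorted_records(out)[cols].to_csv(path, sep="\t", index=False)
    return path


def write_records(records: pd.DataFrame, path) -> Path:
    """Write a full record table (deterministic order)."""
    path = Path(path)
    _sorted_records(records).to_csv(path, sep="\t", index=False)
    return path


def write_run_manifest(path, config: dict, seed: int | None, files: dict) -> Path:
    """JSON manifest of a run: config, seed, and sha256 per output file."""
    import hashlib

    digests = {}
    for name, fpath in files.items():
        fpath = Path(fpath)
        if fpath.exists():
            digests[name] = hashlib.sha256(fpath.read_bytes()).hexdigest()
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"config": config, "seed": seed, "files": digests}, fh, indent=2)
        fh.write("\n")
    return path
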