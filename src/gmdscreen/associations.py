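"""Spearman correlation screens with explicit-count BH-FDR families.

The screening engine used throughout the pipeline: rank correlations over
pairwise-complete samples, Benjamini-Hochberg adjustment over families whose
test count is a declared product (e.g. agents x genes [x cancer types]) that
may exceed the number of p-values actually computed (skipped combinations
count as implicit p = 1 tests), strength filters on |rho|, cis/trans
classification of methylation targets, and cancer-category stratification.

Spearman p-values use the large-sample t approximation on n - 2 degrees of
freedom, with average ranks for ties. Pairs with fewer than ``min_n``
complete observations, or zero variance in either ranked vector, are skipped
but still counted toward their family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PANCANCER = "pancancer"
DEFAULT_MIN_N = 10
DEFAULT_MIN_CATEGORY = 10

RECORD_COLUMNS = [
    "predictor",
    "target",
    "stratum",
    "rho",
    "p_raw",
    "p_fdr",
    "n",
    "relation",
    "significant_strong",
]

__all__ = [
    "PANCANCER",
    "FdrFamily",
    "Thresholds",
    "spearman",
    "bh_adjust",
    "correlate_tables",
    "screen",
    "classify_cis_trans",
    "stratify",
]


def spearman(
    x: np.ndarray, y: np.ndarray, min_n: int = DEFAULT_MIN_N
) -> tuple[float, float, int]:
    """Spearman rho and two-sided p on pairwise-complete observations.

    Returns ``(rho, p_raw, n)``; ``(nan, nan, n)`` when n < min_n or either
    ranked vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, n = _rho_n(x, y, min_n)
    if np.isnan(rho):
        return np.nan, np.nan, n
    return rho, _t_pvalue(rho, n), n


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bh_adjust(p_values, test_count: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values over an explicit family.

    ``test_count`` is the declared family size m; when it exceeds the number
    of supplied p-values the family is implicitly padded with p = 1 tests
    (which never change the adjusted values of the observed tests beyond the
    m in the numerator). NaN entries are passed through and do not count as
    observed tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    obs = ~np.isnan(p)
    pobs = p[obs]
    if ((pobs < 0) | (pobs > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    k = pobs.size
    m = k if test_count is None else int(test_count)
    if m < k:
        raise ValueError(f"test_count {m} < number of p-values {k}")
    if k == 0:
        return out
    order = np.argsort(pobs, kind="mergesort")
    ranked = pobs[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(k)
    res[order] = adj
    out[obs] = res
    return out


@dataclass
class FdrFamily:
    """A BH family with an explicitly declared test count.

    ``test_count`` is the product the study states (e.g. 255 agents x 72
    genes x 23 categories), never smaller than the number of records
    adjusted within it.
    """

    family_id: str
    test_count: int

    def adjust(self, records: pd.DataFrame) -> pd.DataFrame:
        records = records.copy()
        records["p_fdr"] = bh_adjust(records["p_raw"].to_numpy(), self.test_count)
        return records


@dataclass
class Thresholds:
    """Significance/strength cuts for one screen.

    ``p_mode`` selects whether ``p_cut`` applies to raw p (the fixed
    probe-level thresholds) or to BH-adjusted p.
    """

    p_mode: str = "fdr"  # "raw" | "fdr"
    p_cut: float = 0.05
    abs_rho_cut: float = 0.5

    def __post_init__(self) -> None:
        if self.p_mode not in ("raw", "fdr"):
            raise ValueError(f"unknown p_mode {self.p_mode!r}")

    def flag(self, records: pd.DataFrame) -> pd.Series:
        pcol = "p_raw" if self.p_mode == "raw" else "p_fdr"
        return (records[pcol] < self.p_cut) & (
            records["rho"].abs() > self.abs_rho_cut
        )


def correlate_tables(
    predictors: pd.DataFrame,
    targets: pd.DataFrame,
    sample_ids,
    stratum: str = PANCANCER,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """All predictor x target Spearman correlations within one stratum.

    Both tables are features x samples. Every pair is emitted, including
    skipped ones (rho = NaN), so family accounting stays explicit.
    """
    shared = [s for s in sample_ids if s in predictors.columns and s in targets.columns]
    if not shared:
        raise ValueError("no shared samples between predictor and target tables")
    P = predictors[shared].to_numpy(dtype=float)
    T = targets[shared].to_numpy(dtype=float)
    pred_ids = list(predictors.index)
    targ_ids = list(targets.index)
    npair = len(pred_ids) * len(targ_ids)
    rhos = np.full(npair, np.nan)
    ns = np.zeros(npair, dtype=int)
    k = 0
    for i in range(len(pred_ids)):
        x = P[i]
        for j in range(len(targ_ids)):
            rhos[k], ns[k] = _rho_n(x, T[j], min_n)
            k += 1
    # vectorized two-sided t-approximation p-values
    ps = np.full(npair, np.nan)
    ok = ~np.isnan(rhos)
    r, n = rhos[ok], ns[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    ps[ok] = p
    return pd.DataFrame(
        {
            "predictor": np.repeat(pred_ids, len(targ_ids)),
            "target": np.tile(targ_ids, len(pred_ids)),
            "stratum": stratum,
            "rho": rhos,
            "p_raw": ps,
            "n": ns,
        }
    )


def _rho_n(x: np.ndarray, y: np.ndarray, min_n: int) -> tuple[float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < max(min_n, 3):
        return np.nan, n
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx @ sx) * (sy @ sy))
    if denom == 0.0:
        return np.nan, n
    return float(np.clip((sx @ sy) / denom, -1.0, 1.0)), n


def screen(
    predictors: pd.DataFrame,
    targets: pd.DataFrame,
    sample_ids,
    stratum: str,
    thresholds: Thresholds,
    family: FdrFamily,
    min_n: int = DEFAULT_MIN_N,
) -> pd.DataFrame:
    """Correlate, FDR-adjust within ``family``, and flag significant-strong.

    The full record set is returned; ``significant_strong`` marks rows
    passing both the p and |rho| cuts. screen(A, B) and screen(B, A) agree
    on rho and p for each pair.
    """
    records = correlate_tables(predictors, targets, sample_ids, stratum, min_n)
    records = family.adjust(records)
    records["relation"] = "not_applicable"
    records["significant_strong"] = thresholds.flag(records).fillna(False)
    return records[RECORD_COLUMNS]


def classify_cis_trans(target_id: str, gmd_symbol: str, annotation) -> str:
    """cis iff the GMD's symbol is among the target's annotated genes.

    ``target_id`` is a probe id (looked up in ``annotation``) or a region id
    "GENE|CATEGORY". Intergenic probes are trans by convention.
    """
    from .regions import REGION_SEP, split_region_id

    if REGION_SEP in target_id:
        gene, _ = split_region_id(target_id)
        return "cis" if gene == gmd_symbol else "trans"
    return "cis" if gmd_symbol in annotation.genes_of(target_id) else "trans"


def annotate_relations(records: pd.DataFrame, annotation) -> pd.DataFrame:
    """Fill the ``relation`` column for methylation-target records."""
    records = records.copy()
    records["relation"] = [
        classify_cis_trans(t, g, annotation)
        for g, t in zip(records["predictor"], records["target"])
    ]
    return records


def stratify(
    category_map: pd.Series, min_size: int = DEFAULT_MIN_CATEGORY
) -> list[tuple[str, list[str]]]:
    """Strata: pancancer plus every cancer category with >= min_size samples.

    ``category_map`` maps sample id -> category label. Categories are
    returned in sorted label order after the pancancer stratum.
    """
    strata: list[tuple[str, list[str]]] = [
        (PANCANCER, list(category_map.index))
    ]
    sizes = category_map.value_counts()
    for cat in sorted(sizes.index[sizes >= min_size]):
        strata.append((cat, list(category_map.index[category_map == cat])))
    return strata
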