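"""Mutation-conditional regression of drug response.

Tests whether an expression or methylation predictor of response to an agent
(the motivating case is the MEK inhibitor trametinib) survives adjustment
for sequence variants known to drive sensitivity or resistance: BRAF V600E
and any non-synonymous KRAS or NRAS variant. Fits are ordinary least squares
of log10(IC50) on the three mutation indicators plus the predictor, with
two-sided t-tests per coefficient; predictor p-values across a candidate set
are BH-adjusted, mutation-flag p-values are reported unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .associations import bh_adjust

FLAG_COLUMNS = ("braf_v600e", "kras_ns", "nras_ns")

__all__ = [
    "FLAG_COLUMNS",
    "ConditionalFit",
    "build_flags",
    "fit_conditional",
    "conditional_screen",
]


def build_flags(mutations: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Per-sample mutation indicators from a long variant table.

    ``braf_v600e`` is true iff a BRAF row with protein change V600E exists;
    ``kras_ns``/``nras_ns`` iff any non-synonymous row in that gene exists.
    Samples absent from the table are wild-type (all flags false).
    """
    flags = pd.DataFrame(
        False, index=pd.Index(sample_ids, name="sample_id"), columns=list(FLAG_COLUMNS)
    )
    for row in mutations.itertuples(index=False):
        if row.sample_id not in flags.index:
            continue
        gene = row.gene_symbol.upper()
        if gene == "BRAF" and str(row.protein_change) == "V600E":
            flags.loc[row.sample_id, "braf_v600e"] = True
        elif gene == "KRAS" and row.variant_class == "non_synonymous":
            flags.loc[row.sample_id, "kras_ns"] = True
        elif gene == "NRAS" and row.variant_class == "non_synonymous":
            flags.loc[row.sample_id, "nras_ns"] = True
    return flags


@dataclass
class ConditionalFit:
    predictor_coef: float
    predictor_p: float
    flag_coefs: dict[str, float]
    flag_ps: dict[str, float]
    n: int
    dropped_flags: list[str]


def fit_conditional(
    log_ic50: pd.Series,
    predictor: pd.Series,
    flags: pd.DataFrame,
    sample_ids=None,
) -> ConditionalFit:
    """OLS of response on mutation flags plus one predictor, complete cases.

    Flags that are constant within the complete cases (rank-deficient design)
    are dropped with a warning and the model refit without them.
    """
    if sample_ids is None:
        sample_ids = log_ic50.index.intersection(predictor.index).intersection(
            flags.index
        )
    df = pd.DataFrame(
        {
            "y": log_ic50.reindex(sample_ids),
            "predictor": predictor.reindex(sample_ids),
            **{c: flags.reindex(sample_ids)[c].astype(float) for c in FLAG_COLUMNS},
        }
    ).dropna()
    n = len(df)
    flag_cols = list(FLAG_COLUMNS)
    dropped = [c for c in flag_cols if df[c].nunique() <= 1]
    if dropped:
        warnings.warn(
            f"constant mutation flags dropped from the design: {dropped}"
        )
        flag_cols = [c for c in flag_cols if c not in dropped]
    n_params = len(flag_cols) + 2
    if n < n_params + 2:
        raise ValueError(
            f"complete-case n = {n} too small for {n_params}-parameter fit"
        )
    if df["predictor"].nunique() <= 1:
        raise ValueError("predictor has zero variance in complete cases")
    X = sm.add_constant(df[flag_cols + ["predictor"]])
    res = sm.OLS(df["y"], X).fit()
    return ConditionalFit(
        predictor_coef=float(res.params["predictor"]),
        predictor_p=float(res.pvalues["predictor"]),
        flag_coefs={c: float(res.params[c]) for c in flag_cols},
        flag_ps={c: float(res.pvalues[c]) for c in flag_cols},
        n=n,
        dropped_flags=dropped,
    )


def conditional_screen(
    candidates: dict[str, pd.Series],
    log_ic50: pd.Series,
    flags: pd.DataFrame,
) -> pd.DataFrame:
    """Fit every candidate predictor and BH-adjust predictor p-values.

    ``candidates`` maps predictor id -> value series (expression or
    methylation). The BH family is the candidate set itself; mutation-flag
    p-values are reported raw, as in the source analysis.
    """
    rows = []
    for pid, values in candidates.items():
        fit = fit_conditional(log_ic50, values, flags)
        row = {
            "predictor": pid,
            "coef": fit.predictor_coef,
            "p_raw": fit.predictor_p,
            "n": fit.n,
        }
        for c in FLAG_COLUMNS:
            row[f"{c}_coef"] = fit.flag_coefs.get(c, np.nan)
            row[f"{c}_p"] = fit.flag_ps.get(c, np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = bh_adjust(out["p_raw"].to_numpy(), len(out))
    else:
        out["p_fdr"] = pd.Series(dtype=float)
    return out
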