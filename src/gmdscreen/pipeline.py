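"""Orchestration of the three screening analyses.

1. direct screen: GMD expression vs log10(IC50) per agent;
2. two-stage indirect screen: (stage 1) GMD expression vs probe-level and
   gene-region methylation, (stage 2) methylation of the unique stage-1
   targets vs drug response;
3. epigenome-average screens: per-sample mean methylation vs GMD expression
   and vs drug response.

Each analysis runs pancancer and within every cancer category holding at
least ``min_category`` cell lines. Probe-level stage-1 selection uses fixed
raw-p thresholds derived from 1e-6 divided by the number of GMDs (and by the
number of stratified categories for within-category runs); every other
selection uses BH-FDR over an explicitly counted family. Stratified records
are, by default, adjusted in one family spanning all strata via a
multiplicity factor equal to the number of categories; a per-stratum family
mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .associations import (
    PANCANCER,
    DEFAULT_MIN_N,
    DEFAULT_MIN_CATEGORY,
    FdrFamily,
    Thresholds,
    annotate_relations,
    bh_adjust,
    correlate_tables,
    stratify,
)

# study-default derived constants (printed to 4 significant digits)
STUDY_N_GMDS = 72
STUDY_N_CATEGORIES = 23
STUDY_PANCANCER_PROBE_P = 1.389e-8
STUDY_STRATIFIED_PROBE_P = 6.039e-10

__all__ = [
    "PipelineConfig",
    "StageOneTargets",
    "round_sig",
    "derive_probe_thresholds",
    "run_direct_screen",
    "run_stage1",
    "run_stage2",
    "run_average_methylation_screens",
]


def round_sig(x: float, digits: int = 4) -> float:
    """Round to ``digits`` significant digits."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


def derive_probe_thresholds(
    n_gmds: int = STUDY_N_GMDS, n_categories: int = STUDY_N_CATEGORIES
) -> tuple[float, float]:
    """Fixed raw-p cuts for the probe-level stage-1 screen.

    Pancancer: 1e-6 (single-gene epigenome-wide recommendation for the 450K
    array) divided by the number of GMDs; stratified: the pancancer cut
    further divided by the number of cancer categories. Both rounded to four
    significant digits — with the study defaults (72 GMDs, 23 categories)
    these are 1.389e-8 and 6.039e-10.
    """
    pancancer = round_sig(1e-6 / n_gmds, 4)
    stratified = round_sig(pancancer / n_categories, 4)
    return pancancer, stratified


@dataclass
class PipelineConfig:
    """Thresholds and family accounting for one pipeline run."""

    min_n: int = DEFAULT_MIN_N
    min_category: int = DEFAULT_MIN_CATEGORY
    fdr_mode: str = "pooled_times_k"  # or "per_stratum"
    abs_rho_strong: float = 0.5
    abs_rho_relaxed: float = 0.4
    abs_rho_modest: float = 0.3
    fdr_cut: float = 0.05
    fdr_cut_relaxed: float = 0.15  # epigenome-average reporting tier
    n_gmds_for_threshold: int | None = None  # default: actual GMD count
    n_categories_for_threshold: int | None = None  # default: eligible strata

    def __post_init__(self) -> None:
        if self.fdr_mode not in ("pooled_times_k", "per_stratum"):
            raise ValueError(f"unknown fdr_mode {self.fdr_mode!r}")


@dataclass
class StageOneTargets:
    """Stage-1 output: flagged probe/region records plus unique target ids."""

    probe_records: pd.DataFrame
    region_records: pd.DataFrame

    @property
    def probe_targets(self) -> list[str]:
        mask = self.probe_records["significant_strong"].astype(bool)
        return sorted(self.probe_records.loc[mask, "target"].unique())

    @property
    def region_targets(self) -> list[str]:
        mask = self.region_records["significant_strong"].astype(bool)
        return sorted(self.region_records.loc[mask, "target"].unique())

    def is_empty(self) -> bool:
        return not self.probe_targets and not self.region_targets


def _screen_all_strata(
    predictors: pd.DataFrame,
    targets: pd.DataFrame,
    category_map: pd.Series,
    cfg: PipelineConfig,
    per_pair_tests: int,
) -> tuple[pd.DataFrame, list[str]]:
    """Correlate across all strata and BH-adjust with the configured family.

    Pancancer records form their own family of ``per_pair_tests``; stratified
    records form either one pooled family of ``per_pair_tests * n_strata``
    (default) or one family of ``per_pair_tests`` per stratum.
    """
    strata = stratify(category_map, cfg.min_category)
    stratum_names = [s for s, _ in strata]
    chunks = []
    for name, sample_ids in strata:
        chunks.append(
            correlate_tables(predictors, targets, sample_ids, name, cfg.min_n)
        )
    records = pd.concat(chunks, ignore_index=True)
    n_strat = len(stratum_names) - 1

    pan = records["stratum"] == PANCANCER
    out = records.copy()
    out["p_fdr"] = np.nan
    out.loc[pan, "p_fdr"] = bh_adjust(
        records.loc[pan, "p_raw"].to_numpy(), per_pair_tests
    )
    if n_strat:
        if cfg.fdr_mode == "pooled_times_k":
            out.loc[~pan, "p_fdr"] = bh_adjust(
                records.loc[~pan, "p_raw"].to_numpy(), per_pair_tests * n_strat
            )
        else:
            for name in stratum_names[1:]:
                sel = records["stratum"] == name
                out.loc[sel, "p_fdr"] = bh_adjust(
                    records.loc[sel, "p_raw"].to_numpy(), per_pair_tests
                )
    return out, stratum_names


def _flag(records: pd.DataFrame, p_col: str, p_cut, rho_cut: float) -> pd.Series:
    """p_cut may be a scalar or a per-row Series (per-stratum probe cuts)."""
    ok = (records[p_col] < p_cut) & (records["rho"].abs() > rho_cut)
    return ok.fillna(False)


def run_direct_screen(
    expression: pd.DataFrame,
    drug: pd.DataFrame,
    category_map: pd.Series,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """GMD expression vs log10(IC50), all strata.

    Family: agents x GMDs (x strata). ``significant_strong`` flags
    p_FDR < 0.05 with |rho| > 0.5; relaxed tiers at |rho| > 0.4 and > 0.3
    are carried as extra flag columns. Negative rho with log(IC50) means
    higher expression tracks drug sensitivity.
    """
    cfg = cfg or PipelineConfig()
    per_pair = len(drug.index) * len(expression.index)
    records, _ = _screen_all_strata(expression, drug, category_map, cfg, per_pair)
    records["relation"] = "not_applicable"
    records["significant_strong"] = _flag(records, "p_fdr", cfg.fdr_cut,
                                          cfg.abs_rho_strong)
    records["significant_relaxed"] = _flag(records, "p_fdr", cfg.fdr_cut,
                                           cfg.abs_rho_relaxed)
    records["significant_modest"] = _flag(records, "p_fdr", cfg.fdr_cut,
                                          cfg.abs_rho_modest)
    return records


def run_stage1(
    expression: pd.DataFrame,
    beta,
    region_methylation,
    annotation,
    category_map: pd.Series,
    cfg: PipelineConfig | None = None,
) -> StageOneTargets:
    """GMD expression vs probe and gene-region methylation, all strata.

    Probe records are selected on fixed raw-p cuts (1e-6 / n_GMDs pancancer,
    further / n_categories stratified) with |rho| > 0.5; region records on
    p_FDR < 0.05 (family: GMDs x regions [x strata]) with |rho| > 0.5.
    cis/trans is recorded for every entry.
    """
    cfg = cfg or PipelineConfig()
    n_gmds = cfg.n_gmds_for_threshold or len(expression.index)
    strata = stratify(category_map, cfg.min_category)
    n_cats = cfg.n_categories_for_threshold or max(len(strata) - 1, 1)
    pan_cut, strat_cut = derive_probe_thresholds(n_gmds, n_cats)

    beta_df = beta.beta if hasattr(beta, "beta") else beta
    per_pair_probe = len(expression.index) * len(beta_df.index)
    probe_records, _ = _screen_all_strata(
        expression, beta_df, category_map, cfg, per_pair_probe
    )
    cuts = probe_records["stratum"].map(
        lambda s: pan_cut if s == PANCANCER else strat_cut
    )
    probe_records["significant_strong"] = _flag(
        probe_records, "p_raw", cuts, cfg.abs_rho_strong
    )
    probe_records = annotate_relations(probe_records, annotation)

    region_df = (
        region_methylation.values
        if hasattr(region_methylation, "values") and not isinstance(region_methylation, pd.DataFrame)
        else region_methylation
    )
    per_pair_region = len(expression.index) * len(region_df.index)
    region_records, _ = _screen_all_strata(
        expression, region_df, category_map, cfg, per_pair_region
    )
    region_records["significant_strong"] = _flag(
        region_records, "p_fdr", cfg.fdr_cut, cfg.abs_rho_strong
    )
    region_records = annotate_relations(region_records, annotation)
    return StageOneTargets(probe_records, region_records)


def run_stage2(
    stage1: StageOneTargets,
    beta,
    region_methylation,
    drug: pd.DataFrame,
    category_map: pd.Series,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Methylation of unique stage-1 targets vs drug response, all strata.

    A target selected via several GMDs or strata enters once. Probe and
    region targets form separate FDR families (agents x n_targets
    [x strata]). Flags at |rho| > 0.5 plus a relaxed |rho| > 0.4 tier.
    """
    cfg = cfg or PipelineConfig()
    if stage1.is_empty():
        return pd.DataFrame(
            columns=["predictor", "target", "stratum", "rho", "p_raw", "p_fdr",
                     "n", "relation", "significant_strong", "significant_relaxed",
                     "target_kind"]
        )
    beta_df = beta.beta if hasattr(beta, "beta") else beta
    region_df = (
        region_methylation.values
        if hasattr(region_methylation, "values") and not isinstance(region_methylation, pd.DataFrame)
        else region_methylation
    )
    chunks = []
    for kind, table, targets in (
        ("probe", beta_df, stage1.probe_targets),
        ("region", region_df, stage1.region_targets),
    ):
        if not targets:
            continue
        per_pair = len(drug.index) * len(targets)
        recs, _ = _screen_all_strata(
            table.loc[targets], drug, category_map, cfg, per_pair
        )
        recs["target_kind"] = kind
        chunks.append(recs)
    records = pd.concat(chunks, ignore_index=True)
    records["relation"] = "not_applicable"
    records["significant_strong"] = _flag(records, "p_fdr", cfg.fdr_cut,
                                          cfg.abs_rho_strong)
    records["significant_relaxed"] = _flag(records, "p_fdr", cfg.fdr_cut,
                                           cfg.abs_rho_relaxed)
    return records


def run_average_methylation_screens(
    epi_mean: pd.Series,
    expression: pd.DataFrame,
    drug: pd.DataFrame,
    category_map: pd.Series,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Epigenome-average methylation vs GMD expression and vs drug response.

    Returns two record sets, each FDR-adjusted (families: n_GMDs [x strata]
    and n_agents [x strata]) with reporting tiers at p_FDR < 0.05 and < 0.15.
    """
    cfg = cfg or PipelineConfig()
    epi = epi_mean.to_frame().T
    epi.index = pd.Index(["epigenome_mean"])

    expr_recs, _ = _screen_all_strata(
        expression, epi, category_map, cfg, len(expression.index)
    )
    drug_recs, _ = _screen_all_strata(
        epi, drug, category_map, cfg, len(drug.index)
    )
    for recs in (expr_recs, drug_recs):
        recs["relation"] = "not_applicable"
        recs["significant_strong"] = (recs["p_fdr"] < cfg.fdr_cut).fillna(False)
        recs["significant_relaxed"] = (
            recs["p_fdr"] < cfg.fdr_cut_relaxed
        ).fillna(False)
    return expr_recs, drug_recs
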