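"""Synthetic cell-line panel generator with a ground-truth ledger.

Emulates the statistical structure of a pharmaco-epigenomic cell line panel:
RPKM-like expression for a set of genes affecting DNA methylation or
demethylation (GMDs), 450K-style beta-values with region-correlated probes
and bimodal distributions (upstream regions skewed unmethylated, gene body
skewed methylated), per-measurement detection p-values with planted
failures, a SNP-overlap probe mask, log10(IC50) drug response with
dataset-of-origin agent suffixes, a BRAF/KRAS/NRAS mutation table, and a
cancer-category map.

Correlated pairs are planted on a latent-Gaussian copula: all observables
are strictly monotone maps of latent normals, so a latent Pearson
correlation r = 2 sin(pi * rho / 6) yields a population Spearman correlation
of rho between the observables, controllable analytically. Realized
correlations are recorded per effect in the ledger after generation.

A single integer seed feeds hierarchical per-table streams, so each table is
stable when unrelated tables' sizes change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .associations import PANCANCER, spearman
from .qc import BetaMatrix
from .regions import REGION_CATEGORIES, ProbeAnnotation, region_id, split_region_id

EPIGENOME = "epigenome"

EFFECT_KINDS = (
    "expr_meth_trans",
    "expr_meth_cis",
    "meth_drug",
    "expr_drug",
    "mutation_drug",
    "epigenome_average",
)

# logistic intercept per region category: upstream regions skew unmethylated,
# gene body / 3'UTR skew methylated (bimodality from the intercept spread)
_CATEGORY_INTERCEPT = {
    "TSS1500": -2.2,
    "TSS200": -2.8,
    "5'UTR": -2.0,
    "1stExon": -1.8,
    "Body": 1.6,
    "3'UTR": 1.2,
    None: 0.3,  # intergenic
}
_INTERCEPT_SPREAD = 1.4
_LATENT_SLOPE = 1.5
_GLOBAL_MIX = 0.2  # variance share of the epigenome-wide latent, when present

__all__ = [
    "PlantedEffect",
    "PanelConfig",
    "GroundTruthLedger",
    "SyntheticPanel",
    "generate_panel",
    "write_panel",
    "simulate_conditional_scenario",
]


def _latent_r(rho: float) -> float:
    """Latent Pearson r giving population Spearman rho after monotone maps."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


@dataclass
class PlantedEffect:
    """One planted association between a source and a target observable.

    ``rho_target`` is the intended Spearman correlation (within ``stratum``);
    for ``mutation_drug`` the effect is an additive log10(IC50) ``shift`` in
    mutation-flagged lines (|shift| defaults to 1.0, sign from rho_target).
    """

    kind: str
    source_id: str
    target_id: str
    rho_target: float = 0.0
    stratum: str = PANCANCER
    shift: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if not -1.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must lie in [-1, 1]")
        if self.kind == "expr_meth_trans" and self.source_id == self.target_id:
            raise ValueError("trans effect requires source != target")


@dataclass
class PanelConfig:
    """Shape, noise and planted structure of a synthetic panel.

    Defaults are scaled roughly one order of magnitude down from a
    645-line / 485k-probe study panel so a full generate-and-screen cycle
    runs in seconds.
    """

    n_cell_lines: int = 200
    n_cancer_categories: int = 4
    category_sizes: list[int] | None = None
    n_gmds: int = 8
    n_target_genes: int = 60
    probes_per_region: int = 3
    n_agents: int = 12
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    detection_fail_rate: float = 0.01
    snp_masked_fraction: float = 0.05
    seed: int = 0
    # shape/noise knobs beyond the study's stated structure
    region_correlation: float = 0.5
    intergenic_fraction: float = 0.05
    drug_missing_rate: float = 0.05
    mutation_rate: float = 0.15
    n_failing_probes: int = 0
    n_snp_masked: int | None = None

    def __post_init__(self) -> None:
        if self.category_sizes is None:
            base, extra = divmod(self.n_cell_lines, self.n_cancer_categories)
            self.category_sizes = [
                base + (1 if i < extra else 0)
                for i in range(self.n_cancer_categories)
            ]
        self.validate()

    def validate(self) -> None:
        if sum(self.category_sizes) != self.n_cell_lines:
            raise ValueError("category_sizes must sum to n_cell_lines")
        for name in ("n_cell_lines", "n_gmds", "n_target_genes",
                     "probes_per_region", "n_agents"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("detection_fail_rate", "snp_masked_fraction",
                     "region_correlation", "intergenic_fraction",
                     "drug_missing_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        sizes = dict(zip(self._category_labels(), self.category_sizes))
        for eff in self.planted_effects:
            if eff.stratum != PANCANCER:
                if sizes.get(eff.stratum, 0) < 2:
                    raise ValueError(
                        f"effect stratum {eff.stratum!r} has fewer than 2 lines"
                    )

    def _category_labels(self) -> list[str]:
        return [f"CAT{i + 1:02d}" for i in range(len(self.category_sizes))]


@dataclass
class GroundTruthLedger:
    """Planted effects with realized correlations, plus null-pair accounting."""

    effects: list[dict]
    null_pair_counts: dict[str, int]

    def is_planted(self, source_id: str, target_id: str) -> bool:
        return any(
            e["source_id"] == source_id and e["target_id"] == target_id
            for e in self.effects
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"effects": self.effects, "null_pair_counts": self.null_pair_counts},
                fh,
                indent=2,
            )
            fh.write("\n")


@dataclass
class SyntheticPanel:
    expression: pd.DataFrame          # genes x samples, RPKM-like
    beta: BetaMatrix                  # probes x samples with detection p
    drug: pd.DataFrame                # agents x samples, log10(IC50), NaN = missing
    mutations: pd.DataFrame           # sample_id, gene_symbol, protein_change, variant_class
    categories: pd.Series             # sample id -> cancer category
    annotation: ProbeAnnotation
    snp_mask: list[str]
    ledger: GroundTruthLedger
    config: PanelConfig


def _build_annotation(cfg: PanelConfig, rng: np.random.Generator):
    """Gene/region/probe layout plus genomic coordinates."""
    gmds = [f"GMD{i + 1:02d}" for i in range(cfg.n_gmds)]
    targets = [f"TG{i + 1:03d}" for i in range(cfg.n_target_genes)]
    gene_regions: dict[str, list[str]] = {}
    for g in gmds:
        # GMDs always carry upstream regions (cis planting) and a body
        gene_regions[g] = ["TSS1500", "TSS200", "5'UTR", "Body"]
    for g in targets:
        k = int(rng.integers(2, 7))
        cats = list(rng.choice(REGION_CATEGORIES, size=k, replace=False))
        gene_regions[g] = sorted(cats, key=REGION_CATEGORIES.index)

    rows = []
    probe_region: dict[str, str | None] = {}  # probe -> region id (None = intergenic)
    counter = 0
    for g, cats in gene_regions.items():
        chrom = str(rng.integers(1, 23))
        base = int(rng.integers(1_000_000, 200_000_000))
        band = f"{chrom}{'pq'[int(rng.integers(2))]}{rng.integers(11, 36)}"
        for ci, cat in enumerate(cats):
            for k in range(cfg.probes_per_region):
                counter += 1
                pid = f"cg{counter:08d}"
                rows.append(
                    (pid, chrom, base + ci * 2000 + k * 120, band, g, cat)
                )
                probe_region[pid] = region_id(g, cat)
    n_gene_probes = counter
    n_intergenic = max(1, round(cfg.intergenic_fraction * n_gene_probes))
    for _ in range(n_intergenic):
        counter += 1
        pid = f"cg{counter:08d}"
        chrom = str(rng.integers(1, 23))
        band = f"{chrom}{'pq'[int(rng.integers(2))]}{rng.integers(11, 36)}"
        rows.append((pid, chrom, int(rng.integers(1, 2.4e8)), band, "", ""))
        probe_region[pid] = None
    table = pd.DataFrame(
        rows,
        columns=["probe_id", "chromosome", "position", "cytoband",
                 "gene_symbols", "region_categories"],
    )
    return gmds, targets, gene_regions, ProbeAnnotation(table), probe_region


def _stratum_mask(cfg: PanelConfig, categories: pd.Series, stratum: str) -> np.ndarray:
    if stratum == PANCANCER:
        return np.ones(len(categories), dtype=bool)
    return (categories == stratum).to_numpy()


def _plant(
    source: np.ndarray, noise: np.ndarray, rho: float, mask: np.ndarray
) -> np.ndarray:
    """Mix a source latent into fresh noise on masked samples only."""
    r = _latent_r(rho)
    out = noise.copy()
    out[mask] = r * source[mask] + np.sqrt(1.0 - r * r) * noise[mask]
    return out


def generate_panel(config: PanelConfig) -> SyntheticPanel:
    """Generate a full panel plus ground-truth ledger.

    Deterministic per seed; per-table RNG streams are spawned hierarchically
    from ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (s_struct, s_expr, s_meth, s_drug, s_mut, s_det) = [
        np.random.default_rng(child) for child in ss.spawn(6)
    ]

    n = config.n_cell_lines
    samples = [f"CL{i + 1:04d}" for i in range(n)]
    labels = config._category_labels()
    categories = pd.Series(
        np.repeat(labels, config.category_sizes), index=samples, name="category"
    )

    gmds, targets, gene_regions, annotation, probe_region = _build_annotation(
        config, s_struct
    )
    probes = list(annotation.probe_ids)
    region_ids = sorted(
        {rid for rid in probe_region.values() if rid is not None}
    )

    effects = config.planted_effects
    by_kind = lambda *kinds: [e for e in effects if e.kind in kinds]

    # --- expression latents -------------------------------------------------
    z = {g: s_expr.standard_normal(n) for g in gmds}
    mu_expr = {g: s_expr.normal(1.5, 1.0) for g in gmds}
    expression = pd.DataFrame(
        {g: np.exp(mu_expr[g] + z[g]) for g in gmds}, index=samples
    ).T
    expression.index.name = "gene_symbol"

    # --- methylation latents ------------------------------------------------
    region_latent = {rid: s_meth.standard_normal(n) for rid in region_ids}
    planted_regions: set[str] = set()
    for eff in by_kind("expr_meth_cis", "expr_meth_trans"):
        if "|" not in eff.target_id:
            continue
        src = z[eff.source_id]
        mask = _stratum_mask(config, categories, eff.stratum)
        region_latent[eff.target_id] = _plant(
            src, region_latent[eff.target_id], eff.rho_target, mask
        )
        planted_regions.add(eff.target_id)

    w = config.region_correlation
    probe_latent: dict[str, np.ndarray] = {}
    for pid in probes:
        rid = probe_region[pid]
        eps = s_meth.standard_normal(n)
        if rid is None:
            probe_latent[pid] = eps
        elif rid in planted_regions:
            # planted regions share one latent so the region average carries
            # exactly the planted Spearman correlation
            probe_latent[pid] = region_latent[rid]
        else:
            probe_latent[pid] = (
                np.sqrt(w) * region_latent[rid] + np.sqrt(1.0 - w) * eps
            )
    for eff in by_kind("expr_meth_trans"):
        if "|" in eff.target_id:
            continue
        mask = _stratum_mask(config, categories, eff.stratum)
        probe_latent[eff.target_id] = _plant(
            z[eff.source_id], probe_latent[eff.target_id], eff.rho_target, mask
        )

    # epigenome-wide latent, mixed into unplanted probes when referenced
    epi_effects = by_kind("epigenome_average")
    needs_epi = bool(epi_effects) or any(
        e.source_id == EPIGENOME for e in by_kind("meth_drug")
    )
    global_latent = None
    if needs_epi:
        global_latent = s_meth.standard_normal(n)
        for eff in epi_effects:
            mask = _stratum_mask(config, categories, eff.stratum)
            global_latent = _plant(
                z[eff.source_id], global_latent, eff.rho_target, mask
            )
        directly_planted = {
            e.target_id for e in by_kind("expr_meth_trans") if "|" not in e.target_id
        }
        for pid in probes:
            rid = probe_region[pid]
            if pid in directly_planted or (rid is not None and rid in planted_regions):
                continue
            probe_latent[pid] = (
                np.sqrt(_GLOBAL_MIX) * global_latent
                + np.sqrt(1.0 - _GLOBAL_MIX) * probe_latent[pid]
            )

    # --- betas via logistic squash -----------------------------------------
    beta_rows = np.empty((len(probes), n))
    for i, pid in enumerate(probes):
        rid = probe_region[pid]
        cat = None if rid is None else split_region_id(rid)[1]
        a = _CATEGORY_INTERCEPT[cat] + _INTERCEPT_SPREAD * s_meth.standard_normal()
        beta_rows[i] = 1.0 / (1.0 + np.exp(-(a + _LATENT_SLOPE * probe_latent[pid])))
    beta_df = pd.DataFrame(beta_rows, index=pd.Index(probes, name="probe_id"),
                           columns=samples)

    # --- detection p-values -------------------------------------------------
    # passing probes sit far below both detection cuts (1e-3 entry, 1e-6 median)
    detp = 10.0 ** (-s_det.uniform(8.0, 16.0, size=beta_rows.shape))
    fail = s_det.random(beta_rows.shape) < config.detection_fail_rate
    detp[fail] = 10.0 ** (-s_det.uniform(0.0, 3.0, size=int(fail.sum())))
    probe_set = set(probes)
    effect_probes: set[str] = set()
    for e in effects:
        for ident in (e.source_id, e.target_id):
            if ident in probe_set:
                effect_probes.add(ident)
            elif "|" in ident:
                effect_probes.update(
                    p for p, rid in probe_region.items() if rid == ident
                )
    candidates = [p for p in probes if p not in effect_probes]
    if config.n_failing_probes > len(candidates):
        raise ValueError("not enough non-effect probes to plant failures")
    failing = list(
        s_det.choice(candidates, size=config.n_failing_probes, replace=False)
    )
    for pid in failing:
        i = probes.index(pid)
        detp[i] = 10.0 ** (-s_det.uniform(0.0, 5.0, size=n))
    detp_df = pd.DataFrame(detp, index=beta_df.index, columns=samples)
    beta = BetaMatrix(beta_df, detp_df)

    # --- SNP mask ------------------------------------------------------------
    n_mask = (
        config.n_snp_masked
        if config.n_snp_masked is not None
        else round(config.snp_masked_fraction * len(probes))
    )
    maskable = [p for p in candidates if p not in failing]
    if n_mask > len(maskable):
        raise ValueError("not enough non-effect probes to SNP-mask")
    snp_mask = sorted(s_det.choice(maskable, size=n_mask, replace=False))

    # --- drug response -------------------------------------------------------
    agents = [f"AGENT{i + 1:02d}@GDSC" for i in range(config.n_agents)]
    d_latent = {a: s_drug.standard_normal(n) for a in agents}
    for eff in by_kind("expr_drug"):
        mask = _stratum_mask(config, categories, eff.stratum)
        d_latent[eff.target_id] = _plant(
            z[eff.source_id], d_latent[eff.target_id], eff.rho_target, mask
        )
    for eff in by_kind("meth_drug"):
        if eff.source_id == EPIGENOME:
            src = global_latent
        elif "|" in eff.source_id:
            src = region_latent[eff.source_id]
        else:
            src = probe_latent[eff.source_id]
        mask = _stratum_mask(config, categories, eff.stratum)
        d_latent[eff.target_id] = _plant(
            src, d_latent[eff.target_id], eff.rho_target, mask
        )
    drug_rows = {}
    for a in agents:
        mu_a = s_drug.normal(-1.0, 1.0)
        vals = mu_a + 1.2 * d_latent[a]
        miss = s_drug.random(n) < config.drug_missing_rate
        vals = np.where(miss, np.nan, vals)
        drug_rows[a] = vals
    drug = pd.DataFrame(drug_rows, index=samples).T
    drug.index.name = "agent_id"

    # --- mutations -----------------------------------------------------------
    mut_rows: list[tuple[str, str, str, str]] = []
    flagged: dict[str, np.ndarray] = {}
    for eff in by_kind("mutation_drug"):
        gene = eff.source_id
        flag = s_mut.random(n) < config.mutation_rate
        while not flag.any():  # a planted effect needs at least one carrier
            flag = s_mut.random(n) < config.mutation_rate
        flagged[gene] = flag
        change = "V600E" if gene == "BRAF" else "G12D"
        for si, hit in enumerate(flag):
            if hit:
                mut_rows.append((samples[si], gene, change, "non_synonymous"))
        shift = eff.shift if eff.shift is not None else float(np.sign(eff.rho_target) or 1.0)
        vals = drug.loc[eff.target_id].to_numpy()
        drug.loc[eff.target_id] = vals + shift * flag
    for gene, nonsyn_change in (("BRAF", "G469A"), ("KRAS", "A146T"), ("NRAS", "Q61K")):
        syn = s_mut.random(n) < 0.04
        nonsyn = (s_mut.random(n) < 0.06) & ~flagged.get(gene, np.zeros(n, bool))
        for si in range(n):
            if syn[si]:
                mut_rows.append((samples[si], gene, "L441L", "synonymous"))
            if nonsyn[si]:
                # background BRAF protein changes are non-V600E by construction
                mut_rows.append((samples[si], gene, nonsyn_change, "non_synonymous"))
    mutations = pd.DataFrame(
        mut_rows,
        columns=["sample_id", "gene_symbol", "protein_change", "variant_class"],
    )

    # --- ledger with realized correlations -----------------------------------
    ledger = _build_ledger(
        config, effects, expression, beta_df, drug, categories,
        probe_region, flagged, samples,
    )

    return SyntheticPanel(
        expression=expression,
        beta=beta,
        drug=drug,
        mutations=mutations,
        categories=categories,
        annotation=annotation,
        snp_mask=list(snp_mask),
        ledger=ledger,
        config=config,
    )


def _build_ledger(
    config, effects, expression, beta_df, drug, categories,
    probe_region, flagged, samples,
) -> GroundTruthLedger:
    def observable(eff: PlantedEffect, which: str) -> np.ndarray:
        ident = eff.source_id if which == "source" else eff.target_id
        if eff.kind in ("expr_meth_trans", "expr_meth_cis", "expr_drug",
                        "epigenome_average") and which == "source":
            return expression.loc[ident].to_numpy()
        if eff.kind == "mutation_drug" and which == "source":
            return flagged[ident].astype(float)
        if eff.kind == "meth_drug" and which == "source":
            if ident == EPIGENOME:
                return beta_df.mean(axis=0).to_numpy()
            return _meth_values(ident)
        if eff.kind in ("expr_meth_trans", "expr_meth_cis") and which == "target":
            return _meth_values(ident)
        if eff.kind == "epigenome_average" and which == "target":
            return beta_df.mean(axis=0).to_numpy()
        return drug.loc[ident].to_numpy()

    def _meth_values(ident: str) -> np.ndarray:
        if "|" in ident:
            members = [p for p, rid in probe_region.items() if rid == ident]
            return beta_df.loc[members].mean(axis=0).to_numpy()
        return beta_df.loc[ident].to_numpy()

    recorded = []
    for eff in effects:
        mask = _stratum_mask(config, categories, eff.stratum)
        rho, _, n_used = spearman(
            observable(eff, "source")[mask], observable(eff, "target")[mask],
            min_n=3,
        )
        entry = asdict(eff)
        entry["realized_rho"] = None if np.isnan(rho) else round(float(rho), 6)
        entry["n"] = n_used
        recorded.append(entry)

    n_probes = len(probe_region)
    n_regions = len({r for r in probe_region.values() if r is not None})
    counts = {
        "gmd_probe": config.n_gmds * n_probes,
        "gmd_region": config.n_gmds * n_regions,
        "gmd_agent": config.n_gmds * config.n_agents,
        "probe_agent": n_probes * config.n_agents,
        "region_agent": n_regions * config.n_agents,
    }
    planted = {(e["source_id"], e["target_id"]) for e in recorded}
    counts = {k: v for k, v in counts.items()}
    counts["planted"] = len(planted)
    return GroundTruthLedger(effects=recorded, null_pair_counts=counts)


# ---------------------------------------------------------------------------
# file output

PANEL_FILES = {
    "expression": "expression.tsv",
    "beta": "beta.tsv",
    "detection_p": "detection_p.tsv",
    "annotation": "annotation.csv",
    "snp_mask": "snp_mask.txt",
    "drug": "drug_response.tsv",
    "mutations": "mutations.tsv",
    "categories": "categories.tsv",
    "ledger": "ground_truth.json",
    "config": "panel_config.yaml",
}


def write_panel(panel: SyntheticPanel, directory, overwrite: bool = False) -> dict:
    """Write all panel tables in the formats the readers consume.

    Same seed -> byte-identical files; a read-back reproduces the matrices
    bit-exactly (floats are written with shortest round-trip repr).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in PANEL_FILES.items()}
    if not overwrite:
        clashes = [str(p) for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(
                f"refusing to overwrite existing files: {clashes}"
            )
    panel.expression.to_csv(paths["expression"], sep="\t")
    panel.beta.beta.to_csv(paths["beta"], sep="\t")
    if panel.beta.detection_p is not None:
        panel.beta.detection_p.to_csv(paths["detection_p"], sep="\t")
    panel.annotation.table.to_csv(paths["annotation"], index=False)
    paths["snp_mask"].write_text("".join(f"{p}\n" for p in panel.snp_mask))
    long = (
        panel.drug.stack(future_stack=True)
        .rename("log_ic50")
        .rename_axis(["agent_id", "sample_id"])
        .reset_index()
        .dropna(subset=["log_ic50"])
    )
    long.to_csv(paths["drug"], sep="\t", index=False)
    panel.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    panel.categories.rename_axis("sample_id").reset_index().to_csv(
        paths["categories"], sep="\t", index=False
    )
    panel.ledger.to_json(paths["ledger"])
    cfg = asdict(panel.config)
    cfg["planted_effects"] = [asdict(e) for e in panel.config.planted_effects]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# conditional-regression scenarios

def simulate_conditional_scenario(
    kind: str,
    n: int = 300,
    seed: int = 0,
    predictor_beta: float = 0.35,
    braf_shift: float = 1.2,
):
    """Trametinib-style response data for mutation-conditional regression.

    Returns ``(log_ic50, predictor, flags)`` where flags carry BRAF V600E
    and non-synonymous KRAS/NRAS indicators. Kinds:

    - ``"null"``: predictor independent of response given everything;
    - ``"mediated"``: the predictor tracks BRAF V600E status, so its marginal
      association with response vanishes once the flag enters the model;
    - ``"independent"``: the predictor shifts response by ``predictor_beta``
      response-SD per predictor-SD on top of the mutation effects.
    """
    if kind not in ("null", "mediated", "independent"):
        raise ValueError(f"unknown scenario kind {kind!r}")
    rng = np.random.default_rng(seed)
    samples = [f"CL{i + 1:04d}" for i in range(n)]
    flags = pd.DataFrame(
        {
            "braf_v600e": rng.random(n) < 0.20,
            "kras_ns": rng.random(n) < 0.15,
            "nras_ns": rng.random(n) < 0.08,
        },
        index=samples,
    )
    y = (
        braf_shift * flags["braf_v600e"].to_numpy()
        - 0.8 * flags["kras_ns"].to_numpy()
        - 0.5 * flags["nras_ns"].to_numpy()
        + rng.standard_normal(n)
    )
    if kind == "mediated":
        predictor = 1.5 * flags["braf_v600e"].to_numpy() + 0.5 * rng.standard_normal(n)
    else:
        predictor = rng.standard_normal(n)
        if kind == "independent":
            y = y + predictor_beta * predictor
    return (
        pd.Series(y, index=samples, name="log_ic50"),
        pd.Series(predictor, index=samples, name="predictor"),
        flags,
    )
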