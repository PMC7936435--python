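# gmdscreen

Correlation screens linking the expression of genes that write, read or
erase DNA methylation (GMDs — DNA methyltransferases, TET dioxygenases,
methyl-CpG binding proteins, and their cofactors) to epigenome-wide DNA
methylation and to drug response in cancer cell line panels.

The package is aimed at computational pharmaco-epigenomics: given an
RPKM-like expression matrix, a 450K-style methylation beta matrix with
detection p-values, a drug response table on the log10(IC50) scale, a
mutation table, and a cancer-category map for a panel of cell lines, it
runs three analyses, pancancer and within every cancer category holding at
least 10 lines:

1. **Direct screen** — Spearman correlation of each GMD's expression with
   each agent's log10(IC50), Benjamini–Hochberg FDR over the declared
   family of agents × GMDs (× categories), flagged at p_FDR < 0.05 with
   |ρ| > 0.5 (relaxed tiers at 0.4 and 0.3). Negative ρ means higher
   expression tracks drug sensitivity.
2. **Two-stage indirect screen** — stage 1 correlates GMD expression with
   methylation of individual probes (fixed raw-p cuts of 10⁻⁶/n_GMD
   pancancer and a further /n_categories within categories, |ρ| > 0.5) and
   with gene-region-averaged methylation (p_FDR < 0.05, |ρ| > 0.5),
   classifying each hit as *cis* (probe/region annotated to the GMD
   itself) or *trans*; stage 2 correlates methylation of the unique
   stage-1 targets with drug response.
3. **Epigenome-average screens** — per-sample mean beta over all
   QC-passing probes against GMD expression and against drug response,
   with reporting tiers at p_FDR < 0.05 and < 0.15.

Supporting stages implement 450K probe QC (masking betas with detection
p ≥ 10⁻³, dropping probes with median detection p ≥ 10⁻⁶, removing
SNP-overlap probes), gene-region beta averaging over the six manifest
region categories (TSS1500, TSS200, 5′UTR, 1st exon, gene body, 3′UTR),
and a mutation-conditional OLS regression that asks whether a predictor of
response (e.g. to a MEK inhibitor such as trametinib) survives adjustment
for BRAF V600E and non-synonymous KRAS/NRAS variants.

Because the real panels behind such studies are large externally hosted
resources, the package ships a first-class synthetic panel generator
(`gmdscreen.synthetic`) built on a latent-Gaussian copula: planted
expression↔methylation, methylation↔drug, expression↔drug, cis-repression,
mutation and epigenome-average effects achieve specified Spearman
correlations, and a ground-truth ledger records every planted pair with
its realized correlation, so every screening stage is testable end to end.

## Worked example

```python
from gmdscreen import qc, regions, pipeline
from gmdscreen.synthetic import PanelConfig, PlantedEffect, generate_panel

config = PanelConfig(
    n_cell_lines=600, n_cancer_categories=2, n_gmds=6, n_target_genes=25,
    seed=11,
    planted_effects=[
        PlantedEffect("expr_meth_trans", "GMD01", "cg00000300", 0.7),
        PlantedEffect("meth_drug", "cg00000300", "AGENT01@GDSC", -0.6),
    ],
)
panel = generate_panel(config)
beta, report = qc.run_qc(panel.beta, panel.snp_mask)
print(f"QC: {report.n_output_probes}/{report.n_input_probes} probes retained, "
      f"{report.n_betas_masked} betas masked")

index = regions.build_region_index(panel.annotation)
region_meth = regions.average_regions(beta, index)
print(f"{len(region_meth.values)} gene regions averaged")

s1 = pipeline.run_stage1(panel.expression, beta, region_meth,
                         panel.annotation, panel.categories)
print("stage-1 probe targets:", s1.probe_targets)

s2 = pipeline.run_stage2(s1, beta, region_meth, panel.drug, panel.categories)
strong = s2[s2.significant_strong & (s2.stratum == "pancancer")]
print(strong[["predictor", "target", "rho", "p_fdr", "n"]].to_string(index=False))
```

Output:

```
QC: 368/387 probes retained, 2313 betas masked
123 gene regions averaged
stage-1 probe targets: ['cg00000300']
 predictor       target       rho        p_fdr   n
cg00000300 AGENT01@GDSC -0.613011 3.252320e-58 562
```

The planted chain is recovered intact: GMD01's expression selects probe
cg00000300 in stage 1 (trans, ρ ≈ 0.7), and that probe's methylation
correlates with AGENT01's log10(IC50) at ρ ≈ −0.61 across 562 lines with
response data — increased methylation of the target tracks sensitivity to
the agent.

A command-line interface mirrors the library
(`gmdscreen simulate / qc / regions / direct / stage1 / stage2 / avgmeth /
all / report`); `gmdscreen all --config run.yaml` runs everything from a
YAML file naming the inputs and writes result tables plus a JSON run
manifest.

## Layout

| module | contents |
| --- | --- |
| `gmdscreen.synthetic` | panel generator, planted effects, ground-truth ledger |
| `gmdscreen.qc` | detection-p masking, probe drops, SNP-mask filtering |
| `gmdscreen.regions` | region index, region-averaged betas, epigenome mean |
| `gmdscreen.associations` | Spearman engine, explicit-count BH families, cis/trans, strata |
| `gmdscreen.pipeline` | the three orchestrated analyses and derived thresholds |
| `gmdscreen.conditional` | mutation flags and conditional OLS screen |
| `gmdscreen.io_report` | file formats, directional summaries, exports |

See `docs/methods.md` for the statistical model, parameter choices, and
known limitations.
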