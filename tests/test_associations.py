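"""Spearman engine, BH families, cis/trans calls, stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gmdscreen import associations as assoc
from gmdscreen.regions import ProbeAnnotation


class TestSpearman:
    def test_identity_and_reversal(self):
        x = np.arange(10, dtype=float)
        rho, p, n = assoc.spearman(x, x)
        assert rho == pytest.approx(1.0)
        rho, _, _ = assoc.spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)
        assert n == 10

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_with_ties_and_missing(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        x = np.round(rng.normal(size=n), 1)  # rounding forces ties
        y = np.round(rng.normal(size=n) + 0.5 * x, 1)
        x[rng.choice(n, 3, replace=False)] = np.nan
        rho, p, used = assoc.spearman(x, y)
        ok = ~(np.isnan(x) | np.isnan(y))
        ref_rho, ref_p = stats.spearmanr(x[ok], y[ok])
        assert used == ok.sum()
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        assert p == pytest.approx(ref_p, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, size=40)
        y = rng.normal(size=40)
        rho0, p0, _ = assoc.spearman(x, y)
        rho1, p1, _ = assoc.spearman(np.log(x), np.exp(y))
        assert rho1 == pytest.approx(rho0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_small_n_and_zero_variance_skipped(self):
        rho, p, n = assoc.spearman(np.arange(5.0), np.arange(5.0), min_n=10)
        assert np.isnan(rho) and n == 5
        rho, p, n = assoc.spearman(np.ones(20), np.arange(20.0))
        assert np.isnan(rho) and n == 20


class TestBhAdjust:
    def test_single_test_identity(self):
        assert assoc.bh_adjust([0.01], 1)[0] == pytest.approx(0.01)

    def test_step_up_by_hand(self):
        # min over j >= i of m * p(j) / j
        out = assoc.bh_adjust([0.01, 0.02, 0.03], 3)
        assert out.tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_padding_with_declared_count(self):
        assert assoc.bh_adjust([0.001], 100)[0] == pytest.approx(0.1)

    def test_declared_count_too_small_rejected(self):
        with pytest.raises(ValueError, match="test_count"):
            assoc.bh_adjust([0.1, 0.2], 1)

    def test_padding_equals_explicit_ones(self):
        rng = np.random.default_rng(8)
        p = rng.random(12)
        m = 40
        padded = np.concatenate([p, np.ones(m - len(p))])
        full = assoc.bh_adjust(padded, m)[: len(p)]
        assert np.allclose(assoc.bh_adjust(p, m), full, atol=1e-15)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_when_family_is_list(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 60))
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(assoc.bh_adjust(p, len(p)), ref, atol=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_p_rank(self, ps):
        adj = assoc.bh_adjust(ps, len(ps) + 5)
        order = np.argsort(ps, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert ((adj >= 0) & (adj <= 1)).all()


class TestScreen:
    def _tables(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        samples = [f"CL{i:04d}" for i in range(n)]
        A = pd.DataFrame(rng.normal(size=(3, n)), index=list("abc"), columns=samples)
        B = pd.DataFrame(rng.normal(size=(4, n)), index=list("wxyz"), columns=samples)
        return A, B, samples

    def test_symmetry(self):
        A, B, samples = self._tables()
        fam = assoc.FdrFamily("f", 12)
        th = assoc.Thresholds()
        fwd = assoc.screen(A, B, samples, "pancancer", th, fam)
        rev = assoc.screen(B, A, samples, "pancancer", th, fam)
        fwd_keyed = fwd.set_index(["predictor", "target"])
        for (p, t), row in rev.set_index(["target", "predictor"]).iterrows():
            assert fwd_keyed.loc[(p, t), "rho"] == pytest.approx(row["rho"])
            assert fwd_keyed.loc[(p, t), "p_raw"] == pytest.approx(row["p_raw"])

    def test_unattainable_rho_cut_empties_flags(self):
        A, B, samples = self._tables()
        th = assoc.Thresholds(p_mode="raw", p_cut=1.0, abs_rho_cut=1.1)
        out = assoc.screen(A, B, samples, "pancancer", th, assoc.FdrFamily("f", 12))
        assert not out["significant_strong"].any()

    def test_no_shared_samples_rejected(self):
        A, B, _ = self._tables()
        with pytest.raises(ValueError, match="shared"):
            assoc.screen(
                A, B, ["nope"], "pancancer", assoc.Thresholds(),
                assoc.FdrFamily("f", 12),
            )

    def test_planted_pair_flagged(self, chain_panel):
        th = assoc.Thresholds(p_mode="raw", p_cut=1.389e-8, abs_rho_cut=0.5)
        fam = assoc.FdrFamily(
            "gmd_probe",
            len(chain_panel.expression.index) * len(chain_panel.beta.probe_ids),
        )
        out = assoc.screen(
            chain_panel.expression,
            chain_panel.beta.beta,
            list(chain_panel.categories.index),
            "pancancer",
            th,
            fam,
        )
        hit = out[(out.predictor == "GMD01") & (out.target == "cg00000300")]
        assert hit["significant_strong"].all()


class TestCisTrans:
    @pytest.fixture
    def annotation(self):
        return ProbeAnnotation(
            pd.DataFrame(
                [
                    ("cg1", "10", 100, "10q26", "MGMT", "5'UTR"),
                    ("cg2", "1", 200, "1p13", "GENEB", "Body"),
                    ("cg3", "2", 300, "2q22", "", ""),
                ],
                columns=["probe_id", "chromosome", "position", "cytoband",
                         "gene_symbols", "region_categories"],
            )
        )

    def test_own_probe_is_cis(self, annotation):
        assert assoc.classify_cis_trans("cg1", "MGMT", annotation) == "cis"

    def test_other_gene_is_trans(self, annotation):
        assert assoc.classify_cis_trans("cg2", "MGMT", annotation) == "trans"

    def test_intergenic_is_trans(self, annotation):
        assert assoc.classify_cis_trans("cg3", "MGMT", annotation) == "trans"

    def test_region_ids(self, annotation):
        assert assoc.classify_cis_trans("MGMT|5'UTR", "MGMT", annotation) == "cis"
        assert assoc.classify_cis_trans("GENEB|Body", "MGMT", annotation) == "trans"


class TestStratify:
    def _map(self, sizes):
        labels, samples = [], []
        for i, k in enumerate(sizes):
            for j in range(k):
                labels.append(f"C{i}")
                samples.append(f"CL{i}_{j}")
        return pd.Series(labels, index=samples)

    def test_min_size_filter(self):
        strata = assoc.stratify(self._map([12, 9, 30]))
        assert [s for s, _ in strata] == ["pancancer", "C0", "C2"]
        assert len(strata[0][1]) == 51

    def test_all_small_leaves_pancancer_only(self):
        strata = assoc.stratify(self._map([5, 9, 3]))
        assert [s for s, _ in strata] == ["pancancer"]

    def test_study_shaped_category_count(self):
        strata = assoc.stratify(self._map([10] * 23 + [4]))
        assert len(strata) == 24


class TestEmpiricalFdr:
    def test_fdp_controlled_with_planted_effects(self):
        """5% planted pairs at rho=0.6, n=300: pooled false-discovery
        proportion at p_fdr < 0.05 stays below 0.10 over 20 seeds."""
        from gmdscreen.synthetic import PanelConfig, PlantedEffect, generate_panel

        shape = dict(
            n_cell_lines=300, n_cancer_categories=1, n_gmds=8,
            n_target_genes=40, probes_per_region=1,
        )
        false_disc, disc = 0, 0
        for seed in range(20):
            # probe layout depends only on the structure stream, so a
            # no-effect panel with the same seed exposes the probe ids
            probes = list(
                generate_panel(PanelConfig(seed=seed, **shape)).beta.probe_ids
            )
            rng = np.random.default_rng(1000 + seed)
            n_planted = round(0.05 * shape["n_gmds"] * len(probes))
            # one planted GMD partner per probe keeps pairs distinct
            chosen = rng.choice(probes, size=min(n_planted, len(probes)),
                                replace=False)
            effects = [
                PlantedEffect(
                    "expr_meth_trans", f"GMD{rng.integers(1, 9):02d}", p, 0.6
                )
                for p in chosen
            ]
            panel = generate_panel(
                PanelConfig(seed=seed, planted_effects=effects, **shape)
            )
            records = assoc.correlate_tables(
                panel.expression, panel.beta.beta,
                list(panel.categories.index), "pancancer",
            )
            records["p_fdr"] = assoc.bh_adjust(
                records["p_raw"].to_numpy(), len(records)
            )
            hits = records[records["p_fdr"] < 0.05]
            planted = {(e.source_id, e.target_id) for e in effects}
            for row in hits.itertuples(index=False):
                disc += 1
                if (row.predictor, row.target) not in planted:
                    false_disc += 1
        assert disc > 0
        assert false_disc / disc <= 0.10
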