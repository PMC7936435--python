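"""Region index construction, region averaging, epigenome means."""

import numpy as np
import pandas as pd
import pytest

from gmdscreen import regions
from gmdscreen.regions import ProbeAnnotation, build_region_index

from conftest import make_beta, random_beta_matrix


def annot(rows):
    return ProbeAnnotation(
        pd.DataFrame(
            rows,
            columns=["probe_id", "chromosome", "position", "cytoband",
                     "gene_symbols", "region_categories"],
        )
    )


class TestAnnotationParsing:
    def test_pairwise_expansion(self):
        ann = annot([("cg1", "1", 100, "1p11", "GENEA;GENEA", "TSS200;Body")])
        idx = build_region_index(ann)
        assert idx == {"GENEA|TSS200": ["cg1"], "GENEA|Body": ["cg1"]}

    def test_intergenic_probe_absent(self):
        ann = annot([("cg1", "1", 100, "1p11", "", "")])
        assert build_region_index(ann) == {}

    def test_duplicate_pairs_collapsed(self):
        ann = annot([("cg1", "1", 100, "1p11", "G;G", "Body;Body")])
        assert ann.gene_entries("cg1") == [("G", "Body")]

    def test_unpaired_lists_rejected(self):
        with pytest.raises(ValueError, match="cg1"):
            annot([("cg1", "1", 100, "1p11", "GENEA;GENEB", "TSS200")])

    def test_unknown_category_names_probe(self):
        with pytest.raises(ValueError, match="cg9.*SHELF"):
            annot([("cg9", "1", 100, "1p11", "GENEA", "SHELF")])

    def test_hand_built_index(self):
        rows = [
            ("cg01", "1", 1, "1p1", "A", "TSS1500"),
            ("cg02", "1", 2, "1p1", "A", "TSS1500"),
            ("cg03", "1", 3, "1p1", "A;B", "TSS200;Body"),
            ("cg04", "2", 4, "2q1", "B", "Body"),
            ("cg05", "2", 5, "2q1", "B", "3'UTR"),
            ("cg06", "3", 6, "3q2", "", ""),
            ("cg07", "3", 7, "3q2", "C", "5'UTR"),
            ("cg08", "3", 8, "3q2", "C", "1stExon"),
            ("cg09", "3", 9, "3q2", "C;C", "1stExon;1stExon"),
            ("cg10", "4", 10, "4p1", "A", "Body"),
        ]
        expected = {
            "A|TSS1500": ["cg01", "cg02"],
            "A|TSS200": ["cg03"],
            "A|Body": ["cg10"],
            "B|Body": ["cg03", "cg04"],
            "B|3'UTR": ["cg05"],
            "C|5'UTR": ["cg07"],
            "C|1stExon": ["cg08", "cg09"],
        }
        assert build_region_index(annot(rows)) == expected


class TestAverageRegions:
    def test_singleton_and_mean(self):
        bm = make_beta([[0.2, 0.25], [0.4, 0.45], [0.6, 0.65]])
        idx = {"G|Body": ["cg00000001", "cg00000002", "cg00000003"],
               "H|TSS200": ["cg00000001"]}
        rm = regions.average_regions(bm, idx)
        assert rm.values.loc["G|Body"].tolist() == pytest.approx([0.4, 0.45])
        assert rm.values.loc["H|TSS200"].tolist() == pytest.approx([0.2, 0.25])
        assert rm.n_probes["G|Body"] == 3

    def test_missing_probes_skipped_per_sample(self):
        bm = make_beta([[0.2, np.nan], [np.nan, np.nan]])
        rm = regions.average_regions(
            bm, {"G|Body": ["cg00000001", "cg00000002"]}
        )
        assert rm.values.loc["G|Body"].iloc[0] == pytest.approx(0.2)
        assert np.isnan(rm.values.loc["G|Body"].iloc[1])

    def test_region_without_probes_omitted(self):
        bm = make_beta([[0.2]])
        rm = regions.average_regions(bm, {"G|Body": ["cg_absent"]})
        assert len(rm.values) == 0

    def test_matches_brute_force_oracle(self):
        bm = random_beta_matrix(n_probes=100, n_samples=20, seed=42)
        rng = np.random.default_rng(1)
        probes = list(bm.probe_ids)
        index = {
            f"G{k}|Body": list(
                rng.choice(probes, size=rng.integers(1, 9), replace=False)
            )
            for k in range(25)
        }
        rm = regions.average_regions(bm, index)
        for rid, members in index.items():
            for s in bm.sample_ids:
                vals = [
                    bm.beta.loc[p, s]
                    for p in members
                    if not np.isnan(bm.beta.loc[p, s])
                ]
                expected = sum(vals) / len(vals) if vals else np.nan
                got = rm.values.loc[rid, s]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_probe_order_permutation_invariance(self):
        bm = random_beta_matrix(n_probes=30, n_samples=8, seed=2)
        index = {"G|Body": list(bm.probe_ids[:7]), "H|TSS200": list(bm.probe_ids[5:12])}
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(bm.probe_ids))
        from gmdscreen.qc import BetaMatrix

        shuffled = BetaMatrix(bm.beta.iloc[perm])
        a = regions.average_regions(bm, index).values
        b = regions.average_regions(shuffled, index).values
        pd.testing.assert_frame_equal(a, b)

    def test_raising_one_beta_never_decreases_region_value(self):
        bm = random_beta_matrix(n_probes=10, n_samples=5, seed=3, missing_rate=0.2)
        index = {"G|Body": list(bm.probe_ids)}
        base = regions.average_regions(bm, index).values
        bumped = bm.copy()
        target = None
        for p in bumped.probe_ids:
            v = bumped.beta.loc[p].iloc[0]
            if not np.isnan(v) and v < 0.9:
                target = p
                break
        bumped.beta.loc[target, bumped.sample_ids[0]] += 0.05
        after = regions.average_regions(bumped, index).values
        assert after.iloc[0, 0] >= base.iloc[0, 0]

    def test_values_bounded(self, chain_panel):
        idx = build_region_index(chain_panel.annotation)
        rm = regions.average_regions(chain_panel.beta, idx)
        vals = rm.values.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0


class TestEpigenomeMean:
    def test_constant_betas(self):
        bm = make_beta(np.full((4, 3), 0.5))
        em = regions.epigenome_mean(bm)
        assert em.tolist() == pytest.approx([0.5, 0.5, 0.5])

    def test_two_probe_average(self):
        bm = make_beta([[0.0], [1.0]])
        assert regions.epigenome_mean(bm).iloc[0] == pytest.approx(0.5)

    def test_matches_oracle_mean(self):
        bm = random_beta_matrix(n_probes=80, n_samples=15, seed=6)
        em = regions.epigenome_mean(bm)
        for s in bm.sample_ids:
            col = bm.beta[s].dropna()
            assert em[s] == pytest.approx(col.sum() / len(col), abs=1e-12)

    def test_all_missing_sample_warns(self):
        bm = make_beta([[np.nan, 0.2], [np.nan, 0.4]])
        with pytest.warns(UserWarning, match="no non-missing"):
            em = regions.epigenome_mean(bm)
        assert np.isnan(em.iloc[0])
        assert em.iloc[1] == pytest.approx(0.3)
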