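"""Differential expression, rank statistic, GSEA, BH adjustment, annotation."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micromet.synthetic_data import ExpressionSimSpec, generate_expression_dataset
from micromet.transcriptomics_link import (
    bh_adjust, default_annotation, differential_expression, enrichment_score,
    map_sets_to_parameters, preranked_gsea, rank_genes, rank_statistic,
    read_gmt, validate_annotation, write_gmt,
)


@pytest.fixture
def planted_dataset():
    spec = ExpressionSimSpec(
        n_genes=1000, n_responders=20, n_non_responders=20,
        planted_sets={"setA": (30, 1.0)}, noise_sd=0.5, seed=11)
    return generate_expression_dataset(spec)


class TestDifferentialExpression:
    def test_planted_shift_recovered(self):
        # sd 0.3 with 20 vs 20 gives SE(logFC) ~= 0.095, so >= 95% of planted
        # genes land within +-0.2 of the true unit shift (normal theory: 96.5%)
        spec = ExpressionSimSpec(
            n_genes=1000, n_responders=20, n_non_responders=20,
            planted_sets={"setA": (200, 1.0)}, noise_sd=0.3, seed=21)
        expr, labels, truth = generate_expression_dataset(spec)
        de = differential_expression(expr, labels)
        planted = truth["gene"]
        fc = de.loc[planted, "log_fc"]
        assert (fc.between(0.8, 1.2)).mean() >= 0.93
        assert abs(fc.mean() - 1.0) < 0.05
        assert (de.loc[planted, "p_value"] < 0.01).mean() > 0.95

    def test_label_swap_negates_logfc(self, planted_dataset):
        expr, labels, _ = planted_dataset
        de = differential_expression(expr, labels)
        swapped = labels.map({"responder": "non_responder",
                              "non_responder": "responder"})
        de2 = differential_expression(expr, swapped)
        np.testing.assert_allclose(de2["log_fc"], -de["log_fc"])
        np.testing.assert_allclose(de2["p_value"], de["p_value"])

    def test_null_pvalues_roughly_uniform(self):
        spec = ExpressionSimSpec(n_genes=2000, n_responders=10,
                                 n_non_responders=10, seed=5)
        expr, labels, _ = generate_expression_dataset(spec)
        de = differential_expression(expr, labels)
        from scipy.stats import kstest
        assert kstest(de["p_value"], "uniform").pvalue > 0.01

    def test_small_group_rejected(self, planted_dataset):
        expr, labels, _ = planted_dataset
        bad = labels.copy()
        bad[bad == "responder"] = "non_responder"
        bad.iloc[0] = "responder"
        with pytest.raises(ValueError):
            differential_expression(expr, bad)


class TestRankStatistic:
    @pytest.mark.parametrize("fc,p,expected", [
        (2.0, 0.01, 2.0), (-1.0, 0.001, -3.0), (5.0, 1.0, 0.0),
        (-3.0, 1.0, 0.0), (0.0, 0.5, 0.0),
    ])
    def test_closed_form(self, fc, p, expected):
        assert rank_statistic(fc, p) == pytest.approx(expected)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            s = rank_statistic(1.0, 0.0)
        assert np.isfinite(s) and s > 300

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-10, 10, allow_nan=False),
           st.floats(1e-12, 1.0, exclude_min=False))
    def test_odd_in_sign_and_monotone_in_p(self, fc, p):
        s = rank_statistic(fc, p)
        assert rank_statistic(-fc, p) == pytest.approx(-s)
        if p < 0.5:
            assert abs(rank_statistic(fc, p)) >= abs(rank_statistic(fc, min(1.0, p * 2))) - 1e-12


class TestBhAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_fixpoints(self):
        # constant vectors and all-ones are fixpoints of the step-up procedure
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
        np.testing.assert_allclose(bh_adjust(bh_adjust([1.0, 1.0])), [1.0, 1.0])

    def test_monotone_and_dominates_raw(self):
        p = np.random.default_rng(1).random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGmt:
    def test_roundtrip(self, tmp_path):
        sets = {"a": ["g1", "g2"], "b": ["g3", "g4", "g5"]}
        path = tmp_path / "c.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\n")
        with pytest.raises(ValueError):
            read_gmt(path)


class TestEnrichmentScore:
    def test_hand_traced_three_gene_example(self):
        ranks = pd.Series({"g1": 2.0, "g2": 1.0, "g3": -1.0})
        assert enrichment_score(ranks, {"g1"}) == pytest.approx(1.0)
        assert enrichment_score(ranks, {"g3"}) == pytest.approx(-1.0)

    def test_whole_list_set_rejected(self):
        ranks = pd.Series({"g1": 2.0, "g2": 1.0})
        with pytest.raises(ValueError):
            enrichment_score(ranks, {"g1", "g2"})

    def test_matches_fgsea_reference(self, tmp_path):
        """Independent oracle: Bioconductor fgsea on a small fixture."""
        rng = np.random.default_rng(42)
        genes = [f"G{i:03d}" for i in range(60)]
        s = pd.Series(rng.normal(size=60), index=genes)
        sets = {"s1": genes[0:12], "s2": genes[20:28],
                "s3": [genes[i] for i in rng.choice(60, 15, replace=False)]}
        write_gmt(sets, tmp_path / "sets.gmt")
        s.sort_values(ascending=False).to_csv(tmp_path / "ranks.csv", header=False)
        script = textwrap.dedent("""
            suppressMessages(library(fgsea))
            r <- read.csv("ranks.csv", header=FALSE)
            stats <- setNames(r$V2, r$V1)
            pw <- gmtPathways("sets.gmt")
            set.seed(1)
            res <- fgsea(pathways=pw, stats=stats, minSize=3, maxSize=50,
                         nPermSimple=200, scoreType="std")
            write.csv(res[, c("pathway", "ES")], "out.csv", row.names=FALSE)
        """)
        (tmp_path / "check.R").write_text(script)
        subprocess.run(["Rscript", "check.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv").set_index("pathway")["ES"]
        for name, members in sets.items():
            assert enrichment_score(s, members) == pytest.approx(ref[name], abs=1e-9)


class TestPrerankedGsea:
    def test_planted_set_strongly_enriched(self, planted_dataset):
        expr, labels, truth = planted_dataset
        ranks = rank_genes(differential_expression(expr, labels))
        sets = {"setA": truth["gene"].tolist(),
                "decoy": [f"G{i:05d}" for i in range(500, 540)]}
        res = preranked_gsea(ranks, sets, n_permutations=500, seed=0)
        assert res.loc["setA", "es"] > 0.5
        assert res.loc["setA", "p_adjusted"] <= 0.05
        assert res.loc["decoy", "p_value"] > 0.05

    def test_too_small_and_disjoint_sets_skipped(self):
        ranks = pd.Series(np.arange(50, dtype=float) - 25,
                          index=[f"g{i}" for i in range(50)])
        with pytest.warns(UserWarning):
            res = preranked_gsea(ranks, {"tiny": ["g1", "g2"],
                                         "alien": ["x1", "x2", "x3", "x4", "x5"],
                                         "ok": [f"g{i}" for i in range(10, 22)]},
                                 n_permutations=200, seed=0)
        assert list(res.index) == ["ok"]

    def test_min_permutations_enforced(self):
        ranks = pd.Series(np.arange(20, dtype=float), index=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError):
            preranked_gsea(ranks, {"s": ["g1"] * 6}, n_permutations=10)


class TestParameterMapping:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["size", "es", "nes", "p_value",
                                           "p_adjusted", "leading_edge"],
                            index=[r[-1] for r in rows] if False else None)

    def test_mapping_and_expansion_split(self):
        res = pd.DataFrame({
            "nes": [2.0, -1.5, 1.0],
            "p_adjusted": [0.01, 0.02, 0.5],
        }, index=["genome_instability_and_mutation", "weird_unmapped_set",
                  "tgf_beta_signaling"])
        shortlist = map_sets_to_parameters(res, default_annotation(), alpha=0.05)
        assert list(shortlist.parameters.index) == ["p_mutation"]
        assert shortlist.parameters.loc["p_mutation", "directions"] == ["up"]
        assert shortlist.expansion_candidates == ["weird_unmapped_set"]

    def test_no_significant_sets(self):
        res = pd.DataFrame({"nes": [1.0], "p_adjusted": [0.9]},
                           index=["tgf_beta_signaling"])
        shortlist = map_sets_to_parameters(res, default_annotation())
        assert len(shortlist.parameters) == 0
        assert shortlist.expansion_candidates == []

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            validate_annotation({"some_set": ["not_a_parameter"]})

    def test_default_annotation_shape(self):
        ann = default_annotation()
        assert len(ann) == 10
        params = {p for v in ann.values() for p in v}
        assert params == {"p_mutation", "p_migration_cancer", "t_proliferation",
                          "tau_sup", "r_ctl", "tau_enh"}
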