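"""Control-referenced Z-scoring, signature scores, and the score~%AS regression."""

import statistics

import numpy as np
import pandas as pd
import pytest

from splicescore.signature_scores import (
    GeneSignature,
    build_control_reference,
    read_expression_tsv,
    read_gene_list,
    regress_score_on_splicing,
    score_samples,
    zscore,
)
from splicescore.synthetic_data import SimulationConfig, simulate_expression


@pytest.fixture(scope="module")
def expression(tmp_path_factory):
    cfg = SimulationConfig(seed=404)
    out = tmp_path_factory.mktemp("expr")
    truth = simulate_expression(cfg, out)
    matrix = read_expression_tsv(out / "expression.tsv")
    return cfg, out, truth, matrix


class TestControlReference:
    def test_mean_and_sample_sd(self):
        mat = pd.DataFrame(
            {"c1": [3.0, 1.0], "c2": [5.0, 1.0], "c3": [7.0, 1.0], "p1": [9.0, 2.0]},
            index=["gA", "gB"],
        )
        ref = build_control_reference(mat, ["c1", "c2", "c3"])
        assert ref.mean["gA"] == 5.0
        assert ref.sd["gA"] == pytest.approx(2.0)  # ddof 1
        assert ref.dropped_genes == ["gB"]  # constant across controls

    def test_missing_control_raises(self):
        mat = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["g"])
        with pytest.raises(ValueError, match="absent"):
            build_control_reference(mat, ["c1", "cX"])

    def test_fewer_than_two_controls_raises(self):
        mat = pd.DataFrame({"c1": [1.0], "p1": [2.0]}, index=["g"])
        with pytest.raises(ValueError, match="at least 2"):
            build_control_reference(mat, ["c1"])


class TestZscore:
    def test_control_set_standardised(self, expression):
        """Z of the control samples has per-gene mean 0 and sd 1 (ddof 1)."""
        _, _, truth, matrix = expression
        ref = build_control_reference(matrix, truth["control_ids"])
        z = zscore(matrix, ref)[truth["control_ids"]]
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_elementwise_against_brute_force(self, expression):
        """Z matrix equals an independent stdlib-statistics recomputation."""
        _, _, truth, matrix = expression
        ref = build_control_reference(matrix, truth["control_ids"])
        z = zscore(matrix, ref)
        rows = truth["ifn_genes"][:5] + ["BG0001", "BG0002"]
        for g in rows:
            ctrl = [matrix.at[g, c] for c in truth["control_ids"]]
            m, s = statistics.fmean(ctrl), statistics.stdev(ctrl)
            for smp in list(matrix.columns)[:8]:
                assert z.at[g, smp] == pytest.approx(
                    (matrix.at[g, smp] - m) / s, abs=1e-12
                )

    def test_simple_anchor_points(self):
        mat = pd.DataFrame({"c1": [3.0], "c2": [7.0], "p": [5.0], "q": [9.0]},
                           index=["g"])
        ref = build_control_reference(mat, ["c1", "c2"])
        z = zscore(mat, ref)
        assert z.at["g", "p"] == pytest.approx(0.0)  # x = mean
        sd = statistics.stdev([3.0, 7.0])
        assert z.at["g", "q"] == pytest.approx((9.0 - 5.0) / sd)

    def test_dropped_genes_absent_from_output(self):
        mat = pd.DataFrame(
            {"c1": [1.0, 4.0], "c2": [1.0, 6.0], "p": [2.0, 5.0]}, index=["flat", "g"]
        )
        ref = build_control_reference(mat, ["c1", "c2"])
        z = zscore(mat, ref)
        assert "flat" not in z.index


class TestScoring:
    def test_single_gene_signature_equals_its_z(self, expression):
        _, _, truth, matrix = expression
        ref = build_control_reference(matrix, truth["control_ids"])
        z = zscore(matrix, ref)
        gene = truth["ifn_genes"][0]
        table = score_samples(z, GeneSignature("one", (gene,)))
        assert np.allclose(table["score"], z.loc[gene])

    def test_control_cohort_mean_score_is_zero(self, expression):
        _, _, truth, matrix = expression
        ref = build_control_reference(matrix, truth["control_ids"])
        z = zscore(matrix, ref)
        sig = GeneSignature("IFN", tuple(truth["ifn_genes"]))
        table = score_samples(z, sig, aggregator="mean")
        assert table.loc[truth["control_ids"], "score"].mean() == pytest.approx(
            0.0, abs=1e-9
        )

    def test_invariant_under_row_and_column_reordering(self, expression):
        cfg, _, truth, matrix = expression
        rng = np.random.default_rng(0)
        shuffled = matrix.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2
        )
        sig = GeneSignature("IFN", tuple(truth["ifn_genes"]))
        ref_a = build_control_reference(matrix, truth["control_ids"])
        ref_b = build_control_reference(shuffled, truth["control_ids"])
        sa = score_samples(zscore(matrix, ref_a), sig)["score"]
        sb = score_samples(zscore(shuffled, ref_b), sig)["score"]
        assert np.allclose(sa.sort_index(), sb.sort_index())

    def test_case_scores_exceed_control_maximum(self, expression):
        """At the planted effect size, every strongly spliced case scores above
        the whole control range."""
        _, _, truth, matrix = expression
        ref = build_control_reference(matrix, truth["control_ids"])
        z = zscore(matrix, ref)
        table = score_samples(z, GeneSignature("IFN", tuple(truth["ifn_genes"])))
        ctrl_max = table.loc[truth["control_ids"], "score"].max()
        high = [
            s
            for s, v in truth["samples"].items()
            if v["group"] == "case" and v["true_percent_as"] > 40
        ]
        assert (table.loc[high, "score"] > ctrl_max).all()

    def test_zero_present_genes_raises(self, expression):
        _, _, truth, matrix = expression
        ref = build_control_reference(matrix, truth["control_ids"])
        z = zscore(matrix, ref)
        with pytest.raises(ValueError, match="no gene"):
            score_samples(z, GeneSignature("ghost", ("NOT_A_GENE",)))

    def test_gene_list_reader(self, expression):
        _, out, truth, _ = expression
        sig = read_gene_list(out / "ifn_genes.txt")
        assert list(sig.genes) == truth["ifn_genes"]

    def test_packaged_default_signatures(self):
        from splicescore.signature_scores import default_signature

        for name in ("IFN", "NFKB"):
            sig = default_signature(name)
            assert len(sig.genes) >= 10
            assert len(set(sig.genes)) == len(sig.genes)
        with pytest.raises(ValueError, match="no default signature"):
            default_signature("bogus")


class TestRegression:
    def test_perfect_collinearity(self):
        x = pd.Series({f"s{i}": float(i) for i in range(6)})
        fit = regress_score_on_splicing(2.0 * x + 1.0, x)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_constant_predictor_raises(self):
        x = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        y = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError, match="constant"):
            regress_score_on_splicing(y, x)

    def test_too_few_pairs_raises(self):
        x = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match=">= 3"):
            regress_score_on_splicing(x, x)

    def test_r_squared_is_squared_pearson(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.uniform(0, 60, 20), index=[f"s{i}" for i in range(20)])
        y = 0.05 * x + pd.Series(rng.normal(0, 0.4, 20), index=x.index)
        fit = regress_score_on_splicing(y, x)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_pairs_matched_by_sample_id(self):
        y = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "orphan": 9.0})
        x = pd.Series({"c": 30.0, "a": 10.0, "b": 20.0, "other": 1.0})
        fit = regress_score_on_splicing(y, x)
        assert fit.n == 3
        assert fit.slope == pytest.approx(0.1)


class TestMonotonicity:
    def test_mean_case_score_increases_with_effect_size(self, tmp_path):
        """Raising the planted slope strictly raises the mean case score at a
        matched seed."""
        means = []
        for beta in (0.02, 0.05, 0.08):
            cfg = SimulationConfig(seed=777)
            cfg.expression.beta_ifn = beta
            truth = simulate_expression(cfg, tmp_path / f"b{beta}")
            case_scores = [
                v["planted_ifn_score"]
                for v in truth["samples"].values()
                if v["planted_ifn_score"] is not None
            ]
            means.append(np.mean(case_scores))
        assert means[0] < means[1] < means[2]
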