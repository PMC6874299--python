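"""UMI collapse, 3'-window quantification, timecourse QC, response scores."""
import numpy as np
import pandas as pd
import pytest

from duplinoise import rnaseq
from duplinoise import synthetic as syn
from duplinoise.datatypes import ALIGNMENT_COLUMNS, EmptyInputError, GenomeAnnotation, ParameterError


def _aln(rows):
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def brute_force_collapse(table: pd.DataFrame) -> dict:
    """Independent oracle: cardinality of the set of (chrom,strand,pos,umi)."""
    out: dict = {}
    for _, r in table.iterrows():
        out.setdefault((r["chrom"], r["strand"], r["pos"]), set()).add(r["umi"])
    return {k: len(v) for k, v in out.items()}


class TestUmiCollapse:
    def test_duplicate_umis_collapse(self):
        table = _aln([
            ("r1", "c", 10, "+", "A" * 4, 1),
            ("r2", "c", 10, "+", "A" * 4, 1),
            ("r3", "c", 10, "+", "C" * 4, 1),
        ])
        out = rnaseq.umi_collapse(table)
        assert out.loc[0, "count"] == 2

    def test_generator_truth_recovered_after_amplification(self, toy_annotation):
        table, gt = syn.simulate_umi_alignments(toy_annotation, {"g0": 100}, duplication=3, seed=1)
        assert rnaseq.umi_collapse(table)["count"].sum() == 100

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 60))
            table = _aln([
                (f"r{i}", "c", int(rng.integers(0, 5)), "+",
                 "".join(rng.choice(list("ACGT"), 4)), 1)
                for i in range(n)
            ])
            got = rnaseq.umi_collapse(table)
            oracle = brute_force_collapse(table)
            assert {(r["chrom"], r["strand"], r["pos"]): r["count"]
                    for _, r in got.iterrows()} == oracle

    def test_mixed_umi_lengths_rejected(self):
        table = _aln([("r1", "c", 1, "+", "ACGT", 1), ("r2", "c", 1, "+", "ACGTA", 1)])
        with pytest.raises(ParameterError):
            rnaseq.umi_collapse(table)

    def test_empty_table_rejected(self):
        with pytest.raises(EmptyInputError):
            rnaseq.umi_collapse(_aln([]))


class TestQuantifyGenes:
    def test_exact_recovery_without_multimapping(self, toy_annotation):
        expr = {"g0": 40, "g1": 0, "g2": 25}
        table, _ = syn.simulate_umi_alignments(toy_annotation, expr, duplication=2, seed=2)
        counts = rnaseq.quantify_genes(table, toy_annotation)
        assert counts["g0"] == 40 and counts["g1"] == 0 and counts["g2"] == 25

    def test_thirty_ten_multimapper_split(self, toy_annotation):
        rows = []
        w0 = syn.gene_quant_window(toy_annotation.row("g0"))
        w1 = syn.gene_quant_window(toy_annotation.row("g1"))
        umis = [f"{a}{b}{c}{d}" for a in "ACGT" for b in "ACGT" for c in "ACGT" for d in "ACGT"]
        for i in range(30):
            rows.append((f"u{i}", "chrI", w0[0] + i, "+", umis[i], 1))
        for i in range(10):
            rows.append((f"v{i}", "chrI", w1[0] + i, "+", umis[40 + i], 1))
        rows.append(("m0", "chrI", w0[0] + 100, "+", umis[100], 2))
        rows.append(("m0", "chrI", w1[0] + 100, "+", umis[100], 2))
        counts = rnaseq.quantify_genes(_aln(rows), toy_annotation)
        assert counts["g0"] == pytest.approx(30.75)
        assert counts["g1"] == pytest.approx(10.25)

    def test_equal_split_when_no_unique_evidence(self, toy_annotation):
        w0 = syn.gene_quant_window(toy_annotation.row("g0"))
        w1 = syn.gene_quant_window(toy_annotation.row("g1"))
        rows = [("m0", "chrI", w0[0] + 5, "+", "ACGT", 2),
                ("m0", "chrI", w1[0] + 5, "+", "ACGT", 2)]
        counts = rnaseq.quantify_genes(_aln(rows), toy_annotation)
        assert counts["g0"] == counts["g1"] == pytest.approx(0.5)

    def test_mass_conserved_with_multimapping(self, toy_annotation):
        expr = {g: 100 for g in toy_annotation.genes["gene"]}
        table, gt = syn.simulate_umi_alignments(
            toy_annotation, expr, multimap_fraction=0.2, seed=3)
        counts = rnaseq.quantify_genes(table, toy_annotation)
        assert counts.sum() == pytest.approx(gt.params["total_molecules"])
        # and within 2% per the scaled recovery expectation
        truth = pd.Series(gt.params["molecules"])
        assert abs(counts.sum() - truth.sum()) / truth.sum() < 0.02


class TestBuildTimecourse:
    @staticmethod
    def _counts():
        # gene gI is induced at t=30; raw scales differ per sample
        return pd.DataFrame(
            {0.0: [10, 990_990], 30.0: [30, 999_970], 60.0: [30, 999_970]},
            index=["gI", "gRest"],
        )

    def test_low_coverage_interior_sample_interpolated(self):
        counts = pd.DataFrame(
            {0.0: [10, 999_990], 30.0: [77, 999_923], 60.0: [30, 999_970]},
            index=["gI", "gRest"])
        totals = pd.Series({0.0: 1_000_000, 30.0: 149_999, 60.0: 1_000_000})
        tc = rnaseq.build_timecourse(counts, totals)
        assert tc.discarded == [30.0]
        assert tc.values.loc["gI", 30.0] == pytest.approx((10 + 30) / 2)

    def test_boundary_discard_takes_nearest_retained(self):
        counts = self._counts()
        totals = pd.Series({0.0: 100_000, 30.0: 400_000, 60.0: 400_000})
        tc = rnaseq.build_timecourse(counts, totals)
        assert tc.values[0.0].equals(tc.values[30.0])

    def test_retained_columns_sum_to_one_million(self):
        tc = rnaseq.build_timecourse(
            self._counts(), pd.Series({0.0: 5e5, 30.0: 6e5, 60.0: 7e5}))
        np.testing.assert_allclose(tc.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_samples_below_threshold_raise(self):
        with pytest.raises(ParameterError):
            rnaseq.build_timecourse(
                self._counts(), pd.Series({0.0: 10, 30.0: 10, 60.0: 10}))


def _tc(values: dict, genes) -> rnaseq.ExpressionTimecourse:
    df = pd.DataFrame(values, index=genes)
    return rnaseq.build_timecourse(df, pd.Series({t: 1e6 for t in values}))


class TestResponseScores:
    def test_constant_gene_scores_zero_auc(self):
        tc = _tc({0.0: [5, 100], 30.0: [5, 100], 60.0: [5, 100]}, ["gC", "gRest"])
        assert rnaseq.response_auc(tc)["gC"] == 0.0

    def test_step_profile_integrates_to_c_times_T(self):
        # log2 fold exactly c=1 over the whole 90-min course (pseudocount 0)
        df = pd.DataFrame({0.0: [100.0, 900.0], 30.0: [200.0, 800.0],
                           90.0: [200.0, 800.0]}, index=["gI", "gRest"])
        tc = rnaseq.ExpressionTimecourse(values=df, raw_totals=pd.Series(
            {0.0: 1e6, 30.0: 1e6, 90.0: 1e6}))
        auc = rnaseq.response_auc(tc, pseudocount=0.0)
        # trapezoid: rises 0->1 over [0,30], holds 1 over [30,90]
        assert auc["gI"] == pytest.approx(0.5 * 30 + 60)

    def test_auc_is_additive_in_log2_profiles(self):
        times = [0.0, 20.0, 50.0]
        base = np.array([100.0, 100.0, 100.0])
        f1 = np.array([1.0, 2.0, 4.0])
        f2 = np.array([1.0, 1.5, 1.0])
        mk = lambda fold: rnaseq.ExpressionTimecourse(
            values=pd.DataFrame({t: [base[i] * fold[i]] for i, t in enumerate(times)},
                                index=["g"]),
            raw_totals=pd.Series({t: 1e6 for t in times}))
        a1 = rnaseq.response_auc(mk(f1), pseudocount=0.0)["g"]
        a2 = rnaseq.response_auc(mk(f2), pseudocount=0.0)["g"]
        a12 = rnaseq.response_auc(mk(f1 * f2), pseudocount=0.0)["g"]
        assert a12 == pytest.approx(a1 + a2)

    def test_missing_time_zero_rejected(self):
        df = pd.DataFrame({10.0: [1.0], 20.0: [1.0], 30.0: [2.0]}, index=["g"])
        tc = rnaseq.ExpressionTimecourse(values=df, raw_totals=pd.Series(
            {10.0: 1e6, 20.0: 1e6, 30.0: 1e6}))
        with pytest.raises(ParameterError):
            rnaseq.response_auc(tc)


class TestDependency:
    def test_ratio_of_four(self):
        wt = pd.DataFrame({"c1": [4.0], "c2": [4.0]}, index=["g"])
        dd = pd.DataFrame({"c1": [1.0], "c2": [1.0]}, index=["g"])
        out = rnaseq.dependency_score({"WT": wt, "msn2msn4": dd}, eps=1e-12)
        assert out.loc["g", "dependency"] == pytest.approx(4.0)

    def test_equal_induction_scores_one(self):
        a = pd.DataFrame({"c1": [3.0]}, index=["g"])
        out = rnaseq.dependency_score({"WT": a, "msn2msn4": a.copy()}, eps=1.0)
        assert out.loc["g", "dependency"] == pytest.approx(1.0)

    def test_missing_strain_listed(self):
        with pytest.raises(ParameterError, match="msn2msn4"):
            rnaseq.dependency_score({"WT": pd.DataFrame({"c": [1.0]}, index=["g"])})

    def test_dependent_genes_occupy_top_ranks(self, rng):
        n, n_dep = 200, 50
        genes = [f"g{i}" for i in range(n)]
        dep = set(genes[:n_dep])
        wt = pd.DataFrame({
            "c1": [8.0 + rng.normal(0, 0.5) if g in dep else 2.0 + rng.normal(0, 0.3)
                   for g in genes]}, index=genes)
        dd = pd.DataFrame({
            "c1": [0.5 + 0.1 * rng.random() if g in dep else wt.loc[g, "c1"]
                   for g in genes]}, index=genes)
        out = rnaseq.dependency_score({"WT": wt, "msn2msn4": dd})
        assert set(out.index[:n_dep]) == dep

    def test_invariant_to_global_rescaling(self):
        wt = pd.DataFrame({"c1": [4.0, 2.0]}, index=["a", "b"])
        dd = pd.DataFrame({"c1": [1.0, 2.0]}, index=["a", "b"])
        s1 = rnaseq.dependency_score({"WT": wt, "msn2msn4": dd}, eps=1e-12)
        s2 = rnaseq.dependency_score({"WT": 3 * wt, "msn2msn4": 3 * dd}, eps=1e-12)
        # with eps -> 0 the ratio is scale free
        assert np.allclose(s1["dependency"], s2["dependency"], rtol=1e-9)


class TestTargets:
    def test_strict_twofold_boundary(self):
        wt = pd.DataFrame({"c": [5.0, 4.0]}, index=["a", "b"])
        dd = pd.DataFrame({"c": [2.0, 2.0]}, index=["a", "b"])
        sel = rnaseq.select_targets({"WT": wt, "msn2msn4": dd}, "c")
        assert bool(sel["a"]) and not bool(sel["b"])  # 5>4 yes; 4>4 strict no


class TestVariability:
    def test_constant_gene_zero_variance_unit_fold(self):
        df = pd.DataFrame(np.full((1, 25), 7.0), index=["g"])
        out = rnaseq.expression_variability({"ds": df}, "g")
        assert out["variance"].iloc[0] == 0.0
        assert rnaseq.max_fold_change(df.loc["g"]) == 1.0

    def test_flexible_gene_has_larger_variance(self, rng):
        genes = ["msn2like", "msn4like"]
        for rep in range(3):
            flat = 100 + rng.normal(0, 3, 30)
            flex = np.where(rng.random(30) < 0.5, 1000, 100) + rng.normal(0, 3, 30)
            df = pd.DataFrame([flat, flex], index=genes)
            out = rnaseq.expression_variability({"ds": df}, "msn4like")
            base = rnaseq.expression_variability({"ds": df}, "msn2like")
            assert out["variance"].iloc[0] > base["variance"].iloc[0]

    def test_small_dataset_skipped_with_warning(self):
        df = pd.DataFrame(np.ones((1, 5)), index=["g"])
        with pytest.warns(UserWarning):
            out = rnaseq.expression_variability({"tiny": df}, "g")
        assert out.empty

    def test_fold_change_scale_invariant(self):
        s = pd.Series([2.0, 8.0, 4.0])
        assert rnaseq.max_fold_change(s) == rnaseq.max_fold_change(2 * s) == 4.0
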