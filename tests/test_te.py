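"""Translation-efficiency arithmetic, the SNR filter, DE calls, group tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m2acodon.simulate import SimConfig, simulate_expression, simulate_transcriptome
from m2acodon.te import (
    ExpressionTable,
    _compact_letter_display,
    call_de,
    compare_groups,
    compute_snr,
    compute_te,
    cumulative_summary,
    te_fold_change,
)

fpkm = st.floats(min_value=0.0, max_value=1e5, allow_nan=False)


def make_table(values: dict, genes=None) -> ExpressionTable:
    sheet = []
    for name in values:
        assay, cond, rep = name.rsplit("_", 2)
        sheet.append({"sample": name, "assay": assay, "condition": cond,
                      "replicate": int(rep.removeprefix("rep"))})
    n = len(next(iter(values.values())))
    genes = genes or [f"g{i}" for i in range(n)]
    return ExpressionTable(pd.DataFrame(values, index=genes), pd.DataFrame(sheet))


def full_design(inp_wt, rpf_wt, inp_mut, rpf_mut, genes=None):
    return make_table(
        {
            "input_mrna_wildtype_rep1": inp_wt[0],
            "input_mrna_wildtype_rep2": inp_wt[1],
            "ribo_footprint_wildtype_rep1": rpf_wt[0],
            "ribo_footprint_wildtype_rep2": rpf_wt[1],
            "input_mrna_mutant_rep1": inp_mut[0],
            "input_mrna_mutant_rep2": inp_mut[1],
            "ribo_footprint_mutant_rep1": rpf_mut[0],
            "ribo_footprint_mutant_rep2": rpf_mut[1],
        },
        genes=genes,
    )


class TestSnr:
    def test_hand_evaluated(self):
        assert compute_snr(10, 12, 4, 6).snr == pytest.approx(1.5)

    def test_zero_numerator_convention(self):
        assert compute_snr(5, 5, 5, 5).snr == 0.0

    def test_zero_denominator_convention(self):
        assert compute_snr(5, 5, 9, 9).snr == math.inf

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_snr(-1, 2, 3, 4)

    @settings(max_examples=100, deadline=None)
    @given(fpkm, fpkm, fpkm, fpkm)
    def test_symmetries(self, x1, x2, y1, y2):
        base = compute_snr(x1, x2, y1, y2).snr
        assert compute_snr(y1, y2, x1, x2).snr == base  # swap conditions
        assert compute_snr(x2, x1, y1, y2).snr == base  # swap replicates
        assert compute_snr(x1, x2, y2, y1).snr == base


class TestComputeTe:
    def test_identity_when_rpf_equals_input(self):
        inp = [np.array([3.0, 7.0]), np.array([4.0, 8.0])]
        expr = full_design(inp, inp, inp, inp)
        te = compute_te(expr)
        assert np.allclose(te[["te_wildtype", "te_mutant", "te_fold_change"]], 1.0)
        assert te["translated"].all()

    def test_geometric_mean_of_replicates(self):
        # replicate TEs 2 and 8 -> condition TE sqrt(16) = 4
        inp = [np.array([1.0]), np.array([1.0])]
        rpf = [np.array([2.0]), np.array([8.0])]
        expr = full_design(inp, rpf, inp, rpf)
        te = compute_te(expr)
        assert te["te_wildtype"].iloc[0] == pytest.approx(4.0)

    def test_zero_input_marks_untranslated(self):
        inp_wt = [np.array([0.0, 5.0]), np.array([2.0, 5.0])]
        rpf = [np.array([1.0, 5.0]), np.array([1.0, 5.0])]
        inp_mut = [np.array([2.0, 5.0]), np.array([2.0, 5.0])]
        expr = full_design(inp_wt, rpf, inp_mut, rpf)
        te = compute_te(expr)
        assert not te["translated"].iloc[0]
        assert np.isnan(te["te_fold_change"].iloc[0])
        assert te["translated"].iloc[1]

    def test_geomean_commutes_with_ratio(self, rng):
        # geomean_r(rpf_r/inp_r) == geomean_r(rpf_r)/geomean_r(inp_r)
        inp = [rng.uniform(1, 50, 20), rng.uniform(1, 50, 20)]
        rpf = [rng.uniform(1, 50, 20), rng.uniform(1, 50, 20)]
        expr = full_design(inp, rpf, inp, rpf)
        te = compute_te(expr)
        expected = np.sqrt(rpf[0] * rpf[1]) / np.sqrt(inp[0] * inp[1])
        assert np.allclose(te["te_wildtype"], expected)

    def test_unmatched_design_rejected(self):
        expr = make_table(
            {
                "input_mrna_wildtype_rep1": [1.0],
                "input_mrna_wildtype_rep2": [1.0],
                "ribo_footprint_wildtype_rep1": [1.0],
                "input_mrna_mutant_rep1": [1.0],
                "input_mrna_mutant_rep2": [1.0],
                "ribo_footprint_mutant_rep1": [1.0],
                "ribo_footprint_mutant_rep2": [1.0],
            }
        )
        with pytest.raises(ValueError, match="unmatched"):
            compute_te(expr)

    def test_fold_change_ratio(self):
        inp = [np.array([1.0]), np.array([1.0])]
        expr = full_design(inp, [np.array([4.0]), np.array([4.0])],
                           inp, [np.array([2.0]), np.array([2.0])])
        te = compute_te(expr)
        assert te_fold_change(te).iloc[0] == pytest.approx(0.5)


class TestCallDe:
    def test_flat_gene_not_called(self):
        inp = [np.array([10.0]), np.array([10.0])]
        expr = full_design(inp, inp, inp, inp)
        de = call_de(expr)
        assert de["fold_change"].iloc[0] == 1.0
        assert not de["called"].iloc[0]

    def test_perfect_replicates_fold_four(self):
        inp_wt = [np.array([10.0]), np.array([10.0])]
        inp_mut = [np.array([40.0]), np.array([40.0])]
        expr = full_design(inp_wt, inp_wt, inp_mut, inp_mut)
        de = call_de(expr)
        assert de["fold_change"].iloc[0] == pytest.approx(4.0)
        assert de["snr"].iloc[0] == math.inf
        # the call must agree with the conjunction of its own criteria
        assert de["called"].iloc[0] == (de["p_adjusted"].iloc[0] < 0.05)

    def test_noisy_replicates_blocked_by_snr(self):
        # means 20 vs 40: fold change 2, but replicate scatter dominates
        inp_wt = [np.array([5.0]), np.array([35.0])]
        inp_mut = [np.array([30.0]), np.array([50.0])]
        expr = full_design(inp_wt, inp_wt, inp_mut, inp_mut)
        de = call_de(expr)
        assert de["fold_change"].iloc[0] == pytest.approx(2.0)
        assert de["snr"].iloc[0] == pytest.approx(0.4)
        assert not de["called"].iloc[0]

    def test_all_zero_rows_excluded(self):
        z = [np.array([0.0, 1.0]), np.array([0.0, 1.0])]
        expr = full_design(z, z, z, z)
        de = call_de(expr)
        assert list(de.index) == ["g1"]

    def test_invariance_to_row_and_column_order(self, rng):
        n = 40
        cols = {}
        for assay in ("input_mrna", "ribo_footprint"):
            for cond in ("wildtype", "mutant"):
                for rep in (1, 2):
                    cols[f"{assay}_{cond}_rep{rep}"] = rng.uniform(1, 100, n)
        expr = make_table(cols)
        de = call_de(expr)
        perm = rng.permutation(n)
        shuffled_vals = expr.values.iloc[perm, ::-1]
        expr2 = ExpressionTable(shuffled_vals, expr.samples)
        de2 = call_de(expr2)
        pd.testing.assert_frame_equal(de.sort_index(), de2.sort_index())

    def test_null_generator_rarely_calls(self):
        # delta = 1 everywhere: the 3-way conjunction should call <= 10%
        cfg = SimConfig(n_genes=200, tandem_design={0: 140, 3: 20, 4: 20, 6: 20})
        _, truth = simulate_transcriptome(cfg)
        rates = []
        for seed in range(20):
            expr = simulate_expression(truth, SimConfig(
                n_genes=200, tandem_design={0: 140, 3: 20, 4: 20, 6: 20},
                seed=seed))
            rates.append(call_de(expr)["called"].mean())
        assert all(r <= 0.1 for r in rates)


class TestCompareGroups:
    def test_letters_separate_shifted_groups(self, rng):
        fc = pd.Series(
            np.concatenate([rng.normal(1.0, 0.05, 50), rng.normal(0.5, 0.05, 50)]),
            index=[f"g{i}" for i in range(100)],
        )
        grp = pd.Series(["others"] * 50 + ["tandem"] * 50, index=fc.index)
        res = compare_groups(fc, grp)
        assert res.p_value < 0.05
        assert not set(res.letters["others"]) & set(res.letters["tandem"])

    def test_degenerate_all_identical(self):
        fc = pd.Series(1.0, index=[f"g{i}" for i in range(20)])
        grp = pd.Series(["a"] * 10 + ["b"] * 10, index=fc.index)
        res = compare_groups(fc, grp)
        assert res.degenerate
        assert res.letters == {"a": "a", "b": "a"}

    def test_small_groups_excluded_with_warning(self, rng):
        fc = pd.Series(rng.normal(1, 0.1, 23), index=[f"g{i}" for i in range(23)])
        grp = pd.Series(["a"] * 10 + ["b"] * 11 + ["c"] * 2, index=fc.index)
        with pytest.warns(UserWarning, match="excluded"):
            res = compare_groups(fc, grp)
        assert set(res.summary.index) == {"a", "b"}

    def test_summary_quartiles(self, rng):
        vals = np.arange(1.0, 9.0)  # 1..8
        fc = pd.Series(np.concatenate([vals, vals + 10]),
                       index=[f"g{i}" for i in range(16)])
        grp = pd.Series(["a"] * 8 + ["b"] * 8, index=fc.index)
        res = compare_groups(fc, grp)
        assert res.summary.loc["a", "median"] == pytest.approx(4.5)
        assert res.summary.loc["a", "q1"] == pytest.approx(np.quantile(vals, 0.25))
        assert res.summary.loc["a", "n"] == 8

    def test_fewer_than_two_groups_rejected(self, rng):
        fc = pd.Series(rng.normal(1, 0.1, 10), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            compare_groups(fc, pd.Series("a", index=fc.index))


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        out = _compact_letter_display(["a", "b", "c"], set())
        assert len({v for v in out.values()}) == 1

    def test_one_distinct_pair(self):
        out = _compact_letter_display(["a", "b", "c"], {("a", "b")})
        assert not set(out["a"]) & set(out["b"])
        assert set(out["c"]) & set(out["a"])
        assert set(out["c"]) & set(out["b"])

    def test_all_distinct(self):
        out = _compact_letter_display(
            ["a", "b", "c"], {("a", "b"), ("a", "c"), ("b", "c")}
        )
        letters = list(out.values())
        assert len(set(letters)) == 3
        assert all(len(v) == 1 for v in letters)


class TestCumulativeSummary:
    def test_single_value(self):
        cdf = cumulative_summary({"g1": 2.0}, {"g1": "a"})
        assert cdf.iloc[0].tolist() == ["a", 2.0, 1.0]

    def test_four_distinct_values(self):
        fc = {f"g{i}": float(i) for i in range(1, 5)}
        grp = {f"g{i}": "a" for i in range(1, 5)}
        cdf = cumulative_summary(fc, grp)
        assert cdf["cum_fraction"].tolist() == [0.25, 0.5, 0.75, 1.0]
        assert cdf["value"].is_monotonic_increasing

    def test_identical_groups_identical_tables(self, rng):
        vals = rng.uniform(0, 2, 15)
        fc = pd.Series(np.concatenate([vals, vals]),
                       index=[f"g{i}" for i in range(30)])
        grp = pd.Series(["a"] * 15 + ["b"] * 15, index=fc.index)
        cdf = cumulative_summary(fc, grp)
        a = cdf[cdf["group"] == "a"].drop(columns="group").reset_index(drop=True)
        b = cdf[cdf["group"] == "b"].drop(columns="group").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
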