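"""Expression normalization and P_ST."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import f_oneway

from pbs4.expression import (
    PstValue,
    filter_genes,
    fpkm,
    log_transform,
    median_ratio_size_factors,
    pst,
    pst_table,
)
from pbs4.pipeline import expression_differentiation
from pbs4.simulate import QuartetModel, simulate_expression


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 100, 4], "b": [10, 100, 4]})
        assert median_ratio_size_factors(counts).tolist() == pytest.approx([1, 1])

    def test_scale_equivariance(self):
        counts = pd.DataFrame({"a": [10, 100, 4], "b": [20, 200, 8]})
        f = median_ratio_size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)
        # exact: ratios to the geometric mean are 1/sqrt(2) and sqrt(2)
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))

    def test_zero_only_genes_ignored(self):
        counts = pd.DataFrame({"a": [10, 0, 4], "b": [20, 5, 8]})
        f = median_ratio_size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_no_all_positive_gene_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            median_ratio_size_factors(counts)


class TestFpkm:
    def test_direct_value(self):
        counts = pd.DataFrame({"s": [1000, 999000]}, index=["g1", "g2"])
        lengths = pd.Series([1000.0, 10000.0], index=["g1", "g2"])
        factors = pd.Series([1.0], index=["s"])
        out = fpkm(counts, factors, lengths)
        # N = 1e6 total counts: FPKM_g1 = 1e9 * 1000 / (1000 * 1e6) = 1000
        assert out.loc["g1", "s"] == pytest.approx(1000.0)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"s": [0, 100]}, index=["g1", "g2"])
        out = fpkm(counts, pd.Series([1.0], index=["s"]),
                   pd.Series([1000.0, 1000.0], index=["g1", "g2"]))
        assert out.loc["g1", "s"] == 0.0

    def test_doubling_length_halves_fpkm(self):
        counts = pd.DataFrame({"s": [500, 500]}, index=["g1", "g2"])
        lengths = pd.Series([1000.0, 2000.0], index=["g1", "g2"])
        out = fpkm(counts, pd.Series([1.0], index=["s"]), lengths)
        assert out.loc["g1", "s"] == pytest.approx(2 * out.loc["g2", "s"])


class TestFilterGenes:
    ann = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4"],
            "chrom": ["chr1", "chr1", "chrY", "chr1"],
            "biotype": ["protein_coding"] * 3 + ["lincRNA"],
        }
    )

    def counts(self, rows):
        return pd.DataFrame(rows, index=["g1", "g2", "g3", "g4"],
                            columns=["s1", "s2"])

    def test_default_rule_removes_only_all_low(self):
        counts = self.counts([[9, 9], [9, 50], [100, 100], [100, 100]])
        kept, removed = filter_genes(counts, self.ann)
        assert "g1" not in kept  # < 10 in every sample
        assert "g2" in kept      # one sample rescues it
        assert removed["low_expression"] == 1

    def test_sex_chromosome_and_biotype_filters(self):
        counts = self.counts([[100, 100]] * 4)
        kept, removed = filter_genes(counts, self.ann)
        assert list(kept) == ["g1", "g2"]
        assert removed["sex_chromosome"] == 1
        assert removed["non_protein_coding"] == 1

    def test_strict_any_sample_rule(self):
        counts = self.counts([[9, 9], [9, 50], [100, 100], [100, 100]])
        kept, _ = filter_genes(counts, self.ann, low_expression_rule="any")
        assert "g2" not in kept

    def test_unannotated_gene_rejected(self):
        counts = self.counts([[100, 100]] * 4)
        counts.index = ["g1", "g2", "g3", "gX"]
        with pytest.raises(ValueError, match="gX"):
            filter_genes(counts, self.ann)


def test_log_transform_is_natural_log1p():
    m = pd.DataFrame({"s": [0.0, np.e - 1, 10.0]})
    out = log_transform(m)
    assert out["s"].tolist() == pytest.approx([0.0, 1.0, np.log(11.0)])


class TestPst:
    def test_identical_populations_give_zero(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert pst(v, v, h2=1.0).pst == 0.0

    def test_formula_with_recovered_components(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 30), rng.normal(2, 1, 30)
        for h2 in (0.5, 1.0):
            r = pst(x, y, h2=h2)
            assert r.pst == pytest.approx(
                r.sigma2_between / (r.sigma2_between + 2 * h2 * r.sigma2_within)
            )
        # equal components imply 1/3 at h2=1 and 1/2 at h2=0.5
        v = 1.7
        assert v / (v + 2 * 1.0 * v) == pytest.approx(1 / 3)
        assert v / (v + 2 * 0.5 * v) == pytest.approx(1 / 2)

    def test_anova_components_match_scipy_mean_squares(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 12), rng.normal(1, 2, 20)
        r = pst(x, y, h2=1.0)
        # independent route: recover MSW from scipy's F statistic
        F = f_oneway(x, y).statistic
        n1, n2 = len(x), len(y)
        ssw = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
        msw = ssw / (n1 + n2 - 2)
        msb = F * msw
        n0 = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
        assert r.sigma2_within == pytest.approx(msw)
        assert r.sigma2_between == pytest.approx(max(0.0, (msb - msw) / n0))

    def test_lower_heritability_never_decreases_pst(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = rng.normal(0, 1, 10), rng.normal(rng.normal(), 1, 10)
            assert pst(x, y, 0.5).pst >= pst(x, y, 1.0).pst

    @settings(max_examples=30, deadline=None)
    @given(st.floats(-50, 50), st.integers(0, 2**31 - 1))
    def test_location_shift_and_relabeling_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        base = pst(x, y, 1.0).pst
        assert pst(x + shift, y + shift, 1.0).pst == pytest.approx(base, abs=1e-9)
        perm = rng.permutation(len(x))
        assert pst(x[perm], y, 1.0).pst == pytest.approx(base, abs=1e-12)

    def test_constant_expression_flagged_undefined(self):
        r = pst([3.0] * 5, [3.0] * 5, h2=1.0)
        assert not r.defined and np.isnan(r.pst)

    def test_means_method_available(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 10), rng.normal(3, 1, 10)
        r = pst(x, y, 1.0, method="means")
        assert r.sigma2_between == pytest.approx(np.var([x.mean(), y.mean()], ddof=1))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pst([1.0], [1.0, 2.0], 1.0)
        with pytest.raises(ValueError):
            pst([1.0, 2.0], [1.0, 2.0], 0.0)


class TestPstTable:
    def test_vectorized_table_matches_scalar_pst(self):
        model = QuartetModel(sample_sizes={p: 6 for p in "WXYZ"})
        se = simulate_expression(model, 10, seed=3)
        table = expression_differentiation(se)
        logf = log_transform(
            fpkm(se.counts, median_ratio_size_factors(se.counts), se.gene_lengths)
        )
        row = table[(table["gene"] == "gene00002") & (table["pop_a"] == "W")
                    & (table["pop_b"] == "Y") & (table["h2"] == 0.5)].iloc[0]
        cols_w = [s for s in logf.columns if se.sample_map[s] == "W"]
        cols_y = [s for s in logf.columns if se.sample_map[s] == "Y"]
        ref = pst(logf.loc["gene00002", cols_w], logf.loc["gene00002", cols_y], 0.5)
        assert row["pst"] == pytest.approx(ref.pst)

    def test_null_pst_is_small_at_realistic_sample_size(self):
        # no population shifts, n = 90 per population (cohort-scale)
        model = QuartetModel(sample_sizes={p: 90 for p in "WXYZ"})
        se = simulate_expression(model, 300, seed=17)
        table = expression_differentiation(se, h2_values=(1.0,))
        assert table["pst"].median() < 0.1

    def test_shifted_gene_tops_pairwise_ranking(self):
        model = QuartetModel(sample_sizes={p: 90 for p in "WXYZ"})
        se = simulate_expression(
            model, 200, shift_spec={"gene00007": {"W": 4.0}}, seed=23
        )
        table = expression_differentiation(se, h2_values=(1.0,))
        wx = table[(table["pop_a"] == "W") & (table["pop_b"] == "X")]
        top = wx.sort_values("pst", ascending=False).iloc[0]
        assert top["gene"] == "gene00007"
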