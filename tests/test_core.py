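"""Expression containers, thresholding, medians and Pearson correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tissueproxy.core import (
    DEFAULT_THRESHOLD,
    ExpressionMatrix,
    ExpressionThreshold,
    GeneSet,
    SampleMatrix,
    correlate_tissues,
    filter_expressed,
    gene_profile,
    median_per_tissue,
    pearson_r,
    saturation_scatter,
)

finite_floats = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


class TestThresholdAndGeneSet:
    def test_default_is_tpm_ge_1_5(self):
        assert DEFAULT_THRESHOLD.value == 1.5
        assert DEFAULT_THRESHOLD.comparator == "ge"
        assert DEFAULT_THRESHOLD.passes([1.5]).all()  # boundary inclusive
        assert not ExpressionThreshold(1.5, "gt").passes([1.5]).any()

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
    def test_threshold_must_be_positive_finite(self, bad):
        with pytest.raises(ValueError):
            ExpressionThreshold(bad)

    def test_gene_set_rejects_empty_and_duplicates(self):
        with pytest.raises(ValueError):
            GeneSet("x", ())
        with pytest.raises(ValueError):
            GeneSet("x", ("a", "a"))
        gs = GeneSet.from_iterable("x", ["a", "b", "a"])
        assert gs.genes == ("a", "b")


class TestMatrixValidation:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(pd.DataFrame({"t": [-1.0]}, index=["g"]))
        with pytest.raises(ValueError):
            ExpressionMatrix(pd.DataFrame({"t": [math.nan]}, index=["g"]))

    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["g", "g"], columns=["t"])
        with pytest.raises(ValueError, match="duplicate feature"):
            ExpressionMatrix(df)

    def test_transcript_level_requires_mapping(self):
        df = pd.DataFrame({"t": [1.0]}, index=["tx1"])
        with pytest.raises(ValueError, match="feature_to_gene"):
            ExpressionMatrix(df, level="transcript")
        m = ExpressionMatrix(df, level="transcript", feature_to_gene={"tx1": "g1"})
        assert m.feature_to_gene["tx1"] == "g1"

    def test_unmapped_sample_is_named(self):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        with pytest.raises(ValueError, match="s2"):
            SampleMatrix(df, {"s1": "A"})


class TestMedianPerTissue:
    def test_singleton_samples_pass_through(self):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, index=["g1", "g2"])
        m = median_per_tissue(SampleMatrix(df, {"s1": "A", "s2": "B"}))
        assert m.df.loc["g1", "A"] == 1.0 and m.df.loc["g2", "B"] == 4.0

    @pytest.mark.parametrize(
        "values,expected",
        [((1.0, 2.0, 9.0), 2.0), ((1.0, 3.0), 2.0)],  # odd count; even = mid-pair mean
    )
    def test_median_examples(self, values, expected):
        df = pd.DataFrame([list(values)], index=["g"], columns=[f"s{i}" for i in range(len(values))])
        sm = SampleMatrix(df, {f"s{i}": "T" for i in range(len(values))})
        assert median_per_tissue(sm).df.loc["g", "T"] == expected

    def test_sample_order_invariance(self, toy_samples):
        ref = median_per_tissue(toy_samples).df
        perm = toy_samples.df[["b2", "a3", "a1", "b1", "a2"]]
        shuffled = SampleMatrix(perm, toy_samples.sample_to_tissue)
        pd.testing.assert_frame_equal(median_per_tissue(shuffled).df, ref, check_like=True)

    def test_empty_matrix_rejected(self):
        sm = SampleMatrix(pd.DataFrame(index=[], columns=[]), {})
        with pytest.raises(ValueError):
            median_per_tissue(sm)


class TestFilterExpressed:
    def test_counts_and_boundary(self, toy_matrix):
        # heart column: 10, 2, 0.2, 5, 1.5 -> the 1.5 value is included under >=
        assert filter_expressed(toy_matrix, "heart") == {"g1", "g2", "g4", "g5"}
        assert filter_expressed(toy_matrix, "heart", ExpressionThreshold(1.5, "gt")) == {
            "g1", "g2", "g4",
        }

    def test_all_zero_gives_empty_set(self):
        m = ExpressionMatrix(pd.DataFrame({"t": [0.0, 0.0]}, index=["a", "b"]))
        assert filter_expressed(m, "t") == set()

    def test_unknown_tissue_lists_available(self, toy_matrix):
        with pytest.raises(KeyError, match="heart"):
            filter_expressed(toy_matrix, "kidney")

    @given(cut1=st.floats(0.1, 50), cut2=st.floats(0.1, 50))
    @settings(max_examples=50, deadline=None)
    def test_raising_cutoff_never_adds_features(self, cut1, cut2):
        m = ExpressionMatrix(
            pd.DataFrame({"t": [0.0, 0.3, 1.5, 2.0, 7.0, 49.0]}, index=list("abcdef"))
        )
        lo, hi = sorted((cut1, cut2))
        assert filter_expressed(m, "t", ExpressionThreshold(hi)) <= filter_expressed(
            m, "t", ExpressionThreshold(lo)
        )


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 5, 9), (1, 5, 9), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3), (1, 3, 2), 0.5),
        ],
    )
    def test_hand_computed_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_undefined_flags_not_exceptions(self):
        assert math.isnan(pearson_r([1, 1, 1], [1, 2, 3]))  # zero variance
        assert math.isnan(pearson_r([1, 2], [3, 4]))  # too short

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])

    @given(st.lists(finite_floats, min_size=3, max_size=30), st.data())
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_bounds(self, xs, data):
        ys = data.draw(st.lists(finite_floats, min_size=len(xs), max_size=len(xs)))
        r = pearson_r(xs, ys)
        assert pearson_r(ys, xs) == r or (math.isnan(r) and math.isnan(pearson_r(ys, xs)))
        if not math.isnan(r):
            assert abs(r) <= 1 + 1e-12

    @given(
        st.lists(finite_floats, min_size=3, max_size=30),
        st.floats(min_value=-100, max_value=100).filter(lambda a: abs(a) > 1e-6),
        st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_images_correlate_perfectly(self, xs, a, b):
        x = np.asarray(xs)
        if np.ptp(x) < 1e-100:  # spread too small: variance underflows
            return
        r = pearson_r(x, a * x + b)
        assert r == pytest.approx(math.copysign(1.0, a), abs=1e-9)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(3, 80)
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)


class TestCorrelateTissues:
    def test_duplicated_column_gives_r_one(self, all_genes):
        df = pd.DataFrame({"ti": [2.0, 3.0, 8.0, 1.7, 5.0]}, index=all_genes.genes)
        df["ta"] = df["ti"]
        res = correlate_tissues(ExpressionMatrix(df), "ti", "ta", all_genes)
        assert res.r == 1.0 and res.defined

    def test_disjoint_gene_set_is_flagged_undefined(self, toy_matrix):
        genes = GeneSet.from_iterable("none", ["x1", "x2", "x3"])
        with pytest.warns(UserWarning, match="qualifying genes"):
            res = correlate_tissues(toy_matrix, "heart", "muscle", genes)
        assert not res.defined and res.n_genes == 0

    def test_equals_manual_filtered_pearson(self, toy_matrix, all_genes):
        res = correlate_tissues(toy_matrix, "heart", "muscle", all_genes)
        # either_tissue at >=1.5 keeps g1, g2, g4, g5 (g3 is silent in both)
        x = [10.0, 2.0, 5.0, 1.5]
        y = [8.0, 3.0, 4.0, 2.5]
        assert res.n_genes == 4
        assert res.r == pytest.approx(pearson_r(x, y), abs=1e-15)

    def test_selection_rules_differ(self, toy_matrix, all_genes):
        both = correlate_tissues(toy_matrix, "heart", "muscle", all_genes, rule="both_tissues")
        ti_only = correlate_tissues(toy_matrix, "heart", "muscle", all_genes, rule="ti_only")
        assert both.n_genes == 4 and ti_only.n_genes == 4
        with pytest.warns(UserWarning):
            blood = correlate_tissues(toy_matrix, "heart", "blood", all_genes, rule="both_tissues")
        assert blood.n_genes == 0

    def test_same_tissue_rejected(self, toy_matrix, all_genes):
        with pytest.raises(ValueError, match="differ"):
            correlate_tissues(toy_matrix, "heart", "heart", all_genes)


class TestGeneProfile:
    def test_summary_statistics(self, toy_samples):
        prof = gene_profile(toy_samples, "g1")
        a = next(s for s in prof.per_tissue if s.tissue == "A")
        assert a.n_samples == 3 and a.median == 2.0
        assert a.standard_deviation == pytest.approx(np.std([1, 2, 9], ddof=1))
        g2 = gene_profile(toy_samples, "g2")
        assert next(s for s in g2.per_tissue if s.tissue == "A").standard_deviation == 0.0

    def test_sd_of_identical_and_unit_spaced_values(self):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0], "u1": [7.0]}, index=["g"])
        sm = SampleMatrix(df, {"s1": "T", "s2": "T", "s3": "T", "u1": "U"})
        prof = gene_profile(sm, "g")
        t = next(s for s in prof.per_tissue if s.tissue == "T")
        u = next(s for s in prof.per_tissue if s.tissue == "U")
        assert t.standard_deviation == 1.0
        assert math.isnan(u.standard_deviation)  # single sample: SD undefined

    def test_unknown_gene(self, toy_samples):
        with pytest.raises(KeyError):
            gene_profile(toy_samples, "nope")


class TestSaturation:
    def test_counts_match_brute_force(self, toy_samples):
        table = saturation_scatter(toy_samples)
        medians = median_per_tissue(toy_samples)
        for _, row in table.iterrows():
            brute = sum(
                1
                for g in medians.feature_ids
                if medians.df.loc[g, row["tissue"]] >= 1.5
            )
            assert row["n_expressed_genes"] == brute
        assert set(table["tissue"]) == {"A", "B"}

    def test_identical_tissues_identical_counts(self):
        df = pd.DataFrame(
            {"s1": [2.0, 0.1], "s2": [2.0, 0.1]}, index=["g1", "g2"]
        )
        sm = SampleMatrix(df, {"s1": "A", "s2": "B"})
        table = saturation_scatter(sm).set_index("tissue")
        assert table.loc["A", "n_expressed_genes"] == table.loc["B", "n_expressed_genes"] == 1

    def test_all_below_cutoff_counts_zero(self):
        df = pd.DataFrame({"s1": [0.1, 0.2]}, index=["g1", "g2"])
        table = saturation_scatter(SampleMatrix(df, {"s1": "A"}))
        assert table["n_expressed_genes"].tolist() == [0]
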