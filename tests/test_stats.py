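"""Profile statistics: comparison, delta, normalization, identity, series."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dmsprof as dp
from dmsprof.errors import InsufficientDataError, ValidationError
from dmsprof.selection import make_view


def view_from(fractions, sample="s", bases=None, reference="r"):
    """Build a ProfileView carrying the given fractions (NaN = masked)."""
    fractions = np.asarray(fractions, dtype=float)
    n = len(fractions)
    sec = dp.SectionAnnotation("full", "full", 1, n)
    if bases is None:
        bases = ["A"] * n
    cov = np.where(np.isfinite(fractions), 10000, 0)
    prof = dp.PositionProfile(reference, sec, np.arange(1, n + 1), bases, cov,
                              np.zeros(n, dtype=int))
    view = make_view(prof, sample, bases="ACGT")
    return view.with_fraction(fractions)


def oracle_compare(x, y):
    """Independent direct-summation implementation of the paired statistics."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    r = sxy / (sxx * syy) ** 0.5
    slope = sxy / sxx
    intercept = my - slope * mx
    rmse = (sum((yi - xi) ** 2 for xi, yi in zip(x, y)) / n) ** 0.5
    return r, r * r, rmse, slope, intercept


class TestCompareProfiles:
    def test_identity(self):
        v = view_from([0.01, 0.05, 0.03, 0.08])
        res = dp.compare_profiles(v, v)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.rmse == 0.0
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.n == 4

    def test_perfect_anticorrelation(self):
        v1 = view_from([0.04, 0.03, 0.02, 0.01])
        v2 = view_from([0.01, 0.02, 0.03, 0.04])
        assert dp.compare_profiles(v1, v2).pearson_r == pytest.approx(-1.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 0.1, size=6)
        y = 0.8 * x + rng.normal(0, 0.005, size=6)
        res = dp.compare_profiles(view_from(y, "a"), view_from(x, "b"))
        r, r2, rmse, slope, intercept = oracle_compare(list(x), list(y))
        assert res.pearson_r == pytest.approx(r, rel=1e-12)
        assert res.rmse == pytest.approx(rmse, rel=1e-12)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-12)

    def test_matches_scipy_linregress(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        x = rng.uniform(0, 0.1, 20)
        y = rng.uniform(0, 0.1, 20)
        res = dp.compare_profiles(view_from(y, "a"), view_from(x, "b"))
        fit = sps.linregress(x, y)
        assert res.pearson_r == pytest.approx(fit.rvalue, rel=1e-12)
        assert res.slope == pytest.approx(fit.slope, rel=1e-12)
        assert res.intercept == pytest.approx(fit.intercept, rel=1e-10)

    def test_statistics_use_only_shared_unmasked_positions(self):
        v1 = view_from([0.01, np.nan, 0.03, 0.05])
        v2 = view_from([0.02, 0.02, np.nan, 0.04])
        res = dp.compare_profiles(v1, v2)
        assert res.n == 2
        assert list(res.pairs["position"]) == [1, 4]

    def test_r_and_rmse_symmetric_under_swap(self):
        v1 = view_from([0.01, 0.04, 0.02, 0.09])
        v2 = view_from([0.03, 0.01, 0.05, 0.06])
        a = dp.compare_profiles(v1, v2)
        b = dp.compare_profiles(v2, v1)
        assert a.pearson_r == pytest.approx(b.pearson_r)
        assert a.rmse == pytest.approx(b.rmse)

    def test_too_few_shared_positions(self):
        v1 = view_from([0.01, np.nan])
        v2 = view_from([0.02, 0.02])
        with pytest.raises(InsufficientDataError):
            dp.compare_profiles(v1, v2)

    def test_degenerate_variance_masked_with_reason(self):
        v1 = view_from([0.02, 0.02, 0.02])
        v2 = view_from([0.01, 0.03, 0.05])
        res = dp.compare_profiles(v1, v2)
        assert np.isnan(res.pearson_r) and res.reason == "degenerate-variance"

    def test_mismatched_references_rejected(self):
        v1 = view_from([0.01, 0.02], reference="a")
        v2 = view_from([0.01, 0.02], reference="b")
        with pytest.raises(ValidationError):
            dp.compare_profiles(v1, v2)

    @given(
        scale=st.floats(0.1, 5.0),
        offset=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=25, deadline=None)
    def test_r_invariant_under_positive_affine_transform(self, scale, offset):
        x = np.array([0.01, 0.05, 0.02, 0.08, 0.03, 0.06])
        y = np.array([0.02, 0.04, 0.01, 0.09, 0.05, 0.03])
        base = dp.compare_profiles(view_from(y), view_from(x))
        moved = dp.compare_profiles(view_from(y), view_from(scale * x + offset))
        assert moved.pearson_r == pytest.approx(base.pearson_r, rel=1e-9)

    def test_rmse_translation_equivariant(self):
        x = np.array([0.01, 0.05, 0.02, 0.08])
        y = np.array([0.02, 0.04, 0.01, 0.09])
        base = dp.compare_profiles(view_from(y), view_from(x)).rmse
        shifted = dp.compare_profiles(view_from(y + 0.1), view_from(x + 0.1)).rmse
        assert shifted == pytest.approx(base, rel=1e-12)


class TestDeltaProfile:
    def test_identical_profiles_all_zero(self):
        v = view_from([0.01, 0.02, 0.03])
        assert np.allclose(dp.delta_profile(v, v).delta, 0.0)

    def test_example_values(self):
        d = dp.delta_profile(view_from([0.05, 0.01]), view_from([0.02, 0.03]))
        assert np.allclose(d.delta, [0.03, -0.02])

    def test_mask_propagates(self):
        d = dp.delta_profile(view_from([0.05, 0.01]), view_from([0.02, np.nan]))
        assert np.isfinite(d.delta[0]) and np.isnan(d.delta[1])

    def test_antisymmetry(self):
        v1 = view_from([0.05, 0.01, np.nan])
        v2 = view_from([0.02, 0.03, 0.01])
        d12 = dp.delta_profile(v1, v2).delta
        d21 = dp.delta_profile(v2, v1).delta
        assert np.array_equal(d12, -d21, equal_nan=True)

    def test_csv_frame_drops_masked_rows(self):
        d = dp.delta_profile(view_from([0.05, np.nan]), view_from([0.02, 0.03]))
        frame = d.to_frame()
        assert list(frame.columns) == ["position", "base", "delta"]
        assert len(frame) == 1


class TestNormalization:
    def test_double_profile_halved(self):
        v1 = view_from([0.01, 0.02, 0.03])
        v2 = view_from([0.02, 0.04, 0.06])
        res = dp.normalize_profiles(v1, v2)
        assert res.factor == pytest.approx(0.5)
        assert np.allclose(res.normalized.fraction, v1.fraction)

    def test_identical_profiles_factor_one(self):
        v = view_from([0.01, 0.02, 0.03])
        assert dp.normalize_profiles(v, v).factor == pytest.approx(1.0)

    def test_factor_matches_direct_summation(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 0.1, 10)
        y = rng.uniform(0.01, 0.1, 10)
        res = dp.normalize_profiles(view_from(x), view_from(y))
        expected = sum(a * b for a, b in zip(x, y)) / sum(b * b for b in y)
        assert res.factor == pytest.approx(expected, rel=1e-12)

    def test_ls_origin_minimizes_residual(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            x = rng.uniform(0, 0.1, 12)
            y = rng.uniform(0.01, 0.1, 12)
            k = dp.normalize_profiles(view_from(x), view_from(y)).factor

            def residual(kk):
                return float(np.sum((x - kk * y) ** 2))

            assert residual(k) <= residual(k * 1.01) + 1e-15
            assert residual(k) <= residual(k * 0.99) + 1e-15

    def test_median_ratio_method(self):
        v1 = view_from([0.02, 0.04, 0.09])
        v2 = view_from([0.01, 0.02, 0.03])
        res = dp.normalize_profiles(v1, v2, method="median_ratio")
        assert res.factor == pytest.approx(2.0)

    def test_all_zero_sample2_undefined(self):
        v1 = view_from([0.01, 0.02])
        v2 = view_from([0.0, 0.0])
        with pytest.raises(ValidationError, match="undefined"):
            dp.normalize_profiles(v1, v2)

    def test_clipping_counted_and_warned(self):
        # median-ratio factor 1.75 pushes the second scaled fraction past 1
        v1 = view_from([0.5, 0.9])
        v2 = view_from([0.25, 0.6])
        with pytest.warns(UserWarning, match="clipped"):
            res = dp.normalize_profiles(v1, v2, method="median_ratio")
        assert res.n_clipped == 1
        assert np.nanmax(res.normalized.fraction) <= 1.0


class TestFractionIdentity:
    def test_example_stack(self):
        sec = dp.SectionAnnotation("full", "full", 1, 1)
        prof = dp.PositionProfile(
            "r", sec, [1], ["G"], [100], [11],
            sub_counts={"A": [2], "C": [0], "T": [3], "G": [5]},
        )
        frame = dp.fraction_identity(prof)
        assert frame.loc[0, "frac_to_A"] == pytest.approx(0.02)
        assert frame.loc[0, "frac_to_C"] == 0.0
        assert frame.loc[0, "frac_to_T"] == pytest.approx(0.03)
        assert frame.loc[0, "frac_to_G"] == pytest.approx(0.05)

    def test_all_zero_sub_counts(self):
        sec = dp.SectionAnnotation("full", "full", 1, 2)
        prof = dp.PositionProfile(
            "r", sec, [1, 2], ["A", "C"], [100, 100], [0, 0],
            sub_counts={b: [0, 0] for b in "ACGT"},
        )
        frame = dp.fraction_identity(prof)
        assert (frame[[f"frac_to_{b}" for b in "ACGT"]].to_numpy() == 0).all()

    def test_stack_bounded_by_mutation_fraction_on_simulation(self, sim_study):
        for (ref, sec), prof in sim_study.samples["rep1"].profiles.items():
            frame = dp.fraction_identity(prof)
            stack = frame[[f"frac_to_{b}" for b in "ACGT"]].sum(axis=1).to_numpy()
            ok = np.isfinite(prof.fraction)
            assert np.all(stack[ok] <= prof.fraction[ok] + 1e-12)


class TestVariableSeries:
    def test_three_samples_sorted_ascending(self, golden_study):
        import copy

        study = copy.deepcopy(golden_study)
        # add a third Mg concentration out of order
        rec = copy.deepcopy(study.samples["s0"])
        rec.sample = "s1"
        rec.variables = {"MgCl2": {"value": 1.0, "unit": "mM"}}
        study.samples["s1"] = rec
        series = dp.variable_series(study, "ref1", 7, "MgCl2")
        assert list(series["value"]) == [0.0, 1.0, 10.0]

    def test_single_sample_series(self, golden_study):
        series = dp.variable_series(
            golden_study, "ref1", 7, "MgCl2", samples=["s0"]
        )
        assert len(series) == 1

    def test_samples_without_variable_excluded_with_warning(self, golden_study):
        import copy

        study = copy.deepcopy(golden_study)
        study.samples["s10"].variables = {}
        with pytest.warns(UserWarning, match="excluded"):
            series = dp.variable_series(study, "ref1", 7, "MgCl2")
        assert list(series["sample"]) == ["s0"]


class TestHistograms:
    def test_mutations_per_read_example(self):
        hist = dp.mutations_per_read_histogram([0, 0, 1, 2], bin_width=1)
        assert hist.counts[0] == 2 and hist.counts[1] == 1 and hist.counts[2] == 1
        assert hist.total_reads == 4

    def test_empty_input_all_zero_bins(self):
        hist = dp.mutations_per_read_histogram([])
        assert hist.total_reads == 0 and hist.counts.sum() == 0

    def test_overflow_bin_collects_large_counts(self):
        hist = dp.mutations_per_read_histogram([3, 25, 11], cap=10)
        assert hist.counts[-1] == 2  # 25 and 11 both >= cap
        assert hist.counts.sum() == 3

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(8)
        reads = rng.poisson(2.0, size=10000)
        hist = dp.mutations_per_read_histogram(reads, cap=10)
        for k in range(10):
            assert hist.counts[k] == int(np.sum(reads == k))
        assert hist.counts[-1] == int(np.sum(reads >= 10))

    def test_reads_per_reference_single_bin(self):
        rec = dp.SampleRecord(sample="s", aligned_reads={"r1": 10, "r2": 10})
        counts, edges = dp.reads_per_reference_distribution(rec, n_bins=1)
        assert list(counts) == [2]

    def test_reads_per_reference_empty(self):
        rec = dp.SampleRecord(sample="s")
        counts, edges = dp.reads_per_reference_distribution(rec)
        assert len(counts) == 0

    def test_reads_per_reference_sums_to_reference_count(self, sim_study):
        counts, _ = dp.reads_per_reference_distribution(sim_study.samples["rep1"])
        assert counts.sum() == len(sim_study.samples["rep1"].aligned_reads)
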