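import itertools
import math

import numpy as np
import pandas as pd
import pytest

from turnover_aging import comparison as cmp
from turnover_aging.errors import ComparisonError, DataError
from turnover_aging.kinetics import KineticRate, protein_heavy_fraction
from turnover_aging.synthetic import (
    CohortConfig,
    EffectSpec,
    generate_truth,
    simulate_observations,
    truth_halflives,
)

LN2 = math.log(2)


def series(values, prefix="P"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


class TestMedianRescale:
    def test_pure_scaling(self):
        young = series([2.0, 5.0, 9.0, 14.0, 3.0, 7.0, 8.0, 11.0, 6.0, 4.0])
        aged = young * 1.25
        res = cmp.median_rescale(aged, young)
        assert res.factor == pytest.approx(0.25, abs=1e-12)
        assert res.percent == pytest.approx(25.0, abs=1e-9)
        fc = cmp.compute_log2fc(res.rescaled, young)
        np.testing.assert_allclose(fc, 0.0, atol=1e-12)

    def test_identity(self):
        young = series(np.linspace(1, 20, 15))
        res = cmp.median_rescale(young, young)
        assert res.factor == pytest.approx(0.0, abs=1e-15)

    def test_rescaled_median_ratio_is_one(self):
        rng = np.random.default_rng(0)
        young = series(rng.lognormal(2, 0.4, 101))
        aged = young * rng.lognormal(0.2, 0.3, 101)
        res = cmp.median_rescale(aged, young)
        assert (res.rescaled / young).median() == pytest.approx(1.0, abs=1e-12)

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        young = series(rng.lognormal(2, 0.4, 50))
        aged = young * rng.lognormal(0.2, 0.3, 50)
        first = cmp.median_rescale(aged, young)
        second = cmp.median_rescale(first.rescaled, young)
        assert second.factor == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_overlap(self):
        with pytest.raises(ComparisonError):
            cmp.median_rescale(series([1.0] * 5), series([1.0] * 5))

    def test_truth_level_global_factor_recovery(self):
        cfg = CohortConfig(n_proteins=2001, seed=13)
        truth = generate_truth(cfg)
        res = cmp.median_rescale(truth_halflives(truth, "aged", "cortex_hom"),
                                 truth_halflives(truth, "young", "cortex_hom"))
        assert res.percent == pytest.approx(21.7, abs=1e-9)


class TestLog2fc:
    def test_trivials(self):
        young = series([4.0] * 12)
        assert cmp.compute_log2fc(young, young).eq(0).all()
        assert cmp.compute_log2fc(young * 2, young).eq(1).all()

    def test_median_zero_after_rescale(self):
        rng = np.random.default_rng(3)
        young = series(rng.lognormal(2, 0.4, 201))
        aged = young * rng.lognormal(0.2, 0.3, 201)
        res = cmp.median_rescale(aged, young)
        fc = cmp.compute_log2fc(res.rescaled, young)
        assert fc.median() == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            cmp.compute_log2fc(series([1.0, -1.0]), series([1.0, 1.0]))


def brute_force_consistency(signs, min_consistent=3):
    """Independent enumeration of the 3-of-4 same-direction rule."""
    n_inc = sum(1 for s in signs if s == "+")
    n_dec = sum(1 for s in signs if s == "-")
    if n_inc >= min_consistent:
        return "+"
    if n_dec >= min_consistent:
        return "-"
    return None


class TestConsistencyFilter:
    def frame(self, signs):
        values = {"+": 0.5, "-": -0.5, "0": 0.0}
        return pd.DataFrame({f"ds{j}": [values[s]] for j, s in enumerate(signs)},
                            index=["P0"])

    def test_three_of_four_retained(self):
        out = cmp.consistency_filter(self.frame("+++-"))
        assert list(out.index) == ["P0"] and out.at["P0", "direction"] == 1

    def test_two_two_excluded(self):
        assert cmp.consistency_filter(self.frame("++--")).empty

    def test_exhaustive_81_sign_patterns(self):
        for signs in itertools.product("+-0", repeat=4):
            out = cmp.consistency_filter(self.frame(signs))
            expected = brute_force_consistency(signs)
            if expected is None:
                assert out.empty, signs
            else:
                assert list(out.index) == ["P0"], signs
                assert out.at["P0", "direction"] == (1 if expected == "+" else -1), signs

    def test_mean_over_all_measured_datasets(self):
        fc = pd.DataFrame({"a": [0.5], "b": [0.4], "c": [0.3], "d": [-0.2]}, index=["P0"])
        out = cmp.consistency_filter(fc)
        assert out.at["P0", "mean_log2fc"] == pytest.approx(0.25)
        assert out.at["P0", "n_datasets_measured"] == 4
        sem = np.std([0.5, 0.4, 0.3, -0.2], ddof=1) / 2
        assert out.at["P0", "sem_log2fc"] == pytest.approx(sem)

    def test_missing_datasets_counted(self):
        fc = pd.DataFrame({"a": [0.5], "b": [0.4], "c": [0.3], "d": [np.nan]}, index=["P0"])
        out = cmp.consistency_filter(fc)
        assert out.at["P0", "n_datasets_measured"] == 3
        assert out.at["P0", "n_increase"] + out.at["P0", "n_decrease"] <= 3


class TestTopExtremes:
    def consistent_frame(self, values, index=None):
        idx = index or [f"P{i}" for i in range(len(values))]
        return pd.DataFrame({"mean_log2fc": values}, index=idx)

    def test_truth_recovery(self):
        cfg = CohortConfig(n_proteins=400, seed=17,
                           effect_spec=EffectSpec(n_rll=25, n_rsl=25, extra_factor=1.5))
        truth = generate_truth(cfg)
        aged = {ds: truth_halflives(truth, "aged", ds) for ds in
                ("cortex_hom", "cerebellum_hom", "cortex_syn", "cerebellum_syn")}
        young = {ds: truth_halflives(truth, "young", ds) for ds in aged}
        log2fc, _ = cmp.build_log2fc_table(aged, young)
        consistent = cmp.consistency_filter(log2fc)
        rll, rsl = cmp.top_extremes(consistent, k=25)
        truth = truth.set_index("protein_id")
        assert set(rll) == set(truth.index[truth.effect_label == "rll"])
        assert set(rsl) == set(truth.index[truth.effect_label == "rsl"])

    def test_k_zero(self):
        assert cmp.top_extremes(self.consistent_frame([0.1, 0.2]), k=0) == ([], [])

    def test_tie_broken_by_id(self):
        frame = self.consistent_frame([0.5, 0.5, -0.5, -0.5], ["Pb", "Pa", "Pd", "Pc"])
        rll, rsl = cmp.top_extremes(frame, k=1)
        assert rsl == ["Pc"]  # lexicographically first among tied minima
        assert rll == ["Pb"]

    def test_fewer_than_k_warns(self):
        with pytest.warns(UserWarning):
            rll, rsl = cmp.top_extremes(self.consistent_frame([0.1, -0.1]), k=5)
        assert len(rll) == 2 and len(rsl) == 2


class TestPercentileGroups:
    def test_1_to_100(self):
        groups = cmp.percentile_groups(series(np.arange(1.0, 101.0)))
        counts = groups.value_counts()
        assert counts.get("rSL", 0) == 24
        assert counts.get("rLL", 0) == 24
        assert counts.get("middle", 0) == 29

    def test_all_equal_unassigned(self):
        groups = cmp.percentile_groups(series([5.0] * 20))
        assert (groups == "unassigned").all()

    def test_eight_values(self):
        groups = cmp.percentile_groups(series(np.arange(1.0, 9.0)))
        assert list(groups[groups == "rSL"].index) == ["P0"]
        assert list(groups[groups == "rLL"].index) == ["P7"]

    def test_bands_ordered(self):
        rng = np.random.default_rng(5)
        values = series(rng.normal(size=500))
        groups = cmp.percentile_groups(values)
        assert values[groups == "rSL"].max() < values[groups == "middle"].min()
        assert values[groups == "middle"].max() < values[groups == "rLL"].min()

    def test_too_few_values(self):
        with pytest.raises(ComparisonError):
            cmp.percentile_groups(series([1.0] * 7))


class TestZscoreMatrix:
    def test_unit_spaced_row(self):
        z = cmp.zscore_matrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["P0"]))
        np.testing.assert_allclose(z.loc["P0"], [-1, 0, 1])

    def test_complete_rows_standardized(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(5, 2, size=(10, 4)))
        z = cmp.zscore_matrix(df)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, rtol=1e-12)

    def test_missing_preserved(self):
        df = pd.DataFrame([[2.0, np.nan, 4.0]], index=["P0"])
        z = cmp.zscore_matrix(df)
        assert np.isnan(z.iloc[0, 1])
        np.testing.assert_allclose(z.iloc[0, [0, 2]],
                                   [-1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_zero_sd_row_warns(self):
        with pytest.warns(UserWarning):
            z = cmp.zscore_matrix(pd.DataFrame([[3.0, 3.0, 3.0]]))
        np.testing.assert_array_equal(z.iloc[0], [0, 0, 0])

    def test_single_value_row_rejected(self):
        with pytest.raises(ComparisonError):
            cmp.zscore_matrix(pd.DataFrame([[1.0, np.nan, np.nan]]))


def truth_mean_log2fc(truth, dataset="cortex_hom"):
    aged = truth_halflives(truth, "aged", dataset)
    young = truth_halflives(truth, "young", dataset)
    res = cmp.median_rescale(aged, young)
    fc = cmp.compute_log2fc(res.rescaled, young)
    mean_life = (aged + young) / 2
    return fc, mean_life


class TestLifetimeCompression:
    def test_injected_compression_signature(self):
        cfg = CohortConfig(n_proteins=500, seed=31,
                           effect_spec=EffectSpec(compression_slope=0.3))
        fc, life = truth_mean_log2fc(generate_truth(cfg))
        rep = cmp.lifetime_compression(fc, life)
        assert rep.pearson_r < 0
        assert rep.tertile_mean_log2fc["short"] > 0
        assert rep.tertile_mean_log2fc["long"] < 0

    def test_pure_scaling_null_reports_zero(self):
        cfg = CohortConfig(n_proteins=500, seed=32)
        fc, life = truth_mean_log2fc(generate_truth(cfg))
        rep = cmp.lifetime_compression(fc, life)
        assert abs(rep.pearson_r) < 1e-6
        assert rep.degenerate

    def test_noise_artifact_and_its_mitigation(self):
        # measurement noise alone induces regression to the mean when the
        # log2FC is correlated against a single cohort's noisy lifetimes;
        # averaging the two cohorts cancels that artifact to first order
        cfg = CohortConfig(n_proteins=800, seed=33)
        truth = generate_truth(cfg)
        rng = np.random.default_rng(0)
        aged = truth_halflives(truth, "aged", "cortex_hom") * rng.lognormal(0, 0.1, 800)
        young = truth_halflives(truth, "young", "cortex_hom") * rng.lognormal(0, 0.1, 800)
        res = cmp.median_rescale(aged, young)
        fc = cmp.compute_log2fc(res.rescaled, young)
        artifact = cmp.lifetime_compression(fc, young)
        assert artifact.pearson_r < -0.03
        mitigated = cmp.lifetime_compression(fc, (aged + young) / 2)
        assert abs(mitigated.pearson_r) < 0.03

    def test_min_n(self):
        with pytest.raises(ComparisonError):
            cmp.lifetime_compression(series([0.1] * 10), series(np.arange(10.0)))


def observed_fractions(truth, cfg, cohort, dataset="cortex_hom"):
    """Replicate-mean observed fractions per protein x pulse time."""
    tables, _ = simulate_observations(truth, cfg)
    df = tables[(cohort, dataset)]
    df = df[~df["Protein IDs"].str.startswith(("REV__", "CON__", "SITEONLY"))]
    out = {}
    for t in (14.0, 21.0):
        cols = [c for c in df.columns if c.startswith("Ratio") and f"_d{t:g}_" in c]
        ratios = df[cols].to_numpy(dtype=float)
        out[t] = np.nanmean(ratios / (1 + ratios), axis=1)
    return pd.DataFrame(out, index=df["Protein IDs"].to_numpy())


class TestRawRatioCheck:
    def test_identical_cohorts_flag_false(self):
        idx = [f"P{i}" for i in range(60)]
        frac = pd.DataFrame({14.0: np.linspace(0.2, 0.8, 60),
                             21.0: np.linspace(0.3, 0.9, 60)}, index=idx)
        tert = cmp.lifetime_tertiles(pd.Series(np.linspace(1, 60, 60), index=idx))
        rep = cmp.raw_ratio_check(frac, frac.copy(), tert)
        assert not rep.bidirectional
        assert (rep.median_diff.fillna(0) == 0).all().all()

    def test_true_compression_flagged(self):
        cfg = CohortConfig(n_proteins=300, seed=41, ratio_noise_cv=0.0,
                           effect_spec=EffectSpec(compression_slope=0.3))
        truth = generate_truth(cfg)
        aged_f = observed_fractions(truth, cfg, "aged").set_axis(truth["protein_id"])
        young_f = observed_fractions(truth, cfg, "young").set_axis(truth["protein_id"])
        life = (truth_halflives(truth, "aged", "cortex_hom")
                + truth_halflives(truth, "young", "cortex_hom")) / 2
        rep = cmp.raw_ratio_check(aged_f, young_f, cmp.lifetime_tertiles(life))
        assert rep.bidirectional
        assert rep.median_diff.at["short", 14.0] < 0
        assert rep.median_diff.at["long", 14.0] > 0

    def test_global_slowdown_not_flagged(self):
        cfg = CohortConfig(n_proteins=300, seed=42, ratio_noise_cv=0.10)
        truth = generate_truth(cfg)
        aged_f = observed_fractions(truth, cfg, "aged")
        young_f = observed_fractions(truth, cfg, "young")
        life = (truth_halflives(truth, "aged", "cortex_hom")
                + truth_halflives(truth, "young", "cortex_hom")) / 2
        rep = cmp.raw_ratio_check(aged_f, young_f, cmp.lifetime_tertiles(life))
        assert not rep.bidirectional

    def test_small_tertile_skipped(self):
        idx = [f"P{i}" for i in range(12)]
        frac = pd.DataFrame({14.0: np.linspace(0.2, 0.8, 12)}, index=idx)
        tert = cmp.lifetime_tertiles(pd.Series(np.arange(12.0), index=idx))
        with pytest.warns(UserWarning):
            rep = cmp.raw_ratio_check(frac, frac.copy(), tert)
        assert not rep.bidirectional


class TestQuadrants:
    @pytest.mark.parametrize("dl,da,expected", [
        (0.3, 0.2, "up_up"),
        (0.3, -0.2, "up_down"),
        (-0.1, 0.5, "down_up"),
        (-0.1, -0.5, "down_down"),
        (0.0, 0.5, "unclassified"),
        (0.5, 0.0, "unclassified"),
        (np.nan, 0.5, "unclassified"),
    ])
    def test_classification(self, dl, da, expected):
        assert cmp.quadrant_classify(dl, da) == expected

    def test_table(self):
        out = cmp.quadrant_table(series([0.3, -0.1]), series([0.2, 0.5]))
        assert list(out) == ["up_up", "down_up"]


class TestCelltypeSpecificity:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["neuron", "microglia", "astrocyte", "oligodendrocyte"])

    def test_clear_margin(self):
        out = cmp.celltype_specificity(self.frame([[12.0, 10.0, 8.0, 5.0]]))
        assert out.iloc[0] == "neuron"

    def test_flat_none(self):
        out = cmp.celltype_specificity(self.frame([[10.0, 10.0, 10.0, 10.0]]))
        assert out.iloc[0] == "none"

    def test_margin_exactly_one_none(self):
        out = cmp.celltype_specificity(self.frame([[11.0, 10.0, 9.0, 8.0]]))
        assert out.iloc[0] == "none"

    def test_missing_row_warns(self):
        with pytest.warns(UserWarning):
            out = cmp.celltype_specificity(self.frame([[np.nan, 10.0, 8.0, 5.0]]))
        assert out.iloc[0] == "none"

    def test_wrong_shape(self):
        with pytest.raises(DataError):
            cmp.celltype_specificity(pd.DataFrame([[1.0, 2.0]]))
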