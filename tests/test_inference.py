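"""Environment model, robustness analyses and simulation studies."""

import numpy as np
import pandas as pd
import pytest

from ancestryhet import (
    SelectionSpec,
    SimBundleConfig,
    bootstrap_correlation_difference,
    compare_group_means,
    fit_environment_model,
    generate_study_bundle,
    genotyping_error_threshold,
    hybrid_index_deviation_correlation,
    selection_strength_required,
    single_marker_resampling,
    within_family_size_regression,
)
from ancestryhet.errors import ModelError, SimulationError
from ancestryhet.inference import attach_manifest

from conftest import summarize_bundle


def _toy_summaries(h, value, environment="pond", dataset="d1", **extra):
    df = pd.DataFrame({
        "hybrid_index": h, "value": value, "environment": environment,
        "dataset_id": dataset,
    })
    for k, v in extra.items():
        df[k] = v
    return df


class TestEnvironmentModel:
    def test_null_bundle_contrast_near_zero(self, neutral_bundle):
        summaries, _ = summarize_bundle(neutral_bundle)
        res = fit_environment_model(summaries, neutral_bundle.manifest)
        c = res.contrast("BxL")
        assert abs(c["estimate"]) < 2 * c["se"]
        assert 0.0 <= c["p"] <= 1.0

    def test_contrast_recomputable_from_group_means(self, neutral_bundle):
        # with a pure fixed-effects fit and a single cross, the contrast is
        # exactly the difference of environment means
        summaries, _ = summarize_bundle(neutral_bundle)
        df = attach_manifest(summaries, neutral_bundle.manifest)
        res = fit_environment_model(df)
        if res.used_fixed_effects_fallback:
            means = df.groupby("environment")["value"].mean()
            assert res.contrast("BxL")["estimate"] == pytest.approx(
                means["pond"] - means["lab"], abs=1e-9)

    def test_two_cross_types_get_separate_contrasts(self):
        rng = np.random.default_rng(0)
        rows = []
        for cross, shift in (("BxL", 0.02), ("MxF", 0.04)):
            for env in ("lab", "pond"):
                for ds in range(2):
                    n = 150
                    vals = rng.normal(shift if env == "pond" else 0.0, 0.05, n)
                    rows.append(pd.DataFrame({
                        "value": vals, "environment": env,
                        "cross_type": cross, "lake": "none",
                        "dataset_id": f"{cross}_{env}_{ds}",
                    }))
        df = pd.concat(rows, ignore_index=True)
        res = fit_environment_model(df)
        assert res.contrast("BxL")["estimate"] == pytest.approx(0.02, abs=0.012)
        assert res.contrast("MxF")["estimate"] == pytest.approx(0.04, abs=0.012)

    def test_single_environment_errors(self, neutral_bundle):
        summaries, _ = summarize_bundle(neutral_bundle)
        df = attach_manifest(summaries, neutral_bundle.manifest)
        with pytest.raises(ModelError, match="environment"):
            fit_environment_model(df[df["environment"] == "lab"])


class TestDeviationCorrelation:
    def test_perfect_monotone_gives_minus_one(self):
        h = np.array([0.5, 0.55, 0.6, 0.65, 0.7])
        df = _toy_summaries(h, -np.abs(h - 0.5))
        res = hybrid_index_deviation_correlation(df)
        assert res.rho == pytest.approx(-1.0)

    def test_rank_example(self):
        # |h - 0.5| = [0.1, 0.2, 0.3] against values [3, 2, 1]
        df = _toy_summaries(np.array([0.6, 0.7, 0.8]), [3.0, 2.0, 1.0])
        assert hybrid_index_deviation_correlation(df).rho == pytest.approx(-1.0)

    def test_neutral_simulation_weak_correlation(self, neutral_bundle):
        summaries, _ = summarize_bundle(neutral_bundle)
        res = hybrid_index_deviation_correlation(summaries, group="pond")
        assert abs(res.rho) < 0.2
        assert res.n > 100

    def test_constant_vector_errors(self):
        df = _toy_summaries(np.full(5, 0.5), np.arange(5.0))
        with pytest.raises(ModelError, match="constant"):
            hybrid_index_deviation_correlation(df)


class TestBootstrap:
    def test_identical_groups_ci_contains_zero(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(0.3, 0.7, 80)
        df = _toy_summaries(h, rng.normal(0, 0.05, 80))
        res = bootstrap_correlation_difference(df, df, n_boot=400, seed=3)
        assert res.ci_low <= 0 <= res.ci_high
        assert 0.0 < res.p <= 1.0

    def test_distinct_correlations_detected(self):
        rng = np.random.default_rng(2)
        n = 200
        dev = np.abs(rng.normal(size=n))        # |h - 0.5| up to scale
        # group A: value strongly anticorrelated with the deviation;
        # group B: independent
        ya = -0.8 * dev + np.sqrt(1 - 0.64) * rng.normal(size=n)
        a = _toy_summaries(0.5 + dev / 10, ya)
        b = _toy_summaries(0.5 + np.abs(rng.normal(size=n)) / 10,
                           rng.normal(size=n))
        res = bootstrap_correlation_difference(a, b, n_boot=600, seed=4)
        assert not (res.ci_low <= 0 <= res.ci_high)
        assert res.p < 0.05

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        h = rng.uniform(0.3, 0.7, 50)
        df = _toy_summaries(h, rng.normal(0, 0.05, 50))
        r1 = bootstrap_correlation_difference(df, df, n_boot=200, seed=9)
        r2 = bootstrap_correlation_difference(df, df, n_boot=200, seed=9)
        assert (r1.ci_low, r1.ci_high, r1.p) == (r2.ci_low, r2.ci_high, r2.p)

    def test_small_n_boot_warns(self):
        rng = np.random.default_rng(6)
        df = _toy_summaries(rng.uniform(0.3, 0.7, 30), rng.normal(size=30))
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_correlation_difference(df, df, n_boot=50, seed=0)


class TestGroupMeans:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.05, 100)
        df = pd.DataFrame({"value": np.r_[vals, vals],
                           "grp": ["a"] * 100 + ["b"] * 100})
        res = compare_group_means(df, "grp")
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.difference == pytest.approx(0.0, abs=1e-12)

    def test_known_difference_recovered(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "value": np.r_[rng.normal(0, 0.1, 200), rng.normal(0.05, 0.1, 200)],
            "grp": ["a"] * 200 + ["b"] * 200,
        })
        res = compare_group_means(df, "grp")
        assert 0.03 < res.difference < 0.07
        assert res.df_between == 1 and res.df_within == 398

    def test_f_invariant_to_label_permutation(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "value": rng.normal(0, 1, 90),
            "grp": ["x", "y", "z"] * 30,
        })
        f1 = compare_group_means(df, "grp").f
        relabel = {"x": "z", "y": "x", "z": "y"}
        df2 = df.assign(grp=df["grp"].map(relabel))
        assert compare_group_means(df2, "grp").f == pytest.approx(f1)

    def test_tiny_level_errors(self):
        df = pd.DataFrame({"value": [1.0, 2.0, 3.0], "grp": ["a", "a", "b"]})
        with pytest.raises(ModelError, match="n < 2"):
            compare_group_means(df, "grp")


class TestSizeRegression:
    def test_exact_linear_single_family(self):
        rng = np.random.default_rng(0)
        het = rng.uniform(0.3, 0.7, 30)
        df = pd.DataFrame({
            "observed_het": het, "length_mm": 2.0 * het + 40.0,
            "family_id": "f1",
        })
        res = within_family_size_regression(df)
        # z-scoring makes the slope 1/sd(het); the fit is exact
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0 / het.std(ddof=1), rel=1e-6)

    def test_invariant_to_family_offsets(self):
        rng = np.random.default_rng(1)
        het = rng.uniform(0.3, 0.7, 60)
        fam = np.repeat(["f1", "f2"], 30)
        length = 2.0 * het + np.where(fam == "f1", 40.0, 55.0)
        df = pd.DataFrame({"observed_het": het, "length_mm": length,
                           "family_id": fam})
        shifted = df.assign(length_mm=df["length_mm"] + 7.0)
        r1 = within_family_size_regression(df)
        r2 = within_family_size_regression(shifted)
        assert r1.slope == pytest.approx(r2.slope)

    def test_degenerate_family_excluded_with_warning(self):
        df = pd.DataFrame({
            "observed_het": [0.4, 0.5, 0.6, 0.3, 0.5, 0.7],
            "length_mm": [40.0, 40.0, 40.0, 41.0, 43.0, 45.0],
            "family_id": ["f1"] * 3 + ["f2"] * 3,
        })
        with pytest.warns(UserWarning, match="excluded"):
            res = within_family_size_regression(df)
        assert res.n == 3
        assert res.n_families_excluded == 1


class TestSingleMarkerResampling:
    def test_one_marker_per_chromosome_is_deterministic(self):
        config = SimBundleConfig.from_counts(
            1, 1, f2_per_family=80, n_markers=10, n_chromosomes=10,
            sex_chromosome=None, missing_rate=0.0, seed=21)
        bundle = generate_study_bundle(config)
        _, matrices = summarize_bundle(bundle, min_loci=5, min_individuals=5)
        res = single_marker_resampling(matrices, bundle.manifest,
                                       n_reps=50, seed=1)
        assert res.fraction_same_direction == 1.0
        assert res.se == 0.0

    def test_neutral_bundle_fraction_not_extreme(self, neutral_bundle):
        _, matrices = summarize_bundle(neutral_bundle)
        res = single_marker_resampling(matrices, neutral_bundle.manifest,
                                       n_reps=200, seed=2)
        assert 0.05 <= res.fraction_same_direction <= 0.99
        assert res.n_effective == 200

    def test_strong_selection_bundle_sign_stable(self):
        spec = SelectionSpec("heterozygote_advantage", s=0.3)
        config = SimBundleConfig.from_counts(
            1, 1, f2_per_family=250, n_markers=40, missing_rate=0.0,
            selection=spec, seed=23)
        bundle = generate_study_bundle(config)
        _, matrices = summarize_bundle(bundle)
        res = single_marker_resampling(matrices, bundle.manifest,
                                       n_reps=200, seed=3)
        assert res.full_effect > 0
        assert res.fraction_same_direction >= 0.95


@pytest.fixture(scope="module")
def report():
    return genotyping_error_threshold(
        n_fish=300, n_loci=100, n_reps=10,
        grid=[0.0, 0.02, 0.04, 0.06, 0.08, 0.1], seed=5)


class TestErrorThreshold:

    def test_zero_error_mean_near_zero(self, report):
        row = report.table.iloc[0]
        # allow the +1/(4L) finite-locus offset plus Monte-Carlo noise
        assert abs(row["mean_excess"] - 0.0025) < 4 * row["mc_se"] + 1e-4

    def test_analytic_small_e_response(self, report):
        # analytic oracle: mean excess ~ e/2 + (1-e)/(4L)
        for _, row in report.table.iterrows():
            e = row["error_rate"]
            expected = 0.5 * e + (1 - e) / 400
            assert row["mean_excess"] == pytest.approx(expected, abs=0.003)

    def test_monotone_within_mc_error(self, report):
        m = report.table["mean_excess"].to_numpy()
        se = report.table["mc_se"].to_numpy()
        assert all(m[i + 1] >= m[i] - 2 * (se[i] + se[i + 1])
                   for i in range(len(m) - 1))

    def test_threshold_and_bracket(self, report):
        assert report.threshold == pytest.approx(0.06)
        assert report.bracket == (0.04, 0.06)

    def test_unreachable_target_reports_none(self):
        rep = genotyping_error_threshold(
            n_fish=100, n_loci=50, n_reps=3, grid=[0.0, 0.01],
            target_excess=0.5, seed=1)
        assert rep.threshold is None


class TestSelectionStrength:
    def test_monotone_in_target(self):
        r1 = selection_strength_required(
            "heterozygote_advantage", target_excess=0.03, n_fish=8000,
            n_loci=40, seed=2)
        r2 = selection_strength_required(
            "heterozygote_advantage", target_excess=0.06, n_fish=8000,
            n_loci=40, seed=2)
        assert 0 < r1.threshold < r2.threshold

    def test_architectures_differ_by_large_factors(self):
        # selection concentrated on 10 loci must be far stronger than
        # selection spread over all 100 to move the genome-wide average
        r_few = selection_strength_required(
            "heterozygote_advantage", k_loci=10, n_fish=8000, n_loci=100, seed=3)
        r_all = selection_strength_required(
            "heterozygote_advantage", k_loci=100, n_fish=8000, n_loci=100, seed=3)
        assert r_few.threshold / r_all.threshold > 3.0

    def test_single_locus_target_unattainable(self):
        # one selected locus among 100 cannot lift the genome-wide mean
        # excess to 3% even with complete selection
        with pytest.raises(SimulationError, match="unattainable"):
            selection_strength_required(
                "heterozygote_advantage", k_loci=1, n_fish=4000, n_loci=100,
                seed=4)

    def test_fgm_mismatch_bisection_hits_target(self):
        from ancestryhet.inference import _excess_rows
        from ancestryhet.simulate import _selection_fitness

        rep = selection_strength_required(
            "fgm_mismatch", target_excess=0.03, n_fish=20000, n_loci=60,
            tol=0.002, seed=6)
        assert rep.parameter == "sigma_scale"
        # independent re-simulation at the tuned strength
        rng = np.random.default_rng(99)
        cohort = rng.choice([0.0, 1.0, 2.0], size=(20000, 60), p=[0.25, 0.5, 0.25])
        spec = SelectionSpec("fgm_mismatch", sigma_scale=rep.threshold)
        w = _selection_fitness(cohort, spec, (6, 17))
        surv = rng.random(20000) < w / w.max()
        assert np.mean(_excess_rows(cohort[surv])) == pytest.approx(0.03, abs=0.005)

    def test_pairwise_dmi_supported(self):
        rep = selection_strength_required(
            "pairwise_dmi", k_pairs=50, n_fish=8000, n_loci=100,
            target_excess=0.02, seed=7)
        assert rep.threshold > 0
        assert rep.architecture == "pairwise_dmi"
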