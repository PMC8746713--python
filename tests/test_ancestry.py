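"""Marker filtering, polarization and heterozygosity statistics."""

import numpy as np
import pandas as pd
import pytest

from ancestryhet import (
    apply_matrix_filters,
    chromosome_means,
    polarize_to_ancestry,
    select_diagnostic_markers,
    summarize_individuals,
    summarize_loci,
)
from ancestryhet.errors import FilterError, PedigreeError, ValidationError

from conftest import make_cross, random_ancestry_matrix


class TestDiagnosticSelection:
    def test_toy_cross_panel(self, toy_cross):
        panel = select_diagnostic_markers(toy_cross, sex_chrom_label="none")
        assert panel.diagnostic_markers == ["m1", "m2", "m4"]
        reasons = panel.table["rejection_reason"]
        assert reasons["m3"] == "shared_allele"
        assert reasons["m5"] == "f1_not_heterozygous"

    def test_sex_chromosome_rejected_despite_perfect_segregation(self):
        cross = make_cross({
            "f0a": ("F0A", [("A", "A")]),
            "f0b": ("F0B", [("G", "G")]),
            "f1": ("F1", [("A", "G")]),
            "f2": ("F2", [("A", "G")]),
        }, chromosomes=["19"])
        panel = select_diagnostic_markers(cross, sex_chrom_label="19")
        assert panel.table.loc["m1", "rejection_reason"] == "sex_chromosome"

    def test_low_coverage_calls_masked_before_rules(self):
        # the F1's conflicting call sits at depth 20 (<= threshold), so it
        # is treated as missing and the marker stays diagnostic
        cross = make_cross({
            "f0a": ("F0A", [("A", "A")]),
            "f0b": ("F0B", [("G", "G")]),
            "f1x": ("F1", [("A", "G")]),
            "f1y": ("F1", [("A", "A")]),
            "f2": ("F2", [("A", "G")]),
        }, coverage={("f1y", "m1"): 20})
        panel = select_diagnostic_markers(cross, min_coverage=20)
        assert panel.table.loc["m1", "diagnostic"]
        # at depth 21 the call counts and the marker is rejected
        cross21 = make_cross({
            "f0a": ("F0A", [("A", "A")]),
            "f0b": ("F0B", [("G", "G")]),
            "f1x": ("F1", [("A", "G")]),
            "f1y": ("F1", [("A", "A")]),
            "f2": ("F2", [("A", "G")]),
        }, coverage={("f1y", "m1"): 21})
        panel21 = select_diagnostic_markers(cross21, min_coverage=20)
        assert panel21.table.loc["m1", "rejection_reason"] == "f1_not_heterozygous"

    def test_clean_cross_validates_every_f1_call(self, neutral_bundle):
        # analog of the empirical check where every F1 call at a
        # parent-differentiated locus was heterozygous (288 of 288)
        for cross in neutral_bundle.datasets.values():
            panel = select_diagnostic_markers(cross)
            assert panel.n_f1_calls_checked > 0
            assert panel.f1_validation_rate == 1.0

    def test_missing_pedigree_errors(self, toy_cross):
        from ancestryhet.containers import CrossGenotypes

        no_f1 = CrossGenotypes(toy_cross.data[toy_cross.data["generation"] != "F1"])
        with pytest.raises(PedigreeError):
            select_diagnostic_markers(no_f1)


class TestPolarization:
    def test_dosages_follow_side_b_counts(self, toy_cross):
        panel = select_diagnostic_markers(toy_cross, sex_chrom_label="none")
        m = polarize_to_ancestry(toy_cross, panel)
        # F1s are heterozygous everywhere; founders are 0 / 2
        assert (m.dosage.loc["f1x"] == 1).all()
        assert (m.dosage.loc["f0a"] == 0).all()
        assert (m.dosage.loc["f0b"] == 2).all()
        # f2a: m1 = AA -> 0, m2 het -> 1, m4 = GG -> 2
        assert m.dosage.loc["f2a", ["m1", "m2", "m4"]].tolist() == [0, 1, 2]

    def test_novel_allele_becomes_missing_and_is_counted(self):
        cross = make_cross({
            "f0a": ("F0A", [("A", "A")]),
            "f0b": ("F0B", [("G", "G")]),
            "f1": ("F1", [("A", "G")]),
            "f2": ("F2", [("A", "T")]),   # T seen in neither founder side
        })
        panel = select_diagnostic_markers(cross, sex_chrom_label="none")
        m = polarize_to_ancestry(cross, panel)
        assert np.isnan(m.dosage.loc["f2", "m1"])
        assert m.n_unpolarized_calls == 1

    def test_panel_marker_absent_from_cross_errors(self, toy_cross):
        panel = select_diagnostic_markers(toy_cross, sex_chrom_label="none")
        truncated = toy_cross.data[toy_cross.data["marker_id"] != "m2"]
        from ancestryhet.containers import CrossGenotypes

        with pytest.raises(ValidationError, match="absent"):
            polarize_to_ancestry(CrossGenotypes(truncated), panel)

    def test_roundtrip_to_alleles(self, neutral_bundle):
        # re-deriving ancestry calls from dosages and the side allele sets
        # reproduces the original het/hom structure at diagnostic markers
        cross = neutral_bundle.datasets["lab1"]
        panel = select_diagnostic_markers(cross)
        m = polarize_to_ancestry(cross, panel)
        sides = panel.table
        df = cross.data.set_index(["individual_id", "marker_id"])
        d = m.dosage.stack()
        rng = np.random.default_rng(0)
        sample = d.index[rng.choice(len(d), size=200, replace=False)]
        for ind, marker in sample:
            a1, a2 = df.loc[(ind, marker), ["allele_1", "allele_2"]]
            in_b = int(a1 in sides.loc[marker, "side_b_alleles"]) + \
                int(a2 in sides.loc[marker, "side_b_alleles"])
            assert in_b == d.loc[(ind, marker)]


class TestMatrixFilters:
    @staticmethod
    def _with_missing(n, n_loci, missing):
        m = random_ancestry_matrix(n, n_loci, seed=1)
        for ind, k in missing.items():
            m.dosage.iloc[ind, :k] = np.nan
        return m

    def test_boundary_at_exactly_min_loci(self):
        # 30 loci; individual 0 keeps 19 -> dropped, individual 1 keeps 20 -> kept
        m = self._with_missing(40, 30, {0: 11, 1: 10})
        out = apply_matrix_filters(m, min_loci=20, min_individuals=20)
        assert "i0" not in out.dosage.index
        assert "i1" in out.dosage.index

    def test_already_valid_matrix_unchanged(self):
        m = random_ancestry_matrix(30, 25, seed=2)
        out = apply_matrix_filters(m)
        pd.testing.assert_frame_equal(out.dosage, m.dosage)

    def test_iterated_to_fixed_point(self):
        # 21 individuals x 21 markers; marker 0 is genotyped in exactly 20
        # individuals, one of which fails the 20-loci rule once dropped,
        # so the marker must fall on the second pass
        m = random_ancestry_matrix(21, 21, seed=3)
        m.dosage.iloc[20, 0] = np.nan          # marker m0: 20 of 21 individuals
        m.dosage.iloc[0, 2:] = np.nan          # individual i0: only m0, m1 left
        out = apply_matrix_filters(m, min_loci=20, min_individuals=20)
        assert "i0" not in out.dosage.index
        assert "m0" not in out.dosage.columns
        # exhaustive recount of the surviving matrix
        d = out.dosage
        recomb = out.recombinant_mask.to_numpy()
        assert (d.loc[recomb].notna().sum(axis=1) >= 20).all()
        assert (d.loc[recomb].notna().sum(axis=0) >= 20).all()

    def test_filtering_is_monotone(self):
        m = self._with_missing(50, 30, {i: 15 for i in range(10)})
        out = apply_matrix_filters(m)
        assert out.shape[0] <= m.shape[0]
        assert out.shape[1] <= m.shape[1]

    def test_everything_dropped_names_binding_constraint(self):
        m = random_ancestry_matrix(10, 30, seed=4)   # 10 < min_individuals
        with pytest.raises(FilterError) as err:
            apply_matrix_filters(m, min_loci=20, min_individuals=20)
        assert err.value.binding_constraint in ("min_loci", "min_individuals")


class TestSummaries:
    @pytest.mark.parametrize(
        "dosages, h, observed, excess",
        [
            ([1, 1, 1, 1], 0.5, 1.0, 0.5),      # maximally heterozygous
            ([0, 0, 0, 0], 0.0, 0.0, 0.0),      # pure side-A genome
            ([0, 1, 1, 2], 0.5, 0.5, 0.0),      # hand arithmetic
        ],
    )
    def test_individual_statistics(self, dosages, h, observed, excess):
        m = random_ancestry_matrix(1, len(dosages), seed=0)
        m.dosage.iloc[0] = dosages
        s = summarize_individuals(m).iloc[0]
        assert s["hybrid_index"] == pytest.approx(h)
        assert s["observed_het"] == pytest.approx(observed)
        assert s["excess_het"] == pytest.approx(excess)

    def test_small_sample_correction_scales_expected(self):
        m = random_ancestry_matrix(5, 10, seed=1)
        plain = summarize_individuals(m, correction="none")
        corr = summarize_individuals(m, correction="small_sample")
        n = plain["n_loci"]
        np.testing.assert_allclose(
            corr["expected_het"], plain["expected_het"] * 2 * n / (2 * n - 1))

    def test_observed_statistic_switches_value_column(self):
        m = random_ancestry_matrix(5, 10, seed=2)
        s = summarize_individuals(m, statistic="observed")
        np.testing.assert_array_equal(s["value"], s["observed_het"])

    def test_locus_statistics_hand_cases(self):
        m = random_ancestry_matrix(100, 3, seed=3)
        m.dosage["m0"] = [0] * 25 + [1] * 50 + [2] * 25   # 25/50/25
        m.dosage["m1"] = 1.0                              # all heterozygous
        m.dosage["m2"] = 2.0                              # monomorphic side B
        s = summarize_loci(m).set_index("marker_id")
        assert s.loc["m0", "ancestry_freq"] == pytest.approx(0.5)
        assert s.loc["m0", "excess_het"] == pytest.approx(0.0)
        assert s.loc["m1", "excess_het"] == pytest.approx(0.5)
        assert s.loc["m2", "excess_het"] == pytest.approx(0.0)

    def test_only_recombinants_are_summarized(self, toy_cross):
        panel = select_diagnostic_markers(toy_cross, sex_chrom_label="none")
        m = polarize_to_ancestry(toy_cross, panel)
        s = summarize_individuals(m)
        assert set(s["generation"]) == {"F2"}


class TestChromosomeMeans:
    def test_single_locus_chromosome_has_undefined_se(self):
        loci = pd.DataFrame({
            "marker_id": ["a", "b", "c"],
            "chromosome": ["1", "2", "2"],
            "excess_het": [0.07, 0.1, -0.1],
        })
        out = chromosome_means(loci).set_index("chromosome")
        assert out.loc["1", "mean_excess_het"] == pytest.approx(0.07)
        assert np.isnan(out.loc["1", "se"])
        assert out.loc["2", "mean_excess_het"] == pytest.approx(0.0)

    def test_neutral_simulation_within_four_se(self):
        # 20 loci per chromosome keep the per-chromosome SE estimate stable
        m = random_ancestry_matrix(400, 400, seed=1)
        out = chromosome_means(summarize_loci(m))
        multi = out[out["n_loci"] > 1]
        assert (multi["mean_excess_het"].abs() < 4 * multi["se"] + 1e-9).all()
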