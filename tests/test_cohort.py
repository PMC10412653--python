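"""Cohort summary reproduction, t-test correctness against the closed
form, and intraductal-vs-invasive component comparisons."""

import numpy as np
import pytest

from iopn_tme.cell_io import load_cohort_table
from iopn_tme.cohort import (
    compare_components,
    compare_marker_scores,
    immune_infiltration_summary,
    round_half_up,
    summarize_cohort,
    two_sample_t,
)
from iopn_tme.pipeline import (
    analyze_regions,
    simulate_two_component_case,
    simulate_two_zone_case,
    tissue_roi,
)


class TestSummarize:
    def test_reproduces_every_published_mean(self):
        summary = summarize_cohort(load_cohort_table())
        means = summary["means"]
        assert means["CD3"] == 4.6
        assert means["CD4"] == 3.1
        assert means["CD8"] == 4.1
        assert means["CD20"] == 1.9
        assert means["PD1"] == 3.3
        assert means["TPS"] == 10.1
        assert means["CPS"] == 12.3
        assert means["CD68"] == 3.3
        assert means["CD163"] == 2.9
        assert means["size_cm"] == 5.2

    def test_invasive_component_means(self):
        inv = summarize_cohort(load_cohort_table())["invasive_means"]
        assert inv["CD3_inv"] == 5.0
        assert inv["CD4_inv"] == 2.0
        assert inv["CD20_inv"] == 1.5
        assert inv["TPS_inv"] == 2.5
        assert inv["CPS_inv"] == 13.5
        assert inv["size_cm_inv"] == 2.0

    def test_categorical_fractions(self):
        fr = summarize_cohort(load_cohort_table())["fractions"]
        assert fr["gender"]["M"] == 80.0
        assert fr["site"]["H"] == 53.3
        assert fr["duct_type"]["Mx"] == 73.3

    def test_single_case_cohort_means_are_the_case(self):
        one = load_cohort_table().iloc[[0]]
        means = summarize_cohort(one)["means"]
        assert means["CD3"] == 5.0 and means["TPS"] == 5.0

    def test_round_half_up_breaks_ties_away_from_zero(self):
        assert round_half_up(0.25, 1) == 0.3  # banker's rounding would give 0.2
        assert round_half_up(-0.25, 1) == -0.3


class TestTwoSampleT:
    def test_identical_samples_give_null_result(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p > 0.99

    def test_zero_variance_equal_means(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_textbook_instance_matches_closed_form(self):
        # x=(1,2,3), y=(4,5,6): pooled s²=1, t = -3/√(2/3) = -3.67423...
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3 * np.sqrt(3 / 2), abs=1e-10)
        assert res.df == 4
        assert res.p == pytest.approx(0.021311641128756727, abs=1e-10)

    def test_sign_flips_p_invariant_under_swap(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        a, b = two_sample_t(x, y), two_sample_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])

    def test_paired_marker_comparisons_reach_published_significance(self):
        cohort = load_cohort_table()
        t_vs_b = compare_marker_scores(cohort, "CD3", "CD20")
        cd8_vs_cd4 = compare_marker_scores(cohort, "CD8", "CD4")
        assert t_vs_b.p < 0.001
        assert cd8_vs_cd4.p <= 0.001


class TestCompareComponents:
    def test_null_construction_shows_no_differences(self):
        """Both components planted with identical compositions: estimated
        differences are tiny and no phenotype reaches significance."""
        cells_a, _, spec_a = simulate_two_zone_case(seed=31, component="intraductal")
        cells_b, _, _ = simulate_two_zone_case(seed=32, component="invasive")
        cells_b = cells_b.assign(
            x_um=cells_b["x_um"] + 5000.0, component="invasive"
        )
        import pandas as pd

        cells = pd.concat([cells_a, cells_b], ignore_index=True)
        an = analyze_regions(cells, seed=31)
        cmp = compare_components(an.neighborhoods)
        present = cmp[cmp["phenotype"].isin(["tumor", "CD4", "CD8", "CD20"])]
        assert present["difference"].abs().max() < 0.02
        assert (present["p"] > 0.05).all()

    def test_planted_invasive_shift_is_recovered(self):
        """The CD4-down / CD8-up planted shift comes back with the right
        signs and decisive significance at ≥200 neighborhoods per side."""
        cells, spec = simulate_two_component_case(seed=33)
        an = analyze_regions(cells, roi=tissue_roi(spec), seed=33)
        pop = an.neighborhoods[an.neighborhoods["populated"]]
        assert (pop["component"] == "intraductal").sum() >= 200
        assert (pop["component"] == "invasive").sum() >= 200
        cmp = compare_components(an.neighborhoods).set_index("phenotype")
        assert cmp.loc["CD4", "difference"] < 0
        assert cmp.loc["CD8", "difference"] > 0
        assert cmp.loc["CD4", "p"] < 0.001
        assert cmp.loc["CD8", "p"] < 0.001

    def test_permuted_component_labels_control_type_I_error(self, rng):
        """Permuting component labels kills the signal: the p-value
        distribution is near-uniform (rejection rate ≈ 5% at α=0.05)."""
        cells, spec = simulate_two_component_case(
            seed=34, outer_radius_um=1200.0, invasive_core_radius_um=690.0,
            density_per_mm2=900.0,
        )
        an = analyze_regions(cells, roi=tissue_roi(spec), seed=34)
        pop = an.neighborhoods[an.neighborhoods["populated"]].copy()
        x = pop["frac_CD8"].to_numpy()
        n_a = (pop["component"] == "intraductal").sum()
        hits = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = rng.permutation(len(x))
            res = two_sample_t(x[perm[:n_a]], x[perm[n_a:]])
            hits += res.p < 0.05
        assert 0.01 <= hits / n_perm <= 0.11

    def test_infiltration_summary_percentages_sum_to_100(self):
        cells, _ = simulate_two_component_case(seed=35, density_per_mm2=300.0,
                                               outer_radius_um=900.0,
                                               invasive_core_radius_um=500.0,
                                               intraductal_core_radius_um=520.0)
        summary = immune_infiltration_summary(cells)
        for scope, sub in summary.groupby("scope"):
            assert sub["percent_of_immune"].sum() == pytest.approx(100.0)
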