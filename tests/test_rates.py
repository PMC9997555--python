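"""Estimators and statistics: closed-form, oracle, and calibration checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mawgs import (
    MutationRecord,
    TruthRates,
    context_rate_matrix,
    count_comparison_test,
    divisions_from_cfu,
    effective_population_size,
    efficiency_of_plating,
    gene_dispersion,
    gene_enrichment_scan,
    gof_test_ns_s,
    mutation_rate,
    poisson_ci,
    rate_ratio_test,
    spectrum_table,
)
from mawgs.annotate import GenomeAnnotator
from mawgs.core import LineMetadata, MutationAnnotation
from mawgs.rates import eop_curve
from mawgs.synthdata import ExperimentDesign, simulate_ma_lines


def lines_fixture(n, divisions, sites=10_000):
    return [
        LineMetadata(
            line_id=f"C{i + 1:03d}", group="control", dish_id=f"D{i // 2 + 1}",
            transfers=50, divisions_per_transfer=20, mean_depth=50.0,
            analyzable_sites=sites, total_divisions=divisions,
        )
        for i in range(n)
    ]


CLASS_ALLELES = {
    "A:T->G:C": ("A", "G"),
    "G:C->A:T": ("G", "A"),
    "A:T->T:A": ("A", "T"),
    "A:T->C:G": ("A", "C"),
    "G:C->C:G": ("G", "C"),
    "G:C->T:A": ("G", "T"),
}


def make_annotations(class_counts, insertions=0, deletions=0):
    """Minimal annotations carrying the categories the spectrum needs."""
    out = []
    pos = 1
    for cls, n in class_counts.items():
        ref, alt = CLASS_ALLELES[cls]
        for _ in range(n):
            rec = MutationRecord("L1", "chr1", pos, ref, alt)
            out.append(MutationAnnotation(
                record=rec, region="intergenic", coding_effect=None,
                at_fourfold_site=False, spectrum_class=cls,
                ts_tv="transition" if cls in ("A:T->G:C", "G:C->A:T")
                else "transversion", context=None, in_ssr=None))
            pos += 1
    for kind, n in (("insertion", insertions), ("deletion", deletions)):
        for _ in range(n):
            ref, alt = ("A", "AT") if kind == "insertion" else ("AT", "A")
            rec = MutationRecord("L1", "chr1", pos, ref, alt)
            out.append(MutationAnnotation(
                record=rec, region="intergenic", coding_effect=None,
                at_fourfold_site=False, spectrum_class=None, ts_tv=None,
                context=None, in_ssr=False))
            pos += 1
    return out


class TestDivisionsAndNe:
    @pytest.mark.parametrize("cells,expected", [(1_048_576, 20), (1, 0), (131_072, 17)])
    def test_log2_division_estimator(self, cells, expected):
        assert divisions_from_cfu(cells) == pytest.approx(expected)

    def test_fractional_cells_below_one_rejected(self):
        with pytest.raises(ValueError):
            divisions_from_cfu(0)

    @pytest.mark.parametrize("T,expected", [(20, 10.50), (17, 9.00), (0, 1.0)])
    def test_harmonic_mean_ne(self, T, expected):
        assert round(effective_population_size(T), 2) == expected

    def test_negative_divisions_rejected(self):
        with pytest.raises(ValueError):
            effective_population_size(-1)


class TestPoissonCI:
    def test_zero_count_closed_form(self):
        low, high = poisson_ci(0)
        assert low == 0.0
        assert high == pytest.approx(-math.log(0.025))

    def test_interval_widths_monotone_in_count(self):
        widths, rel = [], []
        for m in range(1, 80):
            lo, hi = poisson_ci(m)
            widths.append(hi - lo)
            rel.append((hi - lo) / m)
        assert all(b > a for a, b in zip(widths, widths[1:]))
        assert all(b < a for a, b in zip(rel, rel[1:]))

    def test_monte_carlo_coverage_at_lambda_five(self):
        rng = np.random.default_rng(42)
        ms = rng.poisson(5.0, size=2000)
        low = np.where(ms == 0, 0.0, 0.5 * stats.chi2.ppf(0.025, 2 * ms))
        high = 0.5 * stats.chi2.ppf(0.975, 2 * ms + 2)
        coverage = np.mean((low <= 5.0) & (5.0 <= high))
        assert coverage >= 0.93

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_ci(-1)
        with pytest.raises(ValueError):
            poisson_ci(5, level=1.2)


class TestMutationRate:
    def test_per_genome_rate_matches_hand_arithmetic(self):
        est = mutation_rate(62, lines_fixture(73, 1009), per="genome")
        assert est.exposure == 73 * 1009
        assert est.rate == pytest.approx(62 / (73 * 1009))

    def test_zero_count_has_closed_form_upper_bound(self):
        lines = lines_fixture(10, 1000)
        est = mutation_rate(0, lines, per="site")
        assert est.rate == 0.0 and est.ci_low == 0.0
        assert est.ci_high == pytest.approx(-math.log(0.025) / est.exposure)

    def test_category_sites_override(self):
        lines = lines_fixture(4, 500)
        est = mutation_rate(3, lines, per="site", category_sites=100)
        assert est.exposure == 4 * 100 * 500

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError, match="exposure"):
            mutation_rate(1, [], per="site")

    def test_recovery_on_simulated_experiment(self, toy_ref):
        truth = TruthRates(bps_rate_per_site_per_division=2e-7,
                           indel_rate_per_site_per_division=0.0)
        design = ExperimentDesign(n_lines_control=20, n_lines_treatment=0)
        sim = simulate_ma_lines(toy_ref, truth, design, seed=13)
        m = sum(len(v) for v in sim.mutations.values())
        est = mutation_rate(m, sim.lines, per="site")
        assert est.ci_low <= truth.bps_rate_per_site_per_division <= est.ci_high


class TestSpectrumTable:
    def test_counts_ratios_and_proportions(self):
        anns = make_annotations(
            {"A:T->G:C": 11, "G:C->A:T": 18, "A:T->T:A": 5, "A:T->C:G": 5,
             "G:C->C:G": 5, "G:C->T:A": 18},
            insertions=30, deletions=4,
        )
        spec = spectrum_table(anns)
        assert (spec.ts_count, spec.tv_count) == (29, 33)
        assert round(spec.ts_tv_ratio, 2) == 0.88
        assert round(spec.ins_del_ratio, 2) == 7.50
        assert spec.proportions["G:C->A:T"] == pytest.approx(18 / 29)
        assert sum(spec.proportions[c] for c in
                   ("A:T->G:C", "G:C->A:T")) == pytest.approx(1.0)

    def test_empty_input_gives_zero_table_with_undefined_ratios(self):
        spec = spectrum_table([])
        assert spec.ts_count == spec.tv_count == 0
        assert math.isnan(spec.ts_tv_ratio) and math.isnan(spec.ins_del_ratio)

    def test_invariant_to_input_order(self):
        anns = make_annotations({"A:T->G:C": 3, "G:C->T:A": 7}, insertions=2)
        a = spectrum_table(anns)
        b = spectrum_table(list(reversed(anns)))
        assert a.counts == b.counts and a.ts_tv_ratio == b.ts_tv_ratio


def _yates_2x2_reference(a, b, c, d):
    """Independent Yates chi-square for a 2x2 table, from the marginal
    expected counts."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    return float(np.sum((np.abs(table - exp) - 0.5).clip(0) ** 2 / exp))


class TestChiSquareTests:
    def test_ns_s_goodness_of_fit_printed_examples(self):
        r1 = gof_test_ns_s(26, 6, 6_074_090, 1_641_376)
        assert round(r1.chi2, 2) == 0.02 and round(r1.p, 2) == 0.89
        r2 = gof_test_ns_s(64, 19, 6_074_090, 1_641_376)
        assert round(r2.chi2, 2) == 0.05 and round(r2.p, 2) == 0.82

    def test_gof_clamps_to_zero_at_expectation(self):
        r = gof_test_ns_s(75, 25, 750, 250)
        assert r.chi2 == 0.0 and r.p == 1.0

    def test_gof_undefined_with_no_observations(self):
        assert math.isnan(gof_test_ns_s(0, 0, 100, 50).chi2)

    def test_2x2_printed_examples(self):
        assert round(count_comparison_test(29, 33, 48, 66).chi2, 2) == 0.19
        assert round(count_comparison_test(30, 4, 19, 4).chi2, 2) == 0.04

    def test_homogeneous_table_gives_zero(self):
        assert count_comparison_test(10, 10, 10, 10).chi2 == 0.0

    def test_degenerate_margin_flagged_undefined(self):
        assert math.isnan(count_comparison_test(0, 0, 5, 7).chi2)

    def test_2x2_agrees_with_independent_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 60, size=4)
            got = count_comparison_test(int(a), int(b), int(c), int(d)).chi2
            assert got == pytest.approx(_yates_2x2_reference(a, b, c, d), abs=1e-9)

    def test_gof_agrees_with_independent_implementation(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            o1, o2 = rng.integers(0, 50, size=2)
            if o1 + o2 == 0:
                continue
            s1, s2 = rng.integers(100, 10_000, size=2)
            got = gof_test_ns_s(int(o1), int(o2), int(s1), int(s2)).chi2
            tot = o1 + o2
            e1 = tot * s1 / (s1 + s2)
            e2 = tot - e1
            exp = sum(max(abs(o - e) - 0.5, 0) ** 2 / e
                      for o, e in ((o1, e1), (o2, e2)))
            assert got == pytest.approx(exp, abs=1e-9)


class TestRateRatioTest:
    def test_equal_rates_give_zero_statistic(self):
        r = rate_ratio_test(10, 1000.0, 20, 2000.0)
        assert r.chi2 == pytest.approx(0.0, abs=0.05)
        assert r.ratio == pytest.approx(1.0)

    def test_approximates_exact_conditional_binomial(self):
        m1, e1, m2, e2 = 4, 73_657.0, 14, 74_390.0
        r = rate_ratio_test(m1, e1, m2, e2)
        exact = stats.binomtest(m1, m1 + m2, p=e1 / (e1 + e2)).pvalue
        assert abs(r.p - exact) < 0.02

    def test_scale_invariance_of_ratio(self):
        a = rate_ratio_test(5, 100.0, 15, 200.0)
        b = rate_ratio_test(5, 200.0, 15, 400.0)
        assert a.ratio == pytest.approx(b.ratio)

    def test_no_counts_undefined(self):
        assert math.isnan(rate_ratio_test(0, 10.0, 0, 10.0).chi2)


class TestContextRateMatrix:
    def test_counts_conserved_and_empty_matrix_zero(self, toy_ref):
        annotator = GenomeAnnotator(toy_ref)
        inv = annotator.site_inventory()
        lines = lines_fixture(5, 1000)
        empty = context_rate_matrix([], inv, lines)
        assert (empty.table["count"] == 0).all()
        assert (empty.table.loc[empty.table.sites > 0, "rate_1e10"] == 0).all()

        truth = TruthRates(bps_rate_per_site_per_division=2e-7,
                           indel_rate_per_site_per_division=0.0)
        design = ExperimentDesign(n_lines_control=10, n_lines_treatment=0)
        sim = simulate_ma_lines(toy_ref, truth, design, seed=5)
        anns = annotator.classify_all(sim.all_mutations())
        mat = context_rate_matrix(anns, inv, sim.lines)
        interior = sum(1 for a in anns if a.context is not None)
        assert mat.table["count"].sum() == interior

    def test_zero_site_cells_undefined_not_zero(self, toy_ref):
        inv = GenomeAnnotator(toy_ref).site_inventory()
        inv.context_counts["ACA"] = 0
        mat = context_rate_matrix([], inv, lines_fixture(2, 100))
        assert math.isnan(mat.cell("ACA")["rate_1e10"])

    def test_context_bias_recovered_from_simulation(self, toy_ref):
        """Elevating 5'-C[N]C-3' multipliers must raise those cells'
        estimated rates above the matrix median."""
        mult = {f"C{b}C": 30.0 for b in "ACGT"}
        truth = TruthRates(bps_rate_per_site_per_division=3e-7,
                           indel_rate_per_site_per_division=0.0,
                           context_multipliers=mult)
        design = ExperimentDesign(n_lines_control=20, n_lines_treatment=0)
        annotator = GenomeAnnotator(toy_ref)
        inv = annotator.site_inventory()
        wins = 0
        for rep in range(10):
            sim = simulate_ma_lines(toy_ref, truth, design, seed=100 + rep)
            anns = annotator.classify_all(sim.all_mutations())
            mat = context_rate_matrix(anns, inv, sim.lines)
            med = mat.table["rate_1e10"].median()
            hot = mat.table[mat.table.context.isin(mult)]["rate_1e10"].mean()
            wins += hot > med
        assert wins >= 9


class TestEnrichmentScan:
    def test_p_values_match_direct_poisson_summation(self, toy_ref):
        annotator = GenomeAnnotator(toy_ref)
        lines = lines_fixture(10, 1000)
        rate = mutation_rate(25, lines, per="site")
        truth = TruthRates(bps_rate_per_site_per_division=2e-7,
                           indel_rate_per_site_per_division=0.0)
        design = ExperimentDesign(n_lines_control=10, n_lines_treatment=0)
        sim = simulate_ma_lines(toy_ref, truth, design, seed=31)
        anns = annotator.classify_all(sim.all_mutations())
        df = gene_enrichment_scan(anns, toy_ref.genes, rate, sim.lines)
        total_div = sum(m.total_divisions for m in sim.lines)
        for row in df.itertuples():
            lam = row.cds_length * rate.rate * total_div
            if row.observed == 0:
                assert row.p == 1.0
            else:
                direct = 1.0 - sum(
                    math.exp(-lam) * lam**k / math.factorial(k)
                    for k in range(int(row.observed))
                )
                assert row.p == pytest.approx(direct, abs=1e-9)

    def test_zero_observed_gene_has_p_one(self, toy_ref):
        lines = lines_fixture(5, 1000)
        rate = mutation_rate(10, lines, per="site")
        df = gene_enrichment_scan([], toy_ref.genes, rate, lines)
        assert (df.p == 1.0).all() and not df.enriched.any()


class TestDispersionAndEOP:
    def test_constant_counts_give_minus_one_over_mu(self):
        counts = pd.DataFrame([[10, 10, 10]], index=["g1"])
        stat = gene_dispersion(counts)[0]
        assert stat.alpha == pytest.approx(-0.10)

    def test_hand_computed_two_replicates(self):
        counts = pd.DataFrame([[4, 16]], index=["g1"])
        stat = gene_dispersion(counts)[0]
        assert stat.mean == 10 and stat.variance == 72
        assert stat.alpha == pytest.approx(0.62)

    def test_poisson_counts_center_alpha_on_zero(self):
        # V = mu in expectation under Poisson noise, so alpha centers on
        # zero; the mean is the unbiased summary (the median dips slightly
        # negative because the sample variance is right-skewed at 6
        # replicates)
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(100.0, size=(1000, 6)))
        alphas = np.array([s.alpha for s in gene_dispersion(counts)])
        se = alphas.std(ddof=1) / np.sqrt(len(alphas))
        assert abs(alphas.mean()) <= 3 * se

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            gene_dispersion(pd.DataFrame([[5]], index=["g1"]))

    def test_efficiency_of_plating(self):
        assert efficiency_of_plating(500, 500) == 1.0
        assert efficiency_of_plating(0, 500) == 0.0
        with pytest.raises(ValueError):
            efficiency_of_plating(10, 0)

    def test_eop_curve_uses_first_dose_as_control(self):
        df = eop_curve([0, 20, 40], [400, 200, 100])
        assert list(df.eop) == [1.0, 0.5, 0.25]
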