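"""Stage-two statistics: HWE, allele/trend/genotype tests, odds ratios,
cohort combination and power, checked against the published two-SNP results
and against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolgwas import (
    allele_test,
    analyze_count_table,
    combine_cohorts,
    genotype_or,
    genotype_test_2df,
    hwe_test,
    power_chisq,
    trend_test,
)
from poolgwas.individual import COUNT_COLUMNS, format_report, results_to_frame
from conftest import RS2196447_COMBINED, RS11845632_COMBINED
from oracles import allele_table, hwe_oracle, pearson_chi2_oracle, trend_oracle, woolf_ci_oracle

triple = st.tuples(st.integers(0, 300), st.integers(0, 300), st.integers(0, 300))


def test_hwe_exact_proportions():
    r = hwe_test(25, 50, 25)
    assert r.chi_square == pytest.approx(0.0, abs=1e-12) and r.p_value == 1.0


def test_hwe_hand_computed_example():
    # expecteds at p=0.5, n=30: (7.5, 15, 7.5)
    r = hwe_test(10, 10, 10)
    assert r.chi_square == pytest.approx(10 / 3, abs=1e-12)
    assert r.p_value == pytest.approx(0.0679, abs=5e-4)


def test_hwe_published_combined_value():
    """All 924 combined subjects for the splice-site SNP: p prints as 0.339."""
    r = hwe_test(140, 457, 327)
    assert round(r.p_value, 3) == 0.339


def test_hwe_monomorphic_flag():
    r = hwe_test(50, 0, 0)
    assert r.flagged and r.p_value == 1.0


def test_hwe_rejection_rate_under_null(rng):
    """Genotypes drawn under HWE: rejection rate ~ alpha (binomial band)."""
    n_rep, n, f = 4000, 300, 0.35
    probs = [f * f, 2 * f * (1 - f), (1 - f) * (1 - f)]
    tables = rng.multinomial(n, probs, size=n_rep)
    rate = np.mean([hwe_test(*t).p_value < 0.05 for t in tables])
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)


def test_allele_test_null_identity():
    r = allele_test((30, 50, 20), (30, 50, 20))
    assert r.p_value == pytest.approx(1.0) and r.odds_ratio == pytest.approx(1.0)


def test_allele_test_reproduces_published_results():
    case, ctrl = RS11845632_COMBINED
    r = allele_test(case, ctrl, allele="b")  # G allele
    assert abs(100 * r.freq_case - 64.9) < 0.1
    assert abs(100 * r.freq_control - 56.3) < 0.1
    assert round(r.odds_ratio, 2) == 1.44
    assert round(r.ci_low, 2) == 1.19 and round(r.ci_high, 2) == 1.73
    assert round(r.p_value, 4) == 0.0002

    case, ctrl = RS2196447_COMBINED
    r = allele_test(case, ctrl, allele="a")  # A allele
    assert abs(100 * r.freq_case - 43.2) < 0.1
    assert abs(100 * r.freq_control - 34.9) < 0.1
    assert round(r.odds_ratio, 2) == 1.43
    assert round(r.ci_low, 2) == 1.18 and round(r.ci_high, 2) == 1.72
    assert round(r.p_value, 4) == 0.0002


@given(case=triple, control=triple)
@settings(max_examples=200, derandomize=True)
def test_allele_relabelling_inverts_or(case, control):
    """Swapping which allele is 'A' maps OR -> 1/OR, p unchanged."""
    a = allele_test(case, control, "a")
    b = allele_test(case, control, "b")
    assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
    if not a.flagged:
        assert a.odds_ratio == pytest.approx(1.0 / b.odds_ratio, rel=1e-9)
        rev_case, rev_ctrl = case[::-1], control[::-1]
        c = allele_test(rev_case, rev_ctrl, "a")
        assert c.p_value == pytest.approx(a.p_value, rel=1e-9)
        assert c.odds_ratio == pytest.approx(b.odds_ratio, rel=1e-9)


def test_trend_no_trend_in_proportional_rows():
    assert trend_test((10, 20, 30), (20, 40, 60)).chi_square == pytest.approx(0.0, abs=1e-12)


def test_trend_on_combined_counts_matches_textbook_oracle():
    case, ctrl = RS11845632_COMBINED
    r = trend_test(case, ctrl)
    assert r.chi_square == pytest.approx(trend_oracle(case, ctrl), abs=1e-8)
    assert r.chi_square == pytest.approx(14.5, abs=0.05)


def test_trend_affine_score_invariance():
    case, ctrl = RS2196447_COMBINED
    a = trend_test(case, ctrl, (0, 1, 2))
    b = trend_test(case, ctrl, (10, 20, 30))
    assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)
    c = trend_test(ctrl, case)  # swap labels
    assert c.chi_square == pytest.approx(a.chi_square, rel=1e-12)


def test_trend_degenerate_input():
    assert trend_test((0, 0, 10), (0, 0, 20)).flagged
    with pytest.raises(ValueError):
        trend_test((1, 2, 3), (1, 2, 3), scores=(0, 0, 1))


def test_genotype_2df_identical_rows():
    r = genotype_test_2df((5, 10, 5), (5, 10, 5))
    assert r.chi_square == pytest.approx(0.0, abs=1e-12) and r.p_value == 1.0


def test_genotype_2df_combined_counts():
    case, ctrl = RS11845632_COMBINED
    r = genotype_test_2df(case, ctrl)
    chi2, p = pearson_chi2_oracle([case, ctrl])
    assert r.chi_square == pytest.approx(chi2, abs=1e-10)
    assert r.p_value == pytest.approx(7e-4, abs=1e-4)
    assert r.df == 2


def test_genotype_2df_drops_empty_class_with_flag():
    r = genotype_test_2df((10, 20, 0), (20, 10, 0))
    assert r.df == 1 and r.flagged
    chi2, _ = pearson_chi2_oracle([[10, 20], [20, 10]])
    assert r.chi_square == pytest.approx(chi2, abs=1e-10)


def test_genotype_or_reproduces_published_results():
    case, ctrl = RS11845632_COMBINED
    het, hom = genotype_or(case, ctrl)
    assert round(hom.odds_ratio, 2) == 2.16
    assert round(hom.ci_low, 2) == 1.43 and round(hom.ci_high, 2) == 3.27
    case, ctrl = RS2196447_COMBINED
    het, hom = genotype_or(case, ctrl)
    assert round(hom.odds_ratio, 2) == 0.49
    assert round(hom.ci_low, 2) == 0.32 and round(hom.ci_high, 2) == 0.74


def test_genotype_or_identity_and_zero_cells():
    for orci in genotype_or((10, 20, 30), (10, 20, 30)):
        assert orci.odds_ratio == pytest.approx(1.0)
    # Haldane-Anscombe 0.5 against the hand-coded oracle
    het, hom = genotype_or((0, 5, 10), (4, 5, 10))
    assert (het.odds_ratio, het.ci_low, het.ci_high) == pytest.approx(
        woolf_ci_oracle(5, 0, 5, 4))
    with pytest.raises(ValueError):
        genotype_or((0, 5, 5), (0, 5, 5))


def test_combine_cohorts_reproduces_combined_counts(count_table):
    combined = combine_cohorts(count_table[count_table["cohort"] == "test"],
                               count_table[count_table["cohort"] == "replication"])
    row = combined.set_index(["snp_id", "group"])
    assert row.loc[("rs11845632", "case"), COUNT_COLUMNS].tolist() == [46, 195, 168]
    assert row.loc[("rs11845632", "control"), COUNT_COLUMNS].tolist() == [94, 262, 159]
    assert row.loc[("rs2196447", "case"), COUNT_COLUMNS].tolist() == [67, 220, 122]
    assert row.loc[("rs2196447", "control"), COUNT_COLUMNS].tolist() == [57, 245, 213]


def test_combine_cohorts_identity_and_mismatch(count_table):
    test = count_table[count_table["cohort"] == "test"]
    zero = test.copy()
    zero[COUNT_COLUMNS] = 0
    out = combine_cohorts(test, zero).set_index(["snp_id", "group"])
    ref = test.set_index(["snp_id", "group"])
    assert (out[COUNT_COLUMNS] == ref[COUNT_COLUMNS]).all().all()
    flipped = test.copy()
    flipped["allele_a"] = "T"
    with pytest.raises(ValueError, match="allele"):
        combine_cohorts(test, flipped)


def test_power_chisq():
    assert power_chisq(0.05, 1, 0.0) == pytest.approx(0.05)
    assert power_chisq(0.05, 1, 7.849) == pytest.approx(0.80, abs=0.001)
    assert power_chisq(0.05, 1, 500.0) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        power_chisq(0.0, 1, 1.0)
    with pytest.raises(ValueError):
        power_chisq(0.05, 1, -1.0)


def test_analyze_count_table_and_report(count_table):
    results = analyze_count_table(count_table, combine=True)
    frame = results_to_frame(results)
    assert set(frame["cohort"]) == {"test", "replication", "combined"}
    combined = frame[(frame["cohort"] == "combined")
                     & (frame["snp_id"] == "rs11845632")].iloc[0]
    assert combined["risk_allele"] == "b"
    assert round(combined["allele_or"], 2) == 1.44
    report = format_report(results)
    assert "OR = 1.44" in report and "1.19-1.73" in report


def test_hwe_population_conventions():
    case, ctrl = RS11845632_COMBINED
    from poolgwas import analyze_snp
    on_all = analyze_snp("rs11845632", case, ctrl, hwe_population="all")
    on_ctrl = analyze_snp("rs11845632", case, ctrl, hwe_population="control")
    assert round(on_all.hwe.p_value, 3) == 0.339
    assert on_ctrl.hwe.p_value != on_all.hwe.p_value


def test_hwe_oracle_agreement():
    chi2, p = hwe_oracle(140, 457, 327)
    r = hwe_test(140, 457, 327)
    assert r.chi_square == pytest.approx(chi2, abs=1e-12)
    assert r.p_value == pytest.approx(p, abs=1e-12)
    # allele collapse helper agrees with the oracle's table
    case, ctrl = RS11845632_COMBINED
    tab = allele_table(case, ctrl)
    r = allele_test(case, ctrl, "a")
    chi2, p = pearson_chi2_oracle(tab)
    assert r.chi_square == pytest.approx(chi2, abs=1e-10)
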