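"""Stage-two statistics on individually genotyped case/control SNPs.

Given 3x2 genotype count tables (AA / AG / GG by case / control) this module
provides the Hardy-Weinberg equilibrium goodness-of-fit test, the allelic
Pearson chi-square with per-allele odds ratio and Woolf 95% confidence
interval, the Cochran-Armitage trend test, the 2-df genotypic chi-square,
per-genotype odds ratios against the wild-type homozygote, cohort combination
and a noncentral chi-square power function.

Conventions: no continuity corrections; Woolf intervals use z = 1.96; a
Haldane-Anscombe 0.5 is added to all four cells of a 2x2 only when some cell
is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.96

COUNT_COLUMNS = ["n_AA", "n_AG", "n_GG"]


def _triple(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (3,):
        raise ValueError("genotype counts must be a (n_AA, n_AG, n_GG) triple")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("genotype counts must be non-negative integers")
    return arr


@dataclass
class TestResult:
    chi_square: float
    p_value: float
    df: int = 1
    flagged: bool = False  # monomorphic / degenerate input


@dataclass
class OddsRatioCI:
    odds_ratio: float
    ci_low: float
    ci_high: float
    label: str = ""


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> TestResult:
    """1-df chi-square of observed genotype counts against the HWE expectation
    p^2 : 2pq : q^2 at the sample allele frequency. Monomorphic samples return
    p = 1 with a flag."""
    obs = _triple((n_aa, n_ab, n_bb))
    n = obs.sum()
    if n < 1:
        raise ValueError("hwe_test needs at least one individual")
    p = (2 * obs[0] + obs[1]) / (2 * n)
    if p == 0.0 or p == 1.0:
        return TestResult(0.0, 1.0, df=1, flagged=True)
    q = 1.0 - p
    exp = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return TestResult(chi2, float(stats.chi2.sf(chi2, 1)))


def _pearson_2x2(a1, b1, a2, b2) -> tuple[float, float, bool]:
    row1, row2 = a1 + b1, a2 + b2
    col1, col2 = a1 + a2, b1 + b2
    n = row1 + row2
    if min(row1, row2, col1, col2) == 0:
        return 0.0, 1.0, True
    chi2 = n * (a1 * b2 - b1 * a2) ** 2 / (row1 * row2 * col1 * col2)
    return float(chi2), float(stats.chi2.sf(chi2, 1)), False


def _woolf_or(a1, b1, a2, b2) -> OddsRatioCI:
    cells = np.array([a1, b1, a2, b2], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    a1, b1, a2, b2 = cells
    or_ = (a1 * b2) / (b1 * a2)
    se = float(np.sqrt((1.0 / cells).sum()))
    log_or = np.log(or_)
    return OddsRatioCI(float(or_), float(np.exp(log_or - Z_95 * se)),
                       float(np.exp(log_or + Z_95 * se)))


@dataclass
class AlleleTestResult:
    chi_square: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    freq_case: float
    freq_control: float
    allele: str
    flagged: bool = False


def allele_counts(counts, allele: str = "a") -> tuple[float, float]:
    """Collapse a genotype triple to (chosen allele, other allele) counts."""
    aa, ab, bb = _triple(counts)
    n_a, n_b = 2 * aa + ab, ab + 2 * bb
    return (n_a, n_b) if allele == "a" else (n_b, n_a)


def allele_test(case_counts, control_counts, allele: str = "a") -> AlleleTestResult:
    """Allelic 1-df Pearson chi-square and per-allele odds ratio with Woolf CI.

    ``allele`` selects which allele ("a" = first homozygote class, "b" =
    second) the odds ratio and frequencies refer to; the chi-square and p-value
    do not depend on the choice.
    """
    if allele not in ("a", "b"):
        raise ValueError("allele must be 'a' or 'b'")
    ca, cb = allele_counts(case_counts, allele)
    ua, ub = allele_counts(control_counts, allele)
    chi2, p, flagged = _pearson_2x2(ca, cb, ua, ub)
    if flagged:
        return AlleleTestResult(chi2, p, np.nan, np.nan, np.nan,
                                ca / max(ca + cb, 1), ua / max(ua + ub, 1),
                                allele, flagged=True)
    orci = _woolf_or(ca, cb, ua, ub)
    return AlleleTestResult(chi2, p, orci.odds_ratio, orci.ci_low, orci.ci_high,
                            ca / (ca + cb), ua / (ua + ub), allele)


def trend_test(case_counts, control_counts, scores=(0, 1, 2)) -> TestResult:
    """Cochran-Armitage 1-df trend test for a dose effect of the B allele.

    ``scores`` weight the genotype classes (default additive 0/1/2); the
    statistic is invariant under affine transformation of the scores and under
    swapping case and control labels.
    """
    r = _triple(case_counts)
    m = _triple(control_counts)
    s = np.asarray(scores, dtype=float)
    if s.shape != (3,) or not (np.all(np.diff(s) > 0) or np.all(np.diff(s) < 0)):
        raise ValueError("scores must be three strictly monotone values")
    n_i = r + m
    n = n_i.sum()
    rr = r.sum()
    if rr == 0 or rr == n or np.count_nonzero(n_i) < 2:
        return TestResult(0.0, 1.0, flagged=True)
    num = n * (s * r).sum() - rr * (s * n_i).sum()
    var = rr * (n - rr) * (n * (s * s * n_i).sum() - ((s * n_i).sum()) ** 2)
    if var == 0:
        return TestResult(0.0, 1.0, flagged=True)
    chi2 = float(n * num * num / var)
    return TestResult(chi2, float(stats.chi2.sf(chi2, 1)))


def genotype_test_2df(case_counts, control_counts) -> TestResult:
    """Pearson chi-square on the 3x2 genotype table (2 df).

    Genotype classes empty in both groups are dropped with the degrees of
    freedom adjusted and the result flagged.
    """
    r = _triple(case_counts)
    m = _triple(control_counts)
    keep = (r + m) > 0
    r, m = r[keep], m[keep]
    k = keep.sum()
    flagged = k < 3
    if k < 2 or r.sum() == 0 or m.sum() == 0:
        return TestResult(0.0, 1.0, df=max(int(k) - 1, 0), flagged=True)
    n = r.sum() + m.sum()
    exp_r = (r + m) * r.sum() / n
    exp_m = (r + m) * m.sum() / n
    chi2 = float(((r - exp_r) ** 2 / exp_r).sum() + ((m - exp_m) ** 2 / exp_m).sum())
    df = int(k) - 1
    return TestResult(chi2, float(stats.chi2.sf(chi2, df)), df=df, flagged=bool(flagged))


def genotype_or(case_counts, control_counts, reference: int = 0) -> list[OddsRatioCI]:
    """Per-genotype odds ratios against a reference class (default AA).

    Returns one :class:`OddsRatioCI` per non-reference class, in triple order.
    If the reference class is empty in both groups the ratios are undefined.
    """
    r = _triple(case_counts)
    m = _triple(control_counts)
    labels = ("AA", "AG", "GG")
    if reference not in (0, 1, 2):
        raise ValueError("reference must index a genotype class (0, 1 or 2)")
    if r[reference] + m[reference] == 0:
        raise ValueError("reference genotype class empty in both groups")
    out = []
    for i in range(3):
        if i == reference:
            continue
        orci = _woolf_or(r[i], r[reference], m[i], m[reference])
        orci.label = f"{labels[i]} vs {labels[reference]}"
        out.append(orci)
    return out


def combine_cohorts(test: pd.DataFrame, replication: pd.DataFrame) -> pd.DataFrame:
    """Elementwise sum of two cohort count tables into a "combined" cohort.

    Both tables need one row per (snp_id, group) with columns n_AA, n_AG, n_GG
    and matching allele labels; mismatched alleles are an error (no silent
    strand flipping).
    """
    keys = ["snp_id", "group"]
    allele_cols = [c for c in ("allele_a", "allele_b") if c in test.columns]
    t = test.set_index(keys).sort_index()
    rpl = replication.set_index(keys).sort_index()
    if not t.index.equals(rpl.index):
        raise ValueError("cohort tables must cover the same (snp_id, group) rows")
    for col in allele_cols:
        if not (t[col] == rpl[col]).all():
            raise ValueError("allele labels differ between cohorts")
    out = t[COUNT_COLUMNS] + rpl[COUNT_COLUMNS]
    out = out.reset_index()
    out["cohort"] = "combined"
    for col in allele_cols:
        out[col] = t[col].to_numpy()
    return out


def power_chisq(alpha: float, df: int, noncentrality: float) -> float:
    """Power of a chi-square test: P(noncentral chi2(df, ncp) > critical value
    of the central chi2 at level ``alpha``)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    if noncentrality < 0:
        raise ValueError("noncentrality must be non-negative")
    crit = stats.chi2.isf(alpha, df)
    if noncentrality == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, noncentrality))


@dataclass
class IndividualAssocResult:
    """Full stage-two summary for one SNP in one cohort."""

    snp_id: str
    cohort: str
    hwe: TestResult
    allele: AlleleTestResult
    trend: TestResult
    genotype_2df: TestResult
    genotype_ors: list[OddsRatioCI]
    risk_allele: str


def analyze_snp(snp_id: str, case_counts, control_counts, cohort: str = "combined",
                allele: str = "auto", hwe_population: str = "all") -> IndividualAssocResult:
    """All stage-two statistics for one SNP.

    ``allele="auto"`` reports the odds ratio for the risk allele (the one more
    frequent in cases). ``hwe_population`` selects whose genotypes enter the
    HWE test: "all" (cases + controls), "control" or "case".
    """
    case = _triple(case_counts)
    ctrl = _triple(control_counts)
    if allele == "auto":
        probe = allele_test(case, ctrl, "a")
        allele = "a" if probe.freq_case >= probe.freq_control else "b"
    at = allele_test(case, ctrl, allele)
    hwe_counts = {"all": case + ctrl, "control": ctrl, "case": case}[hwe_population]
    return IndividualAssocResult(
        snp_id=snp_id,
        cohort=cohort,
        hwe=hwe_test(*hwe_counts),
        allele=at,
        trend=trend_test(case, ctrl),
        genotype_2df=genotype_test_2df(case, ctrl),
        genotype_ors=genotype_or(case, ctrl),
        risk_allele=allele,
    )


def load_genotype_counts(path=None) -> pd.DataFrame:
    """Read a genotype-count TSV (snp_id, cohort, group, n_AA, n_AG, n_GG,
    allele_a, allele_b). Without a path, loads the packaged two-SNP
    case/control table used throughout the examples."""
    if path is None:
        ref = resources.files("poolgwas").joinpath("fixtures/nrxn3_counts.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    need = {"snp_id", "cohort", "group", *COUNT_COLUMNS}
    if need - set(df.columns):
        raise ValueError(f"count table missing columns: {sorted(need - set(df.columns))}")
    return df


def analyze_count_table(counts: pd.DataFrame, combine: bool = True,
                        hwe_population: str = "all") -> list[IndividualAssocResult]:
    """Run :func:`analyze_snp` for every SNP and cohort in a count table,
    optionally appending the combined cohort."""
    cohorts = list(counts["cohort"].unique())
    frames = [counts[counts["cohort"] == c] for c in cohorts]
    if combine and {"test", "replication"} <= set(cohorts):
        combined = combine_cohorts(counts[counts["cohort"] == "test"],
                                   counts[counts["cohort"] == "replication"])
        frames.append(combined)
        cohorts.append("combined")
    results = []
    for cohort, frame in zip(cohorts, frames):
        for snp_id, sub in frame.groupby("snp_id", sort=True):
            by_group = sub.set_index("group")
            results.append(analyze_snp(
                snp_id,
                by_group.loc["case", COUNT_COLUMNS].to_numpy(),
                by_group.loc["control", COUNT_COLUMNS].to_numpy(),
                cohort=cohort, hwe_population=hwe_population))
    return results


def results_to_frame(results: list[IndividualAssocResult]) -> pd.DataFrame:
    """Flatten analysis results to one row per SNP x cohort."""
    rows = []
    for r in results:
        row = {
            "snp_id": r.snp_id, "cohort": r.cohort, "risk_allele": r.risk_allele,
            "hwe_chi2": r.hwe.chi_square, "hwe_p": r.hwe.p_value,
            "allele_chi2": r.allele.chi_square, "allele_p": r.allele.p_value,
            "allele_or": r.allele.odds_ratio,
            "allele_ci_low": r.allele.ci_low, "allele_ci_high": r.allele.ci_high,
            "freq_case": r.allele.freq_case, "freq_control": r.allele.freq_control,
            "trend_chi2": r.trend.chi_square, "trend_p": r.trend.p_value,
            "genotype_chi2": r.genotype_2df.chi_square,
            "genotype_p": r.genotype_2df.p_value,
        }
        for orci in r.genotype_ors:
            key = orci.label.split(" ")[0].lower()
            row[f"or_{key}"] = orci.odds_ratio
            row[f"or_{key}_ci_low"] = orci.ci_low
            row[f"or_{key}_ci_high"] = orci.ci_high
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(results: list[IndividualAssocResult]) -> str:
    """Human-readable stage-two report: frequencies to 0.1%, odds ratios and
    CIs to two decimals, p-values to four decimals."""
    lines = []
    for r in results:
        lines.append(f"{r.snp_id} [{r.cohort}] risk allele {r.risk_allele.upper()}")
        lines.append(
            f"  risk-allele frequency: cases {100 * r.allele.freq_case:.1f}%"
            f"  controls {100 * r.allele.freq_control:.1f}%")
        lines.append(
            f"  allele test: chi2 = {r.allele.chi_square:.2f}, p = {r.allele.p_value:.4f},"
            f" OR = {r.allele.odds_ratio:.2f}"
            f" (95% CI {r.allele.ci_low:.2f}-{r.allele.ci_high:.2f})")
        lines.append(f"  trend test: chi2 = {r.trend.chi_square:.2f}, p = {r.trend.p_value:.4f}")
        lines.append(f"  genotype test ({r.genotype_2df.df} df): p = {r.genotype_2df.p_value:.4f}")
        for orci in r.genotype_ors:
            lines.append(f"  {orci.label}: OR = {orci.odds_ratio:.2f}"
                         f" ({orci.ci_low:.2f}-{orci.ci_high:.2f})")
        lines.append(f"  HWE: chi2 = {r.hwe.chi_square:.2f}, p = {r.hwe.p_value:.4f}")
    return "\n".join(lines)
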