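"""Stage-one association screening on pooled allele-frequency estimates.

Within each gender, case and control pool RAFs are compared with a 1-df
Pearson chi-square on the reconstructed 2x2 allele-count table, multiple
testing is controlled by Benjamini-Hochberg FDR, and the two genders are
combined by ranking SNPs on log10 p within gender and ordering on the sum of
the two ranks (smaller sum first; ties broken by the larger case-control RAF
difference, then lexically by SNP id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PooledTest:
    """1-df chi-square comparison of two pool allele frequencies."""

    chi_square: float | np.ndarray
    p_value: float | np.ndarray
    odds_ratio: float | np.ndarray
    monomorphic: bool | np.ndarray


def _effective_counts(raf, n, mode: str) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("pool sizes must be >= 1")
    m = 2.0 * n if mode == "chromosomes" else n
    a = np.round(np.clip(np.asarray(raf, dtype=float), 0.0, 1.0) * m)
    return a, m - a


def pooled_chisq(raf_case, raf_control, n_case, n_control,
                 effective_n_mode: str = "chromosomes") -> PooledTest:
    """Compare two pool RAFs via a reconstructed 2x2 allele-count table.

    Allele counts are ``round(2n * raf)`` per pool (or ``round(n * raf)`` with
    ``effective_n_mode="individuals"``); the test is the 1-df Pearson
    chi-square without continuity correction. The odds ratio is for allele A
    (case vs control); a zero allele margin marks the SNP monomorphic with
    p = 1 and an undefined OR.
    """
    if effective_n_mode not in ("chromosomes", "individuals"):
        raise ValueError("effective_n_mode must be 'chromosomes' or 'individuals'")
    r1 = np.asarray(raf_case, dtype=float)
    if np.any(r1 < 0) or np.any(r1 > 1):
        raise ValueError("raf_case outside [0, 1]")
    r2 = np.asarray(raf_control, dtype=float)
    if np.any(r2 < 0) or np.any(r2 > 1):
        raise ValueError("raf_control outside [0, 1]")

    a1, b1 = _effective_counts(r1, n_case, effective_n_mode)
    a2, b2 = _effective_counts(r2, n_control, effective_n_mode)
    row1, row2 = a1 + b1, a2 + b2
    col_a, col_b = a1 + a2, b1 + b2
    n = row1 + row2

    mono = (col_a == 0) | (col_b == 0)
    denom = np.where(mono, 1.0, row1 * row2 * col_a * col_b)
    chi2 = np.where(mono, 0.0, n * (a1 * b2 - b1 * a2) ** 2 / denom)
    p = np.where(mono, 1.0, stats.chi2.sf(chi2, df=1))

    zero_cell = (a1 == 0) | (b1 == 0) | (a2 == 0) | (b2 == 0)
    h = np.where(zero_cell & ~mono, 0.5, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        odds = np.where(mono, np.nan,
                        ((a1 + h) * (b2 + h)) / ((b1 + h) * (a2 + h)))

    if chi2.ndim == 0:
        return PooledTest(float(chi2), float(p), float(odds), bool(mono))
    return PooledTest(chi2, p, odds, mono)


def fdr_select(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up at level ``q``; returns boolean flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def rank_combine(records: pd.DataFrame) -> pd.DataFrame:
    """Combine per-gender evidence by summed logP rank.

    ``records`` needs columns snp_id, p_female, p_male, raf_diff_female,
    raf_diff_male. Within each gender SNPs are ranked by ascending p (rank 1 =
    smallest p; exact ties get the average rank). The output is sorted by
    ascending rank sum, ties broken by the larger gender-averaged |RAF
    difference|, then by snp_id; ``combined_rank`` is the 1-based position in
    that order.
    """
    for col in ("snp_id", "p_female", "p_male", "raf_diff_female", "raf_diff_male"):
        if col not in records.columns:
            raise ValueError(f"rank_combine input missing column {col}")
    if records["snp_id"].duplicated().any():
        raise ValueError("duplicated snp_id in rank_combine input")
    df = records.copy()
    usable = df[["p_female", "p_male"]].notna().all(axis=1)
    if not usable.all():
        logger.warning("rank_combine: excluding %d SNPs lacking a p-value in "
                       "one gender", int((~usable).sum()))
        df = df[usable].copy()
    df["rank_female"] = stats.rankdata(df["p_female"], method="average")
    df["rank_male"] = stats.rankdata(df["p_male"], method="average")
    df["rank_sum"] = df["rank_female"] + df["rank_male"]
    df["mean_abs_raf_diff"] = (df["raf_diff_female"].abs()
                               + df["raf_diff_male"].abs()) / 2.0
    df = df.sort_values(
        by=["rank_sum", "mean_abs_raf_diff", "snp_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["combined_rank"] = np.arange(1, len(df) + 1)
    return df


def folded_or(odds_ratio) -> np.ndarray:
    """Direction-agnostic effect size max(OR, 1/OR)."""
    o = np.asarray(odds_ratio, dtype=float)
    out = np.where(o > 0, np.maximum(o, 1.0 / o), np.nan)
    return float(out) if out.ndim == 0 else out


def screen_candidates(odds_ratios, p_values, or_min: float = 1.4,
                      p_max: float = 0.05) -> tuple[np.ndarray, dict]:
    """Retain SNPs with folded OR above ``or_min`` and p below ``p_max``.

    Monomorphic SNPs (OR undefined, NaN) are never retained. Returns the
    boolean mask and a funnel of counts at each filter step.
    """
    o = np.atleast_1d(np.asarray(odds_ratios, dtype=float))
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if o.shape != p.shape:
        raise ValueError("odds_ratios and p_values must align")
    defined = np.isfinite(o) & (o > 0)
    p_pass = defined & (p < p_max)
    or_pass = defined & (folded_or(np.where(defined, o, 1.0)) > or_min)
    mask = p_pass & or_pass
    funnel = {
        "n_input": int(o.size),
        "n_defined": int(defined.sum()),
        "n_p_pass": int(p_pass.sum()),
        "n_or_pass": int(or_pass.sum()),
        "n_retained": int(mask.sum()),
    }
    return mask, funnel


@dataclass
class PooledAssociationResult:
    """Per-SNP pooled-stage records plus the filtering funnel."""

    records: pd.DataFrame
    funnel: dict = field(default_factory=dict)


def run_pooled_association(raf: pd.DataFrame, design: pd.DataFrame,
                           fdr_q: float = 0.05, or_min: float = 1.4,
                           p_max: float = 0.05,
                           effective_n_mode: str = "chromosomes",
                           ) -> PooledAssociationResult:
    """Gender-stratified pooled screening over a RAF table.

    ``raf`` comes from :func:`poolgwas.calibration.calibrate_pools`; ``design``
    maps each pool_id to group, gender and n_individuals, with exactly one pool
    per (group, gender). Only SNPs whose four pools all pass replicate QC are
    tested. FDR is applied within gender; a SNP is ``fdr_significant`` when
    flagged in both genders. Candidate screening (folded OR, p) must also hold
    in both genders.
    """
    need = {"pool_id", "group", "gender", "n_individuals"}
    if need - set(design.columns):
        raise ValueError(f"design table missing columns: {sorted(need - set(design.columns))}")
    strata = design.set_index(["group", "gender"])
    if strata.index.duplicated().any():
        raise ValueError("each (group, gender) stratum must map to exactly one pool")

    ok = raf.groupby("snp_id")["qc_pass"].agg(["all", "size"])
    n_pools = len(design)
    tested = ok.index[(ok["all"]) & (ok["size"] == n_pools)]
    n_excluded = int(len(ok) - len(tested))
    if n_excluded:
        logger.info("excluding %d SNPs failing pool QC", n_excluded)

    wide = (raf[raf["snp_id"].isin(tested)]
            .pivot(index="snp_id", columns="pool_id", values="raf_mean")
            .sort_index())

    out = pd.DataFrame({"snp_id": wide.index.to_numpy()})
    for gender in ("female", "male"):
        case = strata.loc[("case", gender)]
        ctrl = strata.loc[("control", gender)]
        t = pooled_chisq(wide[case["pool_id"]].to_numpy(),
                         wide[ctrl["pool_id"]].to_numpy(),
                         case["n_individuals"], ctrl["n_individuals"],
                         effective_n_mode)
        out[f"chi2_{gender}"] = t.chi_square
        out[f"p_{gender}"] = t.p_value
        out[f"or_{gender}"] = t.odds_ratio
        out[f"raf_diff_{gender}"] = (wide[case["pool_id"]]
                                     - wide[ctrl["pool_id"]]).to_numpy()
        out[f"fdr_{gender}"] = fdr_select(out[f"p_{gender}"], fdr_q)
    out["fdr_significant"] = out["fdr_female"] & out["fdr_male"]

    mask_f, funnel_f = screen_candidates(out["or_female"], out["p_female"], or_min, p_max)
    mask_m, funnel_m = screen_candidates(out["or_male"], out["p_male"], or_min, p_max)
    out["candidate"] = mask_f & mask_m

    ranked = rank_combine(out.rename(columns={}))
    funnel = {
        "n_snps_input": int(len(ok)),
        "n_snps_qc_pass": int(len(tested)),
        "female": funnel_f,
        "male": funnel_m,
        "n_candidates": int(ranked["candidate"].sum()),
        "n_fdr_significant": int(ranked["fdr_significant"].sum()),
    }
    return PooledAssociationResult(records=ranked, funnel=funnel)
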