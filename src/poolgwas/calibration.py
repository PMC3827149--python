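"""Pooled-array allele-frequency estimation with per-SNP dye-bias correction.

The estimation chain per SNP and pool replicate is

    RAS  = A / (A + B)                  relative allele signal
    RAFk = A / (A + k * B)              dye-bias corrected allele frequency
    RAF  = (RAFk - ras_hom_B) / (ras_hom_A - ras_hom_B), clipped to [0, 1]

where k is the mean A:B intensity ratio over known heterozygous individuals
(a heterozygote is a 50% pool, so its ratio measures pure dye bias) and the
homozygote RAS anchors rescale against signal compression at the extremes.
Replicate RAFs are averaged; SNP-pool combinations whose replicate standard
deviation exceeds a threshold are flagged as QC failures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFERENCE_COLUMNS = ["snp_id", "k", "ras_hom_A", "ras_hom_B",
                     "n_het", "n_hom_A", "n_hom_B", "k_fallback", "calibratable"]


def ras(channel_a, channel_b):
    """Relative allele signal A/(A+B). Scale invariant; defined for A+B > 0."""
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("channel intensities must be non-negative")
    total = a + b
    if np.any(total <= 0):
        raise ValueError("RAS undefined where A + B = 0")
    out = a / total
    return float(out) if out.ndim == 0 else out


def raf_corrected(channel_a, channel_b, k):
    """Dye-bias corrected allele frequency A/(A + k*B); equals RAS at k = 1."""
    kk = np.asarray(k, dtype=float)
    if np.any(kk <= 0):
        raise ValueError("correction factor k must be positive")
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("channel intensities must be non-negative")
    denom = a + kk * b
    if np.any(denom <= 0):
        raise ValueError("RAF undefined where A + k*B = 0")
    out = a / denom
    return float(out) if out.ndim == 0 else out


def compute_k(het_intensities) -> float:
    """Correction factor k: arithmetic mean of A/B over known heterozygotes.

    ``het_intensities`` is an iterable of (channel_A, channel_B) pairs; every
    pair needs channel_B > 0.
    """
    pairs = np.asarray(list(het_intensities), dtype=float)
    if pairs.size == 0:
        raise ValueError("compute_k requires at least one heterozygote record")
    a, b = pairs[:, 0], pairs[:, 1]
    if np.any(b <= 0):
        raise ValueError("heterozygote records must have channel_B > 0")
    return float(np.mean(a / b))


def normalize_to_homozygotes(raf_raw, ras_hom_a, ras_hom_b):
    """Rescale a raw RAF against the homozygote RAS anchors, clipping to [0, 1].

    ``ras_hom_a`` is the mean RAS of A-homozygotes (upper anchor), ``ras_hom_b``
    of B-homozygotes (lower anchor).
    """
    hi = np.asarray(ras_hom_a, dtype=float)
    lo = np.asarray(ras_hom_b, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("non-calibratable SNP: ras_hom_A must exceed ras_hom_B")
    out = np.clip((np.asarray(raf_raw, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class RafEstimate:
    """Replicate-averaged corrected allele frequency of one SNP in one pool."""

    snp_id: str
    pool_id: str
    raf_mean: float
    raf_replicates: tuple
    replicate_sd: float
    qc_pass: bool


def summarize_replicates(raf_values, variance_threshold: float = 0.02,
                         snp_id: str = "", pool_id: str = "") -> RafEstimate:
    """Average replicate RAFs and apply the replicate-variability QC filter.

    qc_pass is true when the sample standard deviation across replicates is at
    most ``variance_threshold`` (in allele-frequency units). A single replicate
    cannot be QC'd: it passes with a warning.
    """
    vals = np.asarray(list(raf_values), dtype=float)
    if vals.size == 0:
        raise ValueError("summarize_replicates needs at least one replicate")
    mean = float(vals.mean())
    if vals.size == 1:
        logger.warning("single replicate for %s/%s: QC forced to pass", snp_id, pool_id)
        return RafEstimate(snp_id, pool_id, mean, tuple(vals), 0.0, True)
    sd = float(vals.std(ddof=1))
    return RafEstimate(snp_id, pool_id, mean, tuple(vals), sd,
                       bool(sd <= variance_threshold))


def build_reference(calibration: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP calibration reference from individual arrays of known genotype.

    ``calibration`` columns: snp_id, genotype_class in {AA, AB, BB}, channel_A,
    channel_B (subject_id optional). Returns one row per SNP with k, homozygote
    RAS anchors and supporting counts. SNPs with no usable heterozygote fall
    back to k = 1 (``k_fallback`` true); SNPs whose anchors coincide are marked
    non-calibratable.
    """
    required = {"snp_id", "genotype_class", "channel_A", "channel_B"}
    missing = required - set(calibration.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    bad = ~calibration["genotype_class"].isin(("AA", "AB", "BB"))
    if bad.any():
        raise ValueError("genotype_class must be one of AA, AB, BB")

    df = calibration.copy()
    total = df["channel_A"] + df["channel_B"]
    n_dropped = int((total <= 0).sum())
    if n_dropped:
        logger.warning("dropping %d calibration records with A+B = 0", n_dropped)
        df = df[total > 0]
    df["ras"] = df["channel_A"] / (df["channel_A"] + df["channel_B"])

    het = df[(df["genotype_class"] == "AB") & (df["channel_B"] > 0)]
    ratio = (het["channel_A"] / het["channel_B"]).groupby(het["snp_id"]).agg(["mean", "size"])

    def _anchor(cls):
        sub = df[df["genotype_class"] == cls]
        return sub.groupby("snp_id")["ras"].agg(["mean", "size"])

    hom_a, hom_b = _anchor("AA"), _anchor("BB")
    snps = pd.Index(sorted(df["snp_id"].unique()), name="snp_id")
    ref = pd.DataFrame(index=snps)
    ref["k"] = ratio["mean"].reindex(snps)
    ref["n_het"] = ratio["size"].reindex(snps).fillna(0).astype(int)
    ref["k_fallback"] = ref["k"].isna()
    n_fallback = int(ref["k_fallback"].sum())
    if n_fallback:
        logger.warning("%d SNPs without heterozygotes: falling back to k = 1", n_fallback)
    ref["k"] = ref["k"].fillna(1.0)
    ref["ras_hom_A"] = hom_a["mean"].reindex(snps).fillna(1.0)
    ref["n_hom_A"] = hom_a["size"].reindex(snps).fillna(0).astype(int)
    ref["ras_hom_B"] = hom_b["mean"].reindex(snps).fillna(0.0)
    ref["n_hom_B"] = hom_b["size"].reindex(snps).fillna(0).astype(int)
    ref["calibratable"] = ref["ras_hom_A"] > ref["ras_hom_B"]
    return ref.reset_index()[REFERENCE_COLUMNS]


def calibrate_pools(intensities: pd.DataFrame, reference: pd.DataFrame,
                    replicate_sd_max: float = 0.02) -> pd.DataFrame:
    """Corrected, QC-filtered RAF estimates for every (SNP, pool).

    ``intensities`` columns: snp_id, pool_id, replicate, channel_A, channel_B.
    ``reference`` is the output of :func:`build_reference`. Records with
    A + B = 0, or whose SNP is non-calibratable, are dropped with a logged
    count; estimation of one record never depends on any other record.
    """
    required = {"snp_id", "pool_id", "replicate", "channel_A", "channel_B"}
    missing = required - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    dup = intensities.duplicated(subset=["snp_id", "pool_id", "replicate"])
    if dup.any():
        raise ValueError("replicate indices must be unique within (snp, pool)")

    df = intensities.merge(reference, on="snp_id", how="left", validate="many_to_one")
    if df["k"].isna().any():
        missing_snps = sorted(df.loc[df["k"].isna(), "snp_id"].unique())[:5]
        raise ValueError(f"no calibration reference for SNPs: {missing_snps} ...")

    analyzable = (df["channel_A"] + df["channel_B"] > 0) & df["calibratable"]
    n_dropped = int((~analyzable).sum())
    if n_dropped:
        logger.warning("dropping %d non-analyzable pool records", n_dropped)
    df = df[analyzable].copy()

    raw = raf_corrected(df["channel_A"].to_numpy(), df["channel_B"].to_numpy(),
                        df["k"].to_numpy())
    df["raf"] = normalize_to_homozygotes(raw, df["ras_hom_A"].to_numpy(),
                                         df["ras_hom_B"].to_numpy())

    g = df.groupby(["snp_id", "pool_id"])["raf"]
    out = g.agg(raf_mean="mean", replicate_sd=lambda v: v.std(ddof=1),
                n_replicates="size").reset_index()
    single = out["n_replicates"] == 1
    out.loc[single, "replicate_sd"] = 0.0
    if single.any():
        logger.warning("%d SNP-pool combinations had a single replicate", int(single.sum()))
    out["qc_pass"] = out["replicate_sd"] <= replicate_sd_max
    out.loc[single, "qc_pass"] = True
    return out
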