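"""Synthetic data generator for the pooled-GWAS pipeline.

Emulates a gender-stratified case/control study assayed by DNA pooling on a
two-channel SNP array:

* individual genotypes drawn under Hardy-Weinberg equilibrium at per-group
  allele frequencies, with a minority of "effect" SNPs whose case frequency is
  shifted by a fixed delta;
* individual two-channel calibration intensities, where channel A is
  proportional to the A-allele dosage and channel B to the B-allele dosage
  attenuated by a per-SNP dye-bias factor k (a known heterozygote therefore has
  expected A:B ratio k);
* pooled intensities, one pool per group x gender stratum, built from the
  equimolar sum of member dosages and hybridised in ``n_replicates`` technical
  replicates, each with independent multiplicative lognormal noise per channel.

SNPs are simulated independently (no linkage disequilibrium); there are no
chip spatial artifacts or batch effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GENDERS, GROUPS, STRATA, SimulationConfig

GENOTYPE_CLASSES = np.array(["BB", "AB", "AA"])  # indexed by A-allele dosage
_INTENSITY_SCALE = 1000.0

# spawn keys for per-stage independent RNG substreams
_STAGE_GENOTYPES = 0
_STAGE_BIAS = 1
_STAGE_CALIBRATION = 2
_STAGE_POOLS = 3


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent substream per pipeline stage from one root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with subject metadata.

    ``dosage[i, j]`` is the number of A alleles (0, 1 or 2) carried by subject
    ``i`` at SNP ``j``.
    """

    subjects: pd.DataFrame  # subject_id, group, gender
    snp_ids: np.ndarray
    dosage: np.ndarray  # (n_subjects, n_snps) int8
    truth: pd.DataFrame  # snp_id, true_f_case, true_f_control, is_effect

    def stratum_mask(self, group: str, gender: str) -> np.ndarray:
        return ((self.subjects["group"] == group)
                & (self.subjects["gender"] == gender)).to_numpy()

    def to_long(self) -> pd.DataFrame:
        n_subj, n_snp = self.dosage.shape
        return pd.DataFrame({
            "subject_id": np.repeat(self.subjects["subject_id"].to_numpy(), n_snp),
            "group": np.repeat(self.subjects["group"].to_numpy(), n_snp),
            "gender": np.repeat(self.subjects["gender"].to_numpy(), n_snp),
            "snp_id": np.tile(self.snp_ids, n_subj),
            "dosage": self.dosage.ravel(),
        })


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw HWE genotypes for every subject in the four strata.

    Cases use ``maf_control + effect_delta`` at effect SNPs; dosages are
    binomial(2, f) per subject, i.e. exact HWE sampling.
    """
    config.validate()
    rng = _stage_rng(config.seed, _STAGE_GENOTYPES)
    f_control = config.control_freqs
    f_case = config.case_freqs

    snp_ids = np.array([f"snp{j:05d}" for j in range(config.n_snps)])
    rows, blocks = [], []
    idx = 0
    for group, gender in STRATA:
        n = config.stratum_size(group, gender)
        if n < 1:
            raise ValueError(f"empty stratum: {group}/{gender}")
        f = f_case if group == "case" else f_control
        blocks.append(rng.binomial(2, f, size=(n, config.n_snps)).astype(np.int8))
        rows.append(pd.DataFrame({
            "subject_id": [f"S{idx + i:04d}" for i in range(n)],
            "group": group,
            "gender": gender,
        }))
        idx += n

    truth = pd.DataFrame({
        "snp_id": snp_ids,
        "true_f_case": f_case,
        "true_f_control": f_control,
        "is_effect": np.arange(config.n_snps) < config.n_effect_snps,
    })
    return GenotypeMatrix(
        subjects=pd.concat(rows, ignore_index=True),
        snp_ids=snp_ids,
        dosage=np.vstack(blocks),
        truth=truth,
    )


def simulate_dye_bias(config: SimulationConfig) -> np.ndarray:
    """Per-SNP dye-bias factors k, lognormal with median ``k_mean``.

    The log-scale spread is ``k_sd / k_mean`` so the linear standard deviation
    is approximately ``k_sd``; values are clipped to [0.2, 5] to avoid
    degenerate channels.
    """
    config.validate()
    rng = _stage_rng(config.seed, _STAGE_BIAS)
    sigma = config.k_sd / config.k_mean
    k = config.k_mean * np.exp(rng.normal(0.0, sigma, size=config.n_snps))
    return np.clip(k, 0.2, 5.0)


def _noisy(base: np.ndarray, rng: np.random.Generator, cv: float) -> np.ndarray:
    if cv == 0:
        return base
    return base * np.exp(rng.normal(0.0, _lognormal_sigma(cv), size=base.shape))


def simulate_individual_intensities(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    snp_k: np.ndarray,
) -> pd.DataFrame:
    """Two-channel intensities for every subject x SNP (calibration arrays).

    Channel A is proportional to the A dosage and channel B to (2 - dosage)
    scaled by 1/k, so a heterozygote's expected A:B ratio equals k. Both
    channels carry independent multiplicative noise with CV ``noise_cv``.
    Returns a long table: snp_id, subject_id, genotype_class, channel_A,
    channel_B.
    """
    if snp_k.shape != (config.n_snps,):
        raise ValueError("snp_k must have one entry per SNP")
    rng = _stage_rng(config.seed, _STAGE_CALIBRATION)
    d = genotypes.dosage.astype(float)
    a = _noisy(_INTENSITY_SCALE * d, rng, config.noise_cv)
    b = _noisy(_INTENSITY_SCALE * (2.0 - d) / snp_k[None, :], rng, config.noise_cv)
    n_subj, n_snp = d.shape
    return pd.DataFrame({
        "snp_id": np.tile(genotypes.snp_ids, n_subj),
        "subject_id": np.repeat(genotypes.subjects["subject_id"].to_numpy(), n_snp),
        "genotype_class": GENOTYPE_CLASSES[genotypes.dosage.ravel()],
        "channel_A": a.ravel(),
        "channel_B": b.ravel(),
    })


def construct_pools(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    snp_k: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pool the strata and hybridise each pool in replicate.

    Pool channel A is the summed A dosage of the members, channel B the summed
    B dosage scaled by 1/k; each replicate draws fresh multiplicative noise.
    Optional per-individual weight jitter (``pool_weight_cv``) models unequal
    pipetting; it is off by default.

    Returns ``(intensities, design, pool_truth)``:
    intensities has columns snp_id, pool_id, replicate, channel_A, channel_B;
    design maps pool_id -> group, gender, n_individuals; pool_truth holds each
    pool's realized A-allele frequency per SNP (the estimand of calibration).
    """
    if snp_k.shape != (config.n_snps,):
        raise ValueError("snp_k must have one entry per SNP")
    rng = _stage_rng(config.seed, _STAGE_POOLS)

    frames, design_rows, truth_rows = [], [], []
    for group, gender in STRATA:
        mask = genotypes.stratum_mask(group, gender)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty stratum: {group}/{gender}")
        pool_id = f"{group}_{gender}"
        d = genotypes.dosage[mask].astype(float)
        if config.pool_weight_cv > 0:
            w = np.exp(rng.normal(0.0, _lognormal_sigma(config.pool_weight_cv), size=(n, 1)))
        else:
            w = np.ones((n, 1))
        sum_a = (w * d).sum(axis=0)
        sum_b = (w * (2.0 - d)).sum(axis=0)
        total = sum_a + sum_b
        truth_rows.append(pd.DataFrame({
            "snp_id": genotypes.snp_ids,
            "pool_id": pool_id,
            "true_f": np.divide(sum_a, total, out=np.zeros_like(sum_a), where=total > 0),
        }))
        design_rows.append({"pool_id": pool_id, "group": group,
                            "gender": gender, "n_individuals": n})
        for rep in range(config.n_replicates):
            a = _noisy(sum_a, rng, config.noise_cv)
            b = _noisy(sum_b / snp_k, rng, config.noise_cv)
            frames.append(pd.DataFrame({
                "snp_id": genotypes.snp_ids,
                "pool_id": pool_id,
                "replicate": rep,
                "channel_A": a,
                "channel_B": b,
            }))
    return (pd.concat(frames, ignore_index=True),
            pd.DataFrame(design_rows),
            pd.concat(truth_rows, ignore_index=True))


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, ready for the analysis stages."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    snp_k: np.ndarray
    calibration: pd.DataFrame
    pool_intensities: pd.DataFrame
    design: pd.DataFrame
    pool_truth: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all generator stages under one root seed."""
    genotypes = simulate_genotypes(config)
    snp_k = simulate_dye_bias(config)
    calibration = simulate_individual_intensities(genotypes, config, snp_k)
    pools, design, pool_truth = construct_pools(genotypes, config, snp_k)
    return SyntheticDataset(config, genotypes, snp_k, calibration,
                            pools, design, pool_truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the TSV contract of the generator: genotypes, calibration
    intensities, pool intensities, pool design and the truth table."""
    from .io import write_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": dataset.config.seed}
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "calibration": outdir / "calibration_intensities.tsv",
        "intensities": outdir / "pool_intensities.tsv",
        "design": outdir / "pool_design.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_tsv(dataset.genotypes.to_long(), paths["genotypes"], meta)
    write_tsv(dataset.calibration, paths["calibration"], meta)
    write_tsv(dataset.pool_intensities, paths["intensities"], meta)
    write_tsv(dataset.design, paths["design"], meta)
    write_tsv(dataset.genotypes.truth, paths["truth"], meta)
    return paths
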