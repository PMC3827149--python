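# Methods

## Estimation model for pooled allelotyping

Each SNP probe reports two channel intensities, A and B, proportional to the
amount of each allele in the hybridised DNA, with a multiplicative per-SNP dye
bias: the B channel is attenuated by a factor k relative to A (equivalently, a
heterozygote's expected A:B ratio is k rather than 1). The estimation chain per
SNP and pool replicate is

1. `k = mean(A/B)` over individually assayed known heterozygotes — the mean of
   per-individual ratios, not the ratio of means. A heterozygote is an exact
   50% pool, so its ratio isolates the dye term. SNPs without a usable
   heterozygote fall back to k = 1 and are flagged.
2. `RAF_k = A / (A + k·B)`, which reduces to the raw relative allele signal
   `RAS = A/(A+B)` at k = 1 and exactly inverts the bias when k is known.
3. Linear rescaling against the mean RAS of known A- and B-homozygotes,
   clipped to [0, 1]. The same affine map is applied to every value (not only
   extremes): it is the identity when the anchors sit at 1 and 0 and avoids a
   discontinuity between "extreme" and interior values.
4. Replicate averaging with a variability filter: the sample standard
   deviation of the replicate RAFs, in allele-frequency units, must not exceed
   `replicate_sd_max`. A single replicate cannot be QC'd and passes with a
   warning.

All estimates are invariant to rescaling both channels by a common positive
constant, and with zero noise and known per-SNP k the chain returns each
pool's true allele frequency to machine precision (tested).

**Replicate-QC threshold.** The source conventions for "variance between
replicate pools" are ambiguous (standard deviation, statistical variance, or
range — and both 5% and 2% circulate as thresholds). The package takes the
conservative reading: standard deviation in frequency units, default
`replicate_sd_max = 0.02`, exposed as a config knob. Note the interaction with
the noise level: at 5% per-channel intensity noise the per-replicate RAF noise
is ≈ 0.017 SD near f = 0.5, so the 0.02 filter excludes the majority of
SNP-pool combinations; the 0.05 threshold suits that noise level and is what
the simulation studies in `tests/test_acceptance.py` and
`scripts/acceptance.py` use. Choose the threshold against your observed
replicate variability, not by default.

## Pooled association and gender combination

Within each gender the case and control pool RAFs are compared by
reconstructing a 2×2 allele-count table with `round(2n·RAF)` allele-A counts
per pool of n individuals (`effective_n_mode="chromosomes"`; the
`"individuals"` mode uses n and is strictly more conservative) and applying
the 1-df Pearson chi-square without continuity correction. This treats the
estimated pool frequency as if it were a sample allele frequency over 2n
chromosomes: correct for the binomial sampling of pool members, slightly
anticonservative for the additional measurement noise — acceptable for a
screening stage whose output is a ranking.

Multiple testing is controlled per gender with Benjamini–Hochberg at
`fdr_q = 0.05`; a SNP is reported FDR-significant only when flagged in both
genders. Candidate screening keeps SNPs with folded odds ratio
`max(OR, 1/OR) > 1.4` and p < 0.05, again in both genders. Gender evidence is
combined by ranking on ascending p within gender (average ranks for exact
ties), summing the two ranks, and ordering ascending by the sum; ties break by
the larger gender-averaged |case − control| RAF difference, then lexically by
SNP id so the ordering is a deterministic total order (tested by permuting
input rows).

## Stage-two statistics

Given 3×2 genotype count tables (AA/AG/GG by case/control):

- **HWE**: 1-df chi-square of observed counts against p², 2pq, q² at the
  sample allele frequency, no continuity correction. The population whose
  genotypes enter the test (cases + controls, controls only, cases only) is an
  explicit argument; published conventions differ and the packaged table's
  printed value is reproduced by the all-subjects convention.
- **Allelic test**: genotypes collapsed to allele counts
  (het + 2·hom), 1-df Pearson chi-square; per-allele odds ratio with the Woolf
  interval `exp(ln OR ± 1.96·SE)`, `SE = sqrt(Σ 1/cell)`; the Haldane–Anscombe
  0.5 is added to all four cells only when some cell is zero.
- **Cochran–Armitage trend test**: scores (0, 1, 2) by default; the statistic
  is invariant under affine score changes and case/control swapping, and is
  verified against an exact rational-arithmetic oracle.
- **Genotypic test**: 2-df Pearson chi-square on the 3×2 table; classes empty
  in both groups are dropped with the df adjusted and the result flagged.
- **Per-genotype odds ratios** against the wild-type homozygote, Woolf CIs.
- **Power**: `P(χ²(df, ncp) > χ²_crit(α, df))` via the noncentral chi-square;
  effect-size-to-ncp mapping is left to the caller because published power
  parameterizations are rarely reconstructible.

The packaged count table reproduces its source's combined-cohort results at
printed precision (frequencies 64.9/56.3 and 43.2/34.9%, allele ORs 1.44
[1.19–1.73] and 1.43 [1.18–1.72], homozygote ORs 2.16 [1.43–3.27] and 0.49
[0.32–0.74], allele p = 0.0002, HWE p = 0.339), with two caveats the package
does not chase: the printed "genotype" p-values (0.007/0.006) match neither
the 2-df Pearson nor the trend test on the printed counts (both give smaller
values), and the printed heterozygote ORs differ from the crude cross-product
ratios while the homozygote ORs match — likely adjusted models or typos in the
source. The package reports the crude statistics.

## Synthetic data generator

The generator emulates the study design the analysis assumes, with one root
seed and independent substreams per stage (genotypes, dye bias, calibration
arrays, pools) so stages can be regenerated in isolation.

- **Genotypes**: per-subject dosages ~ Binomial(2, f) — exact HWE sampling.
  Controls use `maf_control` (default 0.563); cases add `effect_delta`
  (default 0.086) at the first `n_effect_snps` of `n_snps` SNPs (defaults
  50/1000). Default stratum sizes 91/84 female/male cases and 140/104
  female/male controls mirror the reference pooling design (its Table of
  cohort demographics lists 144 female test controls where the pooling section
  says 140; the pooling sizes are used since pools are what this stage
  models).
- **Dye bias**: per-SNP k lognormal with median `k_mean = 0.87` (the mean
  correction factor reported for the platform) and linear spread
  `k_sd = 0.15`, clipped to [0.2, 5] to avoid degenerate channels.
- **Intensities**: channel A ∝ dosage, channel B ∝ (2−dosage)/k, each
  multiplied by lognormal noise with coefficient of variation `noise_cv`
  (default 0.05) — intensities are positive and chip noise scales with signal.
  Pools sum member dosages (optional lognormal pipetting-weight jitter,
  `pool_weight_cv`, off by default) and draw `n_replicates = 3` independent
  technical replicates.

What the generator does **not** model: linkage disequilibrium between SNPs,
chip spatial artifacts, batch effects, background fluorescence (so simulated
homozygote anchors sit exactly at 0 and 1, making the homozygote normalization
step an identity on synthetic data — the step is unit-tested standalone), and
genotype-calling error. Passing simulation tests therefore demonstrate
correctness of the estimation chain under the stated noise model, not
robustness to platform pathologies.

## Simulation-study results and their honest limits

At the reference design (Δf = 0.086, four pools of ~100 in triplicate, 5%
noise), averaged over 20 seeds: pool-frequency MAE ≈ 0.008, realized
false-discovery proportion among both-gender BH flags 0.0 (the screen flags
almost nothing at these pool sizes — expected, since per-gender power at
BH-adjusted thresholds is tiny), and top-100 recall of the 50 effect SNPs
≈ 0.56. The recall ceiling with zero measurement noise is ≈ 0.61: binomial
sampling of ~200 chromosomes per pool, not the intensity model, is the
binding constraint at this effect size. Claims that this design recovers a
large majority of such effects in the top ranks should be read against that
ceiling.

## Numerical and interface choices

- No continuity corrections anywhere; z = 1.96 exactly for 95% intervals.
- Monomorphic/degenerate inputs return p = 1 with an explicit flag rather
  than raising, except where the input is a contract violation (negative
  counts, mismatched allele labels, duplicated replicate indices), which
  raises `ValueError`.
- Report rounding: frequencies to 0.1%, ORs/CIs to 2 decimals, p-values to 4
  decimals.
- All tables are UTF-8 TSVs with a mandatory header row; pipeline outputs
  carry `# key=value` comment lines with the config hash and seed, and
  identical config + seed yields byte-identical outputs (tested).
- Derived RNG seeds stay below 2³¹.
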