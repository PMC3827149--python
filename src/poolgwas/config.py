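"""Configuration objects for the simulator and the end-to-end pipeline.

Defaults reproduce the study design the package models: four gender-stratified
case/control DNA pools (91/84 female/male cases, 140/104 female/male controls),
each hybridised in triplicate, with a per-SNP dye-bias factor centred on 0.87
and 5% multiplicative intensity noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

GROUPS = ("case", "control")
GENDERS = ("female", "male")
STRATA = tuple((g, s) for g in GROUPS for s in GENDERS)


def _as_freq_array(value, n_snps: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_snps,)).copy()
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of the synthetic pooled-GWAS experiment.

    ``maf_control`` may be a scalar (shared by all SNPs) or a length-``n_snps``
    sequence. ``effect_delta`` is added to the control allele-A frequency in
    cases at the first ``n_effect_snps`` SNPs.
    """

    n_cases_female: int = 91
    n_cases_male: int = 84
    n_controls_female: int = 140
    n_controls_male: int = 104
    n_snps: int = 1000
    n_effect_snps: int = 50
    maf_control: float | Sequence[float] = 0.563
    effect_delta: float = 0.086
    k_mean: float = 0.87
    k_sd: float = 0.15
    noise_cv: float = 0.05
    n_replicates: int = 3
    pool_weight_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_cases_female", "n_cases_male", "n_controls_female",
                     "n_controls_male", "n_snps", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_effect_snps <= self.n_snps:
            raise ValueError("n_effect_snps must lie in [0, n_snps]")
        if self.k_mean <= 0:
            raise ValueError("k_mean must be positive")
        if self.k_sd < 0 or self.noise_cv < 0 or self.pool_weight_cv < 0:
            raise ValueError("spread parameters must be non-negative")
        f_ctrl = _as_freq_array(self.maf_control, self.n_snps, "maf_control")
        f_case = f_ctrl.copy()
        f_case[: self.n_effect_snps] += self.effect_delta
        if np.any(f_case < 0.0) or np.any(f_case > 1.0):
            raise ValueError(
                "maf_control + effect_delta leaves [0, 1] for some effect SNP")

    @property
    def control_freqs(self) -> np.ndarray:
        return _as_freq_array(self.maf_control, self.n_snps, "maf_control")

    @property
    def case_freqs(self) -> np.ndarray:
        f = self.control_freqs
        f[: self.n_effect_snps] += self.effect_delta
        return f

    def stratum_size(self, group: str, gender: str) -> int:
        return {
            ("case", "female"): self.n_cases_female,
            ("case", "male"): self.n_cases_male,
            ("control", "female"): self.n_controls_female,
            ("control", "male"): self.n_controls_male,
        }[(group, gender)]


@dataclass
class PipelineConfig:
    """End-to-end run configuration: thresholds and stage outputs.

    All analysis thresholds are surfaced here; nothing downstream hard-codes
    them. ``effective_n_mode`` picks the sample size behind the pooled
    chi-square: "chromosomes" (2n alleles per pool, default) or "individuals".
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    replicate_sd_max: float = 0.02
    fdr_q: float = 0.05
    or_min: float = 1.4
    p_max: float = 0.05
    top_n: int = 48
    effective_n_mode: str = "chromosomes"
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        for name in ("replicate_sd_max", "fdr_q", "p_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.effective_n_mode not in ("chromosomes", "individuals"):
            raise ValueError("effective_n_mode must be 'chromosomes' or 'individuals'")
        self.simulation.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        sim = d["simulation"]
        if isinstance(sim.get("maf_control"), np.ndarray):
            sim["maf_control"] = sim["maf_control"].tolist()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        known = {f.name for f in fields(SimulationConfig)}
        bad = set(sim_raw) - known
        if bad:
            raise ValueError(f"unknown simulation keys: {sorted(bad)}")
        known_p = {f.name for f in fields(cls)} - {"simulation"}
        bad = set(raw) - known_p
        if bad:
            raise ValueError(f"unknown pipeline keys: {sorted(bad)}")
        return cls(simulation=SimulationConfig(**sim_raw), **raw)
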