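"""Simulation configuration for the synthetic methylation cohort.

The generator plants four classes of exposure-associated CpGs — associated
with exposure A only, with B only, with both in the same direction
(shared-concordant) and with both in opposite directions (shared-discordant)
— on top of logit-scale chip batch effects and sparse latent
cell-composition factors. The defaults describe the study conditions every
downstream stage is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


@dataclass
class EffectConfig:
    """Planted structure of a simulated beta-value matrix.

    Parameters
    ----------
    n_probes_total:
        Number of CpG probes simulated.
    n_a_only, n_b_only, n_shared_concordant, n_shared_discordant:
        Sizes of the planted exposure-associated probe sets. Shared-concordant
        probes respond to both exposures with the same slope sign;
        shared-discordant probes with opposite signs.
    effect_size:
        Planted slope, in logit units per weekly serving.
    noise_sd:
        Residual standard deviation on the logit scale.
    batch_sd:
        Standard deviation of per-probe chip (batch) effects, logit scale.
    position_sd:
        Standard deviation of per-probe chip-position effects, logit scale.
    latent_loading_sd:
        Scale of probe loadings on the latent cell-composition factors.
    exposure_correlation:
        Target Pearson correlation between the two exposures (on the latent
        Gaussian scale; the observed servings correlation is close but
        attenuated by the lognormal transform and quarter-serving rounding).
    n_latent:
        Number of latent factors (cell-composition stand-ins).
    loading_sparsity:
        Fraction of probes with a non-zero loading on each latent factor.
    detection_fail_probe_fraction:
        Fraction of probes injected with detection failures (probe-level
        events: a failing probe fails in most samples).
    detection_fail_sample_rate:
        Within a failing probe, the fraction of samples whose detection P is
        drawn above the QC threshold.
    sex_probe_fraction, multimap_fraction, snp_fraction:
        Fractions of probes flagged sex-chromosomal, multi-mapping, or
        SNP-overlapping in the simulated annotation.
    chip_size:
        Samples per chip (450k chips hold 12 arrays).
    seed:
        Master seed; every operation derives an independent substream from
        (seed, operation name).
    """

    n_probes_total: int = 2000
    n_a_only: int = 50
    n_b_only: int = 50
    n_shared_concordant: int = 25
    n_shared_discordant: int = 25
    effect_size: float = 0.05
    noise_sd: float = 0.3
    batch_sd: float = 0.2
    position_sd: float = 0.05
    latent_loading_sd: float = 0.3
    exposure_correlation: float = 0.3
    n_latent: int = 3
    loading_sparsity: float = 0.3
    detection_fail_probe_fraction: float = 0.005
    detection_fail_sample_rate: float = 0.9
    sex_probe_fraction: float = 0.05
    multimap_fraction: float = 0.02
    snp_fraction: float = 0.02
    chip_size: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        planted = (self.n_a_only + self.n_b_only
                   + self.n_shared_concordant + self.n_shared_discordant)
        if planted > self.n_probes_total:
            raise ValueError(
                f"planted probe sets ({planted}) exceed n_probes_total "
                f"({self.n_probes_total})")
        for name in ("noise_sd", "batch_sd", "position_sd",
                     "latent_loading_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not abs(self.exposure_correlation) < 1:
            raise ValueError("|exposure_correlation| must be < 1")
        if not 0 <= self.loading_sparsity <= 1:
            raise ValueError("loading_sparsity must be in [0, 1]")

    @property
    def n_planted(self) -> int:
        return (self.n_a_only + self.n_b_only
                + self.n_shared_concordant + self.n_shared_discordant)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "EffectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
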