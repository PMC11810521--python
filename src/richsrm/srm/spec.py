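"""Model specifications and parameter containers for the SRM engine."""

from __future__ import annotations

import dataclasses
from typing import Mapping

FULL_CONTROL_FOCAL = ("log_wealth", "food_insecurity")
FULL_CONTROL_ALTER = ("log_wealth", "food_insecurity")
FULL_CONTROL_DYAD = ("relatedness", "marriage")


@dataclasses.dataclass
class PriorConfig:
    """Weakly informative defaults on the standardised scale.

    Fixed effects and parochial bonuses get Normal(0, fixed_sd); random-effect
    SDs get half-Normal(0, sigma_sd); the 2x2 correlation blocks (sender with
    receiver, and the two directions within a dyad) get LKJ(lkj_eta).
    """

    fixed_sd: float = 1.0
    sigma_sd: float = 1.0
    lkj_eta: float = 2.0


@dataclasses.dataclass
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    max_leapfrog: int = 48
    trajectory_length: float = 1.5


@dataclasses.dataclass
class SRMSpec:
    """What to fit: outcome family, covariates, variant and sampler settings.

    ``variant`` follows the paired-model design: ``no_controls`` contains
    only the ethnicity main effects and the parochial same-group bonuses,
    ``full_controls`` adds the declared focal, alter and dyad covariates.
    ``include_dyad_effects`` should be True only for layers where both
    directions of every dyad are observed (interview layers); for
    single-shot game outcomes the dyad effect is confounded with outcome
    noise and is off by default.
    """

    outcome_kind: str  # "bernoulli" | "multinomial"
    variant: str = "full_controls"  # "no_controls" | "full_controls"
    focal_covariates: tuple[str, ...] = FULL_CONTROL_FOCAL
    alter_covariates: tuple[str, ...] = FULL_CONTROL_ALTER
    dyad_covariates: tuple[str, ...] = FULL_CONTROL_DYAD
    parochial_terms: bool = True
    block_parameterisation: bool = False
    include_dyad_effects: bool = False
    priors: PriorConfig = dataclasses.field(default_factory=PriorConfig)
    mcmc: MCMCConfig = dataclasses.field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if self.outcome_kind not in ("bernoulli", "multinomial"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.variant not in ("no_controls", "full_controls"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "no_controls":
            # NC models carry only the predictors directly related to
            # parochial altruism: ethnicity main effects + same-group bonuses.
            self.focal_covariates = ()
            self.alter_covariates = ()
            self.dyad_covariates = ()


@dataclasses.dataclass
class SRMParameters:
    """True or fitted parameter values on the natural (standardised) scale.

    ``fixed`` maps design-column names to coefficients.  Naming convention
    (reference group = alphabetically first group label):

    * ``intercept`` (bernoulli) / ``self_intercept`` (multinomial keep score)
    * ``focal_group:<g>`` / ``self_group:<g>`` — focal-ethnicity main effect
    * ``alter_group:<g>`` — alter-ethnicity main effect
    * ``focal:<cov>`` / ``self:<cov>`` — focal covariate effect
    * ``alter:<cov>`` — alter covariate effect
    * ``dyad:<cov>`` — dyad covariate effect
    * ``parochial:<g>`` — same-group bonus for focals of group ``g``
    * ``block:<g1>-><g2>`` — 2x2 block cell effect (block parameterisation)

    Unnamed design columns default to 0.
    """

    fixed: Mapping[str, float] = dataclasses.field(default_factory=dict)
    sigma_s: float = 0.0
    sigma_r: float = 0.0
    sigma_d: float = 0.0
    rho_gr: float = 0.0
    rho_dd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_s", "sigma_r", "sigma_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_gr", "rho_dd"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")

    def coefficient(self, name: str) -> float:
        return float(self.fixed.get(name, 0.0))
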