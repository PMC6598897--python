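"""Model and sampler configuration for the longitudinal stage."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ConfigurationError

FAMILIES = ("IMM", "JMM", "LTJMM")


@dataclass(frozen=True)
class ModelSpec:
    """Which mixed-effects family to fit, on which markers, with which covariates.

    Families
    --------
    IMM
        Independent per-marker linear mixed models (2x2 random-effect
        covariance per marker; no cross-marker correlation).
    JMM
        Joint multivariate mixed model: one 2p-dimensional random-effect
        vector per subject with unstructured covariance D = V*Omega*V.
    LTJMM
        Latent-time joint model: adds subject-level time shifts delta_i
        and positive marker slopes gamma_k on shifted time.  Baseline
        diagnosis must not appear among its covariates: the latent time
        shift already encodes disease stage, and conditioning on baseline
        diagnosis would make the shift uninterpretable.
    """

    family: str
    markers: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    include_random_slope: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if len(self.markers) == 0:
            raise ConfigurationError("model spec requires at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ConfigurationError("duplicate markers in model spec")
        if self.family == "LTJMM" and "dx_bl" in self.covariates:
            raise ConfigurationError(
                "LTJMM must not include baseline diagnosis (dx_bl) as a covariate"
            )
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    Defaults follow the reference analysis: 5000 iterations per chain with
    the first 2500 discarded as warmup, two chains, thinning by 5 — i.e.
    1000 retained draws in total.
    """

    iterations: int = 5000
    warmup: int = 2500
    chains: int = 2
    thin: int = 5
    seed: int = 0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.warmup <= 0 or self.chains <= 0 or self.thin <= 0:
            raise ConfigurationError("iterations, warmup, chains, thin must be positive")
        if self.warmup >= self.iterations:
            raise ConfigurationError("warmup must be smaller than iterations")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thin

    @property
    def retained_total(self) -> int:
        return self.retained_per_chain * self.chains


def ci_profile(seed: int = 0) -> MCMCConfig:
    """Reduced sampler preset for fast test runs: 500 iterations, 250 warmup, one chain."""
    return MCMCConfig(iterations=500, warmup=250, chains=1, thin=1, seed=seed)


CI_PROFILE = ci_profile()
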