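"""Parameter containers for the accumulation models.

Rates (mu, kappa, nu) are per second; phases in radians; sigma_noise is the
standard deviation of the Gaussian noise on log RT; the oscillation frequency
f (3.3 Hz) and Weber fraction k (0.13) are fixed constants in standard fits.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .oscillation import DEFAULT_FREQ_HZ, OscParams, RESET_MODES

WEBER_K = 0.13


@dataclass(frozen=True)
class TemporalParams:
    """Learning rate alpha, per-20-ms-step discount gamma, Weber fraction."""

    alpha: float
    gamma: float
    weber_k: float = WEBER_K

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.weber_k < 0:
            raise ValueError("weber_k must be nonnegative")


@dataclass(frozen=True)
class OTEMParams:
    """Full parameter vector of the oscillated temporal expectation model.

    Free parameters: alpha (learning rate), gamma (temporal discount),
    mu (leak rate, s^-1), kappa (oscillation decay, s^-1), theta_prime and —
    in masked tasks — theta_mask (reset phases), zeta (preparedness ceiling),
    nu (post-target accumulation rate, s^-1), b (response threshold, > zeta),
    sigma_noise (sd of log-RT noise).  f and weber_k are fixed constants.
    """

    alpha: float
    gamma: float
    mu: float
    kappa: float
    theta_prime: float
    zeta: float
    nu: float
    b: float
    sigma_noise: float
    theta_mask: float = math.pi
    f: float = DEFAULT_FREQ_HZ
    weber_k: float = WEBER_K
    reset_mode: str = "additive"

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.b <= self.zeta:
            raise ValueError("b must exceed zeta (positive expected RT)")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be nonnegative")
        if self.mu < 0 or self.kappa < 0:
            raise ValueError("rates must be nonnegative")
        if self.reset_mode not in RESET_MODES:
            raise ValueError(f"reset_mode must be one of {RESET_MODES}")
        TemporalParams(self.alpha, self.gamma, self.weber_k)  # bounds check

    @property
    def temporal(self) -> TemporalParams:
        return TemporalParams(self.alpha, self.gamma, self.weber_k)

    @property
    def osc(self) -> OscParams:
        return OscParams(
            f=self.f,
            kappa=self.kappa,
            theta_prime=self.theta_prime,
            theta_mask=self.theta_mask,
            reset_mode=self.reset_mode,
        )

    def replace(self, **kw) -> "OTEMParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class UrgencyParams:
    """Oscillated urgency model: preparedness tracks phi(t) * hazard(t).

    Seven free parameters: alpha, kappa, theta (single reset phase applied to
    both prime and mask), zeta, nu, b, sigma_noise.
    """

    alpha: float
    kappa: float
    theta: float
    zeta: float
    nu: float
    b: float
    sigma_noise: float
    f: float = DEFAULT_FREQ_HZ
    weber_k: float = WEBER_K

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.b <= self.zeta:
            raise ValueError("b must exceed zeta")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.sigma_noise < 0 or self.kappa < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")

    @property
    def osc(self) -> OscParams:
        # single phase for both resets, superimposed as in the additive OTEM
        return OscParams(
            f=self.f,
            kappa=self.kappa,
            theta_prime=self.theta,
            theta_mask=self.theta,
            reset_mode="additive",
        )


@dataclass(frozen=True)
class ConstAccumParams:
    """Constant accumulation model (threshold b fixed at 1).

    Four free parameters: lambda_s (stimulus-driven rate, s^-1), mu
    (growth-decay rate, s^-1), zeta (pre-target ceiling), sigma_noise.
    """

    lambda_s: float
    mu: float
    zeta: float
    sigma_noise: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_s <= 0:
            raise ValueError("lambda_s must be positive")
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be nonnegative")
        if self.b != 1.0:
            raise ValueError("b is redundant and fixed at 1")


@dataclass(frozen=True)
class DecisionParams:
    """Post-target race stage of the extended model (simulation only).

    A noise-free leaky-competing-accumulator race: mutual inhibition eta,
    with per-trial accumulation rates drawn from N(nu_target_mean,
    sigma_target^2) and N(nu_other_mean, sigma_other^2).
    """

    eta: float
    nu_target_mean: float
    nu_other_mean: float
    sigma_target: float
    sigma_other: float

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.nu_target_mean <= self.nu_other_mean:
            raise ValueError("nu_target_mean must exceed nu_other_mean")
        if self.sigma_target < 0 or self.sigma_other < 0:
            raise ValueError("rate sds must be nonnegative")


#: printed free-parameter counts per model and task kind
def n_free_params(model: str, task_kind: str = "masked") -> int:
    """Number of free parameters of a model for one condition.

    OTEM has 9 free parameters for unmasked tasks (+ theta_mask for masked),
    the oscillated urgency model 7, the constant accumulation model 4.
    """
    if model in ("otem", "otem_additive", "otem_substitutive"):
        return 9 if task_kind == "unmasked" else 10
    if model == "urgency":
        return 7
    if model == "const_accum":
        return 4
    raise ValueError(f"unknown model {model!r}")
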