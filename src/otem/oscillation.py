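"""Attentional oscillation with stimulus-triggered phase resets.

The attentional gains for the congruent (C) and incongruent (IC) prospective
targets sum to 2 and oscillate in antiphase: phi_C = 1 + D, phi_IC = 1 - D.
The modulation D is a decaying sinusoid phase-reset by the prime (at t = 0)
and, in masked tasks, by the mask (at t = tau_mask).  The mask reset either
*adds to* (superimposes on) or *substitutes* (overwrites) the prime-triggered
oscillation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_FREQ_HZ = 3.3

RESET_MODES = ("additive", "substitutive")


@dataclass(frozen=True)
class OscParams:
    """Oscillation parameters.

    f : oscillation frequency, Hz (fixed at 3.3 in standard fits).
    kappa : exponential amplitude-decay rate, s^-1.
    theta_prime, theta_mask : phases (rad) reset by prime and mask onsets.
    reset_mode : "additive" or "substitutive" mask reset.
    """

    f: float = DEFAULT_FREQ_HZ
    kappa: float = 0.0
    theta_prime: float = 0.0
    theta_mask: float = math.pi
    reset_mode: str = "additive"

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("f must be nonnegative")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.reset_mode not in RESET_MODES:
            raise ValueError(f"reset_mode must be one of {RESET_MODES}")


def modulation(t, tau_mask: float, p: OscParams):
    """Attentional modulation D(t) in [-1, 1].

    ``t`` is time in seconds since prime onset (scalar or array);
    ``tau_mask`` is the mask onset in seconds (``np.inf`` for unmasked tasks,
    in which case only the prime component contributes).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    w = 2.0 * math.pi * p.f
    d_prime = np.exp(-p.kappa * t) * np.sin(w * t + p.theta_prime)
    if not np.isfinite(tau_mask):
        out = np.clip(d_prime, -1.0, 1.0)
        return float(out) if out.ndim == 0 else out
    tm = t - tau_mask
    on = tm >= 0
    d_mask = np.where(on, np.exp(-p.kappa * np.where(on, tm, 0.0)) * np.sin(w * tm + p.theta_mask), 0.0)
    if p.reset_mode == "additive":
        out = np.clip(d_prime + d_mask, -1.0, 1.0)
    else:
        out = np.clip(np.where(on, d_mask, d_prime), -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def attentional_gains(t, tau_mask: float, p: OscParams):
    """Gains (phi_C, phi_IC) = (1 + D, 1 - D); each in [0, 2], summing to 2."""
    d = modulation(t, tau_mask, p)
    return 1.0 + d, 1.0 - d
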