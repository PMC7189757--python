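"""Temporal expectation: trial-by-trial learning of the target-onset (SOA)
distribution and within-trial conditional expectation.

The belief is a discrete distribution over the session's SOA grid (20 ms
spacing).  It starts uniform, and after each trial is nudged toward the
*perceived* onset time of that trial — a Gaussian centred on the true onset
with Weber-law width sigma = k * tau — by delta-rule learning with rate alpha.

Within a trial, conditioning on "no target yet by time t" renormalizes the
remaining mass; its leading value is the hazard rate, and the temporal gain
rho(t) is the expectation of gamma^(steps-to-target), a discounted-future-
reward readout that rises as the target becomes imminent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRID_STEP_MS = 20.0

#: below this remaining mass the belief tail is treated as exhausted
_EXHAUSTED = 1e-250


@dataclass
class SOABelief:
    """Discrete probability distribution over possible target-onset times.

    ``grid`` holds onset times in ms (measured from the task's SOA reference
    onset), strictly increasing with constant 20 ms spacing; ``probs`` is the
    aligned probability vector (nonnegative, sums to 1).
    """

    grid: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.grid.size == 0:
            raise ValueError("belief grid must be nonempty")
        if self.grid.size > 1:
            steps = np.diff(self.grid)
            if not np.allclose(steps, GRID_STEP_MS):
                raise ValueError("grid must be strictly increasing in 20 ms steps")
        if self.grid.shape != self.probs.shape:
            raise ValueError("grid and probs must be aligned")
        if np.any(self.probs < -1e-15):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def copy(self) -> "SOABelief":
        return SOABelief(self.grid.copy(), self.probs.copy())


def init_belief(grid) -> SOABelief:
    """Uniform belief over ``grid`` (the prior before the first trial)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("belief grid must be nonempty")
    return SOABelief(grid, np.full(grid.size, 1.0 / grid.size))


def perceived_distribution(tau_observed: float, grid, weber_k: float) -> np.ndarray:
    """Perceived onset-time distribution after observing a target at ``tau_observed``.

    A Gaussian with mean ``tau_observed`` (ms, in reference time) and scalar-
    timing sd ``weber_k * tau_observed``, evaluated at the grid points and
    renormalized.  ``tau_observed == 0`` degenerates to a point mass on the
    nearest grid point.
    """
    grid = np.asarray(grid, dtype=float)
    if tau_observed < 0:
        raise ValueError("tau_observed must be nonnegative")
    if weber_k < 0:
        raise ValueError("weber_k must be nonnegative")
    sd = weber_k * tau_observed
    if sd < 1e-9:  # degenerate scalar-timing noise: point mass
        out = np.zeros(grid.size)
        out[np.argmin(np.abs(grid - tau_observed))] = 1.0
        return out
    dens = np.exp(-0.5 * ((grid - tau_observed) / sd) ** 2)
    total = dens.sum()
    if total <= 0.0:  # tau far off-grid with tiny sd
        out = np.zeros(grid.size)
        out[np.argmin(np.abs(grid - tau_observed))] = 1.0
        return out
    return dens / total


def update_belief(belief: SOABelief, perceived: np.ndarray, alpha: float) -> SOABelief:
    """Delta-rule update: new = (1 - alpha) * old + alpha * perceived."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    perceived = np.asarray(perceived, dtype=float)
    if perceived.shape != belief.probs.shape:
        raise ValueError("perceived vector does not match belief grid")
    return SOABelief(belief.grid, (1.0 - alpha) * belief.probs + alpha * perceived)


def _tail_index(belief: SOABelief, t: float) -> int:
    """Index of the first grid point >= t (t at most max(grid))."""
    if t > belief.grid[-1] + 1e-9:
        raise ValueError("t beyond the belief support")
    return int(np.searchsorted(belief.grid, t - 1e-9))


def conditional_belief(belief: SOABelief, t: float) -> np.ndarray:
    """Belief conditioned on the target not having appeared before time ``t``.

    Returns q(t'|t) = p(t') / sum_{s>=t} p(s) for grid points t' >= t, zero
    elsewhere.  If the remaining mass is numerically exhausted the target is
    treated as certainly imminent: a point mass on the last grid point.
    """
    i = _tail_index(belief, t)
    tail = belief.probs[i:]
    out = np.zeros(belief.probs.size)
    total = tail.sum()
    if total < _EXHAUSTED:
        out[-1] = 1.0
        return out
    out[i:] = tail / total
    return out


def hazard(belief: SOABelief, t: float) -> float:
    """Hazard rate h(t) = q(t'=t | t): probability the target onsets now."""
    i = _tail_index(belief, t)
    total = belief.probs[i:].sum()
    if total < _EXHAUSTED:
        return 1.0  # exhausted tail: target certainly imminent
    if abs(belief.grid[i] - t) > 1e-9:
        return 0.0  # t falls between grid points: no onset mass exactly at t
    return float(belief.probs[i] / total)


def temporal_gain(belief: SOABelief, t: float, gamma: float) -> float:
    """Discounted expectation of target arrival: rho(t) = E_q[gamma^steps].

    ``gamma`` is the per-20-ms-step discount factor.  rho is 1 when all mass
    sits at ``t`` (or gamma == 1) and decreases as expected arrival recedes.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    i = _tail_index(belief, t)
    tail = belief.probs[i:]
    total = tail.sum()
    if total < _EXHAUSTED:
        return 1.0  # exhausted tail: target certainly imminent
    steps = (belief.grid[i:] - t) / GRID_STEP_MS
    return float(np.sum(tail / total * gamma**steps))
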