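"""Vectorized expected-RT engine.

Computes, for every trial of a session in order, the deterministic expected RT
under each accumulation model, replaying the trial-by-trial belief updates.
This is numerically equivalent to the per-trial reference operations in
:mod:`otem.accumulate` (Euler integration on the 20 ms grid) but vectorized
across trials, which is what makes maximum-likelihood fitting tractable.

All internal times are in 20 ms steps or seconds; the trial table is in ms.
"""

from __future__ import annotations

import math

import numpy as np

from .design import TaskDesign
from .expectation import _EXHAUSTED, perceived_distribution
from .oscillation import OscParams, modulation
from ._kernels import euler_capture_kernel, replay_kernel, rho_kernel
from .params import ConstAccumParams, OTEMParams, UrgencyParams

DT_S = 0.02
DT_MS = 20.0

#: floor on expected RT (s) guarding the log-likelihood
RT_FLOOR_S = 1e-3


class PreparedCondition:
    """Precomputed per-session arrays for one participant x condition.

    Caches everything that does not depend on free parameters: the belief
    grid, each trial's perceived-onset distribution (Weber-scaled Gaussian),
    onset-step bookkeeping, and index lists used to capture preparedness at
    target onset.
    """

    def __init__(self, trials, design: TaskDesign, weber_k: float = 0.13):
        self.design = design
        self.weber_k = weber_k
        self.grid = design.all_soas.astype(float)  # ms, reference time
        n = self.grid.size

        soa = trials["soa_ms"].to_numpy(dtype=float)
        self.soa_idx = np.searchsorted(self.grid, soa - 1e-9)
        self.congruent = (trials["congruency"] == "C").to_numpy()
        self.excluded = trials["excluded"].fillna(False).to_numpy(dtype=bool)
        rt = trials["rt_ms"].to_numpy(dtype=float)
        self.rt_obs_s = rt / 1000.0
        correct = trials["correct"].to_numpy()
        correct = np.array([bool(c) if c is not None and c == c else False for c in correct])
        self.likelihood_mask = correct & ~self.excluded & np.isfinite(rt) & (rt > 0)
        self.update_mask = ~self.excluded

        # within-trial 20 ms step grid: step 0 = prime onset
        self.start_step = int(round((design.reference_offset_ms + self.grid[0]) / DT_MS))
        self.onset_step = self.start_step + self.soa_idx
        self.n_steps = int(self.onset_step.max())
        self.tau_mask_s = (
            math.inf
            if design.task_kind == "unmasked"
            else (design.prime_duration + design.prime_mask_interval) / 1000.0
        )
        # capture lists: trials whose target onsets at each step
        self._capture = [
            np.flatnonzero(self.onset_step == s) for s in range(self.n_steps + 1)
        ]

        # perceived distribution of each trial's observed onset time
        uniq = np.unique(soa)
        g_by_soa = {
            s: perceived_distribution(float(s), self.grid, weber_k) for s in uniq
        }
        self.perceived = np.stack([g_by_soa[s] for s in soa])
        self.n_trials = len(soa)
        # memo caches: numeric gradients re-evaluate with most parameters
        # unchanged, so belief replay and temporal gain are reused
        self._belief_cache: dict = {}
        self._rho_cache: dict = {}

    # -- belief replay ---------------------------------------------------

    def replay_beliefs(self, alpha: float) -> np.ndarray:
        """Pre-trial beliefs, (n_trials, n_grid), by delta-rule replay."""
        return replay_kernel(self.perceived, self.update_mask, float(alpha))

    # -- shared pieces ---------------------------------------------------

    def _beliefs(self, alpha: float) -> np.ndarray:
        if alpha not in self._belief_cache:
            if len(self._belief_cache) > 3:
                self._belief_cache.clear()
            self._belief_cache[alpha] = self.replay_beliefs(alpha)
        return self._belief_cache[alpha]

    def _rho_full(self, alpha: float, gamma: float) -> np.ndarray:
        """Temporal gain at every within-trial step, (n_steps+1, n_trials)."""
        key = (alpha, gamma)
        if key in self._rho_cache:
            return self._rho_cache[key]
        pt = np.ascontiguousarray(self._beliefs(alpha).T)
        out = rho_kernel(pt, float(gamma), self.start_step, self.n_steps, _EXHAUSTED)
        if len(self._rho_cache) > 3:
            self._rho_cache.clear()
        self._rho_cache[key] = out
        return out

    def _phi(self, osc: OscParams):
        """Attentional gains (phi_C, phi_IC) on the within-trial step grid."""
        t = np.arange(self.n_steps + 1) * DT_S
        d = modulation(t, self.tau_mask_s, osc)
        return 1.0 + d, 1.0 - d

    # -- models ----------------------------------------------------------

    def expected_rt_otem(self, p: OTEMParams) -> np.ndarray:
        """Expected RT (s) per trial under the oscillated temporal expectation model."""
        rho = self._rho_full(p.alpha, p.gamma)
        phi_c, phi_ic = self._phi(p.osc)
        e_tgt = euler_capture_kernel(
            rho,
            phi_c,
            phi_ic,
            float(p.mu),
            float(p.zeta),
            DT_S,
            self.onset_step,
            self.congruent,
        )
        return np.maximum((p.b - e_tgt) / p.nu, RT_FLOOR_S)

    def expected_rt_urgency(self, p: UrgencyParams) -> np.ndarray:
        """Expected RT (s) per trial under the oscillated urgency model."""
        beliefs = self._beliefs(p.alpha)
        s = np.flip(np.cumsum(np.flip(beliefs, 1), 1), 1)
        idx = np.arange(self.n_trials)
        mass = s[idx, self.soa_idx]
        h = np.where(
            mass > _EXHAUSTED,
            beliefs[idx, self.soa_idx] / np.maximum(mass, _EXHAUSTED),
            1.0,
        )
        phi_c, phi_ic = self._phi(p.osc)
        phi_tgt = np.where(
            self.congruent, phi_c[self.onset_step], phi_ic[self.onset_step]
        )
        e_tgt = np.clip(phi_tgt * h, 0.0, p.zeta)
        return np.maximum((p.b - e_tgt) / p.nu, RT_FLOOR_S)

    def expected_rt_const_accum(self, p: ConstAccumParams) -> np.ndarray:
        """Expected RT (s) per trial under the constant accumulation model.

        Deterministic given (SOA, congruency): Euler integration of the
        prime-direction accumulator to target onset, then a closed-form
        crossing time of the accumulator difference at threshold 1.
        Non-terminating cells get infinite expected RT.
        """
        # prime-direction accumulator trajectory, shared by all trials
        mask_step = (
            self.n_steps + 1
            if not np.isfinite(self.tau_mask_s)
            else int(round(self.tau_mask_s / DT_S))
        )
        u = np.empty(self.n_steps + 1)
        u[0] = 0.0
        for s in range(self.n_steps):
            rate = p.lambda_s if s < mask_step else -p.lambda_s
            u[s + 1] = min(max(u[s] + DT_S * (rate - p.mu * u[s]), 0.0), p.zeta)

        u0 = u[self.onset_step]
        d0 = np.where(self.congruent, u0, -u0)  # target-acc minus other-acc
        rt = _crossing_time(d0, p.lambda_s, p.mu)
        return np.maximum(rt, RT_FLOOR_S)

    # -- likelihood ------------------------------------------------------

    def expected_rt(self, model: str, params) -> np.ndarray:
        if model in ("otem", "otem_additive", "otem_substitutive"):
            return self.expected_rt_otem(params)
        if model == "urgency":
            return self.expected_rt_urgency(params)
        if model == "const_accum":
            return self.expected_rt_const_accum(params)
        raise ValueError(f"unknown model {model!r}")

    def neg_log_likelihood(self, model: str, params) -> float:
        """-log p(observed RTs | model): log-normal density at the expected RT."""
        rt_exp = self.expected_rt(model, params)
        x = self.rt_obs_s[self.likelihood_mask]
        mu_log = np.log(rt_exp[self.likelihood_mask])
        if not np.all(np.isfinite(mu_log)):
            return 1e12
        sig = max(params.sigma_noise, 1e-6)
        z = (np.log(x) - mu_log) / sig
        nll = np.sum(np.log(x) + math.log(sig) + 0.5 * math.log(2 * math.pi) + 0.5 * z**2)
        return float(nll) if np.isfinite(nll) else 1e12


def _crossing_time(d0: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """Time (s) for d(s) with d' = lam - mu*d, d(0)=d0 to reach 1 (inf if never)."""
    d0 = np.asarray(d0, dtype=float)
    out = np.full(d0.shape, np.inf)
    done = d0 >= 1.0
    out[done] = 0.0
    if mu == 0.0:
        out[~done] = (1.0 - d0[~done]) / lam
        return out
    asym = lam / mu
    coef = d0 - asym  # d(s) = asym + coef * exp(-mu s)
    ratio = np.where(coef != 0.0, (1.0 - asym) / np.where(coef == 0.0, 1.0, coef), np.inf)
    ok = (~done) & (ratio > 0.0) & (ratio <= 1.0)
    out[ok] = -np.log(ratio[ok]) / mu
    return out
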