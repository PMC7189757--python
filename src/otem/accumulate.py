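"""Preparedness accumulation and RT generation.

Two preparedness threads — one per prospective target (congruent /
incongruent with the prime) — grow from prime onset by Euler integration of

    de_alt/dt = phi_alt(t) * rho(t) - mu * e_alt,      0 <= e_alt <= zeta,

where phi_alt is the oscillating attentional gain and rho the discounted
temporal gain.  At target onset the target thread races alone to threshold b
at rate nu, so the expected RT is (b - e_at_onset) / nu; observed RT adds
multiplicative log-normal noise.

The oscillated urgency variant replaces accumulated preparedness with an
instantaneous readout of hazard rate; the constant accumulation model drops
expectation and oscillation entirely in favour of stimulus-triggered constant
rates on two racing accumulators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._engine import DT_MS, DT_S, RT_FLOOR_S, PreparedCondition, _crossing_time
from .design import TaskDesign, generate_trial_sequence
from .expectation import SOABelief, hazard, temporal_gain, update_belief
from .oscillation import attentional_gains
from .params import ConstAccumParams, DecisionParams, OTEMParams, UrgencyParams

MODELS = ("otem_additive", "otem_substitutive", "urgency", "const_accum")


@dataclass
class PreparednessTrace:
    """Preparedness of both threads on the within-trial grid (times in ms)."""

    times: np.ndarray
    e_C: np.ndarray
    e_IC: np.ndarray

    def at_onset(self, congruency: str) -> float:
        return float(self.e_C[-1] if congruency == "C" else self.e_IC[-1])


def _trial_geometry(soa_ms: float, design: TaskDesign):
    """(target onset ms since prime, mask onset s or inf)."""
    onset_ms = design.reference_offset_ms + soa_ms
    tau_mask_s = (
        math.inf
        if design.task_kind == "unmasked"
        else (design.prime_duration + design.prime_mask_interval) / 1000.0
    )
    return onset_ms, tau_mask_s


def accumulate_preparedness(
    trial,
    belief: SOABelief,
    params: OTEMParams,
    design: TaskDesign,
    dt_ms: float = DT_MS,
) -> PreparednessTrace:
    """Integrate both preparedness threads from prime onset to target onset.

    ``trial`` is a trial-table row (needs ``soa_ms``); ``belief`` is the
    pre-trial belief in reference time.  Temporal gain is evaluated in
    reference time, attentional gains in time since prime onset.
    """
    soa = float(trial["soa_ms"])
    onset_ms, tau_mask_s = _trial_geometry(soa, design)
    ref = design.reference_offset_ms
    n = int(round(onset_ms / dt_ms))
    times = np.arange(n + 1) * dt_ms
    e_c = np.zeros(n + 1)
    e_ic = np.zeros(n + 1)
    dt_s = dt_ms / 1000.0
    for i in range(n):
        t_ms = times[i]
        rho = temporal_gain(belief, t_ms - ref, params.gamma)
        phi_c, phi_ic = attentional_gains(t_ms / 1000.0, tau_mask_s, params.osc)
        e_c[i + 1] = min(max(e_c[i] + dt_s * (phi_c * rho - params.mu * e_c[i]), 0.0), params.zeta)
        e_ic[i + 1] = min(max(e_ic[i] + dt_s * (phi_ic * rho - params.mu * e_ic[i]), 0.0), params.zeta)
    return PreparednessTrace(times, e_c, e_ic)


def urgency_preparedness(
    trial,
    belief: SOABelief,
    params: UrgencyParams,
    design: TaskDesign,
    dt_ms: float = DT_MS,
) -> PreparednessTrace:
    """Instantaneous preparedness e_alt(t) = clip(phi_alt(t) * h(t), 0, zeta)."""
    soa = float(trial["soa_ms"])
    onset_ms, tau_mask_s = _trial_geometry(soa, design)
    ref = design.reference_offset_ms
    n = int(round(onset_ms / dt_ms))
    times = np.arange(n + 1) * dt_ms
    e_c = np.zeros(n + 1)
    e_ic = np.zeros(n + 1)
    for i, t_ms in enumerate(times):
        h = hazard(belief, t_ms - ref) if t_ms - ref >= belief.grid[0] - 1e-9 else 0.0
        phi_c, phi_ic = attentional_gains(t_ms / 1000.0, tau_mask_s, params.osc)
        e_c[i] = min(max(phi_c * h, 0.0), params.zeta)
        e_ic[i] = min(max(phi_ic * h, 0.0), params.zeta)
    return PreparednessTrace(times, e_c, e_ic)


def expected_rt(e_at_onset: float, params) -> float:
    """Expected RT in ms: remaining distance to threshold over rate nu."""
    if not 0.0 <= e_at_onset <= params.zeta:
        raise ValueError("preparedness at onset must lie in [0, zeta]")
    return 1000.0 * max((params.b - e_at_onset) / params.nu, RT_FLOOR_S)


def sample_observed_rt(rt_exp_ms: float, sigma_noise: float, rng) -> float:
    """Observed RT (ms): log rt_obs ~ Normal(log rt_exp, sigma_noise^2)."""
    if rt_exp_ms <= 0:
        raise ValueError("expected RT must be positive")
    return float(rt_exp_ms * math.exp(sigma_noise * rng.standard_normal()))


def const_accum_rt(
    trial, params: ConstAccumParams, design: TaskDesign, dt_ms: float = DT_MS
) -> float:
    """Expected RT (ms) of the constant accumulation model for one trial.

    The prime drives its direction's accumulator at +lambda_s, the mask
    reverses it to -lambda_s, and from target onset the target-direction
    accumulator accumulates at +lambda_s (the other only leaks).  RT is the
    closed-form time from target onset at which the accumulator difference
    reaches the threshold 1.

    Raises
    ------
    RuntimeError
        If the difference can never reach threshold (non-terminating trial).
    """
    soa = float(trial["soa_ms"])
    onset_ms, tau_mask_s = _trial_geometry(soa, design)
    n = int(round(onset_ms / dt_ms))
    mask_step = math.inf if not math.isfinite(tau_mask_s) else round(tau_mask_s * 1000 / dt_ms)
    dt_s = dt_ms / 1000.0
    u = 0.0  # prime-direction accumulator; the other stays 0 pre-target
    for s in range(n):
        rate = params.lambda_s if s < mask_step else -params.lambda_s
        u = min(max(u + dt_s * (rate - params.mu * u), 0.0), params.zeta)
    d0 = u if trial["congruency"] == "C" else -u
    rt_s = float(_crossing_time(np.array([d0]), params.lambda_s, params.mu)[0])
    if not math.isfinite(rt_s):
        raise RuntimeError("non-terminating trial: difference never reaches threshold")
    return 1000.0 * max(rt_s, RT_FLOOR_S)


def lca_decision(
    e_c_at_onset: float,
    e_ic_at_onset: float,
    target_congruency: str,
    params: DecisionParams,
    b: float,
    rng,
    dt_ms: float = 1.0,
    horizon_s: float = 10.0,
):
    """Post-target race of the extended model: (choice, decision_time_ms).

    Both threads continue from their onset preparedness, mutually inhibiting
    (de_i/dt = nu_i - eta * e_j, floored at 0); rates are drawn once per trial
    from the model's Gaussians.  The first thread to reach ``b`` determines
    the choice ("C" or "IC"); an error is a choice unequal to
    ``target_congruency``.
    """
    nu_target = params.nu_target_mean + params.sigma_target * rng.standard_normal()
    nu_other = params.nu_other_mean + params.sigma_other * rng.standard_normal()
    if target_congruency == "C":
        rate_c, rate_ic = nu_target, nu_other
    else:
        rate_c, rate_ic = nu_other, nu_target
    e_c, e_ic = float(e_c_at_onset), float(e_ic_at_onset)
    dt_s = dt_ms / 1000.0
    t = 0.0
    while t < horizon_s:
        new_c = max(e_c + dt_s * (rate_c - params.eta * e_ic), 0.0)
        new_ic = max(e_ic + dt_s * (rate_ic - params.eta * e_c), 0.0)
        e_c, e_ic = new_c, new_ic
        t += dt_s
        if e_c >= b or e_ic >= b:
            choice = "C" if e_c >= e_ic else "IC"
            return choice, 1000.0 * t
    raise RuntimeError("no accumulator reached threshold within the horizon")


def simulate_dataset(
    design: TaskDesign,
    params,
    model: str,
    seed: int,
    participant: str = "p01",
    block_order_random: bool = True,
) -> pd.DataFrame:
    """Simulate a full session: trial sequence, belief replay, expected and
    observed RTs.  Returns a trial table in session order.
    """
    _check_model_params(model, params)
    rng = np.random.default_rng(seed)
    trials = generate_trial_sequence(
        design, int(rng.integers(2**31)), block_order_random, participant
    )
    prep = PreparedCondition(trials, design, getattr(params, "weber_k", 0.13))
    if model == "otem_additive":
        rt_exp = prep.expected_rt_otem(params.replace(reset_mode="additive"))
    elif model == "otem_substitutive":
        rt_exp = prep.expected_rt_otem(params.replace(reset_mode="substitutive"))
    else:
        rt_exp = prep.expected_rt(model, params)
    noise = rng.standard_normal(len(trials))
    rt_obs_ms = 1000.0 * rt_exp * np.exp(params.sigma_noise * noise)
    out = trials.copy()
    out["rt_ms"] = rt_obs_ms
    out["response"] = out["target_dir"]
    out["correct"] = True
    out["excluded"] = False
    return out


def _check_model_params(model: str, params) -> None:
    expected = {
        "otem_additive": OTEMParams,
        "otem_substitutive": OTEMParams,
        "urgency": UrgencyParams,
        "const_accum": ConstAccumParams,
    }
    if model not in expected:
        raise ValueError(f"unknown model {model!r}; valid models: {MODELS}")
    if not isinstance(params, expected[model]):
        raise TypeError(
            f"model {model!r} requires {expected[model].__name__}, "
            f"got {type(params).__name__}"
        )
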