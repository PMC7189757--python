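"""Maximum-likelihood fitting, information criteria, and group-level
Bayesian model selection.

Each model is fitted per participant by minimizing the negative log-likelihood
of observed RTs (log-normal around the model's deterministic expected RT)
with bounded L-BFGS-B from multiple random starting points.  Goodness of fit
is summarized by AICc; across participants, models are compared by the
protected exceedance probability of random-effects Bayesian model selection,
with model evidence approximated by -AICc/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp, psi
from scipy.stats import qmc

from ._engine import PreparedCondition
from .design import TaskDesign, make_design
from .params import ConstAccumParams, OTEMParams, UrgencyParams, n_free_params

PI = math.pi

# free-parameter boxes; zeta is optimized as a fraction of b so that the
# b > zeta constraint is honoured throughout the search
_BOUNDS = {
    "alpha": (0.0, 1.0),
    "gamma": (0.0, 1.0),
    "mu": (0.0, 20.0),
    "kappa": (0.0, 20.0),
    "theta_prime": (-PI, PI),
    "theta_mask": (-PI, PI),
    "theta": (-PI, PI),
    "zeta_frac": (0.02, 0.98),
    "nu": (0.5, 100.0),
    "b": (0.1, 50.0),
    "sigma_noise": (0.01, 2.0),
    "lambda_s": (0.05, 100.0),
    "zeta": (0.02, 50.0),
}


def _free_names(model: str, task_kind: str) -> list[str]:
    if model in ("otem", "otem_additive", "otem_substitutive"):
        names = ["alpha", "gamma", "mu", "kappa", "theta_prime"]
        if task_kind == "masked":
            names.append("theta_mask")
        return names + ["zeta_frac", "nu", "b", "sigma_noise"]
    if model == "urgency":
        return ["alpha", "kappa", "theta", "zeta_frac", "nu", "b", "sigma_noise"]
    if model == "const_accum":
        return ["lambda_s", "mu", "zeta", "sigma_noise"]
    raise ValueError(f"unknown model {model!r}")


def _wrap_angle(x: float) -> float:
    return float((x + PI) % (2 * PI) - PI)


def build_params(model: str, values: dict, task_kind: str, f: float = 3.3):
    """Construct a model parameter object from a dict of natural values."""
    v = dict(values)
    if "zeta_frac" in v:
        v["zeta"] = v.pop("zeta_frac") * v["b"]
    if model in ("otem", "otem_additive", "otem_substitutive"):
        reset = "substitutive" if model.endswith("substitutive") else "additive"
        return OTEMParams(
            alpha=v["alpha"],
            gamma=v["gamma"],
            mu=v["mu"],
            kappa=v["kappa"],
            theta_prime=_wrap_angle(v["theta_prime"]),
            theta_mask=_wrap_angle(v.get("theta_mask", PI)),
            zeta=v["zeta"],
            nu=v["nu"],
            b=v["b"],
            sigma_noise=v["sigma_noise"],
            f=f,
            reset_mode=reset,
        )
    if model == "urgency":
        return UrgencyParams(
            alpha=v["alpha"],
            kappa=v["kappa"],
            theta=_wrap_angle(v["theta"]),
            zeta=v["zeta"],
            nu=v["nu"],
            b=v["b"],
            sigma_noise=v["sigma_noise"],
            f=f,
        )
    if model == "const_accum":
        return ConstAccumParams(
            lambda_s=v["lambda_s"],
            mu=v["mu"],
            zeta=v["zeta"],
            sigma_noise=v["sigma_noise"],
        )
    raise ValueError(f"unknown model {model!r}")


@dataclass
class FitResult:
    """Per-participant, per-model maximum-likelihood fit."""

    participant: str
    model: str
    params: dict
    neg_log_lik: float
    n_trials: int
    k_params: int
    aicc: float
    n_restarts: int
    best_restart_seed: int
    success: bool
    bounds: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "participant": self.participant,
            "model": self.model,
            "neg_log_lik": self.neg_log_lik,
            "n_trials": self.n_trials,
            "k_params": self.k_params,
            "aicc": self.aicc,
            "n_restarts": self.n_restarts,
            "best_restart_seed": self.best_restart_seed,
            "success": self.success,
        }
        row.update(self.params)
        return row


def aicc(neg_log_lik: float, k: int, n: int) -> float:
    """Akaike information criterion with finite-sample correction."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return 2.0 * neg_log_lik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def neg_log_likelihood(dataset: pd.DataFrame, model: str, params, design=None) -> float:
    """NLL of one participant's correct, non-excluded trials under ``model``.

    ``design`` defaults to the preset named in the dataset's condition column.
    """
    if design is None:
        design = make_design(dataset["condition"].iloc[0])
    prep = PreparedCondition(dataset, design, getattr(params, "weber_k", 0.13))
    return prep.neg_log_likelihood(model, params)


def _sample_starts(names, n, rng) -> np.ndarray:
    sampler = qmc.LatinHypercube(d=len(names), seed=rng)
    unit = sampler.random(n)
    lo = np.array([_BOUNDS[k.split(":")[0]][0] for k in names])
    hi = np.array([_BOUNDS[k.split(":")[0]][1] for k in names])
    return lo + unit * (hi - lo)


def fit_participant(
    dataset: pd.DataFrame,
    model: str,
    bounds: dict | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    shared_map: tuple[str, ...] | None = None,
    f: float = 3.3,
    stage1_maxiter: int = 150,
    polish_maxiter: int = 500,
    fixed: dict | None = None,
) -> FitResult:
    """Fit ``model`` to one participant's trial table by multistart MLE.

    The dataset may span several conditions (distinct values in the
    ``condition`` column, each naming a design preset).  With
    ``shared_map`` — a tuple of parameter names, e.g. ``("b",
    "sigma_noise")`` — those parameters get one free copy per condition while
    everything else is shared, as in fitting the two prime-to-mask-interval
    conditions jointly.

    Starting points are Latin-hypercube draws within the bounds; each start
    gets a short bounded L-BFGS-B run and the best is polished with a long
    one.  Results are reproducible given ``seed``.
    """
    conditions = list(dict.fromkeys(dataset["condition"]))
    designs = {c: make_design(c) for c in conditions}
    task_kinds = {designs[c].task_kind for c in conditions}
    if len(task_kinds) > 1:
        raise ValueError("cannot share parameters across task kinds")
    task_kind = task_kinds.pop()
    fixed = dict(fixed or {})
    base_names = [n for n in _free_names(model, task_kind) if n not in fixed]

    if shared_map and len(conditions) > 1:
        per_cond = [n for n in base_names if n in shared_map]
        shared = [n for n in base_names if n not in shared_map]
        names = shared + [f"{n}:{c}" for c in conditions for n in per_cond]
    else:
        shared, per_cond = base_names, []
        names = list(base_names)

    box = dict(_BOUNDS)
    if bounds:
        box.update(bounds)
    preps = {
        c: PreparedCondition(dataset[dataset["condition"] == c], designs[c])
        for c in conditions
    }
    n_trials = int(sum(p.likelihood_mask.sum() for p in preps.values()))

    def per_condition_values(vals: dict) -> dict[str, dict]:
        """Natural-scale value dicts per condition; zeta_frac is resolved
        against the smallest condition threshold so zeta stays shared."""
        out = {}
        zf = vals.get("zeta_frac")
        if zf is not None:
            bs = [
                vals[f"b:{c}"] if "b" in per_cond else vals["b"] for c in conditions
            ]
            zeta = zf * min(bs)
        for c in conditions:
            v = {n: vals[n] for n in shared if n != "zeta_frac"}
            v.update(fixed)
            for n in per_cond:
                v[n] = vals[f"{n}:{c}"]
            if zf is not None:
                v["zeta"] = zeta
            out[c] = v
        return out

    lo = np.array([box[k.split(":")[0]][0] for k in names])
    hi = np.array([box[k.split(":")[0]][1] for k in names])

    def objective(x: np.ndarray) -> float:
        vals = dict(zip(names, x))
        total = 0.0
        for c, v in per_condition_values(vals).items():
            try:
                p = build_params(model, v, task_kind, f=f)
            except (ValueError, TypeError):
                return 1e12
            total += preps[c].neg_log_likelihood(model, p)
        return total

    def objective_u(u: np.ndarray) -> float:
        # optimize in unit-box coordinates so finite-difference steps are
        # comparable across parameters of very different scales
        return objective(lo + u * (hi - lo))

    rng = np.random.default_rng(seed)
    # screen a larger pool of candidate starts by raw NLL, then run local
    # searches from the most promising ones (cheap evals, expensive searches)
    sampler = qmc.LatinHypercube(d=len(names), seed=rng)
    pool = list(sampler.random(max(8 * n_restarts, 40)))
    # the likelihood is multimodal over reset phases (and their interaction
    # with the decay rate): add structured starts on a uniform phase grid
    theta_idx = [i for i, nm in enumerate(names) if nm.startswith("theta")]
    kappa_idx = [i for i, nm in enumerate(names) if nm.split(":")[0] == "kappa"]
    if theta_idx:
        phase_grid = np.array([-math.pi / 2, 0.0, math.pi / 2, math.pi])
        combos = np.stack(
            np.meshgrid(*([phase_grid] * len(theta_idx))), axis=-1
        ).reshape(-1, len(theta_idx))
        u_phase = (combos - lo[theta_idx]) / (hi[theta_idx] - lo[theta_idx])
        u_kappa = (np.array([1.0, 6.0]) - lo[kappa_idx[0]]) / (
            hi[kappa_idx[0]] - lo[kappa_idx[0]]
        ) if kappa_idx else [None]
        for x in pool[: max(1, len(pool) // 20)]:
            for cu in u_phase:
                for ku in u_kappa:
                    y = x.copy()
                    y[theta_idx] = cu
                    if ku is not None:
                        y[kappa_idx] = ku
                    pool.append(y)
    pool = sorted(pool, key=objective_u)[:n_restarts]
    unit_bounds = [(0.0, 1.0)] * len(names)

    stage1 = []
    for i, u0 in enumerate(pool):
        res = minimize(
            objective_u,
            u0,
            method="L-BFGS-B",
            bounds=unit_bounds,
            options={"maxiter": stage1_maxiter, "maxfun": 10 * stage1_maxiter * len(names)},
        )
        stage1.append((res.fun, i, res.x))
    stage1.sort(key=lambda r: r[0])
    # the surface is multimodal in (kappa, theta): polish several survivors
    best_fun, best_i, best_u = stage1[0]
    for fun0, i, u0 in stage1[: min(3, len(stage1))]:
        polish = minimize(
            objective_u,
            u0,
            method="L-BFGS-B",
            bounds=unit_bounds,
            options={"maxiter": polish_maxiter},
        )
        if polish.fun < best_fun:
            best_fun, best_i, best_u = polish.fun, i, polish.x
    if not np.isfinite(best_fun) or best_fun >= 1e12:
        raise RuntimeError("optimizer failed on all restarts")

    vals = dict(zip(names, lo + best_u * (hi - lo)))
    # report natural-scale parameters (zeta instead of zeta_frac, wrapped thetas)
    out_params: dict[str, float] = {}
    by_cond = per_condition_values(vals)
    for ci, c in enumerate(conditions):
        p = build_params(model, by_cond[c], task_kind, f=f)
        for n in base_names:
            key = n.replace("zeta_frac", "zeta")
            val = float(getattr(p, key))
            if n in per_cond:
                out_params[f"{key}:{c}"] = val
            elif ci == 0:
                out_params[key] = val
    for n, v in fixed.items():  # echoed for reconstruction; not free params
        out_params.setdefault(n, float(v))
    k = len(names)
    return FitResult(
        participant=str(dataset["participant"].iloc[0]),
        model=model,
        params=out_params,
        neg_log_lik=float(best_fun),
        n_trials=n_trials,
        k_params=k,
        aicc=aicc(best_fun, k, n_trials),
        n_restarts=n_restarts,
        best_restart_seed=int(best_i),
        success=True,
        bounds={k_: box[k_.split(":")[0]] for k_ in names},
    )


def fitted_params(result: FitResult, condition: str | None = None, f: float = 3.3):
    """Reconstruct the parameter object of a fit (for one condition if the
    fit spanned several)."""
    model = result.model
    vals = {}
    for key, v in result.params.items():
        name, _, cond = key.partition(":")
        if cond and condition and cond != condition:
            continue
        vals[name] = v
    task_kind = "unmasked" if "theta_mask" not in vals and model.startswith("otem") else "masked"
    return build_params(model, vals, task_kind, f=f)


# ---------------------------------------------------------------------------
# group-level random-effects Bayesian model selection


@dataclass
class ModelComparison:
    """Group-level comparison: per-model PXP, exceedance probability, and
    the Bayes omnibus risk of the equal-frequency null."""

    models: list[str]
    pxp: np.ndarray
    ep: np.ndarray
    bor: float
    alpha: np.ndarray
    delta_aicc: pd.DataFrame | None = None


def _vb_dirichlet(log_evidence: np.ndarray, alpha0: float = 1.0, max_iter: int = 500):
    """Variational random-effects BMS: posterior Dirichlet weights and ELBO."""
    n, k = log_evidence.shape
    alpha = np.full(k, alpha0)
    u = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        logu = log_evidence + psi(alpha) - psi(alpha.sum())
        logu -= logsumexp(logu, axis=1, keepdims=True)
        u = np.exp(logu)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < 1e-10:
            alpha = new_alpha
            break
        alpha = new_alpha
    e_ln_r = psi(alpha) - psi(alpha.sum())
    elbo = (
        float((u * log_evidence).sum())
        + float((u * e_ln_r[None, :]).sum())
        + (gammaln(k * alpha0) - k * gammaln(alpha0) + (alpha0 - 1) * e_ln_r.sum())
        - float((u * np.log(np.maximum(u, 1e-300))).sum())
        - (gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * e_ln_r).sum())
    )
    return alpha, u, float(elbo)


def protected_exceedance_probability(
    log_evidence: np.ndarray,
    n_samples: int = 100_000,
    seed: int = 0,
    alpha0: float = 1.0,
    models: list[str] | None = None,
) -> ModelComparison:
    """Protected exceedance probabilities from a participant x model
    log-evidence matrix (use -AICc/2 as the evidence approximation).

    PXP_k = EP_k * (1 - BOR) + BOR / K, where EP is the exceedance
    probability under the Dirichlet posterior (Monte-Carlo estimate) and BOR
    the posterior probability of the equal-frequency null model.
    """
    le = np.asarray(log_evidence, dtype=float)
    if le.ndim != 2 or le.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two models")
    n, k = le.shape
    le = le - le.max(axis=1, keepdims=True)  # per-subject shift, invariant
    alpha, _, f1 = _vb_dirichlet(le, alpha0=alpha0)
    f0 = float(logsumexp(le, axis=1).sum() - n * math.log(k))
    bor = float(1.0 / (1.0 + math.exp(min(max(f1 - f0, -700), 700))))
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_samples))
    ep = np.bincount(np.argmax(draws, axis=1), minlength=k) / n_samples
    pxp = ep * (1.0 - bor) + bor / k
    return ModelComparison(
        models=models or [f"m{i}" for i in range(k)],
        pxp=pxp,
        ep=ep,
        bor=bor,
        alpha=alpha,
    )


def compare_models(fit_results: dict[str, list[FitResult]], **kw) -> ModelComparison:
    """Group comparison from per-model lists of fits (same participant order).

    Model evidence is approximated by -AICc/2.
    """
    models = list(fit_results)
    aiccs = np.array([[r.aicc for r in fit_results[m]] for m in models]).T
    comp = protected_exceedance_probability(-aiccs / 2.0, models=models, **kw)
    delta = aiccs - aiccs.min(axis=1, keepdims=True)
    comp.delta_aicc = pd.DataFrame(
        delta, columns=models, index=[r.participant for r in fit_results[models[0]]]
    )
    return comp


def frequency_sweep(
    dataset: pd.DataFrame,
    model: str,
    frequencies=(0.0, 1.0, 2.0, 3.3, 4.0, 5.0, 8.0, 16.0),
    **fit_args,
) -> pd.DataFrame:
    """Fit ``model`` once per assumed oscillation frequency; AICc per row.

    0 Hz means no oscillation: the reset terms reduce to decaying envelopes
    whose phases are no longer free parameters — only the envelope sign
    remains, handled as a discrete model choice (best of the sign
    combinations), so the 0 Hz model has two fewer free parameters.
    Failed fits are recorded with NaN AICc.
    """
    task_kind = make_design(dataset["condition"].iloc[0]).task_kind
    theta_names = [
        n for n in _free_names(model, task_kind) if n.startswith("theta")
    ]
    rows = []
    for f in frequencies:
        try:
            if float(f) == 0.0:
                best = None
                for signs in np.ndindex(*(2,) * len(theta_names)):
                    fixed = {
                        n: (math.pi / 2 if s == 0 else -math.pi / 2)
                        for n, s in zip(theta_names, signs)
                    }
                    res = fit_participant(
                        dataset, model, f=0.0, fixed=fixed, **fit_args
                    )
                    if best is None or res.aicc < best.aicc:
                        best = res
                res = best
            else:
                res = fit_participant(dataset, model, f=float(f), **fit_args)
            rows.append(
                {"frequency_hz": f, "neg_log_lik": res.neg_log_lik,
                 "k_params": res.k_params, "aicc": res.aicc,
                 **{f"param_{k}": v for k, v in res.params.items()}}
            )
        except RuntimeError:
            rows.append({"frequency_hz": f, "neg_log_lik": np.nan, "aicc": np.nan})
    return pd.DataFrame(rows)
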