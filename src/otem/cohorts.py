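"""Synthetic participants and cohorts with known ground-truth parameters.

Cohorts are the package's stand-in for human groups: each participant gets a
parameter vector drawn from configurable per-parameter ranges (or fixed
values) and a simulated session.  All randomness flows from a single seed, so
cohorts are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accumulate import MODELS, simulate_dataset
from .design import make_design
from .params import ConstAccumParams, OTEMParams, UrgencyParams

PI = math.pi

# Demo parameter values: a mid-range, documented operating point with the
# prime resetting phase to ~0 and the mask to ~pi, which yields sustained
# positive priming in unmasked tasks, positive-then-negative priming in
# masked tasks, and near-cancellation when the prime-to-mask interval is
# minimal (additive reset).
_DEMO_OTEM = dict(
    alpha=0.15,
    gamma=0.95,
    mu=1.0,
    kappa=1.5,
    theta_prime=0.0,
    theta_mask=PI,
    zeta=1.0,
    nu=3.0,
    b=1.6,
    sigma_noise=0.05,
)

_DEMO_URGENCY = dict(
    alpha=0.15, kappa=1.5, theta=0.0, zeta=1.0, nu=3.0, b=1.6, sigma_noise=0.05
)

_DEMO_CONST = dict(lambda_s=2.0, mu=1.0, zeta=0.8, sigma_noise=0.05)


def default_demo_params(model: str, task_kind: str = "masked"):
    """A documented fixed parameter set for demos and qualitative checks.

    theta_prime = 0, theta_mask = pi, f = 3.3 Hz, Weber k = 0.13, with
    mid-range values elsewhere.
    """
    if model in ("otem_additive", "otem_substitutive", "otem"):
        reset = "substitutive" if model.endswith("substitutive") else "additive"
        return OTEMParams(**_DEMO_OTEM, reset_mode=reset)
    if model == "urgency":
        return UrgencyParams(**_DEMO_URGENCY)
    if model == "const_accum":
        return ConstAccumParams(**_DEMO_CONST)
    raise ValueError(f"unknown model {model!r}; valid models: {MODELS}")


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    ``param_distributions`` maps parameter names to either a fixed value or
    a (low, high) uniform range; unspecified parameters take the demo value.
    """

    n_participants: int
    design: str  # preset name
    model: str = "otem_additive"
    param_distributions: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_participants": self.n_participants,
                "design": self.design,
                "model": self.model,
                "param_distributions": self.param_distributions,
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d["param_distributions"] = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["param_distributions"].items()
        }
        return cls(**d)


def _draw_params(spec: CohortSpec, rng: np.random.Generator):
    base = default_demo_params(spec.model)
    values = {}
    for name, dist in spec.param_distributions.items():
        if isinstance(dist, (tuple, list)):
            lo, hi = dist
            values[name] = float(rng.uniform(lo, hi))
        else:
            values[name] = float(dist)
    try:
        return dataclasses.replace(base, **values)
    except (ValueError, TypeError) as err:
        raise ValueError(f"invalid parameter draw {values}: {err}") from err


def sample_cohort(spec: CohortSpec):
    """Draw a cohort: (list of ground-truth params, combined trial table).

    Each participant's parameters respect the model invariants (draws that
    violate them, e.g. zeta >= b, raise immediately rather than being
    silently resampled).
    """
    if spec.n_participants < 1:
        raise ValueError("need at least one participant")
    design = make_design(spec.design)
    rng = np.random.default_rng(spec.seed)
    params_list, datasets = [], []
    for i in range(spec.n_participants):
        pid = f"p{i + 1:02d}"
        params = _draw_params(spec, rng)
        ds = simulate_dataset(
            design, params, spec.model, seed=int(rng.integers(2**31)), participant=pid
        )
        params_list.append(params)
        datasets.append(ds)
    return params_list, pd.concat(datasets, ignore_index=True)
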