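"""Estimator interface to the accumulation models.

Each model is exposed as a scikit-learn-style estimator: hyperparameters in
``__init__`` (inspectable via ``get_params``/``set_params``), ``fit(X)`` on a
single participant's trial table (a DataFrame in the package's trial-table
schema), fitted attributes with a trailing underscore, and ``predict(X)``
returning the model's deterministic expected RT (ms) per trial.

These estimators compose with sklearn model-selection utilities that accept
DataFrame inputs; X is a trial table rather than a numeric matrix, so the
usual array validation is intentionally not applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._engine import PreparedCondition
from .design import make_design
from .fitting import fit_participant, fitted_params


class _AccumulationEstimator(BaseEstimator):
    """Shared fit/predict machinery; subclasses pin the model label."""

    _model: str = ""

    def __init__(
        self,
        f: float = 3.3,
        n_restarts: int = 10,
        seed: int = 0,
        shared_map: tuple | None = None,
        bounds: dict | None = None,
        stage1_maxiter: int = 60,
        polish_maxiter: int = 500,
    ):
        self.f = f
        self.n_restarts = n_restarts
        self.seed = seed
        self.shared_map = shared_map
        self.bounds = bounds
        self.stage1_maxiter = stage1_maxiter
        self.polish_maxiter = polish_maxiter

    def _validate(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a trial-table DataFrame")
        if X["participant"].nunique() != 1:
            raise ValueError("fit one participant at a time")
        return X

    def fit(self, X: pd.DataFrame, y=None):
        """Maximum-likelihood fit to one participant's trial table."""
        X = self._validate(X)
        res = fit_participant(
            X,
            self._model,
            bounds=self.bounds,
            n_restarts=self.n_restarts,
            seed=self.seed,
            shared_map=self.shared_map,
            f=self.f,
            stage1_maxiter=self.stage1_maxiter,
            polish_maxiter=self.polish_maxiter,
        )
        self.result_ = res
        self.params_ = res.params
        self.neg_log_lik_ = res.neg_log_lik
        self.aicc_ = res.aicc
        self.n_params_ = res.k_params
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Expected RT (ms) per trial of ``X`` under the fitted parameters."""
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted")
        X = self._validate(X)
        out = np.empty(len(X), dtype=float)
        for cond, sub in X.groupby("condition"):
            design = make_design(cond)
            params = fitted_params(self.result_, condition=cond, f=self.f)
            prep = PreparedCondition(sub, design)
            idx = X.index.get_indexer(sub.index)
            out[idx] = 1000.0 * prep.expected_rt(self._model, params)
        return out

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-trial log-likelihood (higher is better)."""
        X = self._validate(X)
        total, n = 0.0, 0
        for cond, sub in X.groupby("condition"):
            design = make_design(cond)
            params = fitted_params(self.result_, condition=cond, f=self.f)
            prep = PreparedCondition(sub, design)
            total -= prep.neg_log_likelihood(self._model, params)
            n += int(prep.likelihood_mask.sum())
        return total / max(n, 1)


class OTEMModel(_AccumulationEstimator):
    """Oscillated temporal expectation model (additive or substitutive reset)."""

    def __init__(
        self,
        reset_mode: str = "additive",
        f: float = 3.3,
        n_restarts: int = 10,
        seed: int = 0,
        shared_map: tuple | None = None,
        bounds: dict | None = None,
        stage1_maxiter: int = 60,
        polish_maxiter: int = 500,
    ):
        super().__init__(
            f=f,
            n_restarts=n_restarts,
            seed=seed,
            shared_map=shared_map,
            bounds=bounds,
            stage1_maxiter=stage1_maxiter,
            polish_maxiter=polish_maxiter,
        )
        self.reset_mode = reset_mode

    @property
    def _model(self) -> str:
        return f"otem_{self.reset_mode}"


class OscillatedUrgencyModel(_AccumulationEstimator):
    """Hazard-rate urgency model with attentional oscillation."""

    _model = "urgency"


class ConstantAccumulationModel(_AccumulationEstimator):
    """Stimulus-triggered constant-rate racing accumulators."""

    _model = "const_accum"
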