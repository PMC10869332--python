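"""Scikit-learn style estimators: one learner per cognitive model.

Each learner wraps a forward predictor from :mod:`autrel.models` together with
the truncated-normal observation model and fits its parameters to one
participant's judgment series by multi-start bounded maximum likelihood::

    learner = DeltaRuleLearner(random_state=0).fit(bits, judgments)
    learner.params_, learner.loglik_, learner.bic_

``X`` is the automation-correctness bit sequence (shape ``(n,)`` or
``(n, 1)``); ``y`` the 0-100 slider judgments, one per contact. Fitted
attributes follow sklearn conventions (trailing underscore); ``get_params`` /
``set_params`` / cloning work as usual, so learners compose with sklearn
model-selection tooling.

Optimization: uniform seeded draws within the parameter bounds start a bounded
local optimizer (L-BFGS-B for smooth likelihoods; Nelder-Mead for the
two-kernel and IIAB models, whose regime switches make the surface only
piecewise smooth). The discrete contingent-sampling history length ``m`` is
optimized by exhaustive grid with the continuous parameters refit per ``m``.
The two-kernel learner additionally starts one restart from the fitted
single delta rule (its exact special case), which guarantees the nested
log-likelihood dominance two_kernel >= delta on every series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .models import MODEL_REGISTRY, MODEL_NAMES, LatentPrediction, predict
from .observation import llo_transform, prediction_loglik

__all__ = [
    "FitSettings",
    "FitResult",
    "ReliabilityLearner",
    "BayesianLearner",
    "DeltaRuleLearner",
    "TwoKernelDeltaLearner",
    "RecencySamplingLearner",
    "LastAverageSamplingLearner",
    "ContingentSamplingLearner",
    "IIABLearner",
    "NoUpdateLearner",
    "LEARNER_CLASSES",
    "make_learner",
    "expected_judgments",
    "split_params",
]

SIGMA_BOUNDS = (0.01, 1.0)
LLO_BOUNDS = {"gamma_llo": (0.1, 10.0), "p0_llo": (0.01, 0.99)}


@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration shared by all learners.

    ``n_restarts`` uniform seeded starts are drawn within the bounds; the best
    local optimum is reported. ``maxfev_nm`` caps Nelder-Mead evaluations per
    restart for the piecewise-smooth models.
    """

    n_restarts: int = 20
    maxfev_nm: int = 400
    tol: float | None = None


@dataclass(frozen=True)
class FitResult:
    """Per-participant maximum-likelihood fit of one model."""

    model: str
    params: dict
    loglik: float
    k: int
    n: int
    bic: float
    n_restarts: int
    converged: bool
    seed: int
    use_llo: bool = False


def _as_bits(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be a 1-d bit sequence (or a single column)")
    bits = X.astype(int)
    if bits.size and not np.isin(bits, (0, 1)).all():
        raise ValueError("X must contain only 0/1 automation-correctness bits")
    return bits


def _trunc_mean(means: np.ndarray, sigma: float) -> np.ndarray:
    """Mean of a normal(mean, sigma) truncated to [0, 1]."""
    from scipy.special import ndtr

    a = -means / sigma
    b = (1.0 - means) / sigma
    phi = lambda z: np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    mass = ndtr(b) - ndtr(a)
    return means + sigma * (phi(a) - phi(b)) / mass


class _ParamSpace:
    """Continuous optimization space for one model (+ sigma, + optional LLO)."""

    def __init__(self, model: str, use_llo: bool):
        spec = MODEL_REGISTRY[model]
        self.model = model
        self.spec = spec
        self.use_llo = use_llo
        if use_llo and not spec.supports_llo:
            raise ValueError(f"model {model!r} cannot be augmented with LLO")
        names, bounds = [], []
        for name in spec.param_names:
            if name in spec.discrete:
                continue
            if model == "two_kernel" and name == "alpha_fast":
                # reparameterize: alpha_fast = alpha_slow + d*(1 - alpha_slow)
                names.append("_delta_fast")
                bounds.append((0.0, 1.0))
                continue
            names.append(name)
            bounds.append(spec.bounds[name])
        names.append("sigma")
        bounds.append(SIGMA_BOUNDS)
        if use_llo:
            for name, b in LLO_BOUNDS.items():
                names.append(name)
                bounds.append(b)
        self.names = names
        self.bounds = np.asarray(bounds, dtype=float)

    def to_params(self, x: np.ndarray, discrete: dict | None = None) -> dict:
        x = np.clip(x, self.bounds[:, 0], self.bounds[:, 1])
        params = dict(zip(self.names, x))
        if "_delta_fast" in params:
            d = params.pop("_delta_fast")
            a = params["alpha_slow"]
            params["alpha_fast"] = a + d * (1.0 - a)
        if discrete:
            params.update(discrete)
        return params

    def to_vector(self, params: dict) -> np.ndarray:
        x = []
        for name in self.names:
            if name == "_delta_fast":
                a, f = params["alpha_slow"], params["alpha_fast"]
                x.append(0.0 if a >= 1.0 else (f - a) / (1.0 - a))
            else:
                x.append(params[name])
        return np.clip(np.asarray(x, float), self.bounds[:, 0], self.bounds[:, 1])


def split_params(params: dict):
    """Split a flat parameter dict into (learning, sigma, llo-or-None)."""
    learning = {k: v for k, v in params.items()
                if k not in ("sigma", "gamma_llo", "p0_llo")}
    llo = None
    if "gamma_llo" in params:
        llo = {"gamma_llo": params["gamma_llo"], "p0_llo": params["p0_llo"]}
    return learning, params["sigma"], llo


_split_obs = split_params


def expected_judgments(bits, model: str, params: dict) -> np.ndarray:
    """Expected 0-100 judgment per contact for a model at given parameters.

    Mixture-weighted truncated-normal means of the (possibly LLO-distorted)
    latent components, times 100. ``params`` is a flat dict of learning
    parameters plus ``sigma`` (and optionally ``gamma_llo``/``p0_llo``).
    """
    learning, sigma, llo = _split_obs(params)
    pred = predict(model, _as_bits(bits), learning)
    out = np.empty(len(pred))
    for i, (m, w) in enumerate(zip(pred.means, pred.weights)):
        means = m if llo is None else np.asarray(llo_transform(m, llo), float)
        out[i] = float(_trunc_mean(means, sigma) @ w)
    return 100.0 * out


class ReliabilityLearner(BaseEstimator):
    """Base class: maximum-likelihood fit of one learning model to one series.

    Parameters
    ----------
    n_restarts : int
        Number of uniform seeded starts for the local optimizer.
    random_state : int or None
        Seed for the restart draws; fits are deterministic given a seed.
    use_llo : bool
        Augment the observation model with a linear-in-log-odds distortion of
        the latent means (two extra parameters).
    """

    model_name: str = ""  # overridden by subclasses

    def __init__(self, n_restarts: int = 20, random_state=None, use_llo: bool = False):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.use_llo = use_llo

    # -- core ---------------------------------------------------------------

    def _settings(self) -> FitSettings:
        return FitSettings(n_restarts=self.n_restarts)

    def _method(self) -> str:
        return "Nelder-Mead" if self.model_name in ("two_kernel", "iiab") else "L-BFGS-B"

    def _neg_loglik(self, x, space, y01, bits, discrete):
        params = space.to_params(x, discrete)
        learning, sigma, llo = _split_obs(params)
        try:
            pred = predict(self.model_name, bits, learning)
            return -prediction_loglik(y01, pred, sigma, llo)
        except (ValueError, FloatingPointError):
            return np.inf

    def _optimize(self, space, y01, bits, discrete, starts, settings):
        best_x, best_val, success = None, np.inf, False
        method = self._method()
        options = {}
        if method == "Nelder-Mead":
            options["maxfev"] = settings.maxfev_nm
        bounds = [tuple(b) for b in space.bounds]
        for x0 in starts:
            res = minimize(
                self._neg_loglik, x0, args=(space, y01, bits, discrete),
                method=method, bounds=bounds, options=options, tol=settings.tol,
            )
            val = res.fun if np.isfinite(res.fun) else self._neg_loglik(
                res.x, space, y01, bits, discrete)
            if not np.isfinite(val):
                continue
            success = success or bool(res.success)
            if val < best_val:
                best_val, best_x = val, res.x
        if best_x is None:
            # every restart diverged: flag rather than raise, report the best
            # raw start so downstream tables still have an entry
            vals = [self._neg_loglik(x0, space, y01, bits, discrete) for x0 in starts]
            i = int(np.argmin(vals))
            best_x, best_val, success = starts[i], vals[i], False
        return best_x, best_val, success

    def _extra_starts(self, space, y01, bits, seed, settings):
        """Model-specific deterministic starting points (subclass hook)."""
        return []

    def fit(self, X, y):
        bits = _as_bits(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or y.size != bits.size:
            raise ValueError("y must be one judgment per contact")
        if y.size == 0:
            raise ValueError("cannot fit an empty series")
        if y.min() < 0 or y.max() > 100:
            raise ValueError("judgments must lie in [0, 100]")
        y01 = y / 100.0
        seed = 0 if self.random_state is None else int(self.random_state)
        settings = self._settings()
        spec = MODEL_REGISTRY[self.model_name]
        space = _ParamSpace(self.model_name, self.use_llo)
        rng = np.random.default_rng(seed)

        if spec.discrete:
            grid = [
                {name: m for name in spec.discrete}
                for m in range(int(spec.bounds[spec.discrete[0]][0]),
                               int(spec.bounds[spec.discrete[0]][1]) + 1)
            ]
        else:
            grid = [None]

        best = (None, np.inf, None, False)  # (x, val, discrete, success)
        for discrete in grid:
            starts = list(
                rng.uniform(space.bounds[:, 0], space.bounds[:, 1],
                            size=(settings.n_restarts, len(space.names)))
            )
            starts += self._extra_starts(space, y01, bits, seed, settings)
            x, val, ok = self._optimize(space, y01, bits, discrete, starts, settings)
            if val < best[1]:
                best = (x, val, discrete, ok)

        x, val, discrete, ok = best
        params = space.to_params(x, discrete)
        k = spec.k_learning + 1 + (2 if self.use_llo else 0)
        n = int(y.size)
        loglik = -float(val)
        self.params_ = params
        self.loglik_ = loglik
        self.k_ = k
        self.n_ = n
        self.bic_ = k * math.log(n) - 2.0 * loglik
        self.converged_ = bool(ok)
        self.n_restarts_ = settings.n_restarts
        self.result_ = FitResult(
            model=self.model_name, params=params, loglik=loglik, k=k, n=n,
            bic=self.bic_, n_restarts=settings.n_restarts, converged=bool(ok),
            seed=seed, use_llo=self.use_llo,
        )
        return self

    # -- inference ----------------------------------------------------------

    def latent(self, X) -> LatentPrediction:
        """Latent prediction under the fitted parameters."""
        learning, _, _ = _split_obs(self.params_)
        return predict(self.model_name, _as_bits(X), learning)

    def predict(self, X) -> np.ndarray:
        """Expected 0-100 judgment per contact under the fitted model.

        Mixture-weighted truncated-normal means of the (possibly
        LLO-distorted) latent components, times 100.
        """
        return expected_judgments(X, self.model_name, self.params_)

    def score(self, X, y) -> float:
        """Log-likelihood of judgments y (0-100) under the fitted parameters."""
        learning, sigma, llo = _split_obs(self.params_)
        pred = predict(self.model_name, _as_bits(X), learning)
        return prediction_loglik(np.asarray(y, float) / 100.0, pred, sigma, llo)


class BayesianLearner(ReliabilityLearner):
    """Static-environment beta-binomial learner (prior pseudo-counts p, q)."""

    model_name = "bayesian"


class DeltaRuleLearner(ReliabilityLearner):
    """Prediction-error (delta rule) learner with rate alpha and start r0."""

    model_name = "delta"


class TwoKernelDeltaLearner(ReliabilityLearner):
    """Two concurrent delta learners; the fast one reports when they diverge."""

    model_name = "two_kernel"

    def _extra_starts(self, space, y01, bits, seed, settings):
        # the delta rule is the exact T=1 special case; starting one restart
        # from its optimum guarantees two_kernel loglik >= delta loglik
        delta = DeltaRuleLearner(
            n_restarts=self.n_restarts, random_state=seed, use_llo=self.use_llo
        ).fit(bits, y01 * 100.0)
        start = dict(delta.params_)
        alpha = start.pop("alpha")
        start.update(alpha_slow=alpha, alpha_fast=alpha, threshold=1.0)
        return [space.to_vector(start)]


class RecencySamplingLearner(ReliabilityLearner):
    """Single-memory sampling with delta-rule (recency) sampling weights."""

    model_name = "sampling_recency"


class LastAverageSamplingLearner(ReliabilityLearner):
    """Samples the most recent outcome or the running weighted average."""

    model_name = "sampling_last_average"


class ContingentSamplingLearner(ReliabilityLearner):
    """History-matching (contingent) sampling; m optimized on a grid."""

    model_name = "contingent"


class IIABLearner(ReliabilityLearner):
    """Change-point ("if it ain't broke") learner."""

    model_name = "iiab"


class NoUpdateLearner(ReliabilityLearner):
    """No-learning baseline: constant latent estimate r0."""

    model_name = "no_update"


LEARNER_CLASSES: dict[str, type[ReliabilityLearner]] = {
    cls.model_name: cls
    for cls in (
        BayesianLearner, DeltaRuleLearner, TwoKernelDeltaLearner,
        RecencySamplingLearner, LastAverageSamplingLearner,
        ContingentSamplingLearner, IIABLearner, NoUpdateLearner,
    )
}
assert set(LEARNER_CLASSES) == set(MODEL_NAMES)


def make_learner(model: str, **kwargs) -> ReliabilityLearner:
    """Instantiate the learner class registered under ``model``."""
    if model not in LEARNER_CLASSES:
        raise ValueError(f"unknown model {model!r}; known: {tuple(LEARNER_CLASSES)}")
    return LEARNER_CLASSES[model](**kwargs)
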