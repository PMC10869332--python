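"""Per-participant model fitting and BIC-based model comparison.

Functional wrappers over the estimator classes in :mod:`autrel.estimators`,
plus the model-comparison arithmetic: BIC (k*ln(n) - 2*loglik), approximate
Bayes factors from BIC differences (exp(dBIC/2)), and per-participant
classification with the Jeffreys-scale conclusiveness cutoff (a participant is
"inconclusive" when the best model beats the runner-up by a Bayes factor
below 3.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import FitResult, FitSettings, make_learner
from .models import MODEL_NAMES, MODEL_REGISTRY
from .observation import JudgmentSeries

INCONCLUSIVE_BF = 3.2  # Jeffreys' scale: below this, evidence is "barely worth mentioning"

__all__ = [
    "FitResult",
    "FitSettings",
    "ClassificationResult",
    "INCONCLUSIVE_BF",
    "fit_model",
    "fit_all_models",
    "bic",
    "approx_bayes_factor",
    "classify_participant",
    "fits_to_frame",
    "frame_to_fits",
]


@dataclass(frozen=True)
class ClassificationResult:
    """Best-supported model for one participant, or "inconclusive"."""

    participant_id: str
    best_model: str  # model name, or "inconclusive"
    bayes_factor: float  # best vs. runner-up
    conclusive: bool


def fit_model(series: JudgmentSeries, model: str,
              settings: FitSettings | None = None, seed: int = 0,
              use_llo: bool = False) -> FitResult:
    """Maximum-likelihood fit of one model to one judgment series."""
    settings = settings or FitSettings()
    learner = make_learner(
        model, n_restarts=settings.n_restarts, random_state=seed, use_llo=use_llo
    )
    learner.fit(series.bits(), series.judgments)
    return learner.result_


def fit_all_models(series: JudgmentSeries, models=None,
                   settings: FitSettings | None = None, seed: int = 0,
                   use_llo: bool = False) -> dict[str, FitResult]:
    """Fit every requested model (default: all eight) to one series."""
    models = tuple(models) if models is not None else MODEL_NAMES
    return {
        m: fit_model(series, m, settings=settings, seed=seed,
                     use_llo=use_llo and MODEL_REGISTRY[m].supports_llo)
        for m in models
    }


def bic(fit: FitResult) -> float:
    """Bayesian information criterion: k*ln(n) - 2*loglik (lower is better)."""
    if fit.n < 1:
        raise ValueError("BIC requires at least one observation")
    return fit.k * math.log(fit.n) - 2.0 * fit.loglik


def approx_bayes_factor(delta_bic: float) -> float:
    """Approximate Bayes factor from a BIC difference: exp(delta_bic / 2)."""
    return float(math.exp(delta_bic / 2.0))


def classify_participant(fits, participant_id: str = "") -> ClassificationResult:
    """Pick the BIC-best model; label inconclusive if BF(best vs next) < 3.2.

    ``fits`` is a mapping of model name to FitResult (at least two models).
    Exact BIC ties are inconclusive.
    """
    if len(fits) < 2:
        raise ValueError("classification needs fits from at least two models")
    ordered = sorted(fits.items(), key=lambda kv: kv[1].bic)
    (best_name, best), (_, runner_up) = ordered[0], ordered[1]
    bf = approx_bayes_factor(runner_up.bic - best.bic)
    conclusive = bf >= INCONCLUSIVE_BF
    return ClassificationResult(
        participant_id=participant_id,
        best_model=best_name if conclusive else "inconclusive",
        bayes_factor=bf,
        conclusive=conclusive,
    )


def fits_to_frame(cohort_fits) -> pd.DataFrame:
    """Tabulate fits: one row per (participant, model).

    ``cohort_fits`` maps participant id to {model: FitResult}; extra context
    (experiment, condition) is merged in when given as
    {participant_id: (series, fits)} tuples instead.
    """
    rows = []
    for pid, entry in cohort_fits.items():
        series = None
        fits = entry
        if isinstance(entry, tuple):
            series, fits = entry
        for model, fit in fits.items():
            row = {
                "participant_id": pid,
                "model": model,
                "loglik": fit.loglik,
                "k": fit.k,
                "n": fit.n,
                "bic": fit.bic,
                "converged": fit.converged,
                "n_restarts": fit.n_restarts,
                "parameters": ";".join(
                    f"{name}={value:.6g}" for name, value in fit.params.items()
                ),
            }
            if series is not None:
                row["experiment"] = series.experiment
                row["condition"] = series.condition
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_fits(frame: pd.DataFrame) -> dict[str, dict[str, FitResult]]:
    """Rebuild {participant: {model: FitResult}} from a fits table/CSV."""
    out: dict[str, dict[str, FitResult]] = {}
    for _, row in frame.iterrows():
        params = {}
        for pair in str(row["parameters"]).split(";"):
            name, _, value = pair.partition("=")
            params[name] = float(value)
        out.setdefault(str(row["participant_id"]), {})[row["model"]] = FitResult(
            model=row["model"], params=params, loglik=float(row["loglik"]),
            k=int(row["k"]), n=int(row["n"]), bic=float(row["bic"]),
            n_restarts=int(row["n_restarts"]), converged=bool(row["converged"]),
            seed=-1, use_llo="gamma_llo" in params,
        )
    return out
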