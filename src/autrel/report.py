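"""Cohort-level model-comparison outputs.

Mirrors the standard presentation for this kind of model comparison:

* a group comparison table of summed BICs per condition, shown as differences
  from the condition's best model (so the winner reads 0);
* recency-conditioned fit curves - per-trial averages of judgments and model
  predictions split by whether the previous automation decision was correct,
  the signature plot for recency effects;
* M (SE) parameter summaries per condition;
* an individual-differences table - the percentage of conclusively classified
  participants best fit by each model, per condition;
* stratified fit curves for the models winning at least a cutoff share (20%
  by default) of a condition's conclusive participants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import expected_judgments
from .fitting import ClassificationResult, classify_participant
from .observation import JudgmentSeries

__all__ = [
    "group_comparison",
    "recency_conditioned_means",
    "parameter_summary",
    "individual_difference_table",
    "stratified_fit_report",
    "plot_recency_fit",
    "classify_cohort",
]


def _condition_label(series: JudgmentSeries) -> str:
    return f"exp{series.experiment}:{series.condition}"


def group_comparison(cohort_fits: dict) -> pd.DataFrame:
    """Summed-BIC comparison table, minimum subtracted per condition.

    ``cohort_fits`` maps participant id to ``(series, {model: FitResult})``.
    Every participant must be fitted by every model. Rows are models, columns
    conditions; each column has exactly one zero (the condition's best model).
    """
    rows = []
    models = None
    for pid, (series, fits) in cohort_fits.items():
        if models is None:
            models = set(fits)
        elif set(fits) != models:
            missing = models.symmetric_difference(fits)
            raise ValueError(f"participant {pid} missing fits for {sorted(missing)}")
        for model, fit in fits.items():
            rows.append(
                {"condition": _condition_label(series), "model": model, "bic": fit.bic}
            )
    table = (
        pd.DataFrame(rows)
        .pivot_table(index="model", columns="condition", values="bic", aggfunc="sum")
    )
    return table - table.min(axis=0)


def recency_conditioned_means(cohort: list[JudgmentSeries],
                              predictions: dict) -> pd.DataFrame:
    """Per-trial means of data and model, split by previous automation accuracy.

    ``predictions`` maps participant id to the model's expected 0-100 judgment
    per contact. Within each trial, contacts are stratified by whether the
    *previous* contact's automation decision was correct (the session's first
    contact has no stratum). Each participant contributes one mean per
    (trial, stratum); the table reports the across-participant mean, the
    standard error of the data mean (sd/sqrt(n); NaN when only one participant
    contributes), and the participant count.
    """
    rows = []
    for series in cohort:
        bits = series.bits()
        model = np.asarray(predictions[series.participant_id], dtype=float)
        if model.size != bits.size:
            raise ValueError(
                f"prediction length {model.size} misaligned with "
                f"{bits.size} contacts for {series.participant_id}"
            )
        trial_idx = series.schedule.trial_index()
        prev_correct = np.empty(bits.size, dtype=object)
        prev_correct[0] = None
        prev_correct[1:] = bits[:-1] == 1
        frame = pd.DataFrame(
            {
                "trial": trial_idx,
                "prev": prev_correct,
                "data": series.judgments,
                "model": model,
            }
        ).iloc[1:]
        grp = frame.groupby(["trial", "prev"], sort=True).mean()
        for (trial, prev), row in grp.iterrows():
            rows.append(
                {
                    "participant_id": series.participant_id,
                    "trial": int(trial),
                    "previous_outcome": "correct" if prev else "incorrect",
                    "data": row["data"],
                    "model": row["model"],
                }
            )
    per_part = pd.DataFrame(rows)
    out = (
        per_part.groupby(["trial", "previous_outcome"], sort=True)
        .agg(
            data_mean=("data", "mean"),
            model_mean=("model", "mean"),
            data_se=("data", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
            n_participants=("data", "size"),
        )
        .reset_index()
    )
    return out


def parameter_summary(cohort_fits: dict, model: str) -> pd.DataFrame:
    """M (SE) of each fitted parameter of ``model``, per condition.

    ``cohort_fits`` maps participant id to ``(series, {model: FitResult})``.
    SE = sample standard deviation / sqrt(n participants).
    """
    rows = []
    for pid, (series, fits) in cohort_fits.items():
        if model not in fits:
            raise ValueError(f"participant {pid} has no fit for {model!r}")
        for name, value in fits[model].params.items():
            rows.append(
                {"condition": _condition_label(series), "parameter": name,
                 "value": float(value)}
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("no fits supplied")
    out = (
        frame.groupby(["condition", "parameter"], sort=True)["value"]
        .agg(
            M="mean",
            SE=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
            n="size",
        )
        .reset_index()
    )
    return out


def individual_difference_table(
    classifications: dict,
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Percentage of conclusive participants best fit by each model, per condition.

    ``classifications`` maps participant id to
    ``(series, ClassificationResult)``. Returns (table, per-condition
    conclusive rate, overall conclusive rate); the table's percentages are over
    conclusive participants only and sum to 100 per condition.
    """
    rows = [
        {
            "condition": _condition_label(series),
            "model": result.best_model,
            "conclusive": result.conclusive,
        }
        for series, result in classifications.values()
    ]
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(), pd.Series(dtype=float), 0.0
    conclusive_rate = frame.groupby("condition")["conclusive"].mean() * 100.0
    overall_rate = float(frame["conclusive"].mean() * 100.0)
    concl = frame[frame["conclusive"]]
    if concl.empty:
        return pd.DataFrame(), conclusive_rate, overall_rate
    counts = concl.pivot_table(
        index="model", columns="condition", values="conclusive", aggfunc="size",
        fill_value=0,
    )
    percent = counts / counts.sum(axis=0) * 100.0
    return percent, conclusive_rate, overall_rate


def stratified_fit_report(cohort_fits: dict, classifications: dict,
                          cutoff: float = 0.20) -> dict:
    """Recency fit curves per (condition, winning model) above a support cutoff.

    For each condition, models conclusively supported for at least ``cutoff``
    of that condition's conclusive participants get a recency-conditioned fit
    curve computed over exactly those participants, using their own fitted
    parameters of that model. Strata with a single participant report means
    with the SE omitted (NaN).
    """
    by_condition: dict[str, dict[str, list[str]]] = {}
    n_conclusive: dict[str, int] = {}
    for pid, (series, result) in classifications.items():
        cond = _condition_label(series)
        if not result.conclusive:
            continue
        n_conclusive[cond] = n_conclusive.get(cond, 0) + 1
        by_condition.setdefault(cond, {}).setdefault(result.best_model, []).append(pid)

    out: dict[tuple[str, str], pd.DataFrame] = {}
    for cond, winners in by_condition.items():
        for model, pids in winners.items():
            if len(pids) / n_conclusive[cond] < cutoff:
                continue
            subset = [cohort_fits[pid][0] for pid in pids]
            predictions = {
                pid: expected_judgments(
                    cohort_fits[pid][0].bits(), model, cohort_fits[pid][1][model].params
                )
                for pid in pids
            }
            out[(cond, model)] = recency_conditioned_means(subset, predictions)
    return out


def plot_recency_fit(curve: pd.DataFrame, ax=None, title: str = ""):
    """Plot a recency-conditioned fit curve (data as open, model as filled dots)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for stratum, offset in (("correct", -0.1), ("incorrect", 0.1)):
        sub = curve[curve["previous_outcome"] == stratum]
        ax.errorbar(
            sub["trial"] + offset, sub["data_mean"], yerr=sub["data_se"],
            fmt="o", mfc="white", label=f"data | prev {stratum}", capsize=2,
        )
        ax.plot(sub["trial"] + offset, sub["model_mean"], "k.", ms=8,
                label=f"model | prev {stratum}")
    ax.set_xlabel("trial")
    ax.set_ylabel("reliability judgment (0-100)")
    ax.set_ylim(0, 100)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def classify_cohort(cohort_fits: dict) -> dict:
    """Classify every participant from their per-model fits.

    Returns {participant_id: (series, ClassificationResult)}.
    """
    return {
        pid: (series, classify_participant(fits, pid))
        for pid, (series, fits) in cohort_fits.items()
    }
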