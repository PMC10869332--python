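"""Synthetic cohorts: judgment series generated from the learning models.

A synthetic participant is generated by running a learning model forward over
a realized automation schedule and drawing each 0-100 judgment from the
truncated-normal observation model. For memory-sampling models a single
mixture component is drawn per contact (each judgment is driven by one sampled
memory), matching the models' semantics. Disengaged responders - participants
who leave the slider at the 50 default or park it on 0/50/100 for long runs -
can be mixed in to exercise the engagement-based exclusion rules applied to
the real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .designs import AutomationSchedule, make_schedule
from .estimators import split_params
from .models import MODEL_REGISTRY, predict
from .observation import JudgmentSeries, llo_transform

DEFAULT_RUN_THRESHOLD = 10  # "runs of many" identical default judgments

__all__ = [
    "CohortSpec",
    "simulate_participant",
    "simulate_disengaged",
    "apply_exclusions",
    "simulate_cohort",
    "DEFAULT_RUN_THRESHOLD",
]


def _truncnorm_draw(rng, means: np.ndarray, sigma: float) -> np.ndarray:
    a = (0.0 - means) / sigma
    b = (1.0 - means) / sigma
    return truncnorm.rvs(a, b, loc=means, scale=sigma, random_state=rng)


def simulate_participant(model: str, params: dict, schedule: AutomationSchedule,
                         seed: int, participant_id: str | None = None) -> JudgmentSeries:
    """Generate one synthetic judgment series from a learning model.

    ``params`` holds the learning parameters plus ``sigma`` (and optionally
    ``gamma_llo``/``p0_llo``). Deterministic for a fixed seed.
    """
    if model not in MODEL_REGISTRY:
        raise ValueError(f"unknown model {model!r}")
    learning, sigma, llo = split_params(params)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    bits = schedule.flatten()
    pred = predict(model, bits, learning)
    rng = np.random.default_rng(seed)
    latent = np.empty(len(pred))
    for i, (m, w) in enumerate(zip(pred.means, pred.weights)):
        latent[i] = m[0] if m.size == 1 else rng.choice(m, p=w)
    if llo is not None:
        latent = np.asarray(llo_transform(latent, llo), float)
    judgments = 100.0 * _truncnorm_draw(rng, latent, sigma)
    return JudgmentSeries(
        participant_id=participant_id or f"sim_{model}_{seed}",
        schedule=schedule,
        judgments=np.clip(judgments, 0.0, 100.0),
        meta={"generating_model": model, "generating_params": dict(params),
              "seed": seed, "disengaged": False},
    )


def simulate_disengaged(style: str, schedule: AutomationSchedule, seed: int,
                        participant_id: str | None = None) -> JudgmentSeries:
    """Generate a disengaged responder.

    ``constant_default`` leaves the slider at the 50 default on well over half
    the contacts; ``run_heavy`` parks it on 0, 50, or 100 for long runs
    (length >= 10) between stretches of ordinary responding.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_contacts
    judgments = np.round(rng.uniform(0.0, 100.0, size=n), 1)
    if style == "constant_default":
        n_default = int(np.ceil(0.5 * n)) + int(rng.integers(1, max(n // 5, 2)))
        idx = rng.choice(n, size=min(n_default, n), replace=False)
        judgments[idx] = 50.0
    elif style == "run_heavy":
        pos = 0
        while pos < n:
            run_len = int(rng.integers(10, 21))
            value = float(rng.choice([0.0, 50.0, 100.0]))
            judgments[pos : pos + run_len] = value
            pos += run_len + int(rng.integers(5, 15))
    else:
        raise ValueError(f"unknown disengaged style {style!r}")
    return JudgmentSeries(
        participant_id=participant_id or f"sim_disengaged_{style}_{seed}",
        schedule=schedule,
        judgments=judgments,
        meta={"generating_model": "disengaged", "style": style, "seed": seed,
              "disengaged": True},
    )


def apply_exclusions(series: JudgmentSeries,
                     run_threshold: int = DEFAULT_RUN_THRESHOLD
                     ) -> tuple[bool, str]:
    """Engagement screen: returns (keep, reason).

    Excluded when (a) more than half the judgments are exactly the 50 default,
    or (b) the series contains a run of ``run_threshold`` or more consecutive
    identical judgments of 0, 50, or 100. The run threshold operationalizes
    the original visual inspection and is a configuration knob.
    """
    y = series.judgments
    if y.size == 0:
        raise ValueError("cannot screen an empty series")
    if np.mean(y == 50.0) > 0.5:
        return False, "default response (50) on more than half of contacts"
    run_value, run_len = None, 0
    for value in y:
        if value == run_value:
            run_len += 1
        else:
            run_value, run_len = value, 1
        if run_len >= run_threshold and value in (0.0, 50.0, 100.0):
            return False, (
                f"run of {run_threshold}+ consecutive {value:g} judgments"
            )
    return True, ""


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``conditions`` lists (experiment, condition, n_participants). ``models``
    maps generating-model names to assignment probabilities (a single-entry
    dict fixes the generator). ``params`` maps each model to its parameter
    values; an entry may be a point value or a (low, high) tuple drawn
    uniformly per participant. ``disengaged_fraction`` of participants are
    replaced by disengaged responders (style drawn 50/50).
    """

    conditions: tuple
    models: dict
    params: dict
    disengaged_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.disengaged_fraction <= 1.0:
            raise ValueError("disengaged_fraction must lie in [0, 1]")
        total = sum(self.models.values())
        if self.models and abs(total - 1.0) > 1e-9:
            raise ValueError("model assignment probabilities must sum to 1")
        for _, _, n in self.conditions:
            if n < 0:
                raise ValueError("participant counts must be nonnegative")


def _draw_params(rng, spec_params: dict) -> dict:
    out = {}
    for name, value in spec_params.items():
        if isinstance(value, (tuple, list)):
            low, high = value
            out[name] = float(rng.uniform(low, high))
        else:
            out[name] = float(value)
    return out


def simulate_cohort(spec: CohortSpec) -> list[JudgmentSeries]:
    """Generate a cohort; each series carries its exclusion flag in ``meta``.

    Per-participant seeds are derived from the master seed (kept below 2^31);
    each participant gets an independently realized schedule of their
    condition.
    """
    master = np.random.default_rng(spec.seed)
    model_names = list(spec.models)
    model_probs = np.array([spec.models[m] for m in model_names], dtype=float)
    cohort: list[JudgmentSeries] = []
    counter = 0
    for experiment, condition, n in spec.conditions:
        for _ in range(n):
            counter += 1
            pid = f"p{counter:04d}_{experiment}_{condition}"
            sched_seed = int(master.integers(2**31))
            part_seed = int(master.integers(2**31))
            schedule = make_schedule(experiment, condition, sched_seed)
            disengaged = master.uniform() < spec.disengaged_fraction
            if disengaged:
                style = "constant_default" if master.uniform() < 0.5 else "run_heavy"
                series = simulate_disengaged(style, schedule, part_seed, pid)
            else:
                model = model_names[int(master.choice(len(model_names), p=model_probs))]
                params = _draw_params(master, spec.params[model])
                series = simulate_participant(model, params, schedule, part_seed, pid)
            keep, reason = apply_exclusions(series)
            series.meta["keep"] = keep
            series.meta["exclusion_reason"] = reason
            cohort.append(series)
    return cohort
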