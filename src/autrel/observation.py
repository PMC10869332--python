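"""Observation model: from latent reliability estimates to 0-100 slider judgments.

Judgments are divided by 100 and modelled as draws from a normal distribution
truncated to [0, 1], centred on the latent estimate produced by the learning
process, with a free standard deviation ``sigma`` capturing response noise
that is independent of learning. Values of exactly 0 or 100 are ordinary
observations at the truncation bounds (the density is continuous; there is no
censoring mass).

An optional "linear in log odds" (LLO) distortion can be interposed between
the latent estimate and the response: the log odds of the reported probability
are linear in the log odds of the latent one, producing the S- and inverse-S
shaped biases seen in human probability estimation. For mixture (memory
sampling) predictions the distortion is applied to each component mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr

from .designs import AutomationSchedule
from .models import LatentPrediction

MEAN_CLAMP_EPS = 1e-6  # latent means are clamped to [eps, 1-eps] before logit

__all__ = [
    "JudgmentSeries",
    "llo_transform",
    "truncnorm_logpdf",
    "series_loglik",
    "cohort_to_frame",
    "frame_to_cohort",
    "read_judgments_csv",
    "write_judgments_csv",
]


@dataclass
class JudgmentSeries:
    """One participant's reliability judgments aligned to a schedule."""

    participant_id: str
    schedule: AutomationSchedule
    judgments: np.ndarray  # slider values in [0, 100], one per contact
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.judgments = np.asarray(self.judgments, dtype=float)
        if self.judgments.size != self.schedule.n_contacts:
            raise ValueError(
                f"{self.judgments.size} judgments for "
                f"{self.schedule.n_contacts} contacts"
            )
        if self.judgments.size and (
            self.judgments.min() < 0 or self.judgments.max() > 100
        ):
            raise ValueError("judgments must lie in [0, 100]")

    @property
    def experiment(self) -> int:
        return self.schedule.experiment

    @property
    def condition(self) -> str:
        return self.schedule.condition

    @property
    def n(self) -> int:
        return int(self.judgments.size)

    def bits(self) -> np.ndarray:
        return self.schedule.flatten()

    def to_frame(self) -> pd.DataFrame:
        frame = self.schedule.to_frame()
        frame.insert(0, "participant_id", self.participant_id)
        frame["judgment_0_100"] = self.judgments
        return frame


def llo_transform(pi, params):
    """Linear-in-log-odds probability distortion.

    logit of the output = gamma_llo * logit(pi) + (1 - gamma_llo) * logit(p0_llo),
    so p0_llo is the fixed (crossover) point and gamma_llo the log-odds slope;
    gamma_llo = 1 is the identity. Inputs are clamped away from {0, 1}.
    """
    gamma = float(params["gamma_llo"])
    p0 = float(params["p0_llo"])
    if gamma <= 0:
        raise ValueError(f"gamma_llo must be positive; got {gamma}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0_llo must lie in (0, 1); got {p0}")
    pi = np.clip(np.asarray(pi, dtype=float), MEAN_CLAMP_EPS, 1.0 - MEAN_CLAMP_EPS)
    return expit(gamma * logit(pi) + (1.0 - gamma) * logit(p0))


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def truncnorm_logpdf(x, mean, sigma):
    """Log-density of a normal(mean, sigma) truncated to [0, 1], at x in [0, 1].

    Vectorized closed form (normal log-density minus the log of the interval
    mass); agrees with scipy.stats.truncnorm.logpdf.
    """
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    if x.size and (np.min(x) < 0 or np.max(x) > 1):
        raise ValueError("x must lie in [0, 1]")
    z = (x - mean) / sigma
    log_mass = np.log(ndtr((1.0 - mean) / sigma) - ndtr(-mean / sigma))
    return -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI - log_mass


def prediction_loglik(judgments01, prediction: LatentPrediction, sigma,
                      llo_params=None) -> float:
    """Summed log-likelihood of 0-1 scaled judgments under a latent prediction.

    Point predictions contribute one truncated-normal log-density per contact;
    mixtures contribute log sum_k w_k * density(x | mean_k, sigma). LLO
    parameters, when given, distort each component mean before the density.
    """
    x = np.asarray(judgments01, dtype=float)
    if x.size != len(prediction):
        raise ValueError(
            f"{x.size} judgments but prediction covers {len(prediction)} contacts"
        )
    if x.size == 0:
        return 0.0
    means = prediction.flat_means
    weights = prediction.flat_weights
    if llo_params is not None:
        means = llo_transform(means, llo_params)
    if prediction.is_point:
        return float(np.sum(truncnorm_logpdf(x, means, sigma)))
    xx = np.repeat(x, prediction.sizes)
    with np.errstate(divide="ignore"):  # zero-weight components drop out as -inf
        comp = np.log(weights) + truncnorm_logpdf(xx, means, sigma)
    per_contact = np.logaddexp.reduceat(comp, prediction.offsets)
    return float(per_contact.sum())


def series_loglik(series: JudgmentSeries, prediction: LatentPrediction,
                  sigma, llo_params=None) -> float:
    """Log-likelihood of a judgment series (0-100 scale) under a prediction."""
    return prediction_loglik(series.judgments / 100.0, prediction, sigma, llo_params)


# ---------------------------------------------------------------------------
# Judgment CSV I/O (import format for external data, export format of the
# simulator): one row per contact with columns participant_id, experiment,
# condition, trial_index, contact_index, automation_correct, judgment_0_100.
# ---------------------------------------------------------------------------

JUDGMENT_COLUMNS = (
    "participant_id", "experiment", "condition", "trial_index",
    "contact_index", "automation_correct", "judgment_0_100",
)


def cohort_to_frame(cohort) -> pd.DataFrame:
    if not cohort:
        return pd.DataFrame(columns=JUDGMENT_COLUMNS)
    return pd.concat([s.to_frame() for s in cohort], ignore_index=True)


def frame_to_cohort(frame: pd.DataFrame) -> list[JudgmentSeries]:
    cohort = []
    for pid, grp in frame.groupby("participant_id", sort=False):
        grp = grp.sort_values("contact_index")
        trials = tuple(
            tuple(int(b) for b in trial_grp["automation_correct"])
            for _, trial_grp in grp.groupby("trial_index", sort=True)
        )
        schedule = AutomationSchedule(
            experiment=int(grp["experiment"].iloc[0]),
            condition=str(grp["condition"].iloc[0]),
            trials=trials,
            seed=-1,  # imported; realization seed unknown
        )
        cohort.append(
            JudgmentSeries(str(pid), schedule, grp["judgment_0_100"].to_numpy())
        )
    return cohort


def read_judgments_csv(path) -> list[JudgmentSeries]:
    return frame_to_cohort(pd.read_csv(path))


def write_judgments_csv(cohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)
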