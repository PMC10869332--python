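"""Forward predictors: from an automation-correctness sequence to latent judgments.

Each learning model maps the observed sequence of automation-correct bits
(``AC_t``, 1 = the automation's classification of contact *t* was correct) and
a parameter bundle to a per-contact *latent prediction*: the distribution of
the latent reliability estimate that generates the participant's judgment.

Point-estimate models (Bayesian, delta, two-kernel delta, IIAB, no-updating)
produce a single latent mean per contact. Memory-sampling models produce a
finite mixture: each judgment is driven by a single sampled memory, so the
latent estimate is one of a small set of candidate values with known sampling
probabilities. Because automation correctness is binary those mixtures
collapse to a handful of components per contact (components may carry zero
weight where a candidate value cannot be sampled yet).

Prediction convention: the judgment elicited after feedback on contact *t*
(asking about the *next* classification) is paired with the prediction that
incorporates contacts ``1..t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "LatentPrediction",
    "MODEL_REGISTRY",
    "MODEL_NAMES",
    "ModelSpec",
    "predict",
    "predict_bayesian",
    "predict_delta",
    "delta_closed_form",
    "predict_two_kernel",
    "predict_sampling_recency",
    "predict_sampling_last_average",
    "predict_contingent",
    "predict_iiab",
    "predict_no_update",
]

M_MAX = 5  # contingent-sampling history lengths searched: 1..M_MAX


class LatentPrediction:
    """Per-contact latent judgment distribution (point value or finite mixture).

    Stored flat for speed: ``flat()`` exposes (contact index, component mean,
    component weight) arrays over all components; the ``means`` / ``weights``
    properties give the per-contact ragged view. Point predictions are
    single-component mixtures with weight 1.
    """

    __slots__ = ("flat_means", "flat_weights", "sizes", "offsets")

    def __init__(self, means, weights=None):
        if weights is None:  # point predictions
            fm = np.asarray(means, dtype=float).ravel()
            fw = np.ones_like(fm)
            sizes = np.ones(fm.size, dtype=np.intp)
        else:
            m = np.asarray(means, dtype=float) if not isinstance(means, list) else means
            if isinstance(m, np.ndarray) and m.ndim == 2:
                fm = m.ravel()
                fw = np.asarray(weights, dtype=float).ravel()
                if fw.size != fm.size:
                    raise ValueError("means and weights shapes differ")
                sizes = np.full(m.shape[0], m.shape[1], dtype=np.intp)
            else:  # ragged list of per-contact arrays
                mlist = [np.asarray(a, dtype=float).ravel() for a in means]
                wlist = [np.asarray(a, dtype=float).ravel() for a in weights]
                if len(mlist) != len(wlist) or any(
                    a.size != b.size for a, b in zip(mlist, wlist)
                ):
                    raise ValueError("means and weights must align per contact")
                sizes = np.array([a.size for a in mlist], dtype=np.intp)
                fm = np.concatenate(mlist) if mlist else np.zeros(0)
                fw = np.concatenate(wlist) if wlist else np.zeros(0)
        if sizes.size and sizes.min() < 1:
            raise ValueError("each contact needs at least one component")
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.intp)
        if fm.size:
            if fm.min() < -1e-12 or fm.max() > 1 + 1e-12:
                raise ValueError("latent means must lie in [0, 1]")
            if fw.min() < -1e-12:
                raise ValueError("mixture weights must be nonnegative")
            totals = np.add.reduceat(fw, offsets)
            if np.abs(totals - 1.0).max() > 1e-10:
                raise ValueError("mixture weights must sum to 1 per contact")
        self.flat_means = fm
        self.flat_weights = fw
        self.sizes = sizes
        self.offsets = offsets

    def __len__(self) -> int:
        return int(self.sizes.size)

    @property
    def means(self) -> list[np.ndarray]:
        return np.split(self.flat_means, np.cumsum(self.sizes)[:-1])

    @property
    def weights(self) -> list[np.ndarray]:
        return np.split(self.flat_weights, np.cumsum(self.sizes)[:-1])

    @property
    def is_point(self) -> bool:
        return bool(self.sizes.size == 0 or self.sizes.max() == 1)

    def point_means(self) -> np.ndarray:
        if not self.is_point:
            raise ValueError("prediction is a mixture; use mixture_mean()")
        return self.flat_means.copy()

    def mixture_mean(self) -> np.ndarray:
        """Expected latent estimate per contact (weights . means)."""
        if not len(self):
            return np.zeros(0)
        return np.add.reduceat(self.flat_means * self.flat_weights, self.offsets)

    def flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(contact index, component mean, component weight) over all components."""
        idx = np.repeat(np.arange(len(self)), self.sizes)
        return idx, self.flat_means, self.flat_weights

    @classmethod
    def _from_flat(cls, sizes, flat_means, flat_weights) -> "LatentPrediction":
        # fast path for predictors that guarantee validity by construction
        obj = cls.__new__(cls)
        obj.sizes = sizes
        obj.offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.intp)
        obj.flat_means = flat_means
        obj.flat_weights = flat_weights
        return obj


def _validate_bits(bits) -> np.ndarray:
    bits = np.asarray(bits, dtype=int)
    if bits.ndim != 1:
        raise ValueError("bits must be a one-dimensional sequence")
    if bits.size and (bits.min() < 0 or bits.max() > 1):
        raise ValueError("bits must be 0/1 (automation incorrect/correct)")
    return bits


def _check_unit(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1]; got {value}")
    return float(value)


def _check_positive(name: str, value: float) -> float:
    if not value > 0:
        raise ValueError(f"{name} must be positive; got {value}")
    return float(value)


# ---------------------------------------------------------------------------
# Point-estimate learners
# ---------------------------------------------------------------------------

def predict_bayesian(bits, params) -> LatentPrediction:
    """Static-environment Bayesian learner.

    Belief after contact t is Beta(p + N_AC, q + N_AI) over the counts of
    correct/incorrect outcomes so far; the latent mean is its posterior mean.
    All experiences are exchangeable, so this model has no recency effect.
    """
    bits = _validate_bits(bits)
    p = _check_positive("p", params["p"])
    q = _check_positive("q", params["q"])
    t = np.arange(1, bits.size + 1)
    n_correct = np.cumsum(bits)
    return LatentPrediction((p + n_correct) / (p + q + t))


def _delta_path(bits: np.ndarray, r0: float, alpha: float) -> np.ndarray:
    # linear recursion r_t = (1-alpha) r_{t-1} + alpha*AC_t
    r, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], bits.astype(float),
                   zi=[(1.0 - alpha) * r0])
    return np.clip(r, 0.0, 1.0)


def predict_delta(bits, params) -> LatentPrediction:
    """Delta-rule (prediction-error) learner: r_t = r_{t-1} + alpha*(AC_t - r_{t-1})."""
    bits = _validate_bits(bits)
    r0 = _check_unit("r0", params["r0"])
    alpha = _check_unit("alpha", params["alpha"])
    if bits.size == 0:
        return LatentPrediction(np.zeros(0))
    return LatentPrediction(_delta_path(bits, r0, alpha))


def delta_closed_form(bits, params, t: int) -> float:
    """Delta rule as an explicit recency-weighted average at contact t.

    r_t = (1-a)^t r0 + sum_{i=0}^{t-1} a (1-a)^i AC_{t-i}; equals the
    iterative update exactly. t = 0 returns r0.
    """
    bits = _validate_bits(bits)
    r0 = _check_unit("r0", params["r0"])
    alpha = _check_unit("alpha", params["alpha"])
    if not 0 <= t <= bits.size:
        raise ValueError(f"t={t} out of range for {bits.size} contacts")
    i = np.arange(t)
    weights = alpha * (1.0 - alpha) ** i
    recent_first = bits[:t][::-1].astype(float)
    return float((1.0 - alpha) ** t * r0 + weights @ recent_first)


def predict_two_kernel(bits, params) -> LatentPrediction:
    """Two-kernel delta rule: slow and fast learners run concurrently.

    Both kernels share r0 and update by the delta rule on every contact. The
    reported estimate is the fast kernel's when |fast - slow| > threshold
    (signalling environmental volatility), otherwise the slow kernel's.
    Kernels never reset after a switch.
    """
    bits = _validate_bits(bits)
    r0 = _check_unit("r0", params["r0"])
    a_slow = _check_unit("alpha_slow", params["alpha_slow"])
    a_fast = _check_unit("alpha_fast", params["alpha_fast"])
    threshold = _check_unit("threshold", params["threshold"])
    if bits.size == 0:
        return LatentPrediction(np.zeros(0))
    slow = _delta_path(bits, r0, a_slow)
    fast = _delta_path(bits, r0, a_fast)
    return LatentPrediction(np.where(np.abs(fast - slow) > threshold, fast, slow))


def predict_no_update(params, length: int) -> LatentPrediction:
    """No-updating baseline: the latent estimate is a constant intercept r0."""
    r0 = _check_unit("r0", params["r0"])
    if length < 0:
        raise ValueError("length must be nonnegative")
    return LatentPrediction(np.full(length, r0))


# ---------------------------------------------------------------------------
# Memory-sampling learners (finite mixtures)
# ---------------------------------------------------------------------------

def predict_sampling_recency(bits, params) -> LatentPrediction:
    """Single-memory sampling with recency (delta-rule) sampling weights.

    For judgment t one item is sampled from {AC_t, ..., AC_1, r0} with
    probabilities {a, a(1-a), ..., a(1-a)^{t-1}, (1-a)^t} (a = alpha_sampling)
    and the sampled value is the latent estimate. Since outcomes are binary
    the mixture collapses to components {1, 0, r0}. Its mean equals the delta
    rule's point prediction with alpha = alpha_sampling and the same r0.
    """
    bits = _validate_bits(bits)
    r0 = _check_unit("r0", params["r0"])
    a = _check_unit("alpha_sampling", params["alpha_sampling"])
    n = bits.size
    if n == 0:
        return LatentPrediction(np.zeros(0))
    # total sampling weight on "automation was correct" memories follows the
    # delta recursion itself; the prior keeps geometric weight (1-a)^t
    w1, _ = lfilter([a], [1.0, -(1.0 - a)], bits.astype(float), zi=[0.0])
    w_r0 = (1.0 - a) ** np.arange(1, n + 1)
    w0 = np.clip(1.0 - w1 - w_r0, 0.0, 1.0)
    means = np.column_stack([np.ones(n), np.zeros(n), np.full(n, r0)])
    weights = np.column_stack([w1, w0, w_r0])
    weights /= weights.sum(axis=1, keepdims=True)
    return LatentPrediction(means, weights)


def predict_sampling_last_average(bits, params) -> LatentPrediction:
    """Sampling of either the most recent outcome or the running average.

    With probability prob_last the latent estimate is AC_t; otherwise it is
    A_t = (weight_r0*r0 + sum_{i<=t} AC_i) / (weight_r0 + t), the average of
    all experiences with the initial belief contributing weight_r0
    pseudo-observations.
    """
    bits = _validate_bits(bits)
    r0 = _check_unit("r0", params["r0"])
    prob_last = _check_unit("prob_last", params["prob_last"])
    w0 = float(params["weight_r0"])
    if w0 < 0:
        raise ValueError(f"weight_r0 must be nonnegative; got {w0}")
    n = bits.size
    if n == 0:
        return LatentPrediction(np.zeros(0))
    t = np.arange(1, n + 1)
    avg = (w0 * r0 + np.cumsum(bits)) / (w0 + t)
    means = np.column_stack([bits.astype(float), avg])
    weights = np.column_stack([np.full(n, prob_last), np.full(n, 1.0 - prob_last)])
    return LatentPrediction(means, weights)


@lru_cache(maxsize=64)
def _contingent_structure(bits_bytes: bytes, n: int, m: int):
    """Prediction structure for contingent sampling, independent of r0.

    Returns (sizes, flat means, flat weights, r0 mask): entries where the mask
    is True must be replaced by r0 (the pre-history contacts). Cached because
    fitting re-evaluates the same (bits, m) with many r0 values.
    """
    bits = np.frombuffer(bits_bytes, dtype=np.int8)
    sizes, flat_means, flat_weights, r0_mask = [], [], [], []
    table: dict[tuple, list[float]] = {}
    for t in range(1, n + 1):
        if t - 1 >= m:  # outcome at contact t follows a full m-history
            hist = tuple(bits[t - 1 - m : t - 1])
            entry = table.setdefault(hist, [0.0, 0.0])
            entry[0] += 1
            entry[1] += float(bits[t - 1])
        if t <= m:
            comp_means, comp_weights, is_r0 = [0.0], [1.0], [True]
        else:
            current = tuple(bits[t - m : t])
            if current in table:
                count, total = table[current]
                comp_means, comp_weights, is_r0 = [total / count], [1.0], [False]
            elif table:
                comp_means = [total / count for count, total in table.values()]
                w = 1.0 / len(comp_means)
                comp_weights = [w] * len(comp_means)
                is_r0 = [False] * len(comp_means)
            else:
                comp_means, comp_weights, is_r0 = [0.0], [1.0], [True]
        sizes.append(len(comp_means))
        flat_means.extend(comp_means)
        flat_weights.extend(comp_weights)
        r0_mask.extend(is_r0)
    return (
        np.array(sizes, dtype=np.intp),
        np.array(flat_means),
        np.array(flat_weights),
        np.array(r0_mask, dtype=bool),
    )


def predict_contingent(bits, params) -> LatentPrediction:
    """Contingent sampling: predict from outcomes that followed matching histories.

    The estimate for judgment t is the mean outcome over earlier occasions
    whose preceding m outcomes matched the most recent m outcomes. For t <= m
    the estimate is r0. When no earlier occasion matches, the random fallback
    sample is marginalized: the prediction is a uniform mixture over the mean
    following-outcomes of every history observed so far, which keeps the
    likelihood deterministic.
    """
    bits = _validate_bits(bits)
    r0 = _check_unit("r0", params["r0"])
    m = int(params["m"])
    if m < 1:
        raise ValueError(f"m must be a positive integer; got {m}")
    n = bits.size
    if n == 0:
        return LatentPrediction(np.zeros(0))
    sizes, flat_means, flat_weights, r0_mask = _contingent_structure(
        bits.astype(np.int8).tobytes(), n, m
    )
    means = flat_means.copy()
    means[r0_mask] = r0
    return LatentPrediction._from_flat(sizes, means, flat_weights)


# ---------------------------------------------------------------------------
# IIAB ("if it ain't broke, don't fix it") change-point learner
# ---------------------------------------------------------------------------

def _iiab_forward(bits, T1, T2, p, q, p_cp, q_cp):
    """Reference (pure Python) IIAB forward pass.

    Returns (per-contact estimates, change-point indices). Change points are
    0-based contact indices at which a new segment starts. See
    :func:`predict_iiab` for the model; this function and its jitted twin are
    the isolated stage-1/stage-2 implementation.
    """
    n = bits.size
    log_T2 = math.log(T2)
    eps = 1e-9
    cum = np.concatenate([[0], np.cumsum(bits)])
    cps: list[int] = []
    seg_start = 0
    anchor = p / (p + q)
    est = np.empty(n)
    lg = math.lgamma
    logml = lambda k, m: (
        lg(p + k) + lg(q + m - k) - lg(p + q + m) - (lg(p) + lg(q) - lg(p + q))
    )
    for t in range(1, n + 1):
        n_seg = t - seg_start
        k_seg = int(cum[t] - cum[seg_start])
        # stage 1: is the current estimate "broken"?
        phat = k_seg / n_seg
        ref = min(max(anchor, eps), 1.0 - eps)
        kl = 0.0
        if phat > 0.0:
            kl += phat * math.log(phat / ref)
        if phat < 1.0:
            kl += (1.0 - phat) * math.log((1.0 - phat) / (1.0 - ref))
        if math.isfinite(T1) and n_seg * kl > T1:
            n_cp = len(cps)
            pi = (p_cp + n_cp) / (p_cp + q_cp + t)
            log_prior_odds = math.log(pi) - math.log1p(-pi)
            if n_seg >= 2:
                # stage 2a: best within-segment change-point location
                best_c, best_logml = 0, -math.inf
                for c in range(1, n_seg):
                    k1 = int(cum[seg_start + c] - cum[seg_start])
                    value = logml(k1, c) + logml(k_seg - k1, n_seg - c)
                    if value > best_logml:
                        best_logml, best_c = value, c
                if best_logml - logml(k_seg, n_seg) + log_prior_odds > log_T2:
                    seg_start = seg_start + best_c
                    cps.append(seg_start)
                    n_seg = t - seg_start
                    k_seg = int(cum[t] - cum[seg_start])
                    anchor = (p + k_seg) / (p + q + n_seg)
                elif cps:
                    # stage 2b: second thought about the last change point
                    prev = cps[-2] if len(cps) >= 2 else 0
                    n_merged = t - prev
                    k_merged = int(cum[t] - cum[prev])
                    k_a = int(cum[seg_start] - cum[prev])
                    gain = (
                        logml(k_merged, n_merged)
                        - logml(k_a, seg_start - prev)
                        - logml(k_seg, n_seg)
                    )
                    if gain - log_prior_odds > log_T2:
                        cps.pop()
                        seg_start = prev
                        n_seg, k_seg = n_merged, k_merged
                        anchor = (p + k_seg) / (p + q + n_seg)
        est[t - 1] = (p + k_seg) / (p + q + n_seg)
    return est, cps


def _make_iiab_jit():
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional speed-up
        return None

    @njit(cache=False)
    def kernel(bits, T1, T2, p, q, p_cp, q_cp):  # pragma: no cover - jitted
        n = bits.size
        log_T2 = math.log(T2)
        eps = 1e-9
        cum = np.zeros(n + 1, dtype=np.int64)
        for i in range(n):
            cum[i + 1] = cum[i] + bits[i]
        cps = np.empty(n, dtype=np.int64)
        n_cp = 0
        seg_start = 0
        anchor = p / (p + q)
        est = np.empty(n)
        log_beta_prior = (
            math.lgamma(p) + math.lgamma(q) - math.lgamma(p + q)
        )
        for t in range(1, n + 1):
            n_seg = t - seg_start
            k_seg = cum[t] - cum[seg_start]
            phat = k_seg / n_seg
            ref = min(max(anchor, eps), 1.0 - eps)
            kl = 0.0
            if phat > 0.0:
                kl += phat * math.log(phat / ref)
            if phat < 1.0:
                kl += (1.0 - phat) * math.log((1.0 - phat) / (1.0 - ref))
            if n_seg * kl > T1:
                pi = (p_cp + n_cp) / (p_cp + q_cp + t)
                log_prior_odds = math.log(pi) - math.log(1.0 - pi)
                if n_seg >= 2:
                    best_c = 0
                    best_logml = -1e300
                    for c in range(1, n_seg):
                        k1 = cum[seg_start + c] - cum[seg_start]
                        k2 = k_seg - k1
                        value = (
                            math.lgamma(p + k1) + math.lgamma(q + c - k1)
                            - math.lgamma(p + q + c)
                            + math.lgamma(p + k2) + math.lgamma(q + (n_seg - c) - k2)
                            - math.lgamma(p + q + n_seg - c)
                            - 2.0 * log_beta_prior
                        )
                        if value > best_logml:
                            best_logml = value
                            best_c = c
                    nosplit = (
                        math.lgamma(p + k_seg) + math.lgamma(q + n_seg - k_seg)
                        - math.lgamma(p + q + n_seg) - log_beta_prior
                    )
                    if best_logml - nosplit + log_prior_odds > log_T2:
                        seg_start = seg_start + best_c
                        cps[n_cp] = seg_start
                        n_cp += 1
                        n_seg = t - seg_start
                        k_seg = cum[t] - cum[seg_start]
                        anchor = (p + k_seg) / (p + q + n_seg)
                    elif n_cp > 0:
                        prev = cps[n_cp - 2] if n_cp >= 2 else 0
                        n_merged = t - prev
                        k_merged = cum[t] - cum[prev]
                        k_a = cum[seg_start] - cum[prev]
                        n_a = seg_start - prev
                        gain = (
                            math.lgamma(p + k_merged)
                            + math.lgamma(q + n_merged - k_merged)
                            - math.lgamma(p + q + n_merged) - log_beta_prior
                        ) - (
                            math.lgamma(p + k_a) + math.lgamma(q + n_a - k_a)
                            - math.lgamma(p + q + n_a) - log_beta_prior
                        ) - (
                            math.lgamma(p + k_seg) + math.lgamma(q + n_seg - k_seg)
                            - math.lgamma(p + q + n_seg) - log_beta_prior
                        )
                        if gain - log_prior_odds > log_T2:
                            n_cp -= 1
                            seg_start = prev
                            n_seg = n_merged
                            k_seg = k_merged
                            anchor = (p + k_seg) / (p + q + n_seg)
            est[t - 1] = (p + k_seg) / (p + q + n_seg)
        return est, cps[:n_cp]

    return kernel


_IIAB_JIT = _make_iiab_jit()


def predict_iiab(bits, params, return_trace: bool = False):
    """IIAB change-point learner.

    The estimate is the mean of a beta belief over outcomes since the last
    perceived change point. Each contact, a first-stage test asks whether the
    evidence that the current estimate is broken - n*KL(segment proportion ||
    the estimate adopted when the segment began) - exceeds T1. If so, a
    second stage runs Bayesian model comparison: the posterior odds for adding
    a change point at the best within-segment location (beta-binomial
    marginal-likelihood ratio times the prior odds of a change point under the
    Beta(p_changepoint + #cp, q_changepoint + #non-cp) belief) are compared
    against T2; when the addition fails, a "second thought" test symmetrically
    considers dropping the most recent change point.

    With T1 = +inf no change point is ever considered and the model reduces
    exactly to the static Bayesian learner with prior (p, q).
    """
    bits = _validate_bits(bits)
    T1 = _check_positive("T1", params["T1"])
    T2 = _check_positive("T2", params["T2"])
    p = _check_positive("p", params["p"])
    q = _check_positive("q", params["q"])
    p_cp = _check_positive("p_changepoint", params["p_changepoint"])
    q_cp = _check_positive("q_changepoint", params["q_changepoint"])
    if bits.size == 0:
        pred = LatentPrediction(np.zeros(0))
        return (pred, []) if return_trace else pred
    if _IIAB_JIT is not None and math.isfinite(T1):
        est, cps = _IIAB_JIT(
            bits.astype(np.int64), float(T1), float(T2), p, q, p_cp, q_cp
        )
        cps = [int(c) for c in cps]
    else:
        est, cps = _iiab_forward(bits, T1, T2, p, q, p_cp, q_cp)
    pred = LatentPrediction(est)
    return (pred, cps) if return_trace else pred


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: learning-parameter names, fitting bounds, and flags."""

    name: str
    param_names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    predict: callable
    discrete: tuple[str, ...] = ()
    supports_llo: bool = True
    uses_bits: bool = True

    @property
    def k_learning(self) -> int:
        return len(self.param_names)


_UNIT = (0.0, 1.0)
_PRIOR = (0.1, 50.0)

MODEL_REGISTRY: dict[str, ModelSpec] = {
    "bayesian": ModelSpec(
        "bayesian", ("p", "q"), {"p": _PRIOR, "q": _PRIOR}, predict_bayesian
    ),
    "delta": ModelSpec(
        "delta", ("r0", "alpha"), {"r0": _UNIT, "alpha": _UNIT}, predict_delta
    ),
    "two_kernel": ModelSpec(
        "two_kernel",
        ("r0", "alpha_slow", "alpha_fast", "threshold"),
        {"r0": _UNIT, "alpha_slow": _UNIT, "alpha_fast": _UNIT, "threshold": _UNIT},
        predict_two_kernel,
    ),
    "sampling_recency": ModelSpec(
        "sampling_recency",
        ("r0", "alpha_sampling"),
        {"r0": _UNIT, "alpha_sampling": _UNIT},
        predict_sampling_recency,
        supports_llo=False,  # single-sample 0/1 components cannot be meaningfully distorted
    ),
    "sampling_last_average": ModelSpec(
        "sampling_last_average",
        ("r0", "weight_r0", "prob_last"),
        {"r0": _UNIT, "weight_r0": (0.0, 20.0), "prob_last": _UNIT},
        predict_sampling_last_average,
    ),
    "contingent": ModelSpec(
        "contingent",
        ("r0", "m"),
        {"r0": _UNIT, "m": (1, M_MAX)},
        predict_contingent,
        discrete=("m",),
    ),
    "iiab": ModelSpec(
        "iiab",
        ("T1", "T2", "p", "q", "p_changepoint", "q_changepoint"),
        {
            "T1": (0.1, 20.0),
            "T2": (0.5, 50.0),
            "p": _PRIOR,
            "q": _PRIOR,
            "p_changepoint": _PRIOR,
            "q_changepoint": _PRIOR,
        },
        predict_iiab,
    ),
    "no_update": ModelSpec(
        "no_update", ("r0",), {"r0": _UNIT},
        lambda bits, params: predict_no_update(params, len(bits)),
        supports_llo=False,
        uses_bits=False,
    ),
}

MODEL_NAMES: tuple[str, ...] = tuple(MODEL_REGISTRY)


def predict(model: str, bits, params) -> LatentPrediction:
    """Dispatch to the named model's forward predictor."""
    if model not in MODEL_REGISTRY:
        raise ValueError(f"unknown model {model!r}; known: {MODEL_NAMES}")
    return MODEL_REGISTRY[model].predict(bits, params)
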