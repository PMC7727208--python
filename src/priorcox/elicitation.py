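"""Convert elicited expert quantile answers into normal distributions on the
log hazard-ratio scale.

Experts answer each question with three quantiles (2.5th, 50th, 97.5th) of the
number of treated patients out of 100 expected to reach the outcome, together
with a usual-care reference count. Each count is converted to a log hazard
ratio against the reference via the complementary-log-log identity, and a
normal distribution is fitted to the three transformed points by least squares
on the CDF. Individual experts are aggregated by linear opinion pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "Z975",
    "QUESTIONS",
    "CONDITIONAL_QUESTIONS",
    "LogHRDistribution",
    "ExpertAnswer",
    "prob_pair_to_loghr",
    "loghr_to_prob",
    "fit_normal_from_quantiles",
    "answer_to_loghr_distribution",
    "pool_experts",
    "opinion_pool_pdf",
    "read_answers_csv",
    "write_answers_csv",
]

#: 97.5th percentile of the standard normal.
Z975 = float(norm.ppf(0.975))

QUESTIONS = ("uncond_less_severe", "uncond_more_severe", "cond_null", "cond_benefit")
CONDITIONAL_QUESTIONS = ("cond_null", "cond_benefit")

_CDF_TARGETS = np.array([0.025, 0.5, 0.975])


@dataclass(frozen=True)
class LogHRDistribution:
    """A univariate normal on the log hazard-ratio scale."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise ValueError(f"mean must be finite, got {self.mean}")
        if not (np.isfinite(self.sd) and self.sd > 0):
            raise ValueError(f"sd must be positive and finite, got {self.sd}")

    @property
    def variance(self) -> float:
        return self.sd**2

    def quantile(self, q: float) -> float:
        """Quantile on the log-HR scale."""
        return float(norm.ppf(q, loc=self.mean, scale=self.sd))

    def hr_summary(self) -> dict:
        """Median hazard ratio and central 95% interval on the HR scale."""
        return {
            "median_hr": float(np.exp(self.mean)),
            "ci_lower": float(np.exp(self.quantile(0.025))),
            "ci_upper": float(np.exp(self.quantile(0.975))),
        }


@dataclass(frozen=True)
class ExpertAnswer:
    """One expert's raw quantile answer to one elicitation question.

    Counts are out of 100 treated patients; ``usual_care_ref`` is the
    comparator count out of 100 under usual care for the same question.
    """

    expert_id: str
    subgroup_factor: str
    question: str
    q025: int
    q50: int
    q975: int
    usual_care_ref: int

    def __post_init__(self) -> None:
        if self.question not in QUESTIONS:
            raise ValueError(
                f"unknown question {self.question!r}; expected one of {QUESTIONS}"
            )
        for name in ("q025", "q50", "q975", "usual_care_ref"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if not (self.q025 <= self.q50 <= self.q975):
            raise ValueError(
                f"quantile counts must be non-decreasing, got "
                f"({self.q025}, {self.q50}, {self.q975})"
            )


def prob_pair_to_loghr(p_treat: float, p_control: float) -> float:
    """Log hazard ratio implied by a pair of event probabilities.

    Under proportional hazards for the time to the outcome, the probability of
    the outcome by a fixed horizon satisfies
    ``log(HR) = log(log(1 - p_treat) / log(1 - p_control))``.
    Positive values favour treatment (faster recovery) when ``p_treat >
    p_control``.
    """
    for name, p in (("p_treat", p_treat), ("p_control", p_control)):
        if not (0.0 < p < 1.0):
            raise ValueError(
                f"{name}={p} must lie strictly inside (0, 1); the transform is "
                "undefined at the boundary"
            )
    return float(np.log(np.log1p(-p_treat) / np.log1p(-p_control)))


def loghr_to_prob(loghr: float, p_control: float) -> float:
    """Inverse of :func:`prob_pair_to_loghr` for fixed comparator probability."""
    if not (0.0 < p_control < 1.0):
        raise ValueError(f"p_control={p_control} must lie strictly inside (0, 1)")
    return float(1.0 - (1.0 - p_control) ** np.exp(loghr))


def fit_normal_from_quantiles(q025: float, q50: float, q975: float) -> LogHRDistribution:
    """Least-squares normal fit to three quantile points.

    Minimises the sum of squared differences between the normal CDF evaluated
    at the three points and the targets (0.025, 0.5, 0.975). Started from the
    symmetric closed form (mean = median, sd from the outer spread); for
    symmetric inputs the closed form is returned unchanged by the optimiser.
    """
    q = np.array([q025, q50, q975], dtype=float)
    if not (q[0] < q[1] < q[2]):
        raise ValueError(f"quantiles must be strictly increasing, got {tuple(q)}")

    mean0 = q[1]
    sd0 = float(np.clip((q[2] - q[0]) / (2 * Z975), 1e-6, 10.0))

    def objective(params: np.ndarray) -> float:
        mean, sd = params
        return float(np.sum((norm.cdf(q, loc=mean, scale=sd) - _CDF_TARGETS) ** 2))

    res = optimize.minimize(
        objective,
        x0=np.array([mean0, sd0]),
        method="L-BFGS-B",
        bounds=[(None, None), (1e-6, 10.0)],
    )
    # L-BFGS-B can report failure on flat objectives; accept any solution whose
    # residual is essentially zero or no worse than the symmetric start.
    if not res.success and res.fun > objective(np.array([mean0, sd0])) + 1e-12:
        raise RuntimeError(
            f"least-squares quantile fit did not converge (residual {res.fun:.3e})"
        )
    return LogHRDistribution(mean=float(res.x[0]), sd=float(res.x[1]))


def _count_to_prob(count: float, context: str) -> float:
    """Counts of 0 or 100 are clamped to 0.5 / 99.5 with a warning: the log-HR
    transform is undefined at the boundary."""
    if count == 0 or count == 100:
        clamped = 0.5 if count == 0 else 99.5
        warnings.warn(
            f"elicited count {count} in {context} clamped to {clamped} "
            "(transform undefined at 0/100)",
            stacklevel=3,
        )
        count = clamped
    return count / 100.0


def answer_to_loghr_distribution(answer: ExpertAnswer) -> LogHRDistribution:
    """Transform an expert's quantile counts to the log-HR scale and fit a normal."""
    if not (0 < answer.usual_care_ref < 100):
        raise ValueError(
            f"usual_care_ref={answer.usual_care_ref} must be strictly inside "
            "(0, 100); counts of 0/100 give an undefined comparator probability"
        )
    p_control = answer.usual_care_ref / 100.0
    ctx = f"{answer.expert_id}/{answer.question}"
    transformed = [
        prob_pair_to_loghr(_count_to_prob(c, ctx), p_control)
        for c in (answer.q025, answer.q50, answer.q975)
    ]
    return fit_normal_from_quantiles(*transformed)


def pool_experts(
    dists: Sequence[LogHRDistribution],
    weights: Sequence[float] | None = None,
) -> LogHRDistribution:
    """Linear opinion pool of expert distributions, moment-matched to a normal.

    The pool is the weighted mixture of the component normals; the returned
    normal matches the mixture mean and variance
    (``var = Σ wᵢ (sᵢ² + mᵢ²) − mean²``). The raw mixture density is available
    through :func:`opinion_pool_pdf` for plotting.
    """
    if len(dists) == 0:
        raise ValueError("cannot pool an empty list of distributions")
    w = _check_weights(weights, len(dists))
    means = np.array([d.mean for d in dists])
    variances = np.array([d.variance for d in dists])
    mean = float(w @ means)
    variance = float(w @ (variances + means**2) - mean**2)
    # Round-off can push the mixture variance a hair below the (correct)
    # weighted component variance when all means coincide.
    variance = max(variance, float(w @ variances))
    return LogHRDistribution(mean=mean, sd=float(np.sqrt(variance)))


def opinion_pool_pdf(
    x: np.ndarray,
    dists: Sequence[LogHRDistribution],
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Density of the raw (un-matched) linear opinion pool at ``x``."""
    if len(dists) == 0:
        raise ValueError("cannot pool an empty list of distributions")
    w = _check_weights(weights, len(dists))
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for wi, d in zip(w, dists):
        out += wi * norm.pdf(x, loc=d.mean, scale=d.sd)
    return out


def _check_weights(weights: Sequence[float] | None, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")
    return w


# ---------------------------------------------------------------------------
# CSV interface: expert_id,subgroup_factor,question,q025,q50,q975,usual_care_ref

_ANSWER_COLUMNS = [
    "expert_id",
    "subgroup_factor",
    "question",
    "q025",
    "q50",
    "q975",
    "usual_care_ref",
]


def read_answers_csv(path) -> list[ExpertAnswer]:
    df = pd.read_csv(path)
    missing = [c for c in _ANSWER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"elicitation CSV missing columns: {missing}")
    return [
        ExpertAnswer(
            expert_id=str(row.expert_id),
            subgroup_factor=str(row.subgroup_factor),
            question=str(row.question),
            q025=int(row.q025),
            q50=int(row.q50),
            q975=int(row.q975),
            usual_care_ref=int(row.usual_care_ref),
        )
        for row in df.itertuples(index=False)
    ]


def write_answers_csv(answers: Iterable[ExpertAnswer], path) -> None:
    df = pd.DataFrame(
        [
            {
                "expert_id": a.expert_id,
                "subgroup_factor": a.subgroup_factor,
                "question": a.question,
                "q025": a.q025,
                "q50": a.q50,
                "q975": a.q975,
                "usual_care_ref": a.usual_care_ref,
            }
            for a in answers
        ],
        columns=_ANSWER_COLUMNS,
    )
    df.to_csv(path, index=False)
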