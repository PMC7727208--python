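"""Bivariate normal priors on subgroup treatment effects and the community of
priors derived from them.

``theta = (theta1, theta2)`` are the treatment log hazard ratios in the
less-severe and more-severe subgroup. The clinical prior is assembled from
elicited marginal and conditional distributions; the sceptical, interaction,
interaction-variance and vague priors are obtained by re-centring and by
re-parameterising onto ``psi = (mean effect, interaction effect)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import multivariate_normal

from .elicitation import LogHRDistribution, pool_experts

__all__ = [
    "COMMUNITY_LABELS",
    "DEFAULT_L",
    "PD_EIGENVALUE_TOL",
    "NotPositiveDefiniteError",
    "ElicitedPriorInputs",
    "BivariatePrior",
    "ReparamOperator",
    "derive_regression_coefficient",
    "build_clinical_prior",
    "build_sceptical_prior",
    "build_interaction_prior",
    "build_vague_prior",
    "build_community",
    "pooled_inputs_from_answers",
    "inputs_from_expert_answers",
]

COMMUNITY_LABELS = (
    "clinical",
    "sceptical",
    "interaction",
    "interaction_variance",
    "vague",
)

#: Default "arbitrarily large" variance on the log-HR scale (prior sd 100).
DEFAULT_L = 1e4

#: Smallest eigenvalue accepted as positive definite.
PD_EIGENVALUE_TOL = 1e-10


class NotPositiveDefiniteError(ValueError):
    """Raised when a derived covariance matrix is not positive definite."""


@dataclass(frozen=True)
class ElicitedPriorInputs:
    """Pooled elicited distributions feeding the bivariate prior.

    ``theta1``/``theta2`` are the unconditional subgroup effects;
    ``theta2_given_null`` and ``theta2_given_benefit`` are the more-severe
    effect conditional on the less-severe effect being null or beneficial by
    ``d`` (a positive log hazard ratio).
    """

    theta1: LogHRDistribution
    theta2: LogHRDistribution
    theta2_given_null: LogHRDistribution
    theta2_given_benefit: LogHRDistribution
    d: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d) and self.d > 0):
            raise ValueError(f"d must be a positive log hazard ratio, got {self.d}")


@dataclass(frozen=True)
class ReparamOperator:
    """Fixed re-parameterisation ``psi = C theta`` onto (mean effect,
    interaction effect), plus the large variance constant ``L``."""

    L: float = DEFAULT_L
    C: np.ndarray = field(
        default_factory=lambda: np.array([[0.5, 0.5], [-1.0, 1.0]])
    )

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L) and self.L > 0):
            raise ValueError(f"L must be positive, got {self.L}")
        C = np.asarray(self.C, dtype=float)
        if C.shape != (2, 2) or abs(np.linalg.det(C)) < 1e-12:
            raise ValueError("C must be an invertible 2x2 matrix")
        object.__setattr__(self, "C", C)

    @property
    def C_inv(self) -> np.ndarray:
        return np.linalg.inv(self.C)


@dataclass(frozen=True)
class BivariatePrior:
    """Bivariate normal prior N(m, V) on (theta1, theta2), tagged with its
    community label."""

    label: str
    m: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in COMMUNITY_LABELS:
            raise ValueError(
                f"unknown prior label {self.label!r}; expected one of "
                f"{COMMUNITY_LABELS}"
            )
        m = np.asarray(self.m, dtype=float).reshape(2)
        V = np.asarray(self.V, dtype=float)
        if V.shape != (2, 2):
            raise ValueError(f"V must be 2x2, got shape {V.shape}")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("V must be symmetric")
        eigmin = float(np.linalg.eigvalsh(V).min())
        if eigmin <= PD_EIGENVALUE_TOL:
            raise NotPositiveDefiniteError(
                f"V is not positive definite (smallest eigenvalue {eigmin:.3e})"
            )
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "V", V)

    def marginal(self, index: int) -> LogHRDistribution:
        """Marginal normal of theta1 (index 0) or theta2 (index 1)."""
        return LogHRDistribution(
            mean=float(self.m[index]), sd=float(np.sqrt(self.V[index, index]))
        )

    def logpdf(self, theta: np.ndarray) -> float:
        return float(multivariate_normal(mean=self.m, cov=self.V).logpdf(theta))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "m": [float(x) for x in self.m],
            "V": [[float(x) for x in row] for row in self.V],
        }


def derive_regression_coefficient(inputs: ElicitedPriorInputs) -> float:
    """Slope of theta2 on theta1 implied by the two conditional answers:
    ``b12 = (p2d - p20) / d``."""
    return (inputs.theta2_given_benefit.mean - inputs.theta2_given_null.mean) / inputs.d


def build_clinical_prior(
    inputs: ElicitedPriorInputs,
    v22_mode: str = "conditional",
    mean_mode: str = "elicited",
) -> BivariatePrior:
    """Clinical prior N(m, V) assembled from the elicited distributions.

    V11 is the elicited variance of theta1; V12 = b12 * V11; V22 is either the
    conditional derivation ``(s20² + s2d²)/2 + b12² V11`` (default) or the
    unconditional elicited variance ``s2²`` (sensitivity). The mean is either
    the elicited pair (p1, p2) (default) or the regression-derived
    ``(p1, p20 + b12 p1)`` (sensitivity).
    """
    if v22_mode not in ("conditional", "unconditional"):
        raise ValueError(f"unknown v22_mode {v22_mode!r}")
    if mean_mode not in ("elicited", "regression"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")

    b12 = derive_regression_coefficient(inputs)
    v11 = inputs.theta1.variance
    v12 = b12 * v11
    if v22_mode == "conditional":
        var_cond = (
            inputs.theta2_given_null.variance + inputs.theta2_given_benefit.variance
        ) / 2.0
        v22 = var_cond + b12**2 * v11
    else:
        v22 = inputs.theta2.variance

    if mean_mode == "elicited":
        m = np.array([inputs.theta1.mean, inputs.theta2.mean])
    else:
        m = np.array(
            [inputs.theta1.mean, inputs.theta2_given_null.mean + b12 * inputs.theta1.mean]
        )

    V = np.array([[v11, v12], [v12, v22]])
    try:
        return BivariatePrior(label="clinical", m=m, V=V)
    except NotPositiveDefiniteError as err:
        raise NotPositiveDefiniteError(
            f"sensitivity derivation rejected: {err}"
        ) from err


def build_sceptical_prior(clinical: BivariatePrior) -> BivariatePrior:
    """Same covariance as the clinical prior, mean centred on the null."""
    return BivariatePrior(label="sceptical", m=np.zeros(2), V=clinical.V.copy())


def build_interaction_prior(
    clinical: BivariatePrior,
    operator: ReparamOperator | None = None,
    null_mean: bool = False,
) -> BivariatePrior:
    """Prior informative only about the interaction effect theta2 - theta1.

    The clinical covariance is mapped onto psi = C theta (W = C V Cᵀ), the
    mean-effect variance is replaced by the large constant L and the
    covariance between mean and interaction set to zero (W* = diag(L, W22)),
    then back-transformed: V* = C⁻¹ W* C⁻ᵀ. ``null_mean=True`` gives the
    interaction-variance prior N(0, V*); the default keeps the elicited mean.
    """
    op = operator if operator is not None else ReparamOperator()
    W = op.C @ clinical.V @ op.C.T
    W_star = np.diag([op.L, W[1, 1]])
    V_star = op.C_inv @ W_star @ op.C_inv.T
    V_star = (V_star + V_star.T) / 2.0  # symmetrise round-off
    if null_mean:
        return BivariatePrior(label="interaction_variance", m=np.zeros(2), V=V_star)
    return BivariatePrior(label="interaction", m=clinical.m.copy(), V=V_star)


def build_vague_prior(operator: ReparamOperator | None = None) -> BivariatePrior:
    """Uninformative prior N(0, L·I)."""
    op = operator if operator is not None else ReparamOperator()
    return BivariatePrior(label="vague", m=np.zeros(2), V=op.L * np.eye(2))


def build_community(
    inputs: ElicitedPriorInputs,
    operator: ReparamOperator | None = None,
    v22_mode: str = "conditional",
    mean_mode: str = "elicited",
) -> list[BivariatePrior]:
    """The five community priors: clinical, sceptical, interaction,
    interaction-variance and vague."""
    op = operator if operator is not None else ReparamOperator()
    clinical = build_clinical_prior(inputs, v22_mode=v22_mode, mean_mode=mean_mode)
    return [
        clinical,
        build_sceptical_prior(clinical),
        build_interaction_prior(clinical, op, null_mean=False),
        build_interaction_prior(clinical, op, null_mean=True),
        build_vague_prior(op),
    ]


# ---------------------------------------------------------------------------
# Assembly from elicitation answers


def _question_distributions(answers, subgroup_factor):
    from .elicitation import answer_to_loghr_distribution

    by_question: dict[str, list] = {}
    for a in answers:
        if a.subgroup_factor != subgroup_factor:
            continue
        by_question.setdefault(a.question, []).append(a)
    required = (
        "uncond_less_severe",
        "uncond_more_severe",
        "cond_null",
        "cond_benefit",
    )
    missing = [q for q in required if q not in by_question]
    if missing:
        raise ValueError(
            f"no answers for questions {missing} of factor {subgroup_factor!r}"
        )
    return {
        q: [answer_to_loghr_distribution(a) for a in by_question[q]]
        for q in required
    }


def pooled_inputs_from_answers(
    answers: Sequence,
    subgroup_factor: str,
    d: float,
    weights: Sequence[float] | None = None,
) -> ElicitedPriorInputs:
    """Pool all experts' answers for one subgroup factor into prior inputs."""
    dists = _question_distributions(answers, subgroup_factor)
    return ElicitedPriorInputs(
        theta1=pool_experts(dists["uncond_less_severe"], weights),
        theta2=pool_experts(dists["uncond_more_severe"], weights),
        theta2_given_null=pool_experts(dists["cond_null"], weights),
        theta2_given_benefit=pool_experts(dists["cond_benefit"], weights),
        d=d,
    )


def inputs_from_expert_answers(
    answers: Sequence,
    expert_id: str,
    subgroup_factor: str,
    d: float,
) -> ElicitedPriorInputs:
    """Prior inputs from a single expert's answers (per-expert sensitivity)."""
    own = [a for a in answers if a.expert_id == expert_id]
    if not own:
        raise ValueError(f"no answers for expert {expert_id!r}")
    return pooled_inputs_from_answers(own, subgroup_factor, d)
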