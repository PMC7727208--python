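"""Synthetic trial tables and expert-answer fixtures with known ground truth.

The default configuration emulates a 121-patient two-arm UK cardiac-surgery
trial: subgroup splits and covariate prevalences follow the published baseline
table, event times follow a proportional-hazards Weibull calibrated to a
6-day median baseline recovery, and censoring is administrative at a fixed
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elicitation import ExpertAnswer, loghr_to_prob, prob_pair_to_loghr
from .cox import TRIAL_COLUMNS

__all__ = [
    "UK_ARM_SIZES",
    "LOW_RENAL_BY_ARM",
    "ORAL_ONLY_BY_ARM",
    "RENAL_MISSING_N",
    "COVARIATE_PREVALENCE",
    "SUBGROUP_FACTORS",
    "renal_subgroup_sizes",
    "glucose_subgroup_sizes",
    "subgroup_prevalence",
    "benefit_shift",
    "usual_care_reference",
    "SimulationConfig",
    "ExpertProfile",
    "ElicitationFixtureConfig",
    "generate_trial",
    "generate_expert_answers",
    "default_expert_panel",
    "scenario_config",
    "SCENARIOS",
]

# Baseline structure of the UK trial being emulated (counts per arm:
# usual care n=61, intervention n=60).
UK_ARM_SIZES = (61, 60)
LOW_RENAL_BY_ARM = (37, 38)  # low-risk-of-renal-failure counts per arm
ORAL_ONLY_BY_ARM = (30, 35)  # oral-antidiabetic-only counts per arm
RENAL_MISSING_N = 1  # renal-risk status missing for one participant

COVARIATE_PREVALENCE = {
    "age_gt70": (17 + 17) / 121,
    "female": (10 + 10) / 121,
    "creat_gt160": (3 + 4) / 121,
    "ef_lt50": (49 + 49) / 121,
    "angio_5d": (5 + 7) / 121,
}

SUBGROUP_FACTORS = ("renal_risk", "glucose_management")

# Hypothesised benefit d in the less-severe subgroup used by the conditional
# elicitation questions, defined by the usual-care/treated count pairs.
_D_COUNT_PAIRS = {"renal_risk": (70, 60), "glucose_management": (65, 50)}


def renal_subgroup_sizes() -> tuple[int, int]:
    """(less-severe, more-severe) sizes for the renal-risk factor, derived
    from the arm-level counts and the one missing participant."""
    less = sum(LOW_RENAL_BY_ARM)
    more = sum(UK_ARM_SIZES) - less - RENAL_MISSING_N
    return less, more


def glucose_subgroup_sizes() -> tuple[int, int]:
    """(less-severe, more-severe) sizes for the glucose-management factor."""
    less = sum(ORAL_ONLY_BY_ARM)
    more = sum(UK_ARM_SIZES) - less
    return less, more


def subgroup_prevalence(factor: str) -> float:
    """Probability of the less-severe subgroup among patients with known status."""
    if factor == "renal_risk":
        less, more = renal_subgroup_sizes()
    elif factor == "glucose_management":
        less, more = glucose_subgroup_sizes()
    else:
        raise ValueError(f"unknown subgroup factor {factor!r}")
    return less / (less + more)


def benefit_shift(factor: str) -> float:
    """The positive log-HR d used in the conditional questions for a factor."""
    treat, control = _D_COUNT_PAIRS[factor]
    return prob_pair_to_loghr(treat / 100, control / 100)


def usual_care_reference(factor: str) -> int:
    """Usual-care comparator count out of 100 for a factor's questions."""
    return _D_COUNT_PAIRS[factor][1]


# ---------------------------------------------------------------------------
# Trial generation


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth configuration for a synthetic two-arm survival trial."""

    n: int = sum(UK_ARM_SIZES)
    treat_fraction: float = 0.5
    subgroup_factor: str = "renal_risk"
    less_severe_prevalence: float | None = None  # default: factor's empirical split
    theta1: float = 0.0  # treatment log-HR, less-severe subgroup
    theta2: float = 0.0  # treatment log-HR, more-severe subgroup
    subgroup_effect: float = 0.0
    covariate_prevalence: dict = field(
        default_factory=lambda: dict(COVARIATE_PREVALENCE)
    )
    covariate_effects: dict = field(default_factory=dict)
    weibull_shape: float = 1.5
    baseline_median_days: float = 6.0
    censor_horizon_days: float = 30.0
    missing_subgroup_n: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0.0 < self.treat_fraction < 1.0):
            raise ValueError("treat_fraction must be in (0, 1)")
        if self.censor_horizon_days <= 0:
            raise ValueError("censor_horizon_days must be positive")
        if self.weibull_shape <= 0 or self.baseline_median_days <= 0:
            raise ValueError("Weibull shape and median must be positive")
        prev = self.prevalence
        if not (0.0 <= prev <= 1.0):
            raise ValueError(f"less-severe prevalence {prev} outside [0, 1]")
        for name, p in self.covariate_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence of {name!r} outside [0, 1]: {p}")
        if not (0 <= self.missing_subgroup_n <= self.n):
            raise ValueError("missing_subgroup_n outside [0, n]")

    @property
    def prevalence(self) -> float:
        if self.less_severe_prevalence is not None:
            return self.less_severe_prevalence
        return subgroup_prevalence(self.subgroup_factor)

    @property
    def weibull_scale(self) -> float:
        """Scale such that the baseline median time equals the configured median."""
        return self.baseline_median_days / np.log(2.0) ** (1.0 / self.weibull_shape)


def generate_trial(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a trial table; deterministic given ``config.seed``.

    Event times are proportional-hazards Weibull:
    ``T = scale * (-log U / exp(eta))^(1/shape)`` with linear predictor
    ``eta = theta1*arm*(1-subgroup) + theta2*arm*subgroup + subgroup_effect*subgroup
    + covariate effects``. Times beyond the horizon are administratively
    censored.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    n_treat = int(round(n * config.treat_fraction))
    arm = np.zeros(n, dtype=int)
    arm[rng.permutation(n)[:n_treat]] = 1

    # subgroup: 1 = more severe
    sub = (rng.random(n) >= config.prevalence).astype(int)

    covs = {
        name: (rng.random(n) < p).astype(int)
        for name, p in config.covariate_prevalence.items()
    }

    eta = (
        config.theta1 * arm * (1 - sub)
        + config.theta2 * arm * sub
        + config.subgroup_effect * sub
    )
    for name, effect in config.covariate_effects.items():
        if name not in covs:
            raise ValueError(f"effect given for unknown covariate {name!r}")
        eta = eta + effect * covs[name]

    u = rng.random(n)
    t = config.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / config.weibull_shape)
    event = t <= config.censor_horizon_days
    time = np.minimum(t, config.censor_horizon_days)

    sub_col = pd.array(sub, dtype="Int64")
    if config.missing_subgroup_n:
        miss = rng.permutation(n)[: config.missing_subgroup_n]
        sub_col[miss] = pd.NA

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "arm": arm,
            "subgroup": sub_col,
            **covs,
            "time_days": np.round(time, 6),
            "event": event.astype(int),
        }
    )
    return df[TRIAL_COLUMNS] if set(TRIAL_COLUMNS) <= set(df.columns) else df


# ---------------------------------------------------------------------------
# Expert-answer fixtures


@dataclass(frozen=True)
class ExpertProfile:
    """Ground truth behind one synthetic expert's answers.

    ``theta1_mean``/``theta2_mean`` are the expert's central log-HR beliefs per
    subgroup, ``width`` the sd of the unconditional beliefs, ``slope`` the
    implied regression of theta2 on theta1 (recovered downstream as b12), and
    ``cond_width`` the sd of the conditional beliefs (default ``0.8 * width``).
    """

    expert_id: str
    theta1_mean: float
    theta2_mean: float
    width: float
    slope: float = 0.5
    cond_width: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.cond_width is not None and self.cond_width <= 0:
            raise ValueError("cond_width must be positive")

    @property
    def conditional_width(self) -> float:
        return self.cond_width if self.cond_width is not None else 0.8 * self.width


@dataclass(frozen=True)
class ElicitationFixtureConfig:
    experts: tuple = ()
    subgroup_factor: str = "renal_risk"

    def __post_init__(self) -> None:
        if self.subgroup_factor not in SUBGROUP_FACTORS:
            raise ValueError(f"unknown subgroup factor {self.subgroup_factor!r}")
        if not self.experts:
            object.__setattr__(self, "experts", tuple(default_expert_panel()))


def default_expert_panel() -> list[ExpertProfile]:
    """Seven-expert panel: one sceptic (A), two enthusiasts (E, F), the rest
    mildly favourable with greater expected benefit in the more severe group."""
    return [
        ExpertProfile("A", -0.15, -0.10, width=0.35, slope=0.4),
        ExpertProfile("B", 0.10, 0.20, width=0.30, slope=0.5),
        ExpertProfile("C", 0.05, 0.15, width=0.30, slope=0.5),
        ExpertProfile("D", 0.10, 0.25, width=0.35, slope=0.6),
        ExpertProfile("E", 0.30, 0.45, width=0.25, slope=0.5),
        ExpertProfile("F", 0.35, 0.50, width=0.25, slope=0.5),
        ExpertProfile("G", 0.05, 0.20, width=0.40, slope=0.5),
    ]


_QUANTILES = (0.025, 0.5, 0.975)
_Z = {0.025: -1.959963984540054, 0.5: 0.0, 0.975: 1.959963984540054}


def _counts_for(mean: float, sd: float, ref_count: int, context: str) -> tuple[int, int, int]:
    p_ref = ref_count / 100.0
    counts = []
    for q in _QUANTILES:
        loghr = mean + sd * _Z[q]
        c = int(round(100 * loghr_to_prob(loghr, p_ref)))
        if not (0 <= c <= 100):
            raise ValueError(f"{context}: implied count {c} outside [0, 100]")
        counts.append(c)
    if not (counts[0] < counts[1] < counts[2]):
        raise ValueError(
            f"{context}: width too small — quantile counts {counts} not strictly "
            "increasing after rounding"
        )
    return tuple(counts)


def generate_expert_answers(config: ElicitationFixtureConfig) -> list[ExpertAnswer]:
    """Quantile-count answers consistent with each expert's configured log-HR
    beliefs, pushed through the inverse probability transform and rounded to
    integer patient counts."""
    factor = config.subgroup_factor
    ref = usual_care_reference(factor)
    d = benefit_shift(factor)
    answers: list[ExpertAnswer] = []
    for ex in config.experts:
        p20 = ex.theta2_mean - ex.slope * ex.theta1_mean
        specs = [
            ("uncond_less_severe", ex.theta1_mean, ex.width),
            ("uncond_more_severe", ex.theta2_mean, ex.width),
            ("cond_null", p20, ex.conditional_width),
            ("cond_benefit", p20 + ex.slope * d, ex.conditional_width),
        ]
        for question, mean, sd in specs:
            q025, q50, q975 = _counts_for(
                mean, sd, ref, f"expert {ex.expert_id}/{question}"
            )
            answers.append(
                ExpertAnswer(
                    expert_id=ex.expert_id,
                    subgroup_factor=factor,
                    question=question,
                    q025=q025,
                    q50=q50,
                    q975=q975,
                    usual_care_ref=ref,
                )
            )
    return answers


# ---------------------------------------------------------------------------
# Scenario pack


SCENARIOS = ("null", "common_benefit", "qualitative_interaction")


def scenario_config(name: str, seed: int = 0, n: int | None = None) -> SimulationConfig:
    """Named ground-truth scenarios used by the test and acceptance suites:
    no effect, a common HR 1.2 benefit, and a qualitative interaction in which
    the observed benefit is smaller (negative) in the more severe subgroup,
    opposite to the elicited expectation."""
    base = SimulationConfig(seed=seed)
    if n is not None:
        base = replace(base, n=n)
    if name == "null":
        return base
    if name == "common_benefit":
        hr = float(np.log(1.2))
        return replace(base, theta1=hr, theta2=hr)
    if name == "qualitative_interaction":
        return replace(base, theta1=0.35, theta2=-0.35)
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
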