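"""Cox proportional-hazards fitting: Efron partial likelihood, maximum
likelihood, and fully Bayesian estimation under a bivariate prior on the two
subgroup treatment effects.

The Bayesian model uses the partial log-likelihood directly as the likelihood,
adds the bivariate normal log-prior on (theta1, theta2) and vague independent
normal priors on all remaining coefficients, and samples the joint posterior
with an independence Metropolis sampler proposed from a multivariate-t centred
at the posterior mode with scale from the observed information. Convergence is
gated on split R-hat and bulk ESS (computed with arviz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import multivariate_t, norm

from .priors import BivariatePrior, DEFAULT_L

__all__ = [
    "TRIAL_COLUMNS",
    "DEFAULT_COVARIATES",
    "ConvergenceError",
    "ModelSpec",
    "MCMCSettings",
    "PosteriorSummary",
    "EfronPartialLikelihood",
    "build_design",
    "cox_partial_loglik",
    "fit_mle",
    "fit_bayes",
    "summarise_posterior",
    "shrinkage_report",
    "read_trial_csv",
    "write_trial_csv",
]

TRIAL_COLUMNS = [
    "id",
    "arm",
    "subgroup",
    "age_gt70",
    "female",
    "creat_gt160",
    "ef_lt50",
    "angio_5d",
    "time_days",
    "event",
]

DEFAULT_COVARIATES = ("age_gt70", "female", "creat_gt160", "ef_lt50", "angio_5d")

THETA_NAMES = ("theta1", "theta2")


class ConvergenceError(RuntimeError):
    """MCMC failed its convergence gate; carries the diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ModelSpec:
    """Model layout: which prior applies to (theta1, theta2), which adjustment
    covariates enter, and the vague variance for all other coefficients."""

    prior: BivariatePrior
    covariates: tuple = DEFAULT_COVARIATES
    include_subgroup_main: bool = True
    vague_variance: float = DEFAULT_L
    drop_constant_covariates: bool = True


@dataclass(frozen=True)
class MCMCSettings:
    seed: int = 0
    chains: int = 4
    iterations: int = 2000  # per chain; first half discarded as warmup
    proposal_df: float = 8.0
    proposal_scale: float = 1.2
    rhat_max: float = 1.01
    min_ess: float = 400.0
    check_convergence: bool = True


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter posterior summary on the hazard-ratio scale."""

    parameter: str
    median_hr: float
    ci_lower: float
    ci_upper: float
    p_hr_gt1: float
    ess: float | None = None
    rhat: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.median_hr <= self.ci_upper):
            raise ValueError("credible interval must bracket the median")
        if not (0.0 <= self.p_hr_gt1 <= 1.0):
            raise ValueError(f"p_hr_gt1={self.p_hr_gt1} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "median_hr": self.median_hr,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_hr_gt1": self.p_hr_gt1,
            "ess": self.ess,
            "rhat": self.rhat,
        }


class EfronPartialLikelihood:
    """Efron-tie-corrected Cox partial log-likelihood with analytic gradient.

    Risk-set structures are precomputed once so repeated evaluations (MCMC,
    optimisation) cost one exp, a few cumulative sums and segment sums.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, X: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(bool)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != time.shape[0]:
            X = X.T
        if np.any(time <= 0):
            raise ValueError("all event/censoring times must be positive")
        if not event.any():
            raise ValueError("no events in the data; partial likelihood undefined")

        order = np.argsort(time, kind="stable")
        self.time = time[order]
        self.event = event[order]
        self.X = X[order]
        self.n, self.p = self.X.shape
        self.n_events = int(event.sum())

        death_rows = np.flatnonzero(self.event)
        death_times = self.time[death_rows]
        # Deaths sorted by time are contiguous per unique time.
        unique_times, group_starts, group_sizes = np.unique(
            death_times, return_index=True, return_counts=True
        )
        self._death_rows = death_rows
        self._group_starts = group_starts  # reduceat indices into death_rows
        self._gid = np.repeat(np.arange(unique_times.size), group_sizes)
        # Efron fraction l/d for each death within its tied group.
        ranks = np.arange(death_times.size) - group_starts[self._gid]
        self._frac = ranks / group_sizes[self._gid]
        # First index (in the ascending sort) at risk at each unique death time.
        self._risk_idx = np.searchsorted(self.time, unique_times, side="left")

    # -- internals ---------------------------------------------------------

    def _weights(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.p,):
            raise ValueError(f"expected {self.p} coefficients, got {beta.shape}")
        if not np.all(np.isfinite(beta)):
            raise ValueError("coefficients must be finite")
        eta = self.X @ beta
        return eta, np.exp(eta)

    def _denominators(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        suffix = np.cumsum(w[::-1])[::-1]
        R = suffix[self._risk_idx][self._gid]
        Wd = np.add.reduceat(w[self._death_rows], self._group_starts)[self._gid]
        return R - self._frac * Wd, Wd

    # -- public API --------------------------------------------------------

    def loglik(self, beta: np.ndarray) -> float:
        eta, w = self._weights(beta)
        denom, _ = self._denominators(w)
        return float(eta[self._death_rows].sum() - np.log(denom).sum())

    def gradient(self, beta: np.ndarray) -> np.ndarray:
        eta, w = self._weights(beta)
        denom, _ = self._denominators(w)
        wx = w[:, None] * self.X
        suffix_wx = np.cumsum(wx[::-1], axis=0)[::-1]
        Rx = suffix_wx[self._risk_idx][self._gid]
        Wdx = np.add.reduceat(wx[self._death_rows], self._group_starts, axis=0)[
            self._gid
        ]
        num = Rx - self._frac[:, None] * Wdx
        return self.X[self._death_rows].sum(axis=0) - (num / denom[:, None]).sum(axis=0)

    def hessian(self, beta: np.ndarray, step: float = 1e-5) -> np.ndarray:
        """Numeric Hessian by central differences of the analytic gradient."""
        beta = np.asarray(beta, dtype=float)
        H = np.empty((self.p, self.p))
        for j in range(self.p):
            h = step * (1.0 + abs(beta[j]))
            up, dn = beta.copy(), beta.copy()
            up[j] += h
            dn[j] -= h
            H[:, j] = (self.gradient(up) - self.gradient(dn)) / (2 * h)
        return (H + H.T) / 2.0


def cox_partial_loglik(
    time: np.ndarray, event: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> float:
    """Efron-corrected Cox partial log-likelihood (one-shot convenience)."""
    return EfronPartialLikelihood(time, event, X).loglik(np.asarray(beta, float))


# ---------------------------------------------------------------------------
# Design matrix


def build_design(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], int]:
    """Build (time, event, X, names, n_excluded) from a trial table.

    Treatment columns are ``theta1 = arm * (1 - subgroup)`` and ``theta2 =
    arm * subgroup`` so each coefficient is the within-subgroup treatment
    effect. Rows with missing subgroup are excluded (count returned).
    Constant covariate columns are dropped with a warning (they carry no
    information and break full rank).
    """
    df = df.copy()
    n_total = len(df)
    missing = df["subgroup"].isna()
    n_excluded = int(missing.sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} patient(s) with missing subgroup", stacklevel=2
        )
        df = df.loc[~missing]

    arm = df["arm"].to_numpy(dtype=float)
    sub = df["subgroup"].to_numpy(dtype=float)
    cols = [arm * (1.0 - sub), arm * sub]
    names = list(THETA_NAMES)
    if spec.include_subgroup_main:
        cols.append(sub)
        names.append("subgroup")
    for cov in spec.covariates:
        x = df[cov].to_numpy(dtype=float)
        if spec.drop_constant_covariates and np.ptp(x) == 0:
            warnings.warn(f"dropping constant covariate {cov!r}", stacklevel=2)
            continue
        cols.append(x)
        names.append(cov)

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    time = df["time_days"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=float).astype(bool)
    for a in (0, 1):
        if not event[arm == a].any():
            raise ValueError(f"no events in arm {a}; model cannot be fitted")
    if n_total - n_excluded != X.shape[0]:
        raise AssertionError("row bookkeeping error")
    return time, event, X, names, n_excluded


# ---------------------------------------------------------------------------
# Maximum likelihood


@dataclass(frozen=True)
class MLEFit:
    """Cox MLE with Wald intervals on the hazard-ratio scale."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    cov: np.ndarray
    n_excluded: int = 0

    def summary(self, parameter: str) -> PosteriorSummary:
        j = self.names.index(parameter)
        b, s = self.beta[j], self.se[j]
        return PosteriorSummary(
            parameter=parameter,
            median_hr=float(np.exp(b)),
            ci_lower=float(np.exp(b - 1.959963984540054 * s)),
            ci_upper=float(np.exp(b + 1.959963984540054 * s)),
            p_hr_gt1=float(norm.sf(0.0, loc=b, scale=s)) if s > 0 else float(b > 0),
        )

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "loglik": self.loglik,
        }


def fit_mle(df: pd.DataFrame, spec: ModelSpec) -> MLEFit:
    """Maximise the Efron partial likelihood; Wald 95% CIs from the observed
    information. Warns (instead of failing) when monotone-likelihood
    separation drives a coefficient beyond ±10."""
    time, event, X, names, n_excluded = build_design(df, spec)
    if event.sum() < X.shape[1]:
        raise ValueError(
            f"only {int(event.sum())} events for {X.shape[1]} parameters"
        )
    pl = EfronPartialLikelihood(time, event, X)
    res = optimize.minimize(
        lambda b: -pl.loglik(b),
        x0=np.zeros(pl.p),
        jac=lambda b: -pl.gradient(b),
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    beta = res.x
    grad_norm = float(np.linalg.norm(pl.gradient(beta)))
    if np.any(np.abs(beta) > 10):
        warnings.warn(
            "possible separation: |beta| > 10 (monotone partial likelihood)",
            stacklevel=2,
        )
    elif grad_norm > 1e-4 * max(1.0, pl.n_events):
        raise RuntimeError(
            f"MLE did not converge (gradient norm {grad_norm:.3e})"
        )
    H = -pl.hessian(beta)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return MLEFit(
        names=names,
        beta=beta,
        se=se,
        loglik=float(pl.loglik(beta)),
        cov=cov,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Bayesian fit


@dataclass
class BayesFit:
    """Posterior draws plus per-parameter summaries and MCMC metadata."""

    names: list[str]
    draws: np.ndarray  # (chains, draws, p), post-warmup
    summaries: dict
    settings: MCMCSettings
    acceptance_rate: float
    mode: np.ndarray
    n_excluded: int = 0

    @property
    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def parameter_draws(self, parameter: str) -> np.ndarray:
        return self.flat_draws[:, self.names.index(parameter)]

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "summaries": {k: v.to_dict() for k, v in self.summaries.items()},
            "acceptance_rate": self.acceptance_rate,
            "seed": self.settings.seed,
            "chains": self.settings.chains,
            "iterations": self.settings.iterations,
        }


def _log_posterior_factory(pl: EfronPartialLikelihood, spec: ModelSpec):
    prior = spec.prior
    Vinv = np.linalg.inv(prior.V)
    _, logdet = np.linalg.slogdet(prior.V)
    const = -0.5 * (2 * np.log(2 * np.pi) + logdet)
    m = prior.m
    vague_prec = 1.0 / spec.vague_variance

    def log_post(beta: np.ndarray) -> float:
        theta = beta[:2] - m
        lp = const - 0.5 * theta @ Vinv @ theta
        rest = beta[2:]
        lp -= 0.5 * vague_prec * float(rest @ rest)
        return pl.loglik(beta) + lp

    def grad(beta: np.ndarray) -> np.ndarray:
        g = pl.gradient(beta)
        g[:2] -= Vinv @ (beta[:2] - m)
        g[2:] -= vague_prec * beta[2:]
        return g

    return log_post, grad


def fit_bayes(
    df: pd.DataFrame, spec: ModelSpec, mcmc: MCMCSettings | None = None
) -> BayesFit:
    """Sample the posterior: Efron partial log-likelihood + bivariate normal
    log-prior on (theta1, theta2) + vague normal priors on the rest.

    Sampling is by independence Metropolis from a multivariate-t proposal
    centred at the posterior mode with scale from the observed-information
    inverse. Fails loudly when split R-hat exceeds the gate or bulk ESS falls
    short on (theta1, theta2).
    """
    settings = mcmc if mcmc is not None else MCMCSettings()
    time, event, X, names, n_excluded = build_design(df, spec)
    pl = EfronPartialLikelihood(time, event, X)
    log_post, grad = _log_posterior_factory(pl, spec)

    # Posterior mode and curvature for the proposal.
    res = optimize.minimize(
        lambda b: -log_post(b),
        x0=np.zeros(pl.p),
        jac=lambda b: -grad(b),
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    mode = res.x
    H = _posterior_neg_hessian(pl, spec, mode)
    cov = _nearest_pd_inverse(H)
    proposal = multivariate_t(
        loc=mode, shape=settings.proposal_scale * cov, df=settings.proposal_df
    )

    n_keep = settings.iterations // 2
    draws = np.empty((settings.chains, n_keep, pl.p))
    n_accept = 0
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    for c, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        # Independence proposals are iid: draw and score them in one batch.
        candidates = np.atleast_2d(
            proposal.rvs(size=settings.iterations, random_state=rng)
        ).reshape(settings.iterations, pl.p)
        lq = np.atleast_1d(proposal.logpdf(candidates))
        logu = np.log(rng.uniform(size=settings.iterations))
        current = mode.copy()
        lp_current = log_post(current)
        lq_current = float(proposal.logpdf(current))
        kept = 0
        for it in range(settings.iterations):
            lp_cand = log_post(candidates[it])
            if logu[it] < (lp_cand - lp_current) - (lq[it] - lq_current):
                current, lp_current, lq_current = candidates[it], lp_cand, lq[it]
                if it >= settings.iterations - n_keep:
                    n_accept += 1
            if it >= settings.iterations - n_keep:
                draws[c, kept] = current
                kept += 1
    acceptance = n_accept / (settings.chains * n_keep)

    summaries = {}
    diagnostics = {}
    for j, name in enumerate(names):
        chain_draws = draws[:, :, j]
        rhat = float(az.rhat(chain_draws))
        ess = float(az.ess(chain_draws))
        diagnostics[name] = {"rhat": rhat, "ess": ess}
        summaries[name] = summarise_posterior(
            chain_draws.reshape(-1), name, ess=ess, rhat=rhat
        )
    if settings.check_convergence:
        for name in THETA_NAMES:
            d = diagnostics[name]
            if d["rhat"] > settings.rhat_max or d["ess"] < settings.min_ess:
                raise ConvergenceError(
                    f"MCMC convergence gate failed for {name}: "
                    f"rhat={d['rhat']:.4f} (max {settings.rhat_max}), "
                    f"ess={d['ess']:.0f} (min {settings.min_ess:.0f}), "
                    f"acceptance={acceptance:.2f}",
                    diagnostics=diagnostics,
                )

    return BayesFit(
        names=names,
        draws=draws,
        summaries=summaries,
        settings=settings,
        acceptance_rate=acceptance,
        mode=mode,
        n_excluded=n_excluded,
    )


def _posterior_neg_hessian(
    pl: EfronPartialLikelihood, spec: ModelSpec, beta: np.ndarray
) -> np.ndarray:
    H = -pl.hessian(beta)
    H[:2, :2] += np.linalg.inv(spec.prior.V)
    idx = np.arange(2, pl.p)
    H[idx, idx] += 1.0 / spec.vague_variance
    return H


def _nearest_pd_inverse(H: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    vals, vecs = np.linalg.eigh(H)
    vals = np.clip(vals, floor, None)
    return (vecs / vals) @ vecs.T


def summarise_posterior(
    samples: np.ndarray,
    parameter: str,
    ess: float | None = None,
    rhat: float | None = None,
) -> PosteriorSummary:
    """Median HR, central 95% credible interval and P(HR > 1) from draws on
    the log-HR scale. Requires at least 1000 retained draws."""
    samples = np.asarray(samples, dtype=float).reshape(-1)
    if samples.size < 1000:
        raise ValueError(
            f"need >= 1000 retained draws to summarise, got {samples.size}"
        )
    lo, med, hi = np.percentile(samples, [2.5, 50.0, 97.5])
    return PosteriorSummary(
        parameter=parameter,
        median_hr=float(np.exp(med)),
        ci_lower=float(np.exp(lo)),
        ci_upper=float(np.exp(hi)),
        p_hr_gt1=float(np.mean(samples > 0.0)),
        ess=ess,
        rhat=rhat,
    )


def shrinkage_report(
    prior: BivariatePrior, mle: MLEFit, bayes: BayesFit
) -> dict:
    """Compare posterior point estimates with the MLE and the prior mean.

    Per subgroup parameter: whether the posterior median lies between the MLE
    and the prior mean, whether it is pulled from the MLE toward the common
    mean effect (the average of the two subgroup MLEs), and the ratio of
    posterior to MLE interval widths on the log-HR scale.
    """
    if list(mle.names[:2]) != list(THETA_NAMES) or list(bayes.names[:2]) != list(
        THETA_NAMES
    ):
        raise ValueError("fits do not share the subgroup parameterisation")
    common_mean = float(np.mean(mle.beta[:2]))
    out = {"prior_label": prior.label, "common_mean_loghr": common_mean, "parameters": {}}
    for j, name in enumerate(THETA_NAMES):
        post = bayes.summaries[name]
        post_med = float(np.log(post.median_hr))
        mle_sum = mle.summary(name)
        mle_est = float(mle.beta[j])
        prior_mean = float(prior.m[j])
        lo_w = np.log(post.ci_upper) - np.log(post.ci_lower)
        mle_w = np.log(mle_sum.ci_upper) - np.log(mle_sum.ci_lower)
        between = min(mle_est, prior_mean) <= post_med <= max(mle_est, prior_mean)
        toward_common = abs(post_med - common_mean) <= abs(mle_est - common_mean)
        out["parameters"][name] = {
            "mle_loghr": mle_est,
            "prior_mean_loghr": prior_mean,
            "posterior_median_loghr": post_med,
            "between_mle_and_prior": bool(between),
            "pulled_toward_common_mean": bool(toward_common),
            "interval_width_ratio": float(lo_w / mle_w) if mle_w > 0 else np.inf,
        }
    return out


# ---------------------------------------------------------------------------
# Trial table CSV interface


def read_trial_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    df["subgroup"] = df["subgroup"].astype("Int64")
    return df


def write_trial_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="NA")
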