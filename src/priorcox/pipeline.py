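"""End-to-end orchestration: elicitation -> community of priors -> MLE +
per-prior Bayesian fits -> comparison report (JSON, text table, forest plot).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .cox import (
    ConvergenceError,
    MCMCSettings,
    ModelSpec,
    fit_bayes,
    fit_mle,
    read_trial_csv,
    shrinkage_report,
)
from .elicitation import read_answers_csv
from .priors import (
    COMMUNITY_LABELS,
    ReparamOperator,
    build_community,
    inputs_from_expert_answers,
    pooled_inputs_from_answers,
)
from .simulate import (
    ElicitationFixtureConfig,
    SimulationConfig,
    benefit_shift,
    generate_expert_answers,
    generate_trial,
)

__all__ = ["AnalysisConfig", "run_analysis", "render_report"]

logger = logging.getLogger("priorcox")


@dataclass
class AnalysisConfig:
    """Configuration for one subgroup-factor analysis.

    Exactly one data source must be given: CSV paths for the trial table and
    the elicitation answers, or simulation configs to generate both.
    """

    subgroup_factor: str = "renal_risk"
    trial_csv: str | None = None
    elicitation_csv: str | None = None
    simulation: SimulationConfig | None = None
    elicitation_fixture: ElicitationFixtureConfig | None = None
    priors: tuple = COMMUNITY_LABELS
    v22_mode: str = "conditional"
    mean_mode: str = "elicited"
    per_expert: bool = False
    L: float = 1e4
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        files = self.trial_csv is not None and self.elicitation_csv is not None
        sim = self.simulation is not None
        if files == sim:
            raise ValueError(
                "exactly one data source required: both CSV paths, or a "
                "simulation config"
            )
        if not self.priors:
            raise ValueError("community selection must not be empty")
        unknown = set(self.priors) - set(COMMUNITY_LABELS)
        if unknown:
            raise ValueError(f"unknown prior labels {sorted(unknown)}")


def _load_inputs(config: AnalysisConfig):
    if config.simulation is not None:
        trial = generate_trial(config.simulation)
        fixture = config.elicitation_fixture or ElicitationFixtureConfig(
            subgroup_factor=config.subgroup_factor
        )
        answers = generate_expert_answers(fixture)
        source = {"kind": "simulation", "seed": config.simulation.seed}
    else:
        trial = read_trial_csv(config.trial_csv)
        answers = read_answers_csv(config.elicitation_csv)
        source = {
            "kind": "files",
            "trial_csv": str(config.trial_csv),
            "elicitation_csv": str(config.elicitation_csv),
        }
    return trial, answers, source


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis for one subgroup factor and return the report
    bundle (plain dict, JSON-serialisable except for internal draw arrays,
    which are not included)."""
    trial, answers, source = _load_inputs(config)
    d = benefit_shift(config.subgroup_factor)
    logger.info("analysing factor %s (d=%.4f)", config.subgroup_factor, d)

    inputs = pooled_inputs_from_answers(answers, config.subgroup_factor, d)
    operator = ReparamOperator(L=config.L)
    community = build_community(
        inputs, operator, v22_mode=config.v22_mode, mean_mode=config.mean_mode
    )
    community = [p for p in community if p.label in config.priors]

    mle = fit_mle(trial, ModelSpec(prior=community[0]))
    mle_block = {
        "theta1": mle.summary("theta1").to_dict(),
        "theta2": mle.summary("theta2").to_dict(),
        "loglik": mle.loglik,
        "n_excluded_missing_subgroup": mle.n_excluded,
    }

    posteriors = {}
    shrinkage = {}
    errors = {}
    for prior in community:
        spec = ModelSpec(prior=prior, vague_variance=config.L)
        try:
            fit = fit_bayes(trial, spec, config.mcmc)
        except ConvergenceError as err:  # other priors still run
            logger.error("prior %s failed convergence: %s", prior.label, err)
            errors[prior.label] = {
                "error": str(err),
                "diagnostics": err.diagnostics,
            }
            continue
        posteriors[prior.label] = {
            "theta1": fit.summaries["theta1"].to_dict(),
            "theta2": fit.summaries["theta2"].to_dict(),
            "acceptance_rate": fit.acceptance_rate,
        }
        shrinkage[prior.label] = shrinkage_report(prior, mle, fit)

    prior_block = {
        p.label: {
            **p.to_dict(),
            "theta1": p.marginal(0).hr_summary(),
            "theta2": p.marginal(1).hr_summary(),
        }
        for p in community
    }

    per_expert_block = {}
    if config.per_expert:
        for expert_id in sorted({a.expert_id for a in answers}):
            try:
                ex_inputs = inputs_from_expert_answers(
                    answers, expert_id, config.subgroup_factor, d
                )
                ex_community = build_community(ex_inputs, operator)
                clin = ex_community[0]
                spec = ModelSpec(prior=clin, vague_variance=config.L)
                fit = fit_bayes(trial, spec, config.mcmc)
                per_expert_block[expert_id] = {
                    "prior": clin.to_dict(),
                    "theta1": fit.summaries["theta1"].to_dict(),
                    "theta2": fit.summaries["theta2"].to_dict(),
                }
            except (ValueError, ConvergenceError) as err:
                per_expert_block[expert_id] = {"error": str(err)}

    bundle = {
        "config": {
            "subgroup_factor": config.subgroup_factor,
            "priors": list(config.priors),
            "v22_mode": config.v22_mode,
            "mean_mode": config.mean_mode,
            "L": config.L,
            "seed": config.seed,
            "mcmc": asdict(config.mcmc),
            "d": d,
        },
        "source": source,
        "version": __version__,
        "n_patients": int(len(trial)),
        "n_experts": len({a.expert_id for a in answers}),
        "priors": prior_block,
        "mle": mle_block,
        "posteriors": posteriors,
        "shrinkage": shrinkage,
        "convergence_errors": errors,
    }
    if config.per_expert:
        bundle["per_expert"] = per_expert_block
    return bundle


# ---------------------------------------------------------------------------
# Rendering


def _require_complete(bundle: dict) -> None:
    required = ["config", "priors", "mle", "posteriors"]
    missing = [k for k in required if k not in bundle]
    if missing:
        raise ValueError(f"incomplete bundle, missing: {missing}")
    want = [
        label
        for label in bundle["config"]["priors"]
        if label not in bundle.get("convergence_errors", {})
    ]
    absent = [label for label in want if label not in bundle["posteriors"]]
    if absent:
        raise ValueError(f"incomplete bundle, missing posterior cells: {absent}")


def render_report(bundle: dict, outdir) -> dict[str, Path]:
    """Write report.json, report.txt, priors.json, forest.svg and per-prior
    posterior JSONs. JSON output is deterministic (sorted keys) for a given
    bundle."""
    _require_complete(bundle)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def dump(obj, path: Path) -> None:
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")

    paths["report.json"] = outdir / "report.json"
    dump(bundle, paths["report.json"])

    paths["priors.json"] = outdir / "priors.json"
    dump(bundle["priors"], paths["priors.json"])

    post_dir = outdir / "posteriors"
    post_dir.mkdir(exist_ok=True)
    for label, block in bundle["posteriors"].items():
        p = post_dir / f"{label}.json"
        dump(block, p)
        paths[f"posteriors/{label}.json"] = p

    paths["report.txt"] = outdir / "report.txt"
    paths["report.txt"].write_text(_text_table(bundle))

    paths["forest.svg"] = outdir / "forest.svg"
    _forest_plot(bundle, paths["forest.svg"])
    return paths


def _fmt_row(name: str, s: dict) -> str:
    return (
        f"{name:<28} {s['median_hr']:>8.3f} "
        f"[{s['ci_lower']:.3f}, {s['ci_upper']:.3f}]"
        + (f"  P(HR>1)={s['p_hr_gt1']:.3f}" if "p_hr_gt1" in s else "")
    )


def _text_table(bundle: dict) -> str:
    lines = [
        f"Subgroup factor: {bundle['config']['subgroup_factor']}",
        f"Patients: {bundle['n_patients']}  Experts: {bundle['n_experts']}",
        "",
        f"{'estimate':<28} {'HR':>8} 95% interval",
    ]
    for theta in ("theta1", "theta2"):
        lines.append(f"-- {theta} " + "-" * 50)
        for label, block in bundle["priors"].items():
            lines.append(_fmt_row(f"prior:{label}", block[theta]))
        lines.append(_fmt_row("MLE", bundle["mle"][theta]))
        for label, block in bundle["posteriors"].items():
            lines.append(_fmt_row(f"posterior:{label}", block[theta]))
    if bundle.get("convergence_errors"):
        lines.append("")
        for label, err in bundle["convergence_errors"].items():
            lines.append(f"FAILED {label}: {err['error']}")
    return "\n".join(lines) + "\n"


def _forest_plot(bundle: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = []
    for theta, pretty in (("theta1", "less severe"), ("theta2", "more severe")):
        for label, block in bundle["priors"].items():
            rows.append((f"{pretty}: prior {label}", block[theta], "tab:gray"))
        rows.append((f"{pretty}: MLE", bundle["mle"][theta], "tab:red"))
        for label, block in bundle["posteriors"].items():
            rows.append((f"{pretty}: posterior {label}", block[theta], "tab:blue"))

    fig, ax = plt.subplots(figsize=(7, 0.35 * len(rows) + 1.5))
    y = np.arange(len(rows))[::-1]
    for yi, (name, s, colour) in zip(y, rows):
        ax.plot(
            [s["ci_lower"], s["ci_upper"]], [yi, yi], color=colour, lw=1.5
        )
        ax.plot([s["median_hr"]], [yi], "o", color=colour, ms=4)
    ax.axvline(1.0, color="k", lw=0.8, ls=":")
    ax.set_yticks(y)
    ax.set_yticklabels([r[0] for r in rows], fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (log scale)")
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)
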