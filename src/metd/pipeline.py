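"""End-to-end pipeline: simulate -> ROPE -> ANCOVA -> compare -> meta -> report.

A :class:`RunConfig` (YAML or JSON on disk, or built in code) fully
determines a run; re-running with the same config and seed regenerates every
output byte-identically.  Outputs per run directory:

* ``elicitation.csv``, ``cohort.csv``, ``sessions.csv`` — generated inputs
  (omitted when real CSVs are supplied);
* ``rope_draws.csv`` — posterior draws defining the ROPE per outcome;
* ``draws_<outcome>.csv`` — ANCOVA EMM draws per group (long format);
* ``summary.json`` — EffectSummary records per group and outcome, plus the
  meta-analysis summary when requested;
* ``descriptives.csv`` — per group/lift/set-type training descriptives;
* ``densities_<outcome>.png`` — posterior vs ROPE density plot with AUC
  annotations;
* ``run.log`` — stages, seeds, resolved defaults and diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import RopeDistribution, summarize_effect
from .datagen import (CohortConfig, ConfigurationError, ElicitationConfig,
                      GroupConfig, InterventionDataset, generate_cohort,
                      generate_elicitation)
from .models import (ChangeScoreAncova, InterceptOnlyModel, McmcConfig,
                     NestedMetaModel, PriorSpec)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "descriptives"]

logger = logging.getLogger("metd")

OUTCOME_LABELS = ("SQ", "BP", "DL", "Total")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    outdir: str = "metd_run"
    seed: int = 0
    outcomes: tuple[str, ...] = ("Total",)
    # inputs: either CSV paths or generator configs
    elicitation_csv: str | None = None
    cohort_csv: str | None = None
    sessions_csv: str | None = None
    elicitation: ElicitationConfig | None = None
    cohort: CohortConfig | None = None
    rope_draws_csv: str | None = None  # external ROPE (e.g. "objective")
    reference_group: str | None = None
    intercept_prior: PriorSpec | None = None
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    run_meta: bool = True
    make_plots: bool = True

    def __post_init__(self) -> None:
        bad = set(self.outcomes) - set(OUTCOME_LABELS)
        if bad:
            raise ConfigurationError(f"unknown outcomes: {sorted(bad)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML (or JSON — YAML is a superset) run config."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "outcomes" in kwargs:
            kwargs["outcomes"] = tuple(kwargs["outcomes"])
        if isinstance(kwargs.get("elicitation"), dict):
            el = dict(kwargs["elicitation"])
            if "outcomes" in el:
                el["outcomes"] = {k: tuple(v) for k, v in el["outcomes"].items()}
            kwargs["elicitation"] = ElicitationConfig(**el)
        if isinstance(kwargs.get("cohort"), dict):
            co = dict(kwargs["cohort"])
            groups = []
            for g in co.get("groups", []):
                g = dict(g)
                if "pre" in g:
                    g["pre"] = {k: tuple(v) for k, v in g["pre"].items()}
                if "body_mass" in g:
                    g["body_mass"] = tuple(g["body_mass"])
                groups.append(GroupConfig(**g))
            co["groups"] = tuple(groups)
            kwargs["cohort"] = CohortConfig(**co)
        if isinstance(kwargs.get("intercept_prior"), dict):
            kwargs["intercept_prior"] = PriorSpec(**kwargs["intercept_prior"])
        if isinstance(kwargs.get("mcmc"), dict):
            kwargs["mcmc"] = McmcConfig(**kwargs["mcmc"])
        for path_key in ("elicitation_csv", "cohort_csv", "sessions_csv",
                         "rope_draws_csv"):
            p = kwargs.get(path_key)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{path_key} does not exist: {p}")
        return cls(**kwargs)


def descriptives(sessions: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of RPE, soreness and AMRAP reps per group/lift/set-type."""
    required = {"group", "lift", "set_type", "reps", "rpe",
                "soreness_next_day"}
    missing = required - set(sessions.columns)
    if missing:
        raise ConfigurationError(f"session log misses columns {sorted(missing)}")
    if sessions.empty:
        raise ConfigurationError("session log is empty")
    rows = []
    for (group, lift, set_type), sub in sessions.groupby(
            ["group", "lift", "set_type"], sort=True):
        row = {"group": group, "lift": lift, "set_type": set_type,
               "rpe_mean": sub["rpe"].mean(), "rpe_sd": sub["rpe"].std(ddof=1),
               "soreness_mean": sub["soreness_next_day"].mean(),
               "soreness_sd": sub["soreness_next_day"].std(ddof=1)}
        if set_type == "amrap":
            row["reps_mean"] = sub["reps"].mean()
            row["reps_sd"] = sub["reps"].std(ddof=1)
        else:
            row["reps_mean"] = np.nan
            row["reps_sd"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _plot_densities(effect_draws: dict[str, np.ndarray],
                    rope: RopeDistribution, aucs: dict[str, float],
                    outcome: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    fig, ax = plt.subplots(figsize=(7, 4))
    grid_min = min(d.min() for d in effect_draws.values())
    grid_max = max(d.max() for d in effect_draws.values())
    grid_min = min(grid_min, rope.draws.min())
    grid_max = max(grid_max, rope.draws.max())
    grid = np.linspace(grid_min, grid_max, 512)
    ax.fill_between(grid, stats.gaussian_kde(rope.draws, "silverman")(grid),
                    alpha=0.3, color="grey",
                    label=f"ROPE ({rope.source})")
    for label, draws in effect_draws.items():
        ax.plot(grid, stats.gaussian_kde(draws, "silverman")(grid),
                label=f"{label} (AUC {aucs[label]:.1%})")
    ax.set_xlabel(f"{outcome} change (kg)")
    ax.set_ylabel("posterior density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; return the report bundle as a dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("metd %s starting run; seed=%d outcomes=%s",
                __version__, config.seed, list(config.outcomes))
    logger.info("mcmc: %s", config.mcmc)

    stage = "simulate"
    try:
        # --- inputs ---------------------------------------------------
        if config.elicitation_csv:
            elicitation = pd.read_csv(config.elicitation_csv)
        else:
            el_cfg = config.elicitation or ElicitationConfig(
                moment_match=True, seed=config.seed)
            elicitation = generate_elicitation(el_cfg)
            elicitation.to_csv(outdir / "elicitation.csv", index=False)
            logger.info("simulate: elicitation n=%d (config %s)",
                        el_cfg.n_respondents, el_cfg)
        if config.cohort_csv:
            cohort = InterventionDataset.from_csv(config.cohort_csv,
                                                  config.sessions_csv)
        else:
            co_cfg = config.cohort or CohortConfig(
                study="study3",
                groups=(GroupConfig(label="MAX", protocol="MAX",
                                    true_change={"SQ": 4.0, "BP": 3.0,
                                                 "DL": 4.0},
                                    pre={"SQ": (182.5, 36.3),
                                         "BP": (126.5, 18.5),
                                         "DL": (215.0, 31.8)},
                                    body_mass=(85.8, 13.5)),
                        GroupConfig(label="MAX_BOFF")),
                seed=config.seed)
            cohort = generate_cohort(co_cfg)
            cohort.to_csv(outdir / "cohort.csv", outdir / "sessions.csv")
            logger.info("simulate: cohort %d participants",
                        len(cohort.participants))

        # --- ROPE ----------------------------------------------------
        stage = "rope"
        ropes: dict[str, RopeDistribution] = {}
        if config.rope_draws_csv:
            ext = RopeDistribution.from_file(config.rope_draws_csv)
            ropes = {o: ext for o in config.outcomes}
            logger.info("rope: external draws from %s (n=%d)",
                        config.rope_draws_csv, ext.draws.size)
        else:
            rope_frames = []
            for outcome in config.outcomes:
                model = InterceptOnlyModel.from_dataframe(elicitation, outcome)
                res = model.fit(config.mcmc)
                ropes[outcome] = res.rope()
                logger.info("rope[%s]: diagnostics %s", outcome,
                            res.diagnostics)
                rope_frames.append(pd.DataFrame({
                    "outcome": outcome, "draw": ropes[outcome].draws}))
            pd.concat(rope_frames, ignore_index=True).to_csv(
                outdir / "rope_draws.csv", index=False)

        # --- ANCOVA + compare ----------------------------------------
        report: dict = {"version": __version__, "seed": config.seed,
                        "effects": []}
        for outcome in config.outcomes:
            stage = "fit"
            model = ChangeScoreAncova(cohort, outcome,
                                      reference=config.reference_group,
                                      prior=config.intercept_prior)
            res = model.fit(config.mcmc)
            logger.info("fit[%s]: diagnostics %s", outcome, res.diagnostics)
            emm = res.emm_draws
            pd.concat([pd.DataFrame({"group": g, "draw": d})
                       for g, d in emm.items()],
                      ignore_index=True).to_csv(
                outdir / f"draws_{outcome}.csv", index=False)
            stage = "compare"
            aucs = {}
            for g, d in emm.items():
                summ = summarize_effect(d, ropes[outcome], group=g,
                                        outcome=outcome)
                # provenance: Total summaries come from Total change scores
                rec = summ.to_dict() | {"source": f"ancova:{outcome}"}
                report["effects"].append(rec)
                aucs[g] = summ.auc_vs_rope
            if config.make_plots:
                _plot_densities(emm, ropes[outcome], aucs, outcome,
                                outdir / f"densities_{outcome}.png")

        # --- meta ----------------------------------------------------
        if config.run_meta and cohort.scores["study"].nunique() >= 1:
            stage = "meta"
            metas = []
            for outcome in config.outcomes:
                meta_res = NestedMetaModel(cohort, outcome).fit(config.mcmc)
                summ = summarize_effect(meta_res.overall_draws,
                                        ropes[outcome], group="overall",
                                        outcome=outcome)
                metas.append(summ.to_dict() | {"source": f"meta:{outcome}"})
                logger.info("meta[%s]: diagnostics %s", outcome,
                            meta_res.diagnostics)
            report["meta"] = metas

        # --- descriptives + report -----------------------------------
        stage = "report"
        if len(cohort.sessions):
            desc = descriptives(cohort.sessions)
            desc.to_csv(outdir / "descriptives.csv", index=False)
            report["descriptives_rows"] = len(desc)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
        logger.info("report written to %s", outdir / "summary.json")
        return report
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
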