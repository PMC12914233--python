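"""End-to-end orchestration: generate -> clean -> analyse -> simulate.

`run_full_pipeline` executes the nine analysis stages in order, writes
every table as CSV plus a single JSON results bundle, and returns a
:class:`RunManifest` describing the run. A single master seed fans out to
per-stage seeds through fixed offsets, so any stage can be re-run
independently yet reproducibly; re-running the whole pipeline with the
same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import abm, mediation, regression, scenario, sensitivity, survey

__all__ = ["PipelineConfig", "RunManifest", "run_full_pipeline"]

log = logging.getLogger("trustdelay")

# fixed per-stage seed offsets from the master seed
SEED_OFFSETS = {
    "generate": 0,
    "mediate": 101,
    "abm": 202,
    "sensitivity": 303,
}

STAGES = ["generate", "clean", "regression", "mediation", "moderation",
          "scenarios", "abm", "comparison", "sensitivity"]


@dataclass
class PipelineConfig:
    """Top-level run configuration (YAML/JSON serialisable)."""

    output_dir: str = "results"
    master_seed: int = 1
    n_respondents: int = 2460
    n_boot: int = 500
    trials: int = 100
    days: int = 14
    sensitivity_trials: int = 25
    deepseek_cutoff: str = "2025-02-01"
    generator: dict = field(default_factory=dict)
    abm: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def generator_config(self) -> survey.GeneratorConfig:
        kw = dict(self.generator)
        kw.setdefault("n_respondents", self.n_respondents)
        kw.setdefault("seed", self.master_seed + SEED_OFFSETS["generate"])
        return survey.GeneratorConfig.from_dict(kw)

    def abm_config(self, **overrides) -> abm.ABMConfig:
        kw = dict(self.abm)
        kw.setdefault("trials", self.trials)
        kw.setdefault("days", self.days)
        kw.setdefault("n_agents", self.n_respondents)
        kw.setdefault("base_seed", self.master_seed + SEED_OFFSETS["abm"])
        kw.update(overrides)
        return abm.ABMConfig(**kw)


@dataclass
class RunManifest:
    """Record of a pipeline run: config, seeds, outputs, stage status."""

    config: dict
    seed_registry: dict
    outputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest,
               key: str) -> None:
    df.to_csv(path, index=False)
    manifest.outputs[key] = str(path)


def run_full_pipeline(config: PipelineConfig | str | Path) -> RunManifest:
    """Run every stage and write tables, a JSON bundle and a summary.

    Any stage failure aborts with the failing stage recorded in the
    partial manifest (re-raised as ``RuntimeError``).
    """
    cfg = (config if isinstance(config, PipelineConfig)
           else PipelineConfig.from_file(config))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {name: cfg.master_seed + off for name, off in SEED_OFFSETS.items()}
    manifest = RunManifest(config=cfg.to_dict(), seed_registry=seeds)
    bundle: dict = {"seeds": seeds}
    logging.basicConfig(
        level=logging.INFO, format="%(asctime)s %(name)s: %(message)s",
        filename=str(out / "pipeline.log"), filemode="w")

    stage = "setup"
    try:
        # 1. generate -----------------------------------------------------
        stage = "generate"
        gen_cfg = cfg.generator_config()
        raw = survey.generate_raw_population(gen_cfg)
        _write_csv(raw, out / "survey_raw.csv", manifest, "survey_raw")
        log.info("generate: %d raw submissions (seed %d)",
                 len(raw), gen_cfg.seed)
        manifest.stages[stage] = "ok"

        # 2. clean --------------------------------------------------------
        stage = "clean"
        records, report = survey.apply_exclusions(raw)
        _write_csv(records, out / "survey_clean.csv", manifest,
                   "survey_clean")
        bundle["exclusions"] = report.to_dict()
        log.info("clean: retained %d of %d", report.n_retained,
                 report.n_input)
        manifest.stages[stage] = "ok"

        # 3. regression ---------------------------------------------------
        stage = "regression"
        uni = regression.univariate_screen(
            records, ["trust", "frequency", "chronic", "age", "sex",
                      "exposure", "willingness"])
        _write_csv(uni, out / "univariate.csv", manifest, "univariate")
        hier = regression.hierarchical_models(records)
        hier_rows = [dict(model=m, **fit.term(p))
                     for m, fit in hier.items() for p in fit.param_names]
        _write_csv(pd.DataFrame(hier_rows), out / "hierarchical.csv",
                   manifest, "hierarchical")
        strata = regression.stratified_analysis(
            records,
            regression.date_stratifier(date.fromisoformat(
                cfg.deepseek_cutoff)),
            "delay", ["trust", "frequency", "chronic", "age", "sex"])
        bundle["regression"] = {
            "univariate": uni.to_dict("records"),
            "hierarchical": {m: f.to_dict() for m, f in hier.items()},
            "period_stratified": {k: f.to_dict() for k, f in strata.items()},
        }
        manifest.stages[stage] = "ok"

        # 4. mediation ----------------------------------------------------
        stage = "mediation"
        med = mediation.bootstrap_indirect(records, n_boot=cfg.n_boot,
                                           seed=seeds["mediate"])
        bundle["mediation"] = med.to_dict()
        _write_csv(pd.DataFrame([bundle["mediation"]]),
                   out / "mediation.csv", manifest, "mediation")
        manifest.stages[stage] = "ok"

        # 5. moderation ---------------------------------------------------
        stage = "moderation"
        moderation = {}
        for name, rule in [("exposure", lambda s: s > 2),
                           ("willingness", lambda s: s >= 3)]:
            strat = regression.stratified_analysis(
                records, regression.threshold_stratifier(
                    name, 2, ("low", "high")),
                "delay", ["trust", "frequency", "chronic", "age", "sex"])
            inter = regression.interaction_model(
                records, "trust", name,
                ["frequency", "chronic", "age", "sex"],
                moderator_rule=rule)
            moderation[name] = {
                "stratified": {k: f.to_dict() for k, f in strat.items()},
                "interaction": inter.to_dict(),
            }
        bundle["moderation"] = moderation
        manifest.stages[stage] = "ok"

        # 6. scenarios ----------------------------------------------------
        stage = "scenarios"
        table6 = regression.fit_logistic(records, "delay",
                                         ["trust", "frequency", "chronic"])
        scen = scenario.simulate_scenarios(table6, records)
        _write_csv(scen, out / "scenarios.csv", manifest, "scenarios")
        bundle["scenarios"] = {"model": table6.to_dict(),
                               "table": scen.to_dict("records")}
        manifest.stages[stage] = "ok"

        # 7. abm ----------------------------------------------------------
        stage = "abm"
        delay_model = abm.published_delay_model(records)
        arms: dict[str, abm.TrajectorySummary] = {}
        for strat_name in abm.STRATEGIES:
            # one agent per retained respondent
            acfg = cfg.abm_config(strategy=strat_name,
                                  n_agents=len(records))
            arms[strat_name] = abm.run_experiment(records, delay_model, acfg)
            _write_csv(arms[strat_name].to_frame(),
                       out / f"trajectory_{strat_name}.csv", manifest,
                       f"trajectory_{strat_name}")
            log.info("abm: %s arm done (%d trials x %d days)", strat_name,
                     acfg.trials, acfg.days)
        bundle["abm"] = {s: t.to_dict() for s, t in arms.items()}
        manifest.stages[stage] = "ok"

        # 8. comparison ---------------------------------------------------
        stage = "comparison"
        comparison = abm.compare_strategies(arms)
        _write_csv(comparison, out / "strategy_comparison.csv", manifest,
                   "strategy_comparison")
        bundle["strategy_comparison"] = comparison.to_dict("records")
        manifest.stages[stage] = "ok"

        # 9. sensitivity --------------------------------------------------
        stage = "sensitivity"
        sens_rows = []
        for param, values in sensitivity.DEFAULT_SWEEP_VALUES.items():
            base = cfg.abm_config(trials=cfg.sensitivity_trials,
                                  n_agents=len(records),
                                  base_seed=seeds["sensitivity"])
            spec = sensitivity.SweepSpec(param, values, base)
            _, table = sensitivity.sweep(spec, records, delay_model)
            sens_rows.append(table)
        sens = pd.concat(sens_rows, ignore_index=True)
        _write_csv(sens, out / "sensitivity.csv", manifest, "sensitivity")
        bundle["sensitivity"] = sens.to_dict("records")
        manifest.stages[stage] = "ok"
    except Exception as exc:
        manifest.stages[stage] = f"failed: {exc}"
        _finalize(out, manifest, bundle)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _finalize(out, manifest, bundle)
    return manifest


def _finalize(out: Path, manifest: RunManifest, bundle: dict) -> None:
    bundle_path = out / "results.json"
    with open(bundle_path, "w") as fh:
        json.dump(bundle, fh, indent=1, default=str)
    manifest.outputs["results_json"] = str(bundle_path)
    _write_summary(out, bundle, manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, default=str)


def _write_summary(out: Path, bundle: dict, manifest: RunManifest) -> None:
    """Human-readable headline numbers, read back from the JSON bundle."""
    lines = ["trustdelay pipeline summary", "=" * 30]
    if "exclusions" in bundle:
        e = bundle["exclusions"]
        lines.append(f"records: {e['n_retained']} retained of "
                     f"{e['n_input']} ({e['n_excluded']} excluded)")
    if "mediation" in bundle:
        m = bundle["mediation"]
        lines.append(
            f"mediation: a={m['a']:.4f} b={m['b']:.4f} "
            f"indirect={m['indirect']:.4f} "
            f"(OR {m['indirect_or']:.3f}) sobel_p={m['sobel_p']:.2e} "
            f"boot_p={m.get('boot_p')}")
    if "abm" in bundle:
        t = bundle["abm"]["baseline"]["trajectory"]
        lines.append(
            f"ABM baseline: day-1 delay {100 * t[0]['delay_rate']:.2f}%, "
            f"day-{len(t)} delay {100 * t[-1]['delay_rate']:.2f}%, "
            f"day-{len(t)} mean trust {t[-1]['mean_trust']:.3f}")
    if "strategy_comparison" in bundle:
        for row in bundle["strategy_comparison"]:
            lines.append(f"strategy {row['strategy']}: OR {row['or']:.3f} "
                         f"({row['ci_low']:.3f}-{row['ci_high']:.3f})")
    path = out / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    manifest.outputs["summary"] = str(path)
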