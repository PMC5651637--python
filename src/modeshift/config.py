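"""End-to-end pipeline orchestration from a single YAML config.

Sequences the stages — synthetic data, T-MVPA integration, mode
likelihoods, scenario simulations, summary tables — under one master
seed that spawns a named substream per stage, and writes every
artifact plus a manifest (config hash, seeds, per-file checksums) so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import integrate, likelihood, report, simulate, synth
from .scenario import Scenario, build_shift_plan


class ConfigError(ValueError):
    pass


#: stage labels -> substream index under the master seed
_STREAMS = {"generator": 1, "tmvpa_forest": 2, "mode_forest": 3,
            "duration_forest": 4, "scenarios": 5}


def _substream_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([master_seed, _STREAMS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    generator: synth.GeneratorConfig = field(
        default_factory=synth.GeneratorConfig)
    tmvpa_forest: dict = field(default_factory=dict)
    mode_forest: dict = field(default_factory=dict)
    duration_forest: dict = field(default_factory=dict)
    scenarios: list[Scenario] = field(
        default_factory=lambda: [Scenario(name="mobility_plan_x1"),
                                 Scenario(name="mobility_plan_x2",
                                          multiplier=2),
                                 Scenario(name="mobility_plan_x3",
                                          multiplier=3)])
    complementary_increases: dict[str, float] = field(default_factory=dict)
    n_repetitions: int = 100
    seed: int = 0
    min_oob_trees: int = 30

    REQUIRED = ("n_persons_survey", "n_persons_donor")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        gen_raw = data.pop("generator", None)
        if gen_raw is None:
            raise ConfigError("missing required section: 'generator'")
        for key in cls.REQUIRED:
            if key not in gen_raw:
                raise ConfigError(f"generator config missing field: {key!r}")
        if "mvpa" in gen_raw:
            gen_raw["mvpa"] = synth.MvpaMechanism(**gen_raw["mvpa"])
        if "education_probs" in gen_raw:
            gen_raw["education_probs"] = tuple(gen_raw["education_probs"])
        gen = synth.GeneratorConfig(**gen_raw)
        scen_raw = data.pop("scenarios", None)
        kwargs = dict(data)
        if scen_raw is not None:
            kwargs["scenarios"] = [Scenario(**s) for s in scen_raw]
        if "seed" not in kwargs:
            raise ConfigError("missing required field: 'seed'")
        cfg = cls(generator=gen, **kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        self.generator.validate()
        for sc in self.scenarios:
            sc.validate()
        if self.n_repetitions < 1:
            raise ConfigError("n_repetitions must be >= 1")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = [dataclasses.asdict(s) for s in self.scenarios]
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write all artifacts plus a manifest.

    Returns the manifest dict.  Scenario feasibility is checked against
    the generated mode counts before any simulation runs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gen_cfg = dataclasses.replace(
        config.generator, seed=_substream_seed(config.seed, "generator"))
    data_paths = synth.write_datasets(gen_cfg, outdir / "data")
    survey = pd.read_csv(data_paths["survey"])
    survey_persons = pd.read_csv(data_paths["survey_persons"])
    donor = pd.read_csv(data_paths["donor"])

    # feasibility of every scenario, before any model fit
    counts = survey["mode"].value_counts().to_dict()
    for sc in config.scenarios:
        build_shift_plan(counts, sc)

    tmodel = integrate.fit_tmvpa_model(
        donor, random_state=_substream_seed(config.seed, "tmvpa_forest"),
        **config.tmvpa_forest)
    survey = survey.copy()
    survey["tmvpa_min"] = integrate.predict_tmvpa(tmodel, survey)
    survey.to_csv(outdir / "survey_integrated.csv", index=False)
    joblib.dump(tmodel, outdir / "tmvpa_model.joblib")

    mmodel = likelihood.fit_mode_model(
        survey, random_state=_substream_seed(config.seed, "mode_forest"),
        **config.mode_forest)
    lk = likelihood.extract_oob_likelihoods(
        mmodel, survey, min_oob_trees=config.min_oob_trees)
    lk.to_csv(outdir / "likelihoods.csv", index=False)

    dmodel = simulate.fit_duration_model(
        survey, random_state=_substream_seed(config.seed, "duration_forest"),
        **config.duration_forest)

    baseline_decomp = simulate._person_decomp(
        survey, person_ids=survey_persons["person_id"])
    baseline = report.summarize_baseline(baseline_decomp, survey_persons)
    baseline.to_csv(outdir / "table_baseline.csv")

    metrics: dict = {
        "tmvpa_oob_r2": tmodel.oob_r2,
        "mode_oob_accuracy": mmodel.oob_accuracy,
        "duration_oob_r2": dmodel.oob_r2,
        "baseline_mean_tmvpa": float(
            baseline.mean.loc["total", "all_modes"]),
        "scenarios": {},
    }
    scen_seed_root = _substream_seed(config.seed, "scenarios")
    for k, sc in enumerate(config.scenarios):
        sc_run = dataclasses.replace(
            sc, n_repetitions=config.n_repetitions,
            seed=int(np.random.SeedSequence(
                [scen_seed_root, k]).generate_state(1)[0] % (2**31)))
        run = simulate.run_scenario(
            survey, lk, dmodel, tmodel, sc_run,
            person_ids=survey_persons["person_id"])
        gains = report.summarize_gains(run, survey_persons)
        gains.to_csv(outdir / f"table_gains_{sc.name}.csv")
        ineq = report.inequality_delta(baseline, gains)
        metrics["scenarios"][sc.name] = {
            "plan": run.plan.as_dict(),
            "mean_gain": float(gains.mean.loc["total", "all_modes"]),
            "inequality": ineq.as_dict(),
        }

    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))

    cfg_json = json.dumps(config.as_dict(), sort_keys=True, default=list)
    files = sorted(p for p in outdir.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": config.seed,
        "stage_seeds": {s: _substream_seed(config.seed, s)
                        for s in _STREAMS},
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
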