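"""End-to-end orchestration: generate -> preprocess -> split -> train ->
evaluate -> explain -> baselines -> decision report, from one config.

A single global seed deterministically derives every stage seed, so a rerun
with the same config reproduces every artifact.  The demo-scale defaults run
in minutes on one CPU; the full-scale constants live in the stage configs
themselves and can be restored from the config file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from eegmark import synthetic
from eegmark.baselines import feature_matrix, loo_benchmark
from eegmark.cnn import (DIAGNOSIS_CLASS_WEIGHTS, RESPONSE_CLASS_WEIGHTS,
                         ModelSpec, TrainConfig)
from eegmark.decision import DecisionScenario, allocation_from_matrix, scenario_table
from eegmark.evaluation import (make_split, task_labeller, train_and_score,
                                _segment_counts)
from eegmark.gradcam import (GradCamConfig, binarize_and_extract,
                             channel_importance, relevance_for_segments,
                             spectra_of_spans)
from eegmark.preprocess import (PreprocessConfig, normalize_amplitude,
                                segments_from_cohort)

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclasses.dataclass
class RunConfig:
    """Demo-scale default run configuration."""

    sites: list = dataclasses.field(
        default_factory=lambda: [synthetic.SiteProfile(
            "demo", 250.0, 120.0, 32, 34, 0.5, 8)])
    effect: synthetic.EffectSpec = dataclasses.field(
        default_factory=lambda: synthetic.EffectSpec(
            diag_amp_ratio=2.0, resp_amp_ratio=2.0))
    preprocess: PreprocessConfig = dataclasses.field(
        default_factory=PreprocessConfig)
    model: ModelSpec = dataclasses.field(
        default_factory=lambda: ModelSpec(filters=16, dense_units=32))
    train: TrainConfig = dataclasses.field(
        default_factory=lambda: TrainConfig(
            learning_rate=1e-3, max_epochs=8, early_stop_patience=7))
    gradcam: GradCamConfig = dataclasses.field(default_factory=GradCamConfig)
    tasks: tuple[str, ...] = ("diagnosis", "response")
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file of stage-keyed overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "sites" in raw:
        cfg.sites = [synthetic.SiteProfile(**s) for s in raw["sites"]]
    if "effect" in raw:
        eff = dict(raw["effect"])
        for key in ("diag_channels", "resp_channels"):
            if key in eff:
                eff[key] = tuple(eff[key])
        cfg.effect = synthetic.EffectSpec(**eff)
    if "preprocess" in raw:
        cfg.preprocess = PreprocessConfig(**raw["preprocess"])
    if "model" in raw:
        spec = dict(raw["model"])
        for key in ("kernel_schedule", "dropout_schedule"):
            if key in spec:
                spec[key] = tuple(map(tuple, spec[key])) if key == \
                    "kernel_schedule" else tuple(spec[key])
        cfg.model = ModelSpec(**spec)
    if "train" in raw:
        tr = dict(raw["train"])
        if "class_weights" in tr:
            tr["class_weights"] = tuple(tr["class_weights"])
        cfg.train = TrainConfig(**tr)
    if "gradcam" in raw:
        cfg.gradcam = GradCamConfig(**raw["gradcam"])
    if "tasks" in raw:
        cfg.tasks = tuple(raw["tasks"])
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    return cfg


def _stage_seed(base: int, *path: int) -> int:
    return int(np.random.SeedSequence([base, *path]).generate_state(1)[0]
               % (2**31))


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage for each task; returns and writes the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": []}

    def done(stage: str, task: str, **info) -> None:
        manifest["stages"].append({"stage": stage, "task": task, **info})

    cohort = synthetic.generate_cohort(cfg.sites, cfg.effect,
                                       _stage_seed(cfg.seed, 0))
    synthetic.write_cohort_metadata(cohort, out / "cohort.csv")
    done("generate", "both", n_subjects=len(cohort))

    for ti, task in enumerate(cfg.tasks):
        seed = _stage_seed(cfg.seed, 1, ti)
        segs = segments_from_cohort(cohort, cfg.preprocess, task_labeller(task))
        done("preprocess", task, n_segments=len(segs))

        sids, labels, counts = _segment_counts(segs)
        class_weights = (DIAGNOSIS_CLASS_WEIGHTS if task == "diagnosis"
                         else RESPONSE_CLASS_WEIGHTS)
        plan = make_split(sids, labels, counts, task, seed)
        (out / f"split_{task}.json").write_text(json.dumps({
            "train": list(plan.train_subjects), "val": list(plan.val_subjects),
            "test": list(plan.test_subjects)}, indent=1))
        done("split", task, n_test=len(plan.test_subjects))

        tcfg = dataclasses.replace(cfg.train, seed=seed,
                                   class_weights=class_weights)
        res = train_and_score(segs, plan, cfg.model, tcfg)
        pd.DataFrame(res["model"].history).to_csv(
            out / f"history_{task}.csv", index=False)
        metrics_row = {k: res[k] for k in (
            "subject_accuracy", "segment_accuracy", "sensitivity",
            "specificity", "auc")}
        pd.DataFrame([metrics_row]).to_csv(out / f"metrics_{task}.csv",
                                           index=False)
        done("train+evaluate", task, **{k: round(v, 4)
                                        for k, v in metrics_row.items()})

        test_raw = segs.for_subjects(plan.test_subjects)
        test_norm, _ = normalize_amplitude(test_raw, res["model"].norm_stats)
        # aggregate topography targets the positive (patient/responder) class
        gc_cfg = dataclasses.replace(cfg.gradcam, target_class=1)
        maps = relevance_for_segments(res["model"], test_norm, gc_cfg)
        importance, ranking = channel_importance(maps)
        spans = [binarize_and_extract(m, cfg.gradcam) for m in maps]
        report = spectra_of_spans(spans, test_raw.data,
                                  cfg.preprocess.target_rate)
        pd.DataFrame({"channel": list(importance),
                      "importance": list(importance.values())}).to_csv(
            out / f"importance_{task}.csv", index=False)
        rows = [{"channel": c, "peak_frequency": report.peak_frequency[c]}
                for c in report.spectra]
        pd.DataFrame(rows).to_csv(out / f"peaks_{task}.csv", index=False)
        done("gradcam", task, top_channels=ranking[:4])

        X, y, _ = feature_matrix(segs, cfg.preprocess.target_rate)
        bench = loo_benchmark(X, y, seed=seed)
        pd.DataFrame(sorted(bench.items()),
                     columns=["algorithm", "accuracy"]).to_csv(
            out / f"baselines_{task}.csv", index=False)
        done("baselines", task, best=max(bench, key=bench.get))

        if task == "response":
            outcome = allocation_from_matrix(DecisionScenario(
                matrix=res["confusion"]))
            table = scenario_table(matrices=[res["confusion"]])
            table.to_csv(out / "decision_table.csv")
            done("decision", task,
                 nnt=None if outcome.nnt is None else float(outcome.nnt))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
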