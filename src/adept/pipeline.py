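"""End-to-end pipeline: simulate -> episodes -> split -> train -> evaluate
-> recommend -> emulate, with a manifest recording seeds and checksums.

Each stage reads and writes files under one artifact directory so stages
can be re-run individually (the CLI exposes them as subcommands).  All
randomness flows from the seeds recorded in the configuration, making a
full run reproducible artifact-for-artifact.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import PipelineConfig, config_to_dict, save_config
from .episode_builder import (
    build_labeled_episodes,
    feature_columns,
    split_train_test,
)
from .super_learner import DegenerateOutcomeError, delong_ci
from .synthetic_claims import (
    generate_cohort,
    generate_truth_model,
    write_cohort,
    read_cohort,
)
from .treatment_policy import (
    fit_registry,
    observed_proportions,
    predict_matrix,
    recommend,
    recommendation_proportions,
)
from .trial_emulation import run_emulation


class MissingInputError(FileNotFoundError):
    """A stage's input artifact is absent."""


def _need(stage: str, *paths: Path) -> None:
    for p in paths:
        if not p.exists():
            raise MissingInputError(f"stage '{stage}' requires missing input {p}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    truth = generate_truth_model(cfg.generator, cfg.generator.seed)
    tables = generate_cohort(truth, cfg.generator.n_patients, cfg.generator.seed)
    write_cohort(out / "data", *tables, truth=truth)


def stage_build_episodes(cfg: PipelineConfig, out: Path) -> None:
    data = out / "data"
    _need("build-episodes", data / "patients.csv", data / "prescriptions.csv", data / "encounters.csv")
    patients, rx, enc = read_cohort(data)
    episodes = build_labeled_episodes(
        patients, rx, enc,
        switch_gap_days=cfg.generator.switch_gap_days,
        covariate_names=cfg.generator.covariate_names,
    )
    episodes.to_csv(out / "episodes.csv", index=False, float_format="%.10g")


def stage_split(cfg: PipelineConfig, out: Path) -> None:
    _need("split", out / "episodes.csv")
    episodes = pd.read_csv(out / "episodes.csv")
    train, test = split_train_test(episodes["patient_id"], cfg.split_fraction, cfg.split_seed)
    _write_json(out / "split.json", {"train": list(train), "test": list(test),
                                     "fraction": cfg.split_fraction, "seed": cfg.split_seed})


def _load_episodes_split(out: Path, stage: str):
    _need(stage, out / "episodes.csv", out / "split.json")
    episodes = pd.read_csv(out / "episodes.csv")
    split = json.loads((out / "split.json").read_text())
    train = episodes[episodes["patient_id"].isin(set(split["train"]))]
    test = episodes[episodes["patient_id"].isin(set(split["test"]))]
    return episodes, train, test


def _fit_one(cfg: PipelineConfig, train: pd.DataFrame, scenario: str, library: str):
    return fit_registry(
        train, scenario, library,
        min_episodes=cfg.min_episodes, V=cfg.n_folds, alpha=cfg.alpha,
        seed=cfg.train_seed, covariate_names=cfg.generator.covariate_names,
    )


def stage_train(cfg: PipelineConfig, out: Path) -> None:
    _, train, _ = _load_episodes_split(out, "train")
    (out / "models").mkdir(exist_ok=True)
    for scenario in cfg.scenarios:
        registry = _fit_one(cfg, train, scenario, cfg.library)
        with open(out / "models" / f"{scenario}.pkl", "wb") as fh:
            pickle.dump(registry, fh)
        registry.save_manifest(out / f"registry_{scenario}.json")


def _load_registry(out: Path, scenario: str, stage: str):
    path = out / "models" / f"{scenario}.pkl"
    _need(stage, path)
    with open(path, "rb") as fh:
        return pickle.load(fh)


def stage_evaluate(cfg: PipelineConfig, out: Path) -> None:
    """Pooled test-set AUC per scenario: each episode is scored by the model
    of its observed regimen, predictions are pooled, and discrimination is
    summarized by AUC with a DeLong 95% CI; comparator single-algorithm
    pipelines run through the identical harness."""
    _, train, test = _load_episodes_split(out, "evaluate")
    feats = feature_columns(cfg.generator.covariate_names)
    metrics: dict = {}
    for scenario in cfg.scenarios:
        registry = _load_registry(out, scenario, "evaluate")
        entry = {}
        libraries = {"super_learner": registry}
        for comp in cfg.comparators:
            libraries[comp] = _fit_one(cfg, train, scenario, comp)
        for name, reg in libraries.items():
            sub = test[(test["scenario"] == scenario) & test["regimen_key"].isin(reg.keys)]
            if sub.empty:
                entry[name] = {"note": "no scored episodes"}
                continue
            scores = np.concatenate(
                [
                    reg.models[key].predict_proba(grp[feats])
                    for key, grp in sub.groupby("regimen_key")
                ]
            )
            y = np.concatenate(
                [grp["failure"].to_numpy(dtype=float) for _, grp in sub.groupby("regimen_key")]
            )
            try:
                auc, lo, hi = delong_ci(y, scores)
                entry[name] = {
                    "auc": round(auc, 4), "ci_lower": round(lo, 4), "ci_upper": round(hi, 4),
                    "n": int(len(y)), "n_pos": int(y.sum()),
                }
            except (DegenerateOutcomeError, ValueError) as exc:
                entry[name] = {"note": f"not evaluable: {exc}"}
        metrics[scenario] = entry
    _write_json(out / "metrics.json", metrics)


def stage_recommend(cfg: PipelineConfig, out: Path) -> None:
    _, _, test = _load_episodes_split(out, "recommend")
    for scenario in cfg.scenarios:
        registry = _load_registry(out, scenario, "recommend")
        sub = test[test["scenario"] == scenario]
        if sub.empty:
            continue
        matrix = predict_matrix(registry, sub)
        recs = recommend(matrix, scenario)
        recs_out = matrix.add_prefix("p_")
        recs_out = pd.concat([recs, recs_out], axis=1)
        recs_out.to_csv(out / f"recommendations_{scenario}.csv", float_format="%.10g")
        props = {
            "recommendation": recommendation_proportions(recs).round(10).to_dict(),
            "prescription": observed_proportions(sub).round(10).to_dict(),
        }
        _write_json(out / f"proportions_{scenario}.json", props)


def stage_emulate(cfg: PipelineConfig, out: Path) -> None:
    _, _, test = _load_episodes_split(out, "emulate")
    for scenario in cfg.scenarios:
        registry = _load_registry(out, scenario, "emulate")
        sub = test[test["scenario"] == scenario]
        if sub.empty:
            continue
        reports = run_emulation(
            sub, registry, seed=cfg.emulation_seed, modes=tuple(cfg.emulation_modes)
        )
        payload = {mode: rep.to_json_dict() for mode, rep in reports.items()}
        _write_json(out / f"emulation_{scenario}.json", payload)
        frames = []
        for mode, rep in reports.items():
            t = rep.table.copy()
            t.insert(0, "mode", mode)
            frames.append(t)
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"emulation_{scenario}.csv", index=False, float_format="%.10g"
        )


MANIFEST_GLOBS = ("*.csv", "*.json", "*.yaml", "data/*.csv", "data/*.json", "data/*.yaml")


def write_manifest(cfg: PipelineConfig, out: Path) -> dict:
    """Checksum every text artifact; identical configs give identical manifests."""
    checksums = {}
    for pattern in MANIFEST_GLOBS:
        for p in sorted(out.glob(pattern)):
            if p.name == "manifest.json":
                continue
            checksums[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "package_version": _pkg_version,
        "config": config_to_dict(cfg),
        "seeds": {
            "generator": cfg.generator.seed,
            "split": cfg.split_seed,
            "train": cfg.train_seed,
            "emulation": cfg.emulation_seed,
        },
        "artifacts": checksums,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


STAGES = {
    "simulate": stage_simulate,
    "build-episodes": stage_build_episodes,
    "split": stage_split,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "recommend": stage_recommend,
    "emulate": stage_emulate,
}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path, stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write the manifest.

    Returns the manifest dict.  Any stage error propagates after being
    annotated with the stage name.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    for name in stages or list(STAGES):
        if name not in STAGES:
            raise KeyError(f"unknown stage {name!r}")
        try:
            STAGES[name](cfg, out)
        except MissingInputError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    return write_manifest(cfg, out)


# ---------------------------------------------------------------------------
# Reporting


def report(out_dir: str | Path) -> str:
    """Human-readable summary of a pipeline artifact directory."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise MissingInputError(f"no manifest at {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt manifest: {exc}") from exc

    lines = [f"adept pipeline report  (package {manifest.get('package_version', '?')})", ""]
    metrics_path = out / "metrics.json"
    if metrics_path.exists():
        metrics = json.loads(metrics_path.read_text())
        lines.append("Discrimination (AUC, DeLong 95% CI) on the test set:")
        for scenario, entry in metrics.items():
            lines.append(f"  {scenario}:")
            for model, vals in entry.items():
                if "auc" in vals:
                    lines.append(
                        f"    {model:>14s}: AUC {vals['auc']:.3f} "
                        f"({vals['ci_lower']:.3f}, {vals['ci_upper']:.3f})  n={vals['n']}"
                    )
                else:
                    lines.append(f"    {model:>14s}: {vals.get('note', 'n/a')}")
        lines.append("")
    for scenario in ("initial", "next_step"):
        path = out / f"emulation_{scenario}.json"
        if not path.exists():
            continue
        payload = json.loads(path.read_text())
        lines.append(f"Emulated target trial - {scenario} episodes:")
        for mode, rep in payload.items():
            lines.append(f"  {mode}:")
            for row in rep["arms"]:
                hr = (
                    f"HR {row['hazard_ratio']:.3f} ({row['ci_lower']:.3f}, {row['ci_upper']:.3f})"
                    if row["hazard_ratio"] is not None and not (
                        isinstance(row["hazard_ratio"], float) and np.isnan(row["hazard_ratio"])
                    )
                    else "reference"
                )
                lines.append(
                    f"    {row['arm']:>22s}: {row['events']}/{row['person_years']:.0f} py, "
                    f"incidence {row['incidence']:.3f}  {hr}"
                )
        lines.append("")
    return "\n".join(lines)
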