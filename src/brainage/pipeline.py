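"""End-to-end orchestration: simulate → split → train → correct → compare.

``run_pipeline`` executes the full analysis for a configuration and leaves
a self-describing artifact set in the output directory:

* ``participants.csv`` / ``features_<modality>.csv`` — the input cohort
  (written even when simulated, so downstream stages are re-runnable),
* ``training_ids.txt`` / ``holdout_ids.txt`` — the control split,
* ``model_<modality>.json`` — trained GP models with frozen bias correction,
* ``cv_<modality>.json`` — repeated-CV MAE/r distributions and summaries,
* ``bags_<modality>.csv`` — raw/corrected brain age and BAG per subject,
* ``metrics.json`` — corrected MAE/r per modality and dataset,
* ``windows.json`` — duration windows with matched control samples,
* ``ancova_results.csv`` / ``correlations.csv`` / ``cohort_stats.csv``,
* ``bag_trajectories.png`` / ``effect_sizes.png`` (optional),
* ``manifest.json`` — SHA-256 of every artifact.

Every random stage derives its seed from the run seed, so a rerun with the
same configuration reproduces the manifest hashes exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .bias import fit_bias, make_bag_records
from .cohort import (MODALITIES, FeatureTable, ParticipantRecord,
                     SimulationConfig, generate_cohort)
from .model import (GPRSpec, TrainedBrainAgeModel, evaluate, fit_gpr,
                    kfold_oof, repeated_cv, split_controls)
from .stats import (ancova_bag, bag_clinical_correlations, bonferroni_alpha,
                    cohort_stats)
from .windows import WindowSpec, build_windows, match_controls

__all__ = ["PipelineError", "RunConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``simulate`` is set (synthetic cohort) or ``participants_path``
    plus ``features_paths`` point at existing tables.
    """

    outdir: str | Path = "brainage_run"
    seed: int = 0
    modalities: tuple[str, ...] = MODALITIES
    simulate: SimulationConfig | None = None
    participants_path: str | Path | None = None
    features_paths: Mapping[str, str] | None = None
    split_ratio: float = 0.7
    gpr: GPRSpec = field(default_factory=GPRSpec)
    cv_folds: int = 5
    cv_repeats: int = 10
    window: WindowSpec = field(default_factory=WindowSpec)
    matching_mode: str = "greedy"
    family_alpha: float = 0.05
    bonferroni_m: int = 5
    min_group_n: int = 3
    make_plots: bool = True
    run_cv: bool = True

    def __post_init__(self) -> None:
        unknown = [m for m in self.modalities if m not in MODALITIES]
        if unknown:
            raise ValueError(f"unknown modalities: {unknown}")
        if self.simulate is None and (
            self.participants_path is None or self.features_paths is None
        ):
            raise ValueError("either simulate or participants/features paths required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in payload and payload["simulate"] is not None:
            sim = dict(payload["simulate"])
            for key in ("control_age_range", "patient_age_range", "duration_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            payload["simulate"] = SimulationConfig(**sim)
        if "gpr" in payload:
            payload["gpr"] = GPRSpec(**payload["gpr"])
        if "window" in payload:
            payload["window"] = WindowSpec(**payload["window"])
        if "modalities" in payload:
            payload["modalities"] = tuple(payload["modalities"])
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def _window_payload(win) -> dict:
    return {
        "label": win.label,
        "duration_lo": win.duration_lo,
        "duration_hi": win.duration_hi,
        "is_tail": win.is_tail,
        "patient_ids": list(win.patient_ids),
        "matched_control_ids": list(win.matched_control_ids),
        "seed_used": win.seed_used,
        "mean_age_diff": win.mean_age_diff,
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages; returns artifact name → path. See module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # -- load or simulate -------------------------------------------------
    if config.simulate is not None:
        records, tables = _stage("simulate", generate_cohort, config.simulate)
        tables = {m: tables[m] for m in config.modalities if m in tables}
    else:
        records = _stage("read_participants", bio.read_participants,
                         config.participants_path)
        tables = {
            m: _stage("read_features", bio.read_feature_table,
                      config.features_paths[m], m)
            for m in config.modalities
        }
    artifacts.update(_stage("write_cohort", bio.write_cohort, records, tables, outdir))

    controls = [r for r in records if not r.is_patient]
    patients = [r for r in records if r.is_patient]
    by_id = {r.participant_id: r for r in records}
    ages = {r.participant_id: r.age for r in records}

    # -- split -------------------------------------------------------------
    train_ids, holdout_ids = _stage("split", split_controls, controls,
                                    config.split_ratio, config.seed)
    bio.write_ids(train_ids, outdir / "training_ids.txt")
    bio.write_ids(holdout_ids, outdir / "holdout_ids.txt")
    artifacts["training_ids"] = outdir / "training_ids.txt"
    artifacts["holdout_ids"] = outdir / "holdout_ids.txt"
    patient_ids = [r.participant_id for r in patients]

    # -- per-modality train / correct / predict ---------------------------
    metrics: dict[str, dict] = {}
    bags_by_modality: dict[str, dict[str, float]] = {}
    for mi, modality in enumerate(config.modalities):
        table = tables[modality]
        train_tab = table.restrict(train_ids)

        oof = _stage(f"cv_oof_{modality}", kfold_oof, train_tab, ages,
                     config.gpr, config.cv_folds, [config.seed, mi, 11])
        bc = _stage(f"bias_{modality}", fit_bias, oof,
                    {i: ages[i] for i in train_ids}, "training_oof")

        if config.run_cv:
            report = _stage(f"cv_{modality}", repeated_cv, train_tab, ages,
                            config.gpr, config.cv_folds, config.cv_repeats,
                            config.seed)
            cv_path = outdir / f"cv_{modality}.json"
            cv_path.write_text(json.dumps({
                "n_folds": report.n_folds, "n_repeats": report.n_repeats,
                "maes": report.maes, "rs": report.rs,
                "summary": report.summary(),
            }, indent=2))
            artifacts[f"cv_{modality}"] = cv_path

        model = _stage(f"train_{modality}", fit_gpr, train_tab, ages, config.gpr)
        model.bias_correction = bc
        model_path = outdir / f"model_{modality}.json"
        model.save(model_path)
        artifacts[f"model_{modality}"] = model_path

        rows = []
        mod_metrics = {}
        for dataset, ids in (("training", train_ids), ("holdout", holdout_ids),
                             ("patient", patient_ids)):
            raw = (oof if dataset == "training"
                   else model.predict(table.restrict(ids)))
            recs = make_bag_records(raw, ages, bc, modality)
            for r in recs:
                rows.append({
                    "participant_id": r.participant_id,
                    "dataset": dataset,
                    "age": ages[r.participant_id],
                    "raw_brain_age": r.raw_brain_age,
                    "corrected_brain_age": r.corrected_brain_age,
                    "bag": r.bag,
                })
            corrected = {r.participant_id: r.corrected_brain_age for r in recs}
            mae, rho = evaluate(corrected, {i: ages[i] for i in ids})
            mod_metrics[dataset] = {
                "corrected_mae": mae, "corrected_r": rho, "n": len(ids),
                "mean_bag": float(np.mean([r.bag for r in recs])),
            }
        metrics[modality] = mod_metrics
        bags_df = pd.DataFrame(rows)
        bags_path = outdir / f"bags_{modality}.csv"
        bags_df.to_csv(bags_path, index=False)
        artifacts[f"bags_{modality}"] = bags_path
        bags_by_modality[modality] = {
            row["participant_id"]: row["bag"] for row in rows
            if row["dataset"] in ("holdout", "patient")
        }

    metrics_path = outdir / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=2))
    artifacts["metrics"] = metrics_path

    # -- windows and matching ---------------------------------------------
    windows = _stage("windows", build_windows, patients, config.window)
    holdout_records = [by_id[i] for i in holdout_ids]
    matched = []
    for wi, win in enumerate(windows):
        if win.is_empty:
            matched.append(win)
            continue
        matched.append(_stage(
            f"match_{win.label}", match_controls, win, by_id, holdout_records,
            [config.seed, 13, wi], config.matching_mode,
        ))
    windows_path = outdir / "windows.json"
    windows_path.write_text(json.dumps([_window_payload(w) for w in matched],
                                       indent=2))
    artifacts["windows"] = windows_path

    # -- ANCOVA per window per modality ------------------------------------
    adjusted = bonferroni_alpha(config.family_alpha, config.bonferroni_m)
    from .windows import remove_outliers_tukey

    result_rows = []
    summary_rows = []
    for modality in config.modalities:
        bags = bags_by_modality[modality]
        for win in matched:
            if win.is_empty:
                continue
            pat = [(pid, bags[pid]) for pid in win.patient_ids]
            values = np.array([v for _, v in pat])
            if values.size >= 4:
                kept, removed, fences = remove_outliers_tukey(values)
            else:  # screen not defined for tiny windows; keep everything
                removed, fences = np.array([]), None
            if fences is None:
                kept_ids = [pid for pid, _ in pat]
            else:
                kept_ids = [pid for pid, v in pat if fences[0] <= v <= fences[1]]
            ctrl_ids = list(win.matched_control_ids)
            summary_rows.append({
                "modality": modality, "window_label": win.label,
                "duration_lo": win.duration_lo,
                "mean_bag_patients": float(np.mean([bags[i] for i in kept_ids])),
                "sem_bag_patients": float(np.std([bags[i] for i in kept_ids], ddof=1)
                                          / np.sqrt(len(kept_ids)))
                if len(kept_ids) > 1 else np.nan,
                "mean_bag_controls": float(np.mean([bags[i] for i in ctrl_ids])),
                "sem_bag_controls": float(np.std([bags[i] for i in ctrl_ids], ddof=1)
                                          / np.sqrt(len(ctrl_ids)))
                if len(ctrl_ids) > 1 else np.nan,
            })
            row = {
                "modality": modality, "window_label": win.label,
                "n_patients": len(kept_ids), "n_outliers_removed": len(removed),
                "n_controls": len(ctrl_ids), "adjusted_alpha": adjusted,
                "analyzed": False, "F": np.nan, "p": np.nan,
                "partial_eta_sq": np.nan, "significant": False,
                "covariates_used": "",
            }
            if len(kept_ids) >= config.min_group_n and len(ctrl_ids) >= config.min_group_n:
                data = pd.DataFrame([
                    {
                        "bag": bags[pid],
                        "group": "patient" if pid in set(kept_ids) else "control",
                        "age": by_id[pid].age, "sex": by_id[pid].sex,
                        "mmse": by_id[pid].mmse, "education": by_id[pid].education,
                    }
                    for pid in kept_ids + ctrl_ids
                ])
                try:
                    res = ancova_bag(data, win.label, adjusted)
                except ValueError:
                    res = None  # design too small/degenerate: leave unanalyzed
                if res is not None:
                    row.update({
                        "analyzed": True, "F": res.group_F, "p": res.group_p,
                        "partial_eta_sq": res.partial_eta_sq,
                        "significant": res.significant,
                        "covariates_used": "+".join(res.covariates_used),
                    })
            result_rows.append(row)

    results_df = pd.DataFrame(result_rows)
    results_path = outdir / "ancova_results.csv"
    results_df.to_csv(results_path, index=False)
    artifacts["ancova_results"] = results_path
    summary_df = pd.DataFrame(summary_rows)
    summary_path = outdir / "window_summary.csv"
    summary_df.to_csv(summary_path, index=False)
    artifacts["window_summary"] = summary_path

    # -- clinical correlations & demographics ------------------------------
    clinical = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "panss_total": r.panss_total, "panss_pos": r.panss_pos,
                "panss_neg": r.panss_neg, "panss_gen": r.panss_gen,
                "cpz": r.cpz,
            }
            for r in patients
        ]
    ).set_index("participant_id")
    patient_bags = {
        m: {pid: bags_by_modality[m][pid] for pid in patient_ids}
        for m in config.modalities
    }
    corr = _stage("correlations", bag_clinical_correlations, patient_bags, clinical)
    corr_path = outdir / "correlations.csv"
    corr.to_csv(corr_path, index=False)
    artifacts["correlations"] = corr_path

    demo = _stage("cohort_stats", cohort_stats, records)
    demo_path = outdir / "cohort_stats.csv"
    demo.to_csv(demo_path, index=False)
    artifacts["cohort_stats"] = demo_path

    # -- plots --------------------------------------------------------------
    if config.make_plots and not summary_df.empty:
        from .plots import plot_bag_trajectories, plot_effect_sizes

        traj_path = outdir / "bag_trajectories.png"
        _stage("plot_trajectories", plot_bag_trajectories, summary_df, traj_path)
        artifacts["bag_trajectories"] = traj_path
        eff_path = outdir / "effect_sizes.png"
        _stage("plot_effect_sizes", plot_effect_sizes,
               results_df[results_df["analyzed"]], eff_path)
        artifacts["effect_sizes"] = eff_path

    # -- manifest -----------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "artifacts": {name: {"path": p.name, "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest_path
    return artifacts
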