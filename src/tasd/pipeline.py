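"""End-to-end orchestration: simulate -> preprocess -> adjust -> baselines ->
features -> stats / train / cv / ablation, with CSV/JSON artifacts per stage.

Every stage writes its artifact into the output directory and appends a
machine-parseable log line (stage, config hash, seed, row counts) to
``pipeline.log``. Re-running with the same config, seed and inputs is
idempotent.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline_norm import compute_baselines
from .classify_eval import cross_validate, holdout_evaluate, run_ablation
from .config import PipelineConfig
from .feature_extract import FEATURE_COLUMNS, build_feature_table, standardize_per_participant
from .preprocessing import preprocess_record
from .signal_model import SignalRecord, frame_to_record, record_to_frame
from .stats_separability import separability_report
from .synthetic_data import simulate_cohort
from .thermal_adjust import adjust_session

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "preprocess", "adjust", "baselines", "features"]
ANALYSIS_STAGES = ["stats", "train", "cv", "ablation"]


class DependencyError(RuntimeError):
    pass


def _log(out: Path, stage: str, cfg_hash: str, seed: int, **info) -> None:
    line = json.dumps({"stage": stage, "config": cfg_hash, "seed": seed, **info},
                      sort_keys=True)
    logger.info("%s", line)
    with open(out / "pipeline.log", "a") as fh:
        fh.write(line + "\n")


def _records_to_csv(records: list[SignalRecord], path: Path) -> None:
    pd.concat([record_to_frame(r) for r in records], ignore_index=True).to_csv(path, index=False)


def _records_from_csv(path: Path, fs: float) -> list[SignalRecord]:
    df = pd.read_csv(path)
    return [frame_to_record(g, fs)
            for _, g in df.groupby(["Participant_ID", "Session_ID"], sort=True)]


def _sample_table(records: list[SignalRecord]) -> pd.DataFrame:
    """Per-sample table (GSR = raw conductance) used for baseline levels."""
    frames = []
    for r in records:
        frames.append(pd.DataFrame({
            "Time": r.t, "GSR": r.eda, "Class": r.label,
            "Participant_ID": r.participant_id, "Session_ID": r.session_id,
        }))
    return pd.concat(frames, ignore_index=True)


def run_pipeline(cfg: PipelineConfig, out_dir, stages: list[str],
                 seed: int = 0, input_records: list[SignalRecord] | None = None) -> Path:
    """Run a prefix-closed chain of stages, writing artifacts under out_dir.

    ``stages`` must be contiguous in STAGE_ORDER (analysis stages may follow
    "features" in any combination). When "simulate" is omitted,
    ``input_records`` supplies the cohort.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash

    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config") != cfg_hash:
            raise RuntimeError("artifact directory was produced by a different config; aborting")

    core = [s for s in stages if s in STAGE_ORDER]
    analyses = [s for s in stages if s in ANALYSIS_STAGES]
    unknown = set(stages) - set(STAGE_ORDER) - set(ANALYSIS_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {', '.join(sorted(unknown))}")
    idx = sorted(STAGE_ORDER.index(s) for s in core)
    if idx and idx != list(range(idx[0], idx[-1] + 1)):
        missing = [STAGE_ORDER[i] for i in range(idx[0], idx[-1] + 1)
                   if i not in idx]
        raise DependencyError(f"stage chain not contiguous; missing {', '.join(missing)}")

    state: dict = {}
    if input_records is not None:
        state["records"] = input_records

    for stage in [STAGE_ORDER[i] for i in idx] + analyses:
        _run_stage(stage, state, cfg, out, seed, cfg_hash)

    manifest = {"config": cfg_hash, "seed": seed,
                "stages": [STAGE_ORDER[i] for i in idx] + analyses}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _require(state: dict, key: str, stage: str, out: Path, loader=None):
    if key in state:
        return state[key]
    if loader is not None:
        value = loader()
        if value is not None:
            state[key] = value
            return value
    raise DependencyError(f"stage {stage!r} requires missing upstream artifact {key!r}")


def _run_stage(stage: str, state: dict, cfg: PipelineConfig, out: Path,
               seed: int, cfg_hash: str) -> None:
    fs = float(cfg.simulation["fs"])

    if stage == "simulate":
        records, truths = simulate_cohort(cfg.synth_config(seed))
        state["records"] = records
        _records_to_csv(records, out / "signals.csv")
        truth_payload = [{"participant": t.participant_id, "lambda_true": t.lambda_true,
                          "tonic": t.tonic, "n_events": len(t.events)} for t in truths]
        (out / "truth.json").write_text(json.dumps(truth_payload, indent=2))
        _log(out, stage, cfg_hash, seed, n_subjects=len(records),
             n_samples=sum(r.n_samples for r in records))
        return

    if stage == "preprocess":
        def load():
            p = out / "signals.csv"
            return _records_from_csv(p, fs) if p.exists() else None
        records = _require(state, "records", stage, out, load)
        pre = [preprocess_record(r, cfg.preprocess_config()) for r in records]
        state["preprocessed"] = pre
        _records_to_csv(pre, out / "signals_preprocessed.csv")
        _log(out, stage, cfg_hash, seed, n_subjects=len(pre))
        return

    if stage == "adjust":
        def load():
            p = out / "signals_preprocessed.csv"
            return _records_from_csv(p, fs) if p.exists() else None
        pre = _require(state, "preprocessed", stage, out, load)
        params = cfg.adjustment_params()
        as_mode = cfg.adjustment["as_mode"]
        adjusted = [adjust_session(r, params, mode="tasd", as_mode=as_mode) for r in pre]
        state["adjusted"] = adjusted
        rows = []
        for adj in adjusted:
            df = record_to_frame(adj.base)
            df["EDA_PA"] = adj.eda_pa
            df["EDA_AS"] = adj.eda_as
            rows.append(df)
        pd.concat(rows, ignore_index=True).to_csv(out / "adjusted.csv", index=False)
        lam = {a.base.participant_id: a.params.lambda_prop for a in adjusted}
        (out / "adjustment_params.json").write_text(json.dumps(lam, indent=2, sort_keys=True))
        _log(out, stage, cfg_hash, seed, lambda_prop=lam)
        return

    if stage == "baselines":
        pre = _require(state, "preprocessed", stage, out)
        table = _sample_table(pre)
        baselines = compute_baselines(table, alpha_pre=cfg.baselines["alpha_pre"])
        state["baselines"] = baselines
        payload = {
            "global": baselines.baseline_global,
            "indiv": baselines.baseline_indiv,
            "pre": {f"{p}|{s}": v for (p, s), v in baselines.baseline_pre.items()},
            "alpha_pre": baselines.alpha_pre,
        }
        (out / "baselines.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        _log(out, stage, cfg_hash, seed, baseline_global=baselines.baseline_global)
        return

    if stage == "features":
        adjusted = _require(state, "adjusted", stage, out)
        baselines = _require(state, "baselines", stage, out)
        fcfg = cfg.feature_config()
        table = build_feature_table(adjusted, baselines, fcfg)
        table = standardize_per_participant(table)
        state["features"] = table
        table.to_csv(out / "features.csv", index=False)
        _log(out, stage, cfg_hash, seed, n_windows=len(table))
        return

    def load_features():
        p = out / "features.csv"
        return pd.read_csv(p) if p.exists() else None

    if stage == "stats":
        table = _require(state, "features", stage, out, load_features)
        report = separability_report(table, FEATURE_COLUMNS)
        report.to_csv(out / "stats_report.csv", index=False)
        _log(out, stage, cfg_hash, seed, n_features=len(FEATURE_COLUMNS))
        return

    if stage == "train":
        table = _require(state, "features", stage, out, load_features)
        spec = cfg.classifier_spec(seed)
        report = holdout_evaluate(table, spec,
                                  test_fraction=cfg.classifier["test_fraction"])
        _write_train_artifacts(report, out)
        _log(out, stage, cfg_hash, seed, accuracy=report["accuracy"], auc=report["auc"])
        return

    if stage == "cv":
        table = _require(state, "features", stage, out, load_features)
        spec = cfg.classifier_spec(seed)
        report = cross_validate(table, spec, k=int(cfg.classifier["k_folds"]))
        slim = {**report, "folds": [{k: v for k, v in f.items() if k != "roc"}
                                    for f in report["folds"]]}
        (out / "cv_report.json").write_text(json.dumps(slim, indent=2, sort_keys=True))
        _log(out, stage, cfg_hash, seed, mean_accuracy=report["mean_accuracy"],
             mean_auc=report["mean_auc"])
        return

    if stage == "ablation":
        adjusted = _require(state, "adjusted", stage, out)
        baselines = _require(state, "baselines", stage, out)
        fcfg = cfg.feature_config()
        spec = cfg.classifier_spec(seed)
        tables = {}
        for mode in ("raw", "pa", "as", "tasd"):
            variant = [type(a)(base=a.base, eda_pa=a.eda_pa, eda_as=a.eda_as,
                               params=a.params, mode=mode, alpha_trace=a.alpha_trace)
                       for a in adjusted]
            t = build_feature_table(variant, baselines, fcfg)
            tables[mode.upper() if mode != "tasd" else "TASD"] = \
                standardize_per_participant(t)
        reports = run_ablation(tables, spec,
                               test_fraction=cfg.classifier["test_fraction"])
        slim = {name: {k: v for k, v in r.items() if k != "roc"}
                for name, r in reports.items()}
        (out / "ablation_report.json").write_text(json.dumps(slim, indent=2, sort_keys=True))
        _log(out, stage, cfg_hash, seed,
             accuracy={k: r["accuracy"] for k, r in reports.items()})
        return

    raise ValueError(f"unknown stage {stage!r}")


def _write_train_artifacts(report: dict, out: Path) -> None:
    slim = {k: v for k, v in report.items() if k != "roc"}
    (out / "train_report.json").write_text(json.dumps(slim, indent=2, sort_keys=True))
    rows = []
    for cls in ("nostress", "stress"):
        r = report[cls]
        rows.append({"Class": cls, "Precision": r["precision"], "Recall": r["recall"],
                     "F1": r["f1"], "Support": r["support"]})
    rows.append({"Class": "accuracy", "Precision": report["accuracy"],
                 "Recall": report["accuracy"], "F1": report["accuracy"],
                 "Support": report["n_test"]})
    for agg in ("macro", "weighted"):
        a = report[agg]
        rows.append({"Class": f"{agg} avg", "Precision": a["precision"],
                     "Recall": a["recall"], "F1": a["f1"], "Support": report["n_test"]})
    pd.DataFrame(rows).to_csv(out / "classification_report.csv", index=False)
    imp = report.get("feature_importance", {})
    pd.DataFrame({"Feature": list(imp), "Importance": list(imp.values())}) \
        .to_csv(out / "importance.csv", index=False)
    if report.get("roc"):
        pd.DataFrame(report["roc"]).to_csv(out / "roc.csv", index=False)
    pd.DataFrame([report["confusion"]]).to_csv(out / "confusion.csv", index=False)
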