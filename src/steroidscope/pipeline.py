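"""End-to-end pipeline: simulate -> preprocess -> impute -> classify ->
dse -> select -> sympercent -> correlate -> enrich.

One YAML config drives the whole run; a manifest records the config hash,
per-stage output files with SHA-256 digests, seeds, record counts after
each filter, and wall-clock time per stage, so a rerun with the same config
can be checked digest-for-digest on the deterministic stages.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import assoc, dse, lvq, ppca, preprocess, regression, selection, simulate
from .datamodel import write_cohort, write_feature_table, write_steroids

STAGE_ORDER = ("simulate", "preprocess", "impute", "classify", "dse",
               "select", "sympercent", "correlate", "enrich")

#: stage -> stages it requires
_REQUIRES = {
    "preprocess": ("simulate",),
    "impute": ("preprocess",),
    "classify": ("simulate",),
    "dse": ("simulate",),
    "select": ("impute",),
    "sympercent": ("simulate",),
    "correlate": ("select", "preprocess"),
    "enrich": ("select",),
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "out_dir": "steroidscope_run",
    "simulate": {"n_per_group": [104, 70, 70, 47], "n_features": 300,
                 "n_informative": 30, "drift_amplitude": 0.3},
    "preprocess": {},
    "impute": {"k": "auto", "m": 3},
    "classify": {"runs": 5, "epochs": 80},
    "dse": {"flag": "hypertension", "runs": 5, "epochs": 80},
    "select": {"top_n": 100, "runs": 3, "epochs": 100, "omega_rank": 3},
    "sympercent": {"contrast": "hypertension"},
    "correlate": {"n_steroids": 5, "max_features": 200},
    "enrich": {},
}


class ConfigError(ValueError):
    """The pipeline config violates the schema; message carries a path."""


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (config or {}).items():
        if key in ("seed", "out_dir"):
            cfg[key] = val
        elif key in STAGE_ORDER:
            if val is False or val is None:
                cfg[key] = False
            elif isinstance(val, dict):
                base = cfg[key] if isinstance(cfg.get(key), dict) else {}
                base.update(val)
                cfg[key] = base
            else:
                raise ConfigError(f"/{key}: expected mapping or false")
        else:
            raise ConfigError(f"/{key}: unknown key")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("/seed: expected integer")
    enabled = {s for s in STAGE_ORDER if cfg.get(s) is not False}
    for stage in enabled:
        for req in _REQUIRES.get(stage, ()):
            if req not in enabled:
                raise ConfigError(f"/{stage}: requires stage '{req}' to be enabled")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict[str, Any] | str | Path,
                 out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the configured stages in fixed order; return the manifest."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = validate_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    manifest: dict[str, Any] = {
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": seed,
        "stages": [],
    }
    state: dict[str, Any] = {}

    def record(stage: str, files: list[Path], t0: float, **info) -> None:
        manifest["stages"].append({
            "stage": stage, "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {f.name: _digest(f) for f in files},
            **info,
        })

    for stage in STAGE_ORDER:
        if cfg.get(stage) is False:
            continue
        t0 = time.perf_counter()
        opts = dict(cfg[stage]) if isinstance(cfg[stage], dict) else {}
        try:
            files = _STAGES[stage](opts, seed, out, state)
        except Exception as exc:
            manifest["stages"].append({"stage": stage, "status": "failed",
                                       "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        record(stage, files, t0, **state.pop("_info", {}))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# -- stage implementations --------------------------------------------------


def _stage_simulate(opts, seed, out, state):
    sim = simulate.SimConfig(seed=seed, **{
        k: (tuple(v) if isinstance(v, list) else v) for k, v in opts.items()})
    cohort, steroids, truth_c = simulate.simulate_cohort(sim)
    features, truth_f = simulate.simulate_feature_table(sim, cohort)
    state.update(sim=sim, cohort=cohort, steroids=steroids,
                 features=features, truth=truth_f)
    write_cohort(cohort, out / "cohort.csv")
    write_steroids(steroids, out / "steroids.csv")
    write_feature_table(features, out / "features.csv", out / "metadata.csv")
    small_truth = {k: v for k, v in truth_f.items()
                   if k not in ("drift_scale",)}
    (out / "truth.json").write_text(json.dumps(small_truth, indent=2, default=str))
    state["_info"] = {"n_patients": len(cohort),
                      "n_features": sim.n_features,
                      "n_missing_cells": features.n_missing}
    return [out / f for f in ("cohort.csv", "steroids.csv", "features.csv",
                              "metadata.csv", "truth.json")]


def _stage_preprocess(opts, seed, out, state):
    corrected, fit = preprocess.qc_rsc_correct(state["features"])
    filtered, report = preprocess.filter_features(corrected)
    normalised = preprocess.normalise_log(filtered)
    state.update(corrected=corrected, filtered=filtered, normalised=normalised)
    write_feature_table(normalised, out / "normalised.csv", out / "metadata_norm.csv")
    report.table.to_csv(out / "filter_report.csv")
    state["_info"] = {"n_features_in": corrected.abundances.shape[1],
                      "n_features_kept": len(report.kept),
                      "n_uncorrected": len(fit.uncorrected)}
    return [out / "normalised.csv", out / "metadata_norm.csv",
            out / "filter_report.csv"]


def _stage_impute(opts, seed, out, state):
    norm = state["normalised"]
    X = norm.study.to_numpy()
    k = opts.get("k", "auto")
    k = ppca.choose_k(X, k_max=10) if k == "auto" else int(k)
    model = ppca.fit_ppca(X, k=k, max_iter=int(opts.get("max_iter", 200)))
    imps = ppca.draw_imputations(model, X, M=int(opts.get("m", 3)),
                                 seed=seed + 1301)
    state.update(ppca_model=model, imputations=imps,
                 study_ids=list(norm.study.index),
                 feature_names=list(norm.abundances.columns))
    files = []
    for i, mat in enumerate(imps.matrices):
        f = out / f"imputed_{i}.csv"
        pd.DataFrame(mat, index=state["study_ids"],
                     columns=state["feature_names"]).to_csv(f)
        files.append(f)
    state["_info"] = {"k": k, "sigma2": model.sigma2,
                      "em_iterations": len(model.loglik_trace)}
    return files


def _labels_for_study(state):
    cohort = state["cohort"].df.set_index("patient_id")
    return cohort.loc[state["study_ids"]] if "study_ids" in state else cohort


def _stage_classify(opts, seed, out, state):
    steroids = state["steroids"].aligned_to(state["cohort"])
    X = lvq.log_zscore(steroids.values)
    y = state["cohort"].df["group"].to_numpy()
    cfg = lvq.LVQConfig(epochs=int(opts.get("epochs", 80)), seed=seed)
    runs = int(opts.get("runs", 5))
    profile, summary = lvq.repeated_runs(
        X, y, cfg, n_runs=runs, class_order=("NFAT", "MACS1", "MACS2", "CS"),
        seed=seed, feature_names=list(steroids.df.columns))
    model = lvq.train_ordinal_lvq(X, y, ("NFAT", "MACS1", "MACS2", "CS"),
                                  dataclasses.replace(cfg, seed=seed))
    coords, pcoords = lvq.embed_2d(model, X)
    state.update(steroid_profile=profile, steroid_model=model)
    pd.DataFrame(profile.matrix, columns=list(steroids.df.columns)).to_csv(
        out / "steroid_relevances.csv", index=False)
    pd.DataFrame(coords, index=steroids.df.index,
                 columns=["dim1", "dim2"]).to_csv(out / "embedding.csv")
    metrics = {"ccr_mean": summary["ccr_mean"], "ccr_sd": summary["ccr_sd"]}
    (out / "classify_metrics.json").write_text(json.dumps(metrics, indent=2))
    state["_info"] = metrics
    return [out / "steroid_relevances.csv", out / "embedding.csv",
            out / "classify_metrics.json"]


def _stage_dse(opts, seed, out, state):
    flag = opts.get("flag", "hypertension")
    cdf = state["cohort"].df
    steroids = state["steroids"].aligned_to(state["cohort"])
    X = lvq.log_zscore(steroids.values)
    groups = cdf["group"].to_numpy()
    primary = np.where(np.isin(groups, ["MACS1", "MACS2"]), "MACS", groups)
    mask = primary != "CS"
    cfg = lvq.LVQConfig(epochs=int(opts.get("epochs", 80)), seed=seed)
    result = dse.run_dse(X[mask], primary[mask],
                         cdf.loc[mask, flag].to_numpy(),
                         cfg, n_runs=int(opts.get("runs", 5)), seed=seed)
    pd.DataFrame(result.secondary_relevances.matrix,
                 columns=list(steroids.df.columns)).to_csv(
        out / f"dse_{flag}_relevances.csv", index=False)
    state["_info"] = {"flag": flag, "deflated_rank": result.r,
                      "secondary_accuracy_mean": float(np.mean(result.secondary_accuracy))}
    return [out / f"dse_{flag}_relevances.csv"]


def _stage_select(opts, seed, out, state):
    labels = _labels_for_study(state)["group"].to_numpy()
    cfg = lvq.LVQConfig(epochs=int(opts.get("epochs", 40)), seed=seed,
                        omega_rank=opts.get("omega_rank", 2))
    sel = selection.consensus_select(
        state["imputations"], labels, state["feature_names"], cfg,
        top_n=int(opts.get("top_n", 100)), n_runs=int(opts.get("runs", 3)),
        seed=seed)
    state["selection"] = sel
    ann = simulate.annotations_from_truth(state["truth"])
    fcs = selection.fold_changes(state["corrected"],
                                 state["cohort"].df["group"].to_numpy(),
                                 ann, sel.intersection)
    pd.Series(sorted(sel.intersection)).to_csv(out / "consensus_features.csv",
                                               index=False, header=["feature"])
    (out / "venn.json").write_text(json.dumps(sel.venn, indent=2))
    fcs.per_class.to_csv(out / "foldchange_by_class.csv", index=False)
    state["_info"] = dict(sel.venn)
    return [out / "consensus_features.csv", out / "venn.json",
            out / "foldchange_by_class.csv"]


def _stage_sympercent(opts, seed, out, state):
    res = regression.sympercent_regression(state["steroids"], state["cohort"],
                                           opts.get("contrast", "hypertension"))
    res.to_csv(out / "sympercents.csv")
    summary = regression.summarise_cohort(state["cohort"])
    (out / "table1.json").write_text(json.dumps(summary, indent=2, default=str))
    state["_info"] = {"contrast": opts.get("contrast", "hypertension")}
    return [out / "sympercents.csv", out / "table1.json"]


def _stage_correlate(opts, seed, out, state):
    profile = state.get("steroid_profile")
    steroids = state["steroids"].df
    if profile is not None:
        top = np.argsort(profile.mean)[::-1][:int(opts.get("n_steroids", 5))]
        steroids = steroids.iloc[:, sorted(top)]
    feats = sorted(state["selection"].intersection)[:int(opts.get("max_features", 200))]
    norm_study = state["normalised"].study
    res = assoc.spearman_grid(steroids, norm_study[feats])
    res.table.to_csv(out / "correlations.csv", index=False)
    state["_info"] = {"n_significant": res.n_significant,
                      "n_significant_features": res.n_significant_features}
    return [out / "correlations.csv"]


def _stage_enrich(opts, seed, out, state):
    ann = simulate.annotations_from_truth(state["truth"])
    res = assoc.ora(state["selection"].intersection, ann)
    res.table.to_csv(out / "enrichment.csv", index=False)
    state["_info"] = {"n_pathways": len(res.table),
                      "n_enriched": int(res.table["significant"].sum())}
    return [out / "enrichment.csv"]


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "impute": _stage_impute,
    "classify": _stage_classify,
    "dse": _stage_dse,
    "select": _stage_select,
    "sympercent": _stage_sympercent,
    "correlate": _stage_correlate,
    "enrich": _stage_enrich,
}
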