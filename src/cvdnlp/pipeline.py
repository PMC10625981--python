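"""End-to-end experiment orchestration.

Runs, for each requested look-back window: cohort generation (or
loading), harmonisation and labelling, patient-grouped splitting, text
preprocessing, model selection and training, threshold optimisation on
the validation split, and by-visit / by-patient evaluation on the test
split.  Every stage writes its artifacts under the output directory and
records a content hash of the configuration that produced them, so
re-runs with an unchanged configuration can skip completed stages.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import synth
from .evaluate import evaluate_rules, reports_to_frame
from .nn import BiLSTMClassifier
from .presets import PRESETS
from .text import TextVectorizer
from .thresholds import (
    TARGET_UNCERTAINTY_LEVELS,
    optimise_double,
    optimise_single,
)
from .tuning import multi_restart, random_search

logger = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "parse_window", "run_experiment"]


def default_config(seed: int = 0) -> dict:
    """Desk-scale experiment configuration (full protocol via ``full_scale``)."""
    return {
        "seed": seed,
        "generator": {},  # GeneratorConfig field overrides
        "windows": ["infinite", "24m", "12m", "6m"],
        "split": {"fractions": [0.8, 0.1, 0.1]},
        "textprep": {"prune_fraction": 0.01, "max_len": None},
        "model": {"preset": "24m"},  # or {"search": true}
        "train": {
            "learning_rate": 5e-5,
            "max_epochs": 60,
            "patience": 10,
            "min_delta": 1e-4,
            "batch_size": 64,
        },
        "search": {
            "n_search": 20,
            "cv_folds": 3,
            "max_epochs": 6,
            "patience": 2,
        },
        "n_restarts": 5,
        "uncertainty_targets": list(TARGET_UNCERTAINTY_LEVELS),
        "full_scale": False,
        "out_dir": "runs/experiment",
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    config = default_config()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            config = _merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _merge(config, overrides)
    if config.get("full_scale"):
        config["train"].update({"max_epochs": 200, "patience": 20})
        config["search"].update({"n_search": 200, "cv_folds": 5, "max_epochs": 200, "patience": 20})
        config["n_restarts"] = 100
    return config


def parse_window(name: str) -> ch.WindowSpec:
    text = str(name).strip().lower()
    if text in {"inf", "infinite", "none"}:
        return ch.INFINITE
    return ch.WindowSpec(int(text.rstrip("m")))


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_done(marker: Path, signature: str, outputs: list[Path]) -> bool:
    return (
        marker.exists()
        and marker.read_text().strip() == signature
        and all(p.exists() for p in outputs)
    )


def _generator_config(config: dict) -> synth.GeneratorConfig:
    overrides = dict(config.get("generator") or {})
    overrides.setdefault("seed", config.get("seed", 0))
    for key in ("observation_start", "observation_end"):
        if key in overrides and isinstance(overrides[key], str):
            overrides[key] = datetime.date.fromisoformat(overrides[key])
    if "visits_per_patient_range" in overrides:
        overrides["visits_per_patient_range"] = tuple(overrides["visits_per_patient_range"])
    return synth.GeneratorConfig(**overrides)


def run_experiment(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    resume: bool = False,
) -> dict:
    """Run the full pipeline; returns {window name: results dict}.

    ``config`` may be a YAML path or an already-loaded dict (see
    :func:`default_config` for the schema).  With ``resume`` set,
    stages whose configuration hash matches a previous run are skipped.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    stage_seeds = {
        "split": int(rng.integers(0, 2**31 - 1)),
        "search": int(rng.integers(0, 2**31 - 1)),
        "restarts": int(rng.integers(0, 2**31 - 1)),
        "pairs": int(rng.integers(0, 2**31 - 1)),
    }

    # ---- generate ----------------------------------------------------
    gcfg = _generator_config(config)
    gen_sig = _hash(dataclasses.asdict(gcfg))
    gen_marker = out / "generate.hash"
    cohort_dir = out / "cohort"
    gen_outputs = [cohort_dir / f for f in ("visits.csv", "hospitalisations.csv", "eligibility.csv")]
    if resume and _stage_done(gen_marker, gen_sig, gen_outputs):
        logger.info("generate: unchanged, skipping")
        visits, registry, eligibility = synth.read_cohort(cohort_dir)
    else:
        visits, registry, eligibility = synth.generate_cohort(gcfg)
        synth.write_cohort(visits, registry, eligibility, cohort_dir)
        gen_marker.write_text(gen_sig)

    observation = (
        pd.Timestamp(gcfg.observation_start),
        pd.Timestamp(gcfg.observation_end),
    )
    harmonised = ch.harmonise(visits, eligibility, observation)
    split = ch.split_by_patient(
        harmonised["patient_id"],
        tuple(config["split"]["fractions"]),
        seed=stage_seeds["split"],
    )

    results: dict[str, dict] = {}
    for window_name in config["windows"]:
        window = parse_window(window_name)
        wdir = out / window.name
        wdir.mkdir(exist_ok=True)
        results[window.name] = _run_window(
            config, window, wdir, harmonised, registry, eligibility, observation,
            split, stage_seeds, resume,
        )
    run_log = {
        "seed": seed,
        "stage_seeds": stage_seeds,
        "generator": dataclasses.asdict(gcfg),
        "windows": list(results),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return results


def _run_window(
    config, window, wdir, harmonised, registry, eligibility, observation,
    split, stage_seeds, resume,
) -> dict:
    # ---- label -------------------------------------------------------
    labelled = ch.label_visits(
        harmonised, registry, None, window,
        eligibility=eligibility, observation_end=observation[1],
    )
    labelled["split"] = labelled["patient_id"].map(split)
    labelled = labelled[labelled["split"].notna()].reset_index(drop=True)
    labelled.assign(visit_date=labelled["visit_date"].dt.strftime("%Y-%m-%d")).to_csv(
        wdir / "labelled.csv", index=False
    )

    # ---- prep --------------------------------------------------------
    tp_cfg = config["textprep"]
    train_mask = (labelled["split"] == "train").to_numpy()
    vectorizer = TextVectorizer(
        prune_fraction=tp_cfg.get("prune_fraction", 0.01),
        max_len=tp_cfg.get("max_len"),
    )
    vectorizer.fit(labelled.loc[train_mask, "text"])
    vectorizer.vocabulary_.to_tsv(wdir / "vocabulary.tsv")
    X, retained = vectorizer.transform_with_mask(labelled["text"])
    data = labelled[retained].reset_index(drop=True)
    X = X[retained]
    y = data["label"].to_numpy()
    masks = {name: (data["split"] == name).to_numpy() for name in ("train", "validation", "test")}

    # ---- train -------------------------------------------------------
    train_cfg = dict(config["train"])
    train_cfg["vocab_size"] = vectorizer.vocab_size_
    model_cfg = config["model"]
    search_log = None
    if model_cfg.get("arch"):
        arch = dict(model_cfg["arch"])
    elif model_cfg.get("search"):
        s_cfg = config["search"]
        arch, search_log = random_search(
            X[masks["train"]], y[masks["train"]],
            data.loc[masks["train"], "patient_id"].to_numpy(),
            n_search=s_cfg["n_search"],
            cv_folds=s_cfg["cv_folds"],
            seed=stage_seeds["search"],
            train_params={**train_cfg, "max_epochs": s_cfg["max_epochs"], "patience": s_cfg["patience"]},
            log_path=wdir / "search_log.jsonl",
        )
    else:
        preset = model_cfg.get("preset") or "auto"
        if preset == "auto":
            preset = window.name if window.name in PRESETS else "24m"
        arch = dict(PRESETS[preset])
    model, restart_log = multi_restart(
        arch,
        X[masks["train"]], y[masks["train"]],
        X[masks["validation"]], y[masks["validation"]],
        n_restarts=int(config["n_restarts"]),
        seed=stage_seeds["restarts"],
        train_params=train_cfg,
        log_path=wdir / "restart_log.jsonl",
    )
    model.save_weights(wdir / "model.npz")

    # ---- threshold ---------------------------------------------------
    p_val = model.predict_proba(X[masks["validation"]])[:, 1]
    y_val = y[masks["validation"]]
    rules = {0.0: optimise_single(p_val, y_val)}
    for target in config["uncertainty_targets"]:
        rules[float(target)] = optimise_double(
            p_val, y_val, float(target), seed=stage_seeds["pairs"]
        )
    (wdir / "thresholds.json").write_text(
        json.dumps({str(k): v.to_dict() for k, v in rules.items()}, indent=2)
    )

    # ---- evaluate ----------------------------------------------------
    p_test = model.predict_proba(X[masks["test"]])[:, 1]
    reports = evaluate_rules(
        p_test,
        y[masks["test"]],
        data.loc[masks["test"], "patient_id"].to_numpy(),
        {k: v.rule for k, v in rules.items()},
        window=window.name,
    )
    frame = reports_to_frame(reports)
    frame.to_csv(wdir / "evaluation.csv", index=False)
    (wdir / "evaluation.json").write_text(json.dumps([r.to_dict() for r in reports], indent=2))
    return {
        "window": window.name,
        "architecture": arch,
        "search_log": search_log,
        "restart_log": restart_log,
        "rules": rules,
        "reports": reports,
        "model": model,
        "vectorizer": vectorizer,
        "data": data,
        "X": X,
        "masks": masks,
        "p_val": p_val,
        "p_test": p_test,
    }
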