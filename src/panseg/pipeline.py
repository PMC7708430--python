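"""End-to-end orchestration: generate -> normalize -> train -> predict ->
quantify -> evaluate, with every artifact written under one output directory.

The runner is deterministic for a fixed config + seed on one thread: every
stochastic stage draws a named child seed from the run's seed registry, and
the manifest of declared outputs is written before any stage runs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import RunConfig, RunLog, SeedRegistry
from .fusion import fuse, quantify
from .metrics import evaluate_cohort
from .models import (
    TrainedModel,
    compose_training_set,
    extract_class_tiles,
    predict_image,
    train_model,
)
from .normalization import (
    compute_reinhard_stats,
    fit_stain_stats,
    normalize_by_crops,
    normalize_macenko,
    normalize_vahadane,
    reinhard_normalize,
)
from .synthetic import LABEL_CODES, cohort_specs, generate_cohort

POSITIVE_CLASSES = ("acinar", "adm", "dysplasia")


def fit_reference(image: np.ndarray, cfg: RunConfig):
    if cfg.normalization.method == "reinhard":
        return compute_reinhard_stats(image, space=cfg.normalization.space)
    return fit_stain_stats(image, cfg.normalization.method, seed=cfg.seed)


def normalize_image(image: np.ndarray, ref, cfg: RunConfig) -> np.ndarray:
    n = cfg.normalization
    if n.method == "reinhard":
        if n.mode == "crops":
            return normalize_by_crops(
                image, ref, crop_size=n.crop_size, overlap_fraction=n.overlap,
                threshold=n.background_threshold,
            )
        return reinhard_normalize(image, ref)
    if n.method == "macenko":
        return normalize_macenko(image, ref)
    return normalize_vahadane(image, ref, seed=0)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the whole desk pipeline on a seeded synthetic cohort.

    Returns a dict with models, per-sample area reports, cohort evaluation
    and the paths of every artifact written.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = SeedRegistry(config.seed)
    log = RunLog(config)

    manifest = {
        "config": "config.yaml",
        "normalized_dir": "normalized",
        "models_dir": "models",
        "labels_dir": "labels",
        "area_report": "area_report.csv",
        "evaluation": "evaluation.json",
        "run_log": "run_log.json",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.yaml").write_text(config.to_yaml())
    for d in ("normalized", "models", "labels"):
        (out / d).mkdir(exist_ok=True)

    # ---- generate ----------------------------------------------------------
    syn = config.synthetic
    specs = cohort_specs(
        syn.n_train + syn.n_test, seed=seeds.seed_for("cohort"), image_size=syn.image_size
    )
    samples, gen_manifest = generate_cohort(specs)
    gen_manifest.to_csv(out / "synthetic_manifest.csv", index=False)
    train_samples = samples[: syn.n_train]
    test_samples = samples[syn.n_train :]
    log.record("generate", n_train=syn.n_train, n_test=syn.n_test)

    # ---- normalize ---------------------------------------------------------
    ref = fit_reference(train_samples[0].image, config)
    norm_train, norm_test = [], []
    for i, s in enumerate(samples):
        norm = normalize_image(s.image, ref, config)
        (norm_train if i < syn.n_train else norm_test).append(norm)
        pio.write_image(out / "normalized" / f"sample_{i:03d}.png", norm)
    log.record("normalize", method=config.normalization.method, mode=config.normalization.mode)

    # ---- train -------------------------------------------------------------
    models: dict[str, TrainedModel] = {}
    tcfg = config.training
    for cname in POSITIVE_CLASSES:
        rel, oth = [], []
        for norm, s in zip(norm_train, train_samples):
            r, o = extract_class_tiles(
                norm.astype(np.float32) / 255.0,
                s.truth,
                LABEL_CODES[cname],
                tile_size=tcfg.input_size,
                stride=tcfg.input_size,  # disjoint training tiles
            )
            rel += r
            oth += o
        class_cfg = dataclasses.replace(tcfg, seed=seeds.seed_for(f"train:{cname}"))
        tr, held = compose_training_set(rel, oth, class_cfg)
        model = train_model((tr, held), class_cfg, cname)
        model.save(out / "models" / f"{cname}")
        models[cname] = model
        log.record(
            "train", class_name=cname, n_train_tiles=len(tr), n_heldout=len(held),
            best_epoch=model.best_epoch,
        )

    # ---- predict + fuse + quantify ----------------------------------------
    stride = config.tiling.stride
    pred_rows, ref_rows = [], []
    reports = []
    for i, (norm, s) in enumerate(zip(norm_test, test_samples)):
        probs = {c: predict_image(models[c], norm, stride=stride) for c in POSITIVE_CLASSES}
        labels = fuse(
            probs["acinar"], probs["adm"], probs["dysplasia"], s.image, config.thresholds,
            bg_threshold=config.normalization.background_threshold,
        )
        pio.write_label_map(out / "labels" / f"test_{i:03d}.png", labels)
        rep = quantify(labels)
        reports.append(rep)
        pred_rows.append(
            {"sample_id": i, "amy": rep.amy_equiv, "pank": rep.pank_equiv, "other": rep.other_equiv}
        )
        dapi = s.if_dapi.sum()
        ref_rows.append(
            {
                "sample_id": i,
                "amy": s.if_amy.sum() / dapi,
                "pank": s.if_pank.sum() / dapi,
                "other": (dapi - s.if_amy.sum() - s.if_pank.sum()) / dapi,
            }
        )
    area = pd.concat(
        [r.to_frame(sample_id=i) for i, r in enumerate(reports)], ignore_index=True
    )
    area.to_csv(out / "area_report.csv", index=False)
    log.record("quantify", n_test=len(reports))

    # ---- evaluate ----------------------------------------------------------
    evaluation = None
    if len(pred_rows) >= 3:
        evaluation = evaluate_cohort(pd.DataFrame(pred_rows), pd.DataFrame(ref_rows))
        (out / "evaluation.json").write_text(
            json.dumps({"spearman": evaluation["spearman"], "n": evaluation["n"]}, indent=2)
        )
        log.record("evaluate", **evaluation["spearman"])
    log.write(out / "run_log.json", seeds)
    return {
        "models": models,
        "reports": reports,
        "predicted_fractions": pd.DataFrame(pred_rows),
        "reference_fractions": pd.DataFrame(ref_rows),
        "evaluation": evaluation,
        "out_dir": out,
    }
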