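"""End-to-end orchestration: simulate -> train -> score -> survival ->
enrich -> spatial, with derived per-stage seeds and a reproducibility
manifest.

Each stage writes plain-text artifacts into the run directory; the
manifest records the configuration, the per-stage seeds, stage status and
SHA-256 checksums of the tabular outputs, so a rerun with the same
configuration can be verified stage by stage.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .enrichment import group_by_median, gsea
from .io import write_spatial_sample
from .model import (ModelConfig, attention_saliency, load_checkpoint,
                    save_checkpoint)
from .pipeline import (TrainConfig, cross_validate, ensemble_score_many,
                       prepare_cohort)
from .spatial import annotate_spots, correlate_attention_signature
from .survival import best_cutoff, hazard_ratio, logrank_test


@dataclass
class RunConfig:
    """Configuration for a full synthetic-cohort run."""

    seed: int = 0
    # cohort: the test split is kept large so survival-label noise does not
    # dominate the held-out AUROC (the label's information ceiling under the
    # default hazards is ~0.71)
    n_patients: int = 420
    test_fraction: float = 0.6
    image_size: int = 64
    cohort: synthetic.CohortParams = field(default_factory=synthetic.CohortParams)
    # model / training
    backbone: str = "tiny"
    epochs: int = 6
    repeats_per_fold: int = 2
    k_folds: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 6
    # expression / enrichment
    n_genes: int = 400
    signature_size: int = 40
    expression_fold_change: float = 2.0
    n_perm: int = 200
    # spatial
    spatial_fold_change: float = 2.0
    spatial_image_size: int = 160
    n_clusters: int = 4
    # analysis thresholds
    os_threshold_months: float = 36.0
    alpha_p: float = 0.05
    fdr_threshold: float = 0.25
    min_group_frac: float = 0.1
    run_spatial: bool = True
    run_enrich: bool = True

    @classmethod
    def tiny(cls, seed: int = 0) -> "RunConfig":
        """Desk-scale profile: 64 px tiles, tiny backbone."""
        return cls(seed=seed)

    @classmethod
    def full_scale(cls, seed: int = 0) -> "RunConfig":
        """Reference-protocol settings (needs far more compute)."""
        return cls(seed=seed, image_size=1024, backbone="resnet101-like",
                   epochs=10, repeats_per_fold=5, k_folds=5,
                   learning_rate=2e-4, n_patients=335)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the base seed."""
    return zlib.crc32(f"{stage}:{base_seed}".encode()) % (2 ** 31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages, writing artifacts and a manifest under
    ``out_dir``. A stage failure is recorded and dependent stages are
    skipped; the manifest is always written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "checksums": {}}
    state: dict = {}

    def record(stage: str, status: str, **info) -> None:
        manifest["stages"][stage] = {"status": status,
                                     "seed": stage_seed(config.seed, stage), **info}

    def checksum(name: str) -> None:
        p = out / name
        if p.exists():
            manifest["checksums"][name] = _sha256(p)

    stages = [
        ("simulate", _stage_simulate, []),
        ("train", _stage_train, ["simulate"]),
        ("score", _stage_score, ["train"]),
        ("survival", _stage_survival, ["score"]),
        ("enrich", _stage_enrich, ["score"]),
        ("spatial", _stage_spatial, ["train"]),
    ]
    for name, fn, deps in stages:
        if name == "enrich" and not config.run_enrich:
            record(name, "skipped", reason="disabled")
            continue
        if name == "spatial" and not config.run_spatial:
            record(name, "skipped", reason="disabled")
            continue
        failed_dep = next((d for d in deps
                           if manifest["stages"].get(d, {}).get("status") != "ok"), None)
        if failed_dep is not None:
            record(name, "skipped", reason=f"dependency {failed_dep} not ok")
            continue
        try:
            info = fn(config, out, state) or {}
            record(name, "ok", **info)
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            record(name, "failed", error=f"{type(exc).__name__}: {exc}",
                   trace=traceback.format_exc(limit=3))
    for name in ("clinical.csv", "truth.csv", "scores.csv", "survival.json",
                 "enrichment.csv", "spatial.json"):
        checksum(name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "simulate")
    cohort = synthetic.generate_cohort(config.n_patients, config.image_size,
                                       config.cohort, seed=seed)
    synthetic.write_cohort(cohort, out)
    rng = np.random.default_rng(seed + 1)
    pids = list(cohort.clinical["patient_id"])
    n_test = int(round(config.test_fraction * len(pids)))
    test_ids = set(rng.choice(pids, size=n_test, replace=False))
    split = pd.DataFrame({"patient_id": pids,
                          "split": ["test" if p in test_ids else "train" for p in pids]})
    split.to_csv(out / "split.csv", index=False)

    signature = synthetic.default_signature(config.n_genes, config.signature_size)
    markers = synthetic.default_tumor_markers(config.n_genes)
    state["signature"], state["markers"] = signature, markers
    if config.run_enrich:
        test_truth = cohort.truth[cohort.truth["patient_id"].isin(test_ids)]
        expr = synthetic.generate_cohort_expression(
            test_truth, config.n_genes, signature,
            fold_change=config.expression_fold_change, seed=seed + 2)
        expr.to_csv(out / "expression.csv")
    if config.run_spatial:
        img, mask, tmask = synthetic.render_tissue_image(
            config.spatial_image_size, config.spatial_image_size,
            infiltrate_density=0.25, seed=seed + 3, return_tumor_mask=True)
        table = synthetic.generate_spatial_sample(
            img, mask, config.n_genes, signature,
            fold_change=config.spatial_fold_change, seed=seed + 4,
            tumor_mask=tmask, marker_genes=markers)
        write_spatial_sample(table, out / "spatial")
        from .io import write_image
        write_image(img, out / "spatial" / "tissue.png")
        state["spatial_table"], state["spatial_image"] = table, img
    state["cohort"], state["split"] = cohort, split
    return {"n_patients": len(pids), "n_images": len(cohort.images)}


def _stage_train(config: RunConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "train")
    cohort = state["cohort"]
    split = state["split"]
    clinical, labels = prepare_cohort(cohort.clinical, config.os_threshold_months)
    train_ids = set(split[split["split"] == "train"]["patient_id"])
    label_of = dict(zip(labels["patient_id"], labels["target"]))
    idx = cohort.image_index
    usable = idx[idx["patient_id"].isin(train_ids & set(label_of))]
    images = {r.image_id: cohort.images[r.image_id] for r in usable.itertuples()}
    img_labels = {r.image_id: label_of[r.patient_id] for r in usable.itertuples()}
    cfg = ModelConfig(backbone=config.backbone, input_size=config.image_size,
                      batch_size=config.batch_size)
    tc = TrainConfig(learning_rate=config.learning_rate, epochs=config.epochs,
                     repeats_per_fold=config.repeats_per_fold,
                     k_folds=config.k_folds, batch_size=config.batch_size,
                     seed=seed)
    results = cross_validate(images, img_labels, cfg, tc)
    (out / "models").mkdir(exist_ok=True)
    for f, r in enumerate(results):
        save_checkpoint(r.model, out / "models" / f"fold{f}.npz")
    pd.DataFrame({"fold": range(len(results)),
                  "val_auroc": [r.auroc for r in results]}
                 ).to_csv(out / "fold_aurocs.csv", index=False)
    state["fold_models"] = [r.model for r in results]
    state["labels"] = labels
    return {"fold_aurocs": [round(r.auroc, 4) for r in results],
            "n_training_images": len(images)}


def _stage_score(config: RunConfig, out: Path, state: dict) -> dict:
    cohort, split = state["cohort"], state["split"]
    test_ids = set(split[split["split"] == "test"]["patient_id"])
    idx = cohort.image_index
    test_imgs = {r.image_id: cohort.images[r.image_id]
                 for r in idx[idx["patient_id"].isin(test_ids)].itertuples()}
    scores = ensemble_score_many(state["fold_models"], test_imgs)
    pid_of = dict(zip(idx["image_id"], idx["patient_id"]))
    scores["patient_id"] = scores["image_id"].map(pid_of)
    scores.to_csv(out / "scores.csv", index=False)
    state["scores"] = scores
    return {"n_scored": len(scores)}


def _stage_survival(config: RunConfig, out: Path, state: dict) -> dict:
    cohort = state["cohort"]
    scores = state["scores"]
    patient_scores = scores.groupby("patient_id")["score"].mean()
    clin = cohort.clinical.set_index("patient_id").loc[patient_scores.index]
    times = clin["os_months"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=int)
    s = patient_scores.to_numpy()
    cut = best_cutoff(s, times, events, min_group_frac=config.min_group_frac)
    high = (s > cut.cutoff).astype(int)
    lr = logrank_test(times, events, high)
    hr = hazard_ratio(times, events, high)
    report = {
        "n_patients": int(len(s)),
        "stepwise_cutoff": cut.cutoff,
        "stepwise_logrank_p": cut.p,
        "logrank_chi2": lr.chi2,
        "hazard_ratio_high_vs_low": hr.hr,
        "hr_ci": [hr.ci_low, hr.ci_high],
        "significant": bool(cut.p < config.alpha_p),
    }
    (out / "survival.json").write_text(json.dumps(report, indent=2))
    _km_plot(times, events, high, out / "km_stepwise.png")
    state["survival"] = report
    return {"logrank_p": cut.p}


def _km_plot(times, events, group, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .survival import km_estimate

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, label in ((0, "low score"), (1, "high score")):
        sel = np.asarray(group) == g
        if sel.sum() == 0:
            continue
        km = km_estimate(np.asarray(times)[sel], np.asarray(events)[sel])
        xs = np.concatenate([[0], np.repeat(km.event_times, 2)])
        ys = np.concatenate([[1, 1], np.repeat(km.survival, 2)[:-1]]) if km.event_times.size else [1]
        ax.plot(xs, ys[:len(xs)], label=label, drawstyle="steps-post")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _stage_enrich(config: RunConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "enrich")
    scores = state["scores"].groupby("patient_id")["score"].mean()
    expr = pd.read_csv(out / "expression.csv", index_col=0)
    common = [p for p in expr.columns if p in scores.index]
    expr = expr[common]
    labels = group_by_median(scores.loc[common].to_numpy())
    sets = [state["signature"]]
    # decoy sets make the FDR/NES machinery meaningful on synthetic data
    rng = np.random.default_rng(seed)
    genes = list(expr.index)
    from .enrichment import GeneSet
    for i in range(19):
        sets.append(GeneSet(f"DECOY_{i:02d}",
                            tuple(rng.choice(genes, size=len(state["signature"]),
                                             replace=False))))
    results = gsea(expr, labels, sets, n_perm=config.n_perm, seed=seed)
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    df["abs_nes"] = df["nes"].abs()
    df = (df.sort_values(["p", "abs_nes"], ascending=[True, False])
          .drop(columns="abs_nes").reset_index(drop=True))
    df["significant"] = (df["p"] < config.alpha_p) & (df["fdr"] < config.fdr_threshold)
    df.to_csv(out / "enrichment.csv", index=False)
    state["enrichment"] = df
    top = df.iloc[0]
    return {"top_set": top["set_name"], "top_p": float(top["p"]),
            "top_fdr": float(top["fdr"])}


def _stage_spatial(config: RunConfig, out: Path, state: dict) -> dict:
    seed = stage_seed(config.seed, "spatial")
    table = state["spatial_table"]
    img = state["spatial_image"]
    heatmaps = [attention_saliency(m, _fit_tile(img, config.image_size))
                for m in state["fold_models"]]
    from .nn.layers import upsample_bilinear
    hm = np.mean([upsample_bilinear(h, img.shape[0], img.shape[1])
                  for h in heatmaps], axis=0)
    lo, hi = hm.min(), hm.max()
    hm = (hm - lo) / (hi - lo) if hi > lo else np.zeros_like(hm)
    ann = annotate_spots(table, hm, state["signature"], state["markers"],
                         n_clusters=config.n_clusters, seed=seed)
    ann.to_csv(out / "spot_annotations.csv", index=False)
    res = correlate_attention_signature(ann, tumor_only=True)
    report = {"rho": res.rho, "p": res.p, "n_spots": res.n,
              "significant": bool(res.p < config.alpha_p)}
    (out / "spatial.json").write_text(json.dumps(report, indent=2))
    state["spatial_result"] = report
    return report


def _fit_tile(image: np.ndarray, size: int) -> np.ndarray:
    from .pipeline import tile_image

    return tile_image(image, size)[0]
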