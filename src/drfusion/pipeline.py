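"""End-to-end orchestration: synthesize/load -> curate -> split -> augment ->
enhance -> features -> PCA -> fuse -> train -> evaluate.

Two classifier paths are wired:

* ``hybrid-svm``  — filter-bank embedding -> PCA -> SVM.
* ``fusion-ffnn`` — PCA-reduced embedding || handcrafted 232 -> FFNN.

Every run writes its artifacts (manifest, plans, metrics, confusion matrix)
plus a provenance record (config hash, seed, package versions) so a run can
be reproduced from the record alone.  Augmentation is applied to the
training partition only; validation and test images are never augmented,
and PCA statistics are fitted on training features only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasetops import (DEFAULT_AUG_FACTORS, ClassCounts, apply_augmentation,
                         assign_partitions, augmentation_plan, curate_manifest,
                         split_plan)
from .embeddings import DEFAULT_PCA_K, FilterBankEmbedder, PCAReducer
from .evaluation import MetricsReport, confusion, metrics
from .handcrafted import HandcraftedExtractor
from .image import CLASS_NAMES, ImageRGB
from .models import FusionFFNNClassifier, HybridSVMClassifier, fuse_features
from .preprocess import FundusEnhancer
from .synthetic import SynthSpec, generate_corpus


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults reproduce the reference design."""

    seed: int = 0
    model_path: str = "fusion-ffnn"  # or "hybrid-svm"
    n_per_class: int = 20
    image_size: int = 128
    keep_normal_fraction: float = 1.0  # synthetic corpora are already balanced
    test_fraction: float = 0.2
    val_fraction: float = 0.2
    augmentation_factors: dict[str, int] = field(
        default_factory=lambda: dict.fromkeys(CLASS_NAMES, 1))
    kernel_size: int = 4
    n_filters: int = 64
    embed_dim: int = 4096
    pca_k: int = DEFAULT_PCA_K
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    ffnn_hidden_units: int = 15
    auc_mode: str = "roc"
    outdir: str | None = None

    def validate(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigError("test_fraction must be in (0, 1)")
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigError("val_fraction must be in (0, 1)")
        if not (0.0 < self.keep_normal_fraction <= 1.0):
            raise ConfigError("keep_normal_fraction must be in (0, 1]")
        if self.model_path not in ("fusion-ffnn", "hybrid-svm"):
            raise ConfigError("model_path must be 'fusion-ffnn' or 'hybrid-svm'")
        if self.n_per_class < 5:
            raise ConfigError("n_per_class must be >= 5")
        if any(f < 0 for f in self.augmentation_factors.values()):
            raise ConfigError("augmentation factors must be >= 0")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    import sklearn

    return {"config": asdict(config), "config_hash": config.hash(),
            "seed": config.seed, "drfusion_version": __version__,
            "numpy_version": np.__version__,
            "sklearn_version": sklearn.__version__}


def _prepare_partitions(images: list[ImageRGB], manifest: pd.DataFrame,
                        config: PipelineConfig):
    """Curate, split, and augment; returns per-partition image lists."""
    by_id = {img.id: img for img in images}
    if config.keep_normal_fraction < 1.0:
        manifest = curate_manifest(manifest, config.keep_normal_fraction,
                                   seed=config.seed)
    counts = ClassCounts(manifest["class"].value_counts().to_dict())
    plan = split_plan(counts, config.test_fraction, config.val_fraction,
                      seed=config.seed)
    manifest = assign_partitions(manifest, plan)

    aug_plan = augmentation_plan(plan.train_counts(),
                                 config.augmentation_factors, seed=config.seed)
    parts: dict[str, list[ImageRGB]] = {p: [] for p in ("train", "validation",
                                                        "test")}
    aug_rows = []
    for pos, (_, row) in enumerate(manifest.iterrows()):
        img = by_id[row["id"]]
        parts[row["partition"]].append(img)
        if row["partition"] == "train":
            k = aug_plan.factors.get(row["class"], 0)
            if k > 0:
                extras = apply_augmentation(img, k, seed=config.seed * 100003 + pos)
                parts["train"].extend(extras)
                aug_rows.extend({"id": e.id, "class": row["class"],
                                 "label": img.label, "partition": "train",
                                 "provenance": f"augmented:{img.id}"}
                                for e in extras)
    manifest = pd.concat([manifest, pd.DataFrame(aug_rows)], ignore_index=True) \
        if aug_rows else manifest
    return parts, manifest, plan, aug_plan


def _extract_features(parts: dict[str, list[ImageRGB]], config: PipelineConfig):
    """Enhanced images -> embeddings and handcrafted matrices per partition."""
    enhancer = FundusEnhancer(kernel_size=config.kernel_size)
    embedder = FilterBankEmbedder(n_filters=config.n_filters,
                                  out_dim=config.embed_dim)
    handcrafted = HandcraftedExtractor(kernel_size=config.kernel_size)
    feats = {}
    for part, imgs in parts.items():
        enhanced = enhancer.transform(imgs)
        feats[part] = {
            "deep": embedder.transform(enhanced),
            "hand": handcrafted.transform(imgs),
            "y": np.array([img.label for img in imgs]),
        }
    return feats


def _fit_eval_path(feats: dict, path: str, config: PipelineConfig):
    """Train one classifier path and evaluate on the test partition."""
    pca = PCAReducer(k=config.pca_k).fit(feats["train"]["deep"])
    deep = {p: pca.transform(feats[p]["deep"]) for p in feats}
    if path == "hybrid-svm":
        X = {p: deep[p] for p in feats}
        clf = HybridSVMClassifier(kernel=config.svm_kernel, C=config.svm_C,
                                  random_state=config.seed)
    else:
        X = {p: fuse_features(deep[p], feats[p]["hand"]) for p in feats}
        clf = FusionFFNNClassifier(hidden_units=config.ffnn_hidden_units,
                                   random_state=config.seed)
    clf.fit(X["train"], feats["train"]["y"])
    y_test = feats["test"]["y"]
    probs = clf.predict_proba(X["test"])
    y_pred = clf.classes_[np.argmax(probs, axis=1)]
    cm = confusion(y_test, y_pred)
    report = metrics(cm, y_true=y_test, probabilities=probs,
                     auc_mode=config.auc_mode)
    extras = {"validation_accuracy": clf.score(X["validation"],
                                               feats["validation"]["y"]),
              "pca_k": pca.k_}
    return report, cm, clf, extras


def _write_artifacts(outdir: str, config: PipelineConfig, manifest, plan,
                     aug_plan, report, cm) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "split_plan.json").write_text(json.dumps(
        {"per_class": plan.per_class, "test_fraction": plan.test_fraction,
         "val_fraction": plan.val_fraction, "seed": plan.seed}, indent=2))
    (out / "augmentation_plan.json").write_text(json.dumps(
        {"factors": aug_plan.factors, "pre_counts": aug_plan.pre_counts,
         "post_counts": aug_plan.post_counts}, indent=2))
    report.to_json(out / "metrics.json")
    cm.to_csv(out / "confusion.csv")
    (out / "provenance.json").write_text(json.dumps(_provenance(config),
                                                    indent=2))


def run_pipeline(config: PipelineConfig,
                 corpus: tuple[list[ImageRGB], pd.DataFrame] | None = None
                 ) -> MetricsReport:
    """Execute the full study for one classifier path.

    ``corpus`` may supply pre-loaded (images, manifest); otherwise a seeded
    synthetic corpus of ``n_per_class`` images per grade is generated.
    """
    config.validate()

    try:
        if corpus is None:
            spec = SynthSpec(n_per_class=config.n_per_class,
                             image_size=config.image_size, seed=config.seed)
            images, manifest = generate_corpus(spec)
        else:
            images, manifest = corpus
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("data", str(exc)) from exc

    try:
        parts, manifest, plan, aug_plan = _prepare_partitions(images, manifest,
                                                              config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("datasetops", str(exc)) from exc

    try:
        feats = _extract_features(parts, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("features", str(exc)) from exc

    try:
        report, cm, _, extras = _fit_eval_path(feats, config.model_path, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("model", str(exc)) from exc

    if config.outdir:
        _write_artifacts(config.outdir, config, manifest, plan, aug_plan,
                         report, cm)
    report.per_class["_run"] = {"validation_accuracy": extras["validation_accuracy"],
                                "pca_k": extras["pca_k"]}
    return report


def run_experiment(config: PipelineConfig,
                   corpus: tuple[list[ImageRGB], pd.DataFrame] | None = None
                   ) -> dict[str, MetricsReport]:
    """Run both classifier paths on shared features (one extraction pass)."""
    config.validate()
    if corpus is None:
        spec = SynthSpec(n_per_class=config.n_per_class,
                         image_size=config.image_size, seed=config.seed)
        corpus = generate_corpus(spec)
    parts, _, _, _ = _prepare_partitions(corpus[0], corpus[1], config)
    feats = _extract_features(parts, config)
    reports = {}
    for path in ("hybrid-svm", "fusion-ffnn"):
        report, _, _, extras = _fit_eval_path(feats, path, config)
        report.per_class["_run"] = {
            "validation_accuracy": extras["validation_accuracy"],
            "pca_k": extras["pca_k"]}
        reports[path] = report
    return reports
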