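"""End-to-end orchestration: phantoms -> split -> balance -> train -> heads.

This is the desk-scale realisation of the full grading protocol: generate
(or load) labelled fundus images, hold out a stratified 20% test set,
balance the training partition by augmentation, train the Wavelet CNN end
to end, extract global-average-pooling features, fit the classical heads,
and evaluate every head on the untouched test partition.  Balancing happens
after the split and only on the training side, so no augmented copy of a
test image can leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import classify, data_io, synthetic
from .model import (ModelConfig, TrainConfig, build_network, extract_features,
                    tiny_config, train as train_network)

__all__ = ["RunConfig", "tiny_run_config", "prepare_arrays", "run_end_to_end"]

DEFAULT_HEADS = ("svm", "random_forest", "xgboost", "softmax_head")


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    preprocess: data_io.PreprocessConfig = field(default_factory=data_io.PreprocessConfig)
    augment: data_io.AugmentationConfig = field(default_factory=data_io.AugmentationConfig)
    split: data_io.SplitConfig = field(default_factory=data_io.SplitConfig)
    phantom: synthetic.PhantomConfig = field(default_factory=synthetic.PhantomConfig)
    heads: tuple[str, ...] = DEFAULT_HEADS
    n_per_class: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.preprocess.crop_side != self.model.input_side:
            problems.append(
                f"preprocess.crop_side={self.preprocess.crop_side} must equal "
                f"model.input_side={self.model.input_side}"
            )
        if self.preprocess.crop_side % (2 ** self.model.levels):
            problems.append(
                f"preprocess.crop_side={self.preprocess.crop_side} must be divisible "
                f"by 2**model.levels={2 ** self.model.levels}"
            )
        for kind in self.heads:
            if kind not in classify.KINDS:
                problems.append(f"heads: unknown classifier kind {kind!r}")
        if problems:
            raise ValueError("invalid run config: " + "; ".join(problems))

    def reseed(self, seed: int) -> "RunConfig":
        """Propagate one master seed to every stochastic stage."""
        self.seed = seed
        self.model.seed = seed
        self.train.seed = seed + 1
        self.preprocess.seed = seed + 2
        self.augment.seed = seed + 3
        self.split.seed = seed + 4
        self.phantom.seed = seed + 5
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def tiny_run_config(seed: int = 0, n_per_class: int = 50) -> RunConfig:
    """Desk-scale run: 64x64 phantoms, T=2 network, one-CPU friendly."""
    cfg = RunConfig(
        model=tiny_config(seed=seed),
        train=TrainConfig(max_epochs=30, batch_size=25, seed=seed),
        preprocess=data_io.PreprocessConfig(resize_side=72, crop_side=64,
                                            contrast_method="stretch", seed=seed),
        phantom=synthetic.PhantomConfig(image_side=64, seed=seed),
        n_per_class=n_per_class,
        seed=seed,
    )
    return cfg.reseed(seed)


def prepare_arrays(manifest: data_io.Manifest, cfg: RunConfig, training: bool,
                   images: dict[str, np.ndarray] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every record to the network's input shape.

    Each record gets its own crop/flip stream derived from the run seed and
    the record id, so the result is order-independent and reproducible.
    """
    arrays, labels = [], []
    for rec in manifest:
        parsed = data_io.parse_provenance(rec.provenance) if rec.is_augmented else None
        if parsed is not None:
            src, desc = parsed
            if images is not None and src in images:
                img = data_io.apply_transform(images[src], desc, cfg.augment.fill_mode)
            else:
                img = data_io.load_image(rec, cfg.augment.fill_mode)
        elif images is not None and rec.image_id in images:
            img = images[rec.image_id]
        else:
            img = data_io.load_image(rec, cfg.augment.fill_mode)
        rng = np.random.default_rng(
            [cfg.preprocess.seed, synthetic.derive_seed(cfg.seed, rec.grade, rec.image_id)]
        )
        arrays.append(data_io.preprocess_image(img, cfg.preprocess, training=training, rng=rng))
        labels.append(rec.grade)
    return np.stack(arrays), np.array(labels, dtype=int)


def run_end_to_end(cfg: RunConfig,
                   manifest: data_io.Manifest | None = None,
                   images: dict[str, np.ndarray] | None = None) -> dict:
    """Run the full protocol; returns reports per head plus run artefacts.

    When no manifest is supplied, a balanced synthetic phantom dataset is
    generated in memory from ``cfg.phantom``.
    """
    if manifest is None:
        manifest, images = synthetic.generate_dataset(cfg.n_per_class, cfg.phantom)
    train_m, test_m = data_io.split(manifest, cfg.split)
    train_m = data_io.balance_classes(train_m, cfg.augment)

    x_train, y_train = prepare_arrays(train_m, cfg, training=True, images=images)
    x_test, y_test = prepare_arrays(test_m, cfg, training=False, images=images)

    net = build_network(cfg.model)
    train_network(net, x_train, y_train, cfg.train)
    f_train = extract_features(net, x_train)
    f_test = extract_features(net, x_test)

    reports: dict[str, classify.EvaluationReport] = {}
    for kind in cfg.heads:
        spec = classify.ClassifierSpec(kind=kind, seed=cfg.seed)
        clf = classify.fit_classifier(f_train, y_train, spec)
        y_pred = classify.predict(clf, f_test)
        scores = classify.predict_scores(clf, f_test)
        reports[kind] = classify.compute_metrics(y_test, y_pred, scores,
                                                 classes=list(range(cfg.model.num_classes)))

    summary = {
        kind: dict(accuracy=r.accuracy, macro_precision=r.macro_precision,
                   macro_recall=r.macro_recall, macro_f1=r.macro_f1,
                   macro_auc=r.macro_auc)
        for kind, r in reports.items()
    }
    best = max(summary, key=lambda k: summary[k]["macro_f1"])
    return dict(
        network=net,
        history=net.history,
        reports=reports,
        summary=summary,
        best_head=best,
        y_test=y_test,
        features_train=f_train,
        features_test=f_test,
        train_manifest=train_m,
        test_manifest=test_m,
    )
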