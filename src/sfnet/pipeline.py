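"""End-to-end runs: synth -> edge precomputation -> train -> evaluate.

A run is configured by one YAML/dict with ``data``, ``edge``, ``model`` and
``training`` sections, all validated up front before any work starts. Edge
maps are cached as 1-bit PNGs keyed by the image content hash plus the edge
configuration hash, so re-running a pipeline never recomputes unchanged
images. A run directory collects ``config.yaml``, ``history.csv``,
``curves.png``, ``metrics.json``, ``confusion.csv``, ``report.txt``, the
checkpoint (``checkpoint.npz`` + ``model_config.json``) and a log file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .canny import ImprovedCannyEdgeDetector
from .classifier import SFNetClassifier
from .evaluation import confusion_matrix, format_report_table, metrics_from_confusion
from .image_io import CLASSES, LabeledDataset, ValidationError, load_dataset, save_image
from .model import SFNetConfig, build_sfnet
from .synthetic import PhantomSpec, generate_dataset
from .training import TrainConfig, split_dataset

logger = logging.getLogger("sfnet")

_DATA_KEYS = {"root", "synth_n_per_class", "side", "noise_sigma", "split_ratio"}
_EDGE_KEYS = {"window", "ratio", "n_bins"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    data: dict
    edge: dict
    model: SFNetConfig
    training: TrainConfig

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - {"data", "edge", "model", "training"}
        if unknown:
            raise ValidationError(f"unknown config sections {sorted(unknown)}")
        data = dict(raw.get("data", {}))
        bad = set(data) - _DATA_KEYS
        if bad:
            raise ValidationError(f"unknown data keys {sorted(bad)}")
        edge = dict(raw.get("edge", {}))
        bad = set(edge) - _EDGE_KEYS
        if bad:
            raise ValidationError(f"unknown edge keys {sorted(bad)}")
        model = SFNetConfig.from_dict(raw.get("model", {}))
        training = TrainConfig(**raw.get("training", {}))
        return cls(data=data, edge=edge, model=model, training=training)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _edge_config_hash(detector: ImprovedCannyEdgeDetector) -> str:
    blob = json.dumps(detector.get_params(), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def cached_edge_maps(
    images: np.ndarray, detector: ImprovedCannyEdgeDetector, cache_dir: str | Path
) -> np.ndarray:
    """Edge maps for an image stack with a content-addressed PNG cache."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _edge_config_hash(detector)
    out = []
    for img in images:
        key = hashlib.sha1(np.ascontiguousarray(img).tobytes()).hexdigest()[:16]
        path = cache_dir / f"{key}_{cfg_hash}.png"
        if path.exists():
            from .image_io import load_image

            out.append(load_image(path) > 0.5)
        else:
            em = detector.transform(img[None])[0]
            save_image(em.astype(np.float64), path)
            out.append(em)
    return np.stack(out)


def _materialize(cfg: RunConfig, run_dir: Path, seed: int) -> LabeledDataset:
    data = cfg.data
    if data.get("root"):
        ds = load_dataset(data["root"])
        logger.info("[data] loaded %d items from %s", len(ds), data["root"])
        return ds
    n = int(data.get("synth_n_per_class", 50))
    spec = PhantomSpec(
        side=int(data.get("side", cfg.model.input_side)),
        noise_sigma=float(data.get("noise_sigma", 0.05)),
    )
    ds = generate_dataset(n, template=spec, seed=seed, out_dir=run_dir / "synth")
    logger.info("[data] generated %d phantoms into %s", len(ds), run_dir / "synth")
    return ds


def evaluate_split(clf: SFNetClassifier, images: np.ndarray, labels: list[str]) -> dict:
    pred = clf.predict(images)
    cm = confusion_matrix(labels, list(pred))
    report = metrics_from_confusion(cm)
    return {"confusion": cm, "report": report}


def run_pipeline(cfg: RunConfig, run_dir: str | Path, seed: int = 0) -> dict:
    """Execute the full flow and write all artifacts; returns a summary dict."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        with open(run_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "data": cfg.data,
                    "edge": cfg.edge,
                    "model": cfg.model.to_dict(),
                    "training": cfg.training.__dict__,
                },
                fh,
            )
        ds = _materialize(cfg, run_dir, seed)
        split = split_dataset(ds, ratio=cfg.training.split_ratio, seed=seed)
        logger.info("[split] %s", split.per_class_counts)

        m = cfg.model
        clf = SFNetClassifier(
            input_side=m.input_side,
            input_channels=m.input_channels,
            conv_widths=m.conv_widths,
            kernel_side=m.kernel_side,
            dense_units=m.dense_units,
            dropout_rate=m.dropout_rate,
            lrn_n=m.lrn.n,
            edge_window=int(cfg.edge.get("window", 3)),
            edge_ratio=float(cfg.edge.get("ratio", 0.5)),
            epochs=cfg.training.epochs,
            batch_size=cfg.training.batch_size,
            learning_rate=cfg.training.learning_rate,
            optimizer=cfg.training.optimizer,
            random_state=seed,
        )
        train_imgs = split.train.images()
        test_imgs = split.test.images()
        logger.info("[train] fitting on %d items", len(train_imgs))
        clf.fit(train_imgs, np.array(split.train.labels),
                X_val=test_imgs, y_val=np.array(split.test.labels))

        hist = pd.DataFrame(clf.history_)
        hist.insert(0, "epoch", np.arange(1, len(hist) + 1))
        hist.to_csv(run_dir / "history.csv", index=False)
        _plot_curves(hist, run_dir / "curves.png")

        np.savez(run_dir / "checkpoint.npz", **clf.model_.state_arrays())
        with open(run_dir / "model_config.json", "w") as fh:
            json.dump(clf.model_.config.to_dict(), fh, indent=2)

        result = evaluate_split(clf, test_imgs, split.test.labels)
        write_evaluation(result, run_dir)
        summary = {
            "accuracy": result["report"].accuracy,
            "n_train": len(train_imgs),
            "n_test": len(test_imgs),
            "n_parameters": clf.n_parameters_,
        }
        logger.info("[evaluate] %s", summary)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def write_evaluation(result: dict, out_dir: Path) -> None:
    cm, report = result["confusion"], result["report"]
    pd.DataFrame(
        cm.array, index=[f"true_{c}" for c in CLASSES],
        columns=[f"pred_{c}" for c in CLASSES],
    ).to_csv(out_dir / "confusion.csv")
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(report.rounded(4), fh, indent=2)
    with open(out_dir / "report.txt", "w") as fh:
        fh.write(format_report_table({"SFNet run": report}) + "\n")


def _plot_curves(hist: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, kind in zip(axes, ("loss", "acc")):
        for split in ("train", "val"):
            col = f"{split}_{kind}"
            if col in hist:
                ax.plot(hist["epoch"], hist[col], label=split)
        ax.set_xlabel("epoch")
        ax.set_ylabel(kind)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def load_checkpoint(run_dir: str | Path, use_edge_stream: bool = True):
    """Rebuild the network from a run directory's checkpoint."""
    run_dir = Path(run_dir)
    with open(run_dir / "model_config.json") as fh:
        config = SFNetConfig.from_dict(json.load(fh))
    model = build_sfnet(config, use_edge_stream=use_edge_stream)
    with np.load(run_dir / "checkpoint.npz") as arrays:
        model.load_state_arrays(dict(arrays))
    return model
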