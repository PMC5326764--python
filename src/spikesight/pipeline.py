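"""End-to-end pipeline orchestration.

Train: enhance every training patch (decorrelation stretch), extract SIFT
features, fit the K-means vocabulary on pooled descriptors, LLC-encode and
spatial-pyramid-pool every image, then fit the one-vs-all Hellinger SVM.
Classify: the same enhance/extract/encode/pool chain followed by the SVM
argmax — one pyramid vector per image, whatever its size, so a model
trained on small patches transfers to full canopy scenes.

All stage randomness (descriptor subsampling, K-means seeding, SVM seed)
derives from one master seed. ``run_ablation`` sweeps the axes of the
classic comparison grid (decorrelation on/off, coding method, pyramid
on/off, vocabulary size); ``learning_curve`` measures accuracy over nested
training subsets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import hellinger_svm as hsvm
from .codebook import Codebook, fit_kmeans
from .decorrelation import decorrelation_stretch, contrast_stretch
from .image import load_image
from .llc import encode_batch
from .sift import extract_features
from .spm import pool_spm, spm_region_count

__all__ = [
    "DEFAULTS", "Config", "Dataset", "PipelineModel",
    "train_pipeline", "classify_image", "evaluate_pipeline",
    "run_ablation", "learning_curve",
]

#: every tunable knob of every stage, by dotted path
DEFAULTS = {
    "ds.enabled": True,
    "ds.target_sd": 50.0,
    "ds.recenter": 127.5,
    "ds.matrix": "covariance",
    "ds.clip_pct": None,  # e.g. (1, 99) to add a percentile contrast stretch
    "sift.sigma0": 1.6,
    "sift.scales_per_octave": 3,
    "sift.upsample": True,
    "sift.contrast_threshold": 0.03,
    "sift.edge_ratio": 10.0,
    "sift.dense": False,
    "sift.dense_step": 8,
    "sift.max_pixels": 8e6,
    "codebook.k": 200,
    "codebook.max_descriptors": 200000,
    "codebook.init": "kmeans++",
    "codebook.max_iter": 100,
    "encode.method": "llc",  # llc | hard
    "encode.knn": 5,
    "encode.lambda": 1e-4,
    "spm.enabled": True,
    "spm.levels": 3,
    "spm.mode": "sum",  # sum | max
    "spm.weights": None,  # None -> (0.25, 0.25, 0.5)
    "svm.C": 1.0,
}


class Config(dict):
    """Flat dotted-path configuration with defaults.

    ``Config({"codebook.k": 500})`` overrides one knob; unknown keys are
    rejected so typos fail loudly. ``from_yaml`` accepts either flat dotted
    keys or nested mappings.
    """

    def __init__(self, overrides=None):
        super().__init__(DEFAULTS)
        for k, v in (overrides or {}).items():
            if k not in DEFAULTS:
                raise KeyError(f"unknown config key: {k}")
            self[k] = v

    @classmethod
    def from_yaml(cls, path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat = {}

        def walk(prefix, obj):
            if isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            else:
                flat[prefix] = tuple(obj) if isinstance(obj, list) else obj

        walk("", raw)
        return cls(flat)

    def hash(self) -> str:
        blob = json.dumps({k: self[k] for k in sorted(self)}, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class Dataset:
    """Directory-per-class image dataset with train/test splits."""

    root: Path
    train: dict  # class -> list of paths
    test: dict

    @classmethod
    def from_directory(cls, root) -> "Dataset":
        root = Path(root)
        splits = {}
        for split in ("train", "test"):
            d = root / split
            classes = {}
            if d.is_dir():
                for cdir in sorted(p for p in d.iterdir() if p.is_dir()):
                    imgs = sorted(p for p in cdir.iterdir()
                                  if p.suffix.lower() in
                                  (".png", ".jpg", ".jpeg", ".tif", ".tiff"))
                    if imgs:
                        classes[cdir.name] = imgs
            splits[split] = classes
        if len(splits["train"]) < 2:
            raise ValueError(f"{root}: need >= 2 training classes")
        both = {p for ps in splits["train"].values() for p in ps} & \
               {p for ps in splits["test"].values() for p in ps}
        if both:
            raise ValueError("images shared between train and test splits")
        return cls(root=root, train=splits["train"], test=splits["test"])

    @property
    def classes(self):
        return sorted(self.train)


@dataclass
class PipelineModel:
    codebook: Codebook
    classifier: hsvm.TrainedModel
    config: Config
    seed: int
    n_train_images: int

    @property
    def dim(self) -> int:
        levels = self.config["spm.levels"] if self.config["spm.enabled"] else 1
        return spm_region_count(levels) * self.codebook.K

    def save(self, path) -> None:
        np.savez(
            path,
            centers=self.codebook.centers,
            weights=self.classifier.weights,
            biases=self.classifier.biases,
            meta=json.dumps({
                "classes": self.classifier.classes,
                "K": self.codebook.K,
                "codebook_seed": self.codebook.seed,
                "inertia": self.codebook.inertia,
                "C": self.classifier.C,
                "svm_seed": self.classifier.seed,
                "loss": self.classifier.loss,
                "seed": self.seed,
                "n_train_images": self.n_train_images,
                "config": {k: self.config[k] for k in sorted(self.config)},
            }, default=str),
        )

    @classmethod
    def load(cls, path) -> "PipelineModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            raw = {}
            for k, v in meta["config"].items():
                d = DEFAULTS[k]
                if v == "None":
                    v = None
                elif isinstance(d, bool):
                    v = v in (True, "True", "true")
                elif isinstance(d, (int, float)) and not isinstance(d, bool):
                    v = type(d)(float(v))
                raw[k] = v
            cfg = Config(raw)
            cb = Codebook(centers=z["centers"], K=meta["K"],
                          seed=meta["codebook_seed"], n_iter=0,
                          inertia=meta["inertia"])
            clf = hsvm.TrainedModel(
                classes=meta["classes"], weights=z["weights"],
                biases=z["biases"], C=meta["C"], seed=meta["svm_seed"])
            return cls(codebook=cb, classifier=clf, config=cfg,
                       seed=meta["seed"], n_train_images=meta["n_train_images"])


def enhance_image(image: np.ndarray, config: Config) -> np.ndarray:
    if not config["ds.enabled"]:
        return image
    out = decorrelation_stretch(
        image, target_sd=config["ds.target_sd"],
        recenter=config["ds.recenter"], matrix=config["ds.matrix"])
    if config["ds.clip_pct"] is not None:
        lo, hi = config["ds.clip_pct"]
        out = contrast_stretch(out, lo, hi)
    return out


def image_features(image: np.ndarray, config: Config):
    img = enhance_image(image, config)
    return extract_features(
        img,
        sigma0=config["sift.sigma0"],
        scales_per_octave=config["sift.scales_per_octave"],
        upsample=config["sift.upsample"],
        contrast_threshold=config["sift.contrast_threshold"],
        edge_ratio=config["sift.edge_ratio"],
        max_pixels=config["sift.max_pixels"],
        dense_step=config["sift.dense_step"] if config["sift.dense"] else None,
    )


def _spm_args(config: Config):
    levels = config["spm.levels"] if config["spm.enabled"] else 1
    weights = config["spm.weights"]
    if weights is None and not config["spm.enabled"]:
        weights = (1.0,)
    return levels, weights


def image_vector(features, codebook: Codebook, config: Config):
    codes = encode_batch(
        codebook, features.descriptors, method=config["encode.method"],
        k_nn=config["encode.knn"], lam=config["encode.lambda"])
    levels, weights = _spm_args(config)
    return pool_spm(codes, features.positions, features.image_size,
                    codebook.K, mode=config["spm.mode"], levels=levels,
                    level_weights=weights)


def _gather_features(dataset: Dataset, config: Config, feature_cache=None,
                     subset=None, log=None):
    """(class -> list of FeatureSet) for the training split.

    ``feature_cache`` maps path -> FeatureSet and is filled in place, so
    ablation cells and learning-curve sizes that share a feature config
    reuse extractions. Unreadable images are skipped with a warning count.
    """
    out = {}
    for cls, paths in dataset.train.items():
        if subset is not None:
            paths = subset.get(cls, paths)
        feats, skipped = [], 0
        for p in paths:
            key = str(p)
            if feature_cache is not None and key in feature_cache:
                feats.append(feature_cache[key])
                continue
            try:
                img = load_image(p)
            except Exception:
                skipped += 1
                continue
            fs = image_features(img, config)
            if feature_cache is not None:
                feature_cache[key] = fs
            feats.append(fs)
        if skipped and log is not None:
            log(f"warning: skipped {skipped} unreadable image(s) in class {cls}")
        if not feats:
            raise ValueError(f"no readable training images for class {cls!r}")
        out[cls] = feats
    return out


def train_pipeline(dataset: Dataset, config: Config | None = None,
                   seed: int = 0, feature_cache=None, log=None) -> PipelineModel:
    """Fit codebook + classifier on the dataset's training split."""
    config = config if config is not None else Config()
    per_class = _gather_features(dataset, config, feature_cache, log=log)
    all_desc = np.concatenate(
        [fs.descriptors for feats in per_class.values() for fs in feats]
        or [np.zeros((0, 128))])
    if all_desc.shape[0] == 0:
        raise ValueError("no descriptors extracted from the training set")
    rng = np.random.default_rng(seed)
    cap = int(config["codebook.max_descriptors"])
    if all_desc.shape[0] > cap:
        all_desc = all_desc[rng.choice(all_desc.shape[0], cap, replace=False)]
    K = int(config["codebook.k"])
    if all_desc.shape[0] < K:
        raise ValueError(
            f"codebook.k={K} exceeds the {all_desc.shape[0]} training "
            "descriptors: lower K or add training patches")
    cb = fit_kmeans(all_desc, K=K, seed=seed,
                    max_iter=int(config["codebook.max_iter"]),
                    init=config["codebook.init"])
    samples, labels = [], []
    for cls, feats in per_class.items():
        for fs in feats:
            samples.append(image_vector(fs, cb, config))
            labels.append(cls)
    n_imgs = len(samples)
    clf = hsvm.train(samples, labels, C=config["svm.C"], seed=seed,
                     codebook_hash=hashlib.sha1(cb.centers.tobytes()).hexdigest()[:12])
    return PipelineModel(codebook=cb, classifier=clf, config=config,
                         seed=seed, n_train_images=n_imgs)


def classify_image(model: PipelineModel, image: np.ndarray):
    """(label, per-class scores) for one image of any size.

    A featureless image yields the zero pyramid vector and is classified by
    bias alone; the returned scores carry a ``low_confidence`` marker key.
    """
    fs = image_features(image, model.config)
    vec = image_vector(fs, model.codebook, model.config)
    label, scores = hsvm.predict(model.classifier, vec)
    if vec.empty:
        scores = dict(scores)
        scores["low_confidence"] = True
    return label, scores


def evaluate_pipeline(model: PipelineModel, dataset: Dataset,
                      split: str = "test", feature_cache=None,
                      positive_label=None) -> hsvm.EvalReport:
    preds, gold = [], []
    for cls, paths in getattr(dataset, split).items():
        for p in paths:
            key = str(p)
            if feature_cache is not None and key in feature_cache:
                fs = feature_cache[key]
            else:
                fs = image_features(load_image(p), model.config)
                if feature_cache is not None:
                    feature_cache[key] = fs
            vec = image_vector(fs, model.codebook, model.config)
            label, _ = hsvm.predict(model.classifier, vec)
            preds.append(label)
            gold.append(cls)
    return hsvm.evaluate(preds, gold, positive_label=positive_label)


DEFAULT_GRID = {
    "decorrelation": [True, False],
    "feature": ["sift", "surf"],
    "coding": ["llc", "hard"],
    "spm": [True, False],
    "vocabulary": [100, 200],
}


def run_ablation(dataset: Dataset, grid: dict | None = None,
                 config: Config | None = None, seed: int = 0, log=None):
    """One train/test cycle per grid cell on the fixed split.

    The grid varies one axis at a time around the default cell
    (decorrelation on, SIFT, LLC, pyramid on, first vocabulary size), the
    layout of the classic comparison table. Infeasible cells (an
    unavailable detector) are marked skipped and the run continues.
    Returns a list of row dicts.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    base = config if config is not None else Config()
    vocabs = list(grid.get("vocabulary", [base["codebook.k"]]))
    cells = []
    head = {"decorrelation": grid["decorrelation"][0] if "decorrelation" in grid else True,
            "feature": "sift",
            "coding": grid.get("coding", ["llc"])[0],
            "spm": grid.get("spm", [True])[0],
            "vocabulary": vocabs[0]}
    cells.append(dict(head))
    for axis in ("decorrelation", "feature", "coding", "spm"):
        for val in grid.get(axis, []):
            cell = dict(head)
            cell[axis] = val
            if cell not in cells:
                cells.append(cell)
    for v in vocabs[1:]:
        cell = dict(head)
        cell["vocabulary"] = v
        if cell not in cells:
            cells.append(cell)

    rows = []
    caches = {}  # ds.enabled flag -> feature cache (features depend on it)
    for cell in cells:
        row = dict(cell)
        if cell["feature"] != "sift":
            row.update(status=f"skipped: no {cell['feature']} detector available",
                       accuracy=None, precision=None, recall=None, dim=None)
            rows.append(row)
            continue
        cfg = Config({
            **{k: base[k] for k in base if k not in
               ("ds.enabled", "encode.method", "spm.enabled", "codebook.k")},
            "ds.enabled": cell["decorrelation"],
            "encode.method": cell["coding"] if cell["coding"] != "knn" else "hard",
            "spm.enabled": cell["spm"],
            "codebook.k": cell["vocabulary"],
        })
        cache = caches.setdefault(cell["decorrelation"], {})
        model = train_pipeline(dataset, cfg, seed=seed, feature_cache=cache, log=log)
        report = evaluate_pipeline(model, dataset, feature_cache=cache)
        row.update(status="ok", accuracy=report.accuracy,
                   precision=report.precision, recall=report.recall,
                   dim=model.dim, config_hash=cfg.hash())
        rows.append(row)
        if log is not None:
            log(f"ablation cell {cell}: accuracy={report.accuracy:.3f}")
    return rows


def learning_curve(dataset: Dataset, sizes, seed: int = 0,
                   config: Config | None = None, log=None):
    """Accuracy on the fixed test split over nested training subsets.

    Per class, a seeded permutation of the training list is truncated to
    each requested size, so smaller subsets are contained in larger ones.
    Returns a list of {size, accuracy, precision, recall} rows.
    """
    config = config if config is not None else Config()
    sizes = sorted(int(s) for s in sizes)
    avail = {c: len(ps) for c, ps in dataset.train.items()}
    limit = min(avail.values())
    if sizes[-1] > limit:
        raise ValueError(
            f"requested {sizes[-1]} training images/class but only {limit} "
            "are available")
    rng = np.random.default_rng(seed)
    order = {c: rng.permutation(len(ps)) for c, ps in dataset.train.items()}
    cache = {}
    rows = []
    for n in sizes:
        subset = {c: [dataset.train[c][i] for i in order[c][:n]]
                  for c in dataset.train}
        per_class = _gather_features(dataset, config, cache, subset=subset)
        all_desc = np.concatenate(
            [fs.descriptors for feats in per_class.values() for fs in feats])
        K = min(int(config["codebook.k"]), all_desc.shape[0])
        cb = fit_kmeans(all_desc, K=K, seed=seed,
                        max_iter=int(config["codebook.max_iter"]),
                        init=config["codebook.init"])
        samples, labels = [], []
        for cls, feats in per_class.items():
            for fs in feats:
                samples.append(image_vector(fs, cb, config))
                labels.append(cls)
        clf = hsvm.train(samples, labels, C=config["svm.C"], seed=seed)
        model = PipelineModel(codebook=cb, classifier=clf, config=config,
                              seed=seed, n_train_images=len(samples))
        report = evaluate_pipeline(model, dataset, feature_cache=cache)
        rows.append({"size": n, "accuracy": report.accuracy,
                     "precision": report.precision, "recall": report.recall})
        if log is not None:
            log(f"learning curve n={n}: accuracy={report.accuracy:.3f}")
    return rows
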