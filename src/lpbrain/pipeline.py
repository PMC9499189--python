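"""End-to-end orchestration: phantoms -> features/CNN -> classifiers -> report.

Three method rows are compared, mirroring the experiment grid:

* ``DWT`` — features from the wavelet approximation band of the raw image;
* ``DWT+LPT`` — log-polar transform first, then the wavelet band, so
  rotations/scalings of the subject become shifts the features shrug off;
* ``DWT+LPT+CNN`` — the shallow CNN consuming log-polar images directly.

Feature-based methods are evaluated with all four SVM kernels; the CNN has
no kernel, so its row carries a single kernel-independent accuracy.  Every
run is a pure function of (preset, config, master seed); reports embed a
config hash so artifacts from incompatible configurations cannot be mixed
silently.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from lpbrain.cnn_classify import (
    CNNConfig, TrainedCNN, build_4lcnn, predict_cnn, predict_cnn_batch, train_cnn,
)
from lpbrain.features import (
    FeatureConfig, FeatureMatrix, extract_feature_matrix, extract_feature_vector,
)
from lpbrain.kernel_classify import (
    KERNEL_KINDS, KernelSpec, TrainedKSVM, evaluate_accuracy, train_ksvm,
)
from lpbrain.logpolar import foreground_centroid, lpt
from lpbrain.phantom import LabeledDataset, make_preset_dataset
from lpbrain.preprocess import load_image, preprocess_chain

METHODS = ("DWT", "DWT+LPT", "DWT+LPT+CNN")
KERNEL_COLUMNS = {"rbf": "RBF (%)", "linear": "Linear (%)",
                  "polynomial": "Polynomial (%)", "quadratic": "Quadratic (%)"}


def method_feature_config(method: str, base: FeatureConfig = FeatureConfig()) -> FeatureConfig:
    """The feature flags implied by a method row name."""
    if method == "DWT":
        return replace(base, use_lpt=False, use_dwt=True)
    if method in ("DWT+LPT", "DWT+LPT+CNN"):
        return replace(base, use_lpt=True, use_dwt=True)
    raise ValueError(f"method must be one of {METHODS}, got {method!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that determines a pipeline run."""

    method: str = "DWT+LPT"
    task: str = "tumor"
    kernel: KernelSpec = KernelSpec(kind="quadratic")
    cnn: CNNConfig = CNNConfig(input_shape=(64, 64, 3), epochs=60)
    features: FeatureConfig = FeatureConfig()
    image_size: tuple[int, int] = (256, 256)
    cnn_use_lpt: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.task not in ("tumor", "abnormality"):
            raise ValueError("task must be 'tumor' or 'abnormality'")

    def hash(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            return str(o)
        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ExperimentReport:
    """Per-(method, kernel) accuracies plus provenance.

    ``table`` has one row per method with the four kernel percentage
    columns (NaN on the CNN row) and a ``CNN (%)`` column (NaN on feature
    rows).  ``predictions`` records each validation image's true and
    predicted label per method.
    """

    table: pd.DataFrame
    predictions: pd.DataFrame
    dataset: str
    config_hash: str
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _cnn_input_images(images, cfg: PipelineConfig) -> list[np.ndarray]:
    """Optionally map images to the log-polar domain before the CNN."""
    if not cfg.cnn_use_lpt:
        return list(images)
    M = cfg.cnn.input_shape[0]
    N = cfg.cnn.input_shape[1]
    out = []
    for im in images:
        center = foreground_centroid(im) if cfg.features.recenter else None
        out.append(lpt(im, M=M, N=N, r_min=cfg.features.lpt_r_min,
                       center=center).pixels)
    return out


def train_method(dataset: LabeledDataset, method: str, cfg: PipelineConfig):
    """Train one method row on the dataset's training split.

    Returns a dict of per-kernel :class:`TrainedKSVM` models for feature
    methods, or a single :class:`TrainedCNN` for the CNN method.
    """
    tr_images, tr_labels, tr_ids = dataset.split("train")
    if "CNN" in method:
        net = build_4lcnn(replace(cfg.cnn, seed=cfg.seed))
        trained = train_cnn(net, _cnn_input_images(tr_images, cfg), tr_labels,
                            seed=cfg.seed, stop_at_accuracy=100.0)
        return trained
    fcfg = method_feature_config(method, cfg.features)
    F = extract_feature_matrix(tr_images, tr_labels, fcfg, tr_ids)
    return {kind: train_ksvm(F, replace(cfg.kernel, kind=kind))
            for kind in KERNEL_KINDS}


def run_experiment(
    preset: str,
    cfg: PipelineConfig = PipelineConfig(),
    methods: tuple[str, ...] = METHODS,
    distortion: str | None = None,
    seed: int | None = None,
) -> ExperimentReport:
    """Generate the preset's phantoms, train every method row, evaluate.

    ``distortion`` overrides the preset's distortion policy (applied to the
    validation split), e.g. ``"rotate"`` to probe rotation robustness.
    """
    seed = cfg.seed if seed is None else int(seed)
    dataset = make_preset_dataset(preset, seed=seed, size=cfg.image_size,
                                  distortion=distortion)
    va_images, va_labels, va_ids = dataset.split("validation")

    rows = []
    pred_rows = []
    for method in methods:
        row: dict = {"task": cfg.task, "method": method}
        row.update({col: np.nan for col in KERNEL_COLUMNS.values()})
        row["CNN (%)"] = np.nan
        models = train_method(dataset, method, replace(cfg, seed=seed))
        if isinstance(models, TrainedCNN):
            preds = predict_cnn_batch(models, _cnn_input_images(va_images, cfg))
            acc = 100.0 * sum(p == t for p, t in zip(preds, va_labels)) / len(va_labels)
            row["CNN (%)"] = acc
            for iid, t, p in zip(va_ids, va_labels, preds):
                pred_rows.append({"method": method, "kernel": "cnn",
                                  "image_id": iid, "true": t, "predicted": p})
        else:
            fcfg = method_feature_config(method, cfg.features)
            F_val = extract_feature_matrix(va_images, va_labels, fcfg, va_ids)
            for kind, model in models.items():
                row[KERNEL_COLUMNS[kind]] = evaluate_accuracy(model, F_val)
                for iid, t, p in zip(va_ids, va_labels, model.predict(F_val.X)):
                    pred_rows.append({"method": method, "kernel": kind,
                                      "image_id": iid, "true": t, "predicted": p})
        rows.append(row)

    return ExperimentReport(pd.DataFrame(rows), pd.DataFrame(pred_rows),
                            preset, cfg.hash(), seed)


def mean_accuracy_over_seeds(
    preset: str,
    seeds,
    cfg: PipelineConfig = PipelineConfig(),
    methods: tuple[str, ...] = ("DWT", "DWT+LPT"),
    distortion: str | None = "rotate",
):
    """Mean validation accuracy per method (averaged over kernels and seeds).

    Single-split accuracy on these small validation sets is noise-dominated,
    so robustness claims are made on means across master seeds.
    """
    per_method: dict[str, list[float]] = {m: [] for m in methods}
    for s in seeds:
        rep = run_experiment(preset, cfg, methods=methods,
                             distortion=distortion, seed=int(s))
        for _, row in rep.table.iterrows():
            m = row["method"]
            if "CNN" in m:
                per_method[m].append(row["CNN (%)"])
            else:
                per_method[m].append(
                    np.nanmean([row[c] for c in KERNEL_COLUMNS.values()]))
    return {m: float(np.mean(v)) for m, v in per_method.items()}


class CompatibilityError(RuntimeError):
    """Model artifact was produced under an incompatible configuration."""


def run_classify(image, model, cfg: PipelineConfig = PipelineConfig(),
                 expected_hash: str | None = None):
    """Classify a single image with a trained model.

    ``image`` may be a path (loaded and pre-processed) or a [0,1] array.
    ``model`` is a :class:`TrainedKSVM` or :class:`TrainedCNN`.  If
    ``expected_hash`` is given it must equal ``cfg.hash()``.

    Returns ``(label, probability_or_score, artifacts)`` where artifacts
    holds the intermediate working images.
    """
    if expected_hash is not None and expected_hash != cfg.hash():
        raise CompatibilityError(
            f"model config hash {expected_hash} != pipeline hash {cfg.hash()}")
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        image = preprocess_chain(load_image(image))
    img = np.asarray(image, dtype=np.float64)
    artifacts: dict = {"preprocessed": img}

    if isinstance(model, TrainedCNN):
        x = _cnn_input_images([img], cfg)[0]
        artifacts["cnn_input"] = x
        label, probs = predict_cnn(model, x)
        return label, float(probs.max()), artifacts

    if isinstance(model, TrainedKSVM):
        fcfg = method_feature_config(cfg.method if "CNN" not in cfg.method
                                     else "DWT+LPT", cfg.features)
        vec = extract_feature_vector(img, fcfg)
        artifacts["features"] = vec
        label = model.predict(vec[None])[0]
        score = float(model.decision_function(vec[None])[0])
        return label, score, artifacts
    raise TypeError(f"unsupported model type {type(model).__name__}")
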